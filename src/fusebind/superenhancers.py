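"""ROSE-style super-enhancer calling from H3K27ac peaks and coverage.

Peaks within a stitching distance (12.5 kb by default) are merged into
candidate regions; each region is scored by its input-subtracted ChIP signal;
regions are rank-ordered by signal and the super-enhancer cutoff is placed at
the elbow of the scaled signal-vs-rank curve — the point where a line of slope
one is tangent to the hockey stick, found exhaustively as the point lying
furthest below the diagonal.  Regions with signal strictly above the cutoff
are super-enhancers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import (
    BedParseError,
    GenomicInterval,
    _build_trees,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "StitchedRegion",
    "read_bedgraph",
    "write_bedgraph",
    "stitch_peaks",
    "score_region",
    "score_regions",
    "call_superenhancers",
    "se_binding_overlap",
    "compare_site_classes",
    "STITCH_DISTANCE",
]

#: Default stitching distance: peaks within 12.5 kb merge into one region.
STITCH_DISTANCE = 12_500


class CoverageTrack:
    """Per-chromosome non-overlapping step intervals of sequencing depth."""

    def __init__(self, steps: dict[str, np.ndarray] | None = None):
        # each value: float array of shape (n, 3) with columns start, end, depth
        self.steps: dict[str, np.ndarray] = steps or {}

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, depth in records:
            if end <= start:
                raise ValueError(f"empty step {chrom}:{start}-{end}")
            if depth < 0:
                raise ValueError(f"negative depth at {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, depth))
        steps = {}
        for chrom, rows in by_chrom.items():
            arr = np.array(sorted(rows), dtype=float)
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"overlapping steps on {chrom}")
            steps[chrom] = arr
        return cls(steps)

    def total_signal(self, chrom: str, start: int, end: int) -> float:
        """Sum of depth x covered bp over [start, end); uncovered bases are 0."""
        arr = self.steps.get(chrom)
        if arr is None:
            return 0.0
        overlap = np.minimum(arr[:, 1], end) - np.maximum(arr[:, 0], start)
        overlap = np.clip(overlap, 0, None)
        return float(np.sum(overlap * arr[:, 2]))


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a sorted, validated coverage track."""
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    try:
        return CoverageTrack.from_records(records)
    except ValueError as exc:
        raise BedParseError(f"{path}: {exc}") from None


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.steps):
            for start, end, depth in track.steps[chrom]:
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{depth:g}\n")


@dataclass(frozen=True)
class StitchedRegion:
    """A stitched cluster of peaks with input-normalized signal and SE status."""

    interval: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    chip_signal: float = 0.0
    input_signal: float = 0.0
    net_signal: float = 0.0
    rank: int | None = None
    is_super: bool = False


def stitch_peaks(
    peaks: Sequence[GenomicInterval],
    stitch_distance: int = STITCH_DISTANCE,
    tss_exclusion: Sequence[GenomicInterval] | None = None,
) -> list[StitchedRegion]:
    """Merge peaks within ``stitch_distance`` into candidate enhancer regions.

    Merging is transitive on each chromosome: consecutive peaks join when the
    gap between them is at most ``stitch_distance`` (inclusive).  The region
    span is the hull of its constituents.  Peaks wholly inside any
    ``tss_exclusion`` interval (e.g. promoter windows) are dropped before
    stitching, mirroring the optional promoter exclusion of rank-ordering SE
    callers.
    """
    kept = list(peaks)
    if tss_exclusion:
        trees = _build_trees(tss_exclusion)
        kept = [
            p
            for p in kept
            if not any(
                h.begin <= p.start and p.end <= h.end
                for h in (trees.get(p.chrom).overlap(p.start, p.end)
                          if p.chrom in trees else ())
            )
        ]
    regions: list[StitchedRegion] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in kept:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        group: list[GenomicInterval] = []
        hull_end = None
        for p in sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end)):
            if group and p.start - hull_end > stitch_distance:
                regions.append(_make_region(chrom, group))
                group = []
                hull_end = None
            group.append(p)
            hull_end = p.end if hull_end is None else max(hull_end, p.end)
        if group:
            regions.append(_make_region(chrom, group))
    return regions


def _make_region(chrom: str, group: list[GenomicInterval]) -> StitchedRegion:
    start = min(p.start for p in group)
    end = max(p.end for p in group)
    return StitchedRegion(
        interval=GenomicInterval(chrom, start, end),
        constituents=tuple(group),
    )


def score_region(
    region: StitchedRegion, chip: CoverageTrack, input_track: CoverageTrack
) -> StitchedRegion:
    """Input-normalize a region: net = max(chip - input, 0) summed over the span."""
    iv = region.interval
    chip_sig = chip.total_signal(iv.chrom, iv.start, iv.end)
    input_sig = input_track.total_signal(iv.chrom, iv.start, iv.end)
    return replace(
        region,
        chip_signal=chip_sig,
        input_signal=input_sig,
        net_signal=max(chip_sig - input_sig, 0.0),
    )


def score_regions(
    regions: Sequence[StitchedRegion],
    chip: CoverageTrack,
    input_track: CoverageTrack,
) -> list[StitchedRegion]:
    return [score_region(r, chip, input_track) for r in regions]


def call_superenhancers(
    regions: Sequence[StitchedRegion],
) -> list[StitchedRegion]:
    """Rank regions by net signal and flag supers above the tangent cutoff.

    With ranks and signals each scaled to [0, 1] over the ascending signal
    curve, the cutoff sits at the point maximizing (scaled rank - scaled
    signal): the point of the hockey stick furthest below the diagonal, where
    the slope-one tangent touches.  Regions with net signal strictly above the
    cutoff signal are super-enhancers; ties in the maximization resolve toward
    fewer supers.  When all signals are equal the curve has no elbow and no
    region is flagged.
    """
    if len(regions) < 2:
        raise ValueError("super-enhancer calling requires >= 2 regions")
    order = sorted(
        range(len(regions)),
        key=lambda i: (regions[i].net_signal, regions[i].interval.chrom,
                       regions[i].interval.start),
    )
    signals = np.array([regions[i].net_signal for i in order], dtype=float)
    n = len(signals)
    if signals.max() == signals.min():
        warnings.warn("all region signals equal; no super-enhancers called",
                      stacklevel=2)
        cutoff = np.inf
    else:
        x = np.arange(n) / (n - 1)
        y = (signals - signals.min()) / (signals.max() - signals.min())
        gap = x - y
        # ties toward the higher-signal point => fewer supers
        cut_idx = int(np.flatnonzero(gap == gap.max())[-1])
        cutoff = signals[cut_idx]
    out: list[StitchedRegion] = [None] * len(regions)  # type: ignore[list-item]
    for rank_pos, idx in enumerate(order):
        r = regions[idx]
        out[idx] = replace(
            r,
            rank=rank_pos + 1,
            is_super=bool(r.net_signal > cutoff),
        )
    return out


def se_binding_overlap(
    superenhancers: Sequence[StitchedRegion],
    binding_sites: Sequence[GenomicInterval],
) -> tuple[float, list[int]]:
    """Fraction of super-enhancer spans containing >= 1 binding site.

    Returns the fraction and per-SE binding-site counts.
    """
    if not superenhancers:
        raise ValueError("empty super-enhancer set")
    trees = _build_trees(binding_sites)
    counts: list[int] = []
    for se in superenhancers:
        iv = se.interval
        tree = trees.get(iv.chrom)
        counts.append(len(tree.overlap(iv.start, iv.end)) if tree is not None else 0)
    fraction = sum(c > 0 for c in counts) / len(counts)
    return fraction, counts


def compare_site_classes(
    groups: dict[str, Sequence[float]],
) -> tuple[dict[str, float], "pd.DataFrame"]:
    """Group means and all-pairs Tukey HSD on binding-site scores.

    Typical groups are promoter-associated, distal, and SE-associated binding
    sites.  Groups with fewer than 2 members are excluded with a warning.
    Returns per-group means and a tidy frame of pairwise adjusted p-values.
    """
    import pandas as pd

    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    for k in groups:
        if k not in usable:
            warnings.warn(f"group {k!r} has < 2 members; excluded", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need >= 2 groups of >= 2 members")
    names = list(usable)
    means = {k: float(v.mean()) for k, v in usable.items()}
    res = stats.tukey_hsd(*usable.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_difference": means[names[i]] - means[names[j]],
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return means, pd.DataFrame(rows)
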