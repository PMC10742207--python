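"""Trinucleotide repeat-tract scanning and fixed-motif classification.

The scanner looks for microsatellite-like runs of TGA and its reverse
complement TCA inside binding-site sequences: a 3-bp window slides one base at
a time, matched units are chained while the gap between consecutive units stays
within a tolerance, and a chain is recorded as one repeat tract once it
accumulates enough units.  Because {TGA, TCA} is closed under reverse
complementation, tract detection is strand-symmetric by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "ScannerConfig",
    "RepeatTract",
    "MotifHit",
    "MotifClassification",
    "extract_central_window",
    "scan_motif",
    "classify_by_motif",
    "detect_repeat_tracts",
    "repeat_fraction",
    "reverse_complement",
    "CANONICAL_MOTIF",
    "VARIANT_MOTIF",
    "AP1_MOTIF",
]

CANONICAL_MOTIF = "TGACGTCA"   # palindromic ATF/CREB dimer site
VARIANT_MOTIF = "TGANNTCA"     # center-flexible ATF/CREB variant
AP1_MOTIF = "TGAGTCA"          # AP1 (JUN/FOS) heterodimer site

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScannerConfig:
    """Parameters of the repeat-tract scan.

    Defaults follow the published procedure: 3-bp window advanced 1 bp at a
    time over the patterns TGA and TCA, a 5-bp gap tolerance between
    consecutive units, and a minimum of 4 units per recorded tract.  A stricter
    2-bp gap tolerance is also in published use for repeat-prevalence
    summaries; both are supported through ``gap_tolerance``.
    """

    patterns: frozenset[str] = frozenset({"TGA", "TCA"})
    gap_tolerance: int = 5
    threshold: int = 4
    window: int = 3
    step: int = 1

    def __post_init__(self) -> None:
        if self.step < 1 or self.threshold < 1:
            raise ValueError("step and threshold must be >= 1")
        for p in self.patterns:
            if len(p) != self.window:
                raise ValueError(
                    f"pattern {p!r} length differs from window {self.window}"
                )


@dataclass(frozen=True)
class RepeatTract:
    """One detected run of repeat units within a scanned sequence."""

    start: int
    end: int
    occurrences: int
    unit_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.occurrences != len(self.unit_positions):
            raise ValueError("occurrences must equal the number of unit positions")
        if self.end - self.start < 3 * self.occurrences:
            raise ValueError("tract span shorter than its units")


@dataclass(frozen=True)
class MotifHit:
    offset: int
    strand: str
    matched: str


@dataclass(frozen=True)
class MotifClassification:
    """Per-sequence motif flags and the exclusive class label.

    Flags are independent; the exclusive label gives canonical precedence over
    the variant (a canonical hit also matches the variant pattern, so variant
    counts exclude canonical), then AP1, then a repeat tract, then none.
    """

    has_canonical: bool
    has_variant: bool           # any TGANNTCA hit, canonical included
    has_ap1: bool
    has_repeat_tract: bool
    label: str                  # canonical_TGACGTCA | variant_TGANNTCA | AP1_TGAGTCA | repeat_TGA | none


def extract_central_window(
    peak: GenomicInterval,
    genome_sequence: Mapping[str, object],
    width: int = 100,
) -> str:
    """Sequence of ``width`` bp centered on the peak midpoint.

    When the peak length and window parity force a choice, the window is
    biased one base to the left.  Windows wider than the peak are clipped to
    the peak with a warning; the genome mapping is typically a
    :class:`pyfaidx.Fasta`.
    """
    if peak.chrom not in genome_sequence:
        raise KeyError(f"chromosome {peak.chrom!r} missing from genome sequence")
    if width >= len(peak):
        if width > len(peak):
            warnings.warn(
                f"window {width} bp wider than peak "
                f"{peak.chrom}:{peak.start}-{peak.end}; clipped to peak",
                stacklevel=2,
            )
        lo, hi = peak.start, peak.end
    else:
        center = (peak.start + peak.end) // 2  # left-biased for odd lengths
        lo = max(0, center - width // 2)
        hi = lo + width
    return str(genome_sequence[peak.chrom][lo:hi]).upper()


def _iupac_match(seq: str, offset: int, motif: str) -> bool:
    for i, code in enumerate(motif):
        if seq[offset + i] not in IUPAC[code]:
            return False
    return True


def scan_motif(sequence: str, iupac_motif: str) -> list[MotifHit]:
    """All double-stranded matches of an IUPAC motif, one hit per offset.

    An offset matching on both strands (palindromes, or N-rich motifs) is
    reported once, with the forward strand taking precedence.
    """
    motif = iupac_motif.upper()
    for code in motif:
        if code not in IUPAC:
            raise ValueError(f"non-IUPAC character {code!r} in motif")
    seq = sequence.upper()
    rc_motif = reverse_complement(motif)
    hits: list[MotifHit] = []
    m = len(motif)
    for offset in range(len(seq) - m + 1):
        if _iupac_match(seq, offset, motif):
            hits.append(MotifHit(offset, "+", seq[offset : offset + m]))
        elif _iupac_match(seq, offset, rc_motif):
            hits.append(MotifHit(offset, "-", seq[offset : offset + m]))
    return hits


def classify_by_motif(
    peak_sequences: Sequence[str],
    config: ScannerConfig | None = None,
) -> tuple[list[MotifClassification], dict[str, int]]:
    """Classify each sequence by fixed motifs and repeat-tract content.

    Returns per-sequence classifications and exclusive class counts under the
    precedence canonical > variant (excluding canonical) > AP1 > repeat > none.
    """
    config = config or ScannerConfig()
    results: list[MotifClassification] = []
    counts = {
        "canonical_TGACGTCA": 0,
        "variant_TGANNTCA": 0,
        "AP1_TGAGTCA": 0,
        "repeat_TGA": 0,
        "none": 0,
    }
    for seq in peak_sequences:
        has_canonical = bool(scan_motif(seq, CANONICAL_MOTIF))
        has_variant = bool(scan_motif(seq, VARIANT_MOTIF))
        has_ap1 = bool(scan_motif(seq, AP1_MOTIF))
        has_repeat = bool(detect_repeat_tracts(seq, config))
        if has_canonical:
            label = "canonical_TGACGTCA"
        elif has_variant:
            label = "variant_TGANNTCA"
        elif has_ap1:
            label = "AP1_TGAGTCA"
        elif has_repeat:
            label = "repeat_TGA"
        else:
            label = "none"
        counts[label] += 1
        results.append(
            MotifClassification(has_canonical, has_variant, has_ap1, has_repeat, label)
        )
    return results, counts


def detect_repeat_tracts(
    sequence: str, config: ScannerConfig | None = None
) -> list[RepeatTract]:
    """Scan a sequence for repeat tracts of the configured trinucleotides.

    A 3-bp window advances one base at a time; each window matching a pattern
    (TGA or TCA by default; N never matches) is a unit.  Consecutive units
    chain while the gap from the end of one unit to the start of the next is
    at most ``gap_tolerance`` bp.  A larger gap closes the chain and re-seeds
    scanning from the unit that broke it, keeping tracts maximal and
    non-overlapping.  A closed chain is emitted iff it holds at least
    ``threshold`` units.
    """
    config = config or ScannerConfig()
    seq = sequence.upper()
    w, tol, thr = config.window, config.gap_tolerance, config.threshold
    patterns = config.patterns
    tracts: list[RepeatTract] = []
    chain: list[int] = []

    def flush() -> None:
        if len(chain) >= thr:
            tracts.append(
                RepeatTract(
                    start=chain[0],
                    end=chain[-1] + w,
                    occurrences=len(chain),
                    unit_positions=tuple(chain),
                )
            )

    for i in range(0, len(seq) - w + 1, config.step):
        if seq[i : i + w] not in patterns:
            continue
        if chain and i - (chain[-1] + w) > tol:
            flush()
            chain = [i]
        else:
            chain.append(i)
    flush()
    for t in tracts:
        assert t.occurrences >= thr
        assert all(
            b - (a + w) <= tol for a, b in zip(t.unit_positions, t.unit_positions[1:])
        )
    return tracts


def repeat_fraction(
    peak_sequences: Sequence[str],
    other_sequences: Sequence[str] | None = None,
    config: ScannerConfig | None = None,
) -> dict[str, float | None]:
    """Fraction of sequences containing >= 1 repeat tract, with a Welch test.

    When a second sequence set is supplied, the per-sequence binary indicators
    of the two sets are compared by a two-sided unpaired (Welch) t-test.
    """
    config = config or ScannerConfig()

    def indicators(seqs: Sequence[str]) -> np.ndarray:
        return np.array(
            [bool(detect_repeat_tracts(s, config)) for s in seqs], dtype=float
        )

    ind_a = indicators(peak_sequences)
    out: dict[str, float | None] = {
        "fraction": float(ind_a.mean()) if len(ind_a) else float("nan"),
        "other_fraction": None,
        "t_statistic": None,
        "p_value": None,
    }
    if other_sequences is None:
        return out
    ind_b = indicators(other_sequences)
    out["other_fraction"] = float(ind_b.mean()) if len(ind_b) else float("nan")
    if len(ind_a) < 2 or len(ind_b) < 2:
        warnings.warn("fewer than 2 sequences in a set; t-test skipped", stacklevel=2)
        return out
    t, p = stats.ttest_ind(ind_a, ind_b, equal_var=False)
    if np.isnan(t):  # identical constant indicators: no detectable difference
        t, p = 0.0, 1.0
    out["t_statistic"], out["p_value"] = float(t), float(p)
    return out
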