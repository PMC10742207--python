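"""Genome-interval data model, BED/GTF I/O, overlap arithmetic, and peak annotation.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  GTF input
(1-based, closed) is converted on read.  Overlap is defined as sharing at least
one base on the same chromosome and is strand-blind throughout, because ChIP-seq
peak calls carry no strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PeakAnnotation",
    "GeneAssignment",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "intersect_intervals",
    "consensus_sites",
    "annotate_peak_location",
    "annotate_peaks",
    "nearest_genes",
    "map_peaks_to_promoters",
    "three_way_overlap_counts",
    "PROMOTER_HALFWIDTH",
    "NEAREST_GENE_MAX_DISTANCE",
]

#: Promoter window half-width: a site within +/- 3 kb of a TSS is promoter-associated.
PROMOTER_HALFWIDTH = 3000
#: Distance cap for GREAT-style nearest-two-gene assignment.
NEAREST_GENE_MAX_DISTANCE = 500_000


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph/gene-table lines; message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genome region with optional name, score and strand.

    ``start`` is 0-based inclusive, ``end`` exclusive.  ``score`` is a
    non-negative enrichment value (ChIP-seq peak significance or signal).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least one shared base on the same chromosome (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-resolved transcription start site.

    The TSS is the first transcribed base: ``gene_start`` on the + strand and
    ``gene_end - 1`` on the - strand.  ``tes`` is the last transcribed base.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.gene_start >= self.gene_end:
            raise ValueError(
                f"gene_start must be < gene_end for {self.gene_id}: "
                f"[{self.gene_start}, {self.gene_end})"
            )

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1

    @property
    def tes(self) -> int:
        return self.gene_end - 1 if self.strand == "+" else self.gene_start

    def promoter_window(self, halfwidth: int = PROMOTER_HALFWIDTH) -> tuple[int, int]:
        """Half-open window of bases within ``halfwidth`` bp of the TSS."""
        return max(0, self.tss - halfwidth), self.tss + halfwidth + 1

    def signed_distance(self, position: int) -> int:
        """Signed bp from TSS to ``position`` in gene orientation (negative = upstream)."""
        d = position - self.tss
        return d if self.strand == "+" else -d


@dataclass(frozen=True)
class PeakAnnotation:
    """Location category of a single peak relative to gene models."""

    peak: GenomicInterval
    category: Literal["promoter", "intragenic", "intergenic"]
    nearest_gene: str | None
    distance_to_tss: int | None


@dataclass(frozen=True)
class GeneAssignment:
    """GREAT-style assignment of a peak to its nearest (up to two) genes."""

    peak: GenomicInterval
    genes: tuple[str, ...]
    distances: tuple[int, ...]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving input order.

    Columns 4-6 (name, score, strand) populate the optional fields when
    present.  A score of "." is treated as absent.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: malformed coordinate: {exc}"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(
                        f"{path}:{lineno}: malformed score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return intervals


def _format_score(score: float | None) -> str:
    if score is None:
        return "."
    return f"{score:g}"


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6; round-trips through :func:`read_bed` losslessly."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{_format_score(iv.score)}\t{iv.strand}\n"
            )


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(
    path: str | Path, format: Literal["gtf", "tsv"] = "gtf"
) -> list[GeneModel]:
    """Read gene models from GTF ``gene`` features or a 5-column gene TSV.

    GTF is 1-based closed and converted to 0-based half-open on read.  The TSV
    format has columns gene_id, chrom, strand, start, end with 0-based
    half-open coordinates (a header line starting with ``gene_id`` is skipped).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "gtf":
                    if len(fields) < 9:
                        raise BedParseError(
                            f"{path}:{lineno}: expected 9 GTF columns"
                        )
                    if fields[2] != "gene":
                        continue
                    m = _GTF_GENE_ID.search(fields[8])
                    if m is None:
                        raise BedParseError(
                            f"{path}:{lineno}: missing gene_id attribute"
                        )
                    genes.append(
                        GeneModel(
                            gene_id=m.group(1),
                            chrom=fields[0],
                            strand=fields[6],
                            gene_start=int(fields[3]) - 1,
                            gene_end=int(fields[4]),
                        )
                    )
                else:
                    if fields[0] == "gene_id":
                        continue
                    if len(fields) < 5:
                        raise BedParseError(
                            f"{path}:{lineno}: expected 5 gene-table columns"
                        )
                    genes.append(
                        GeneModel(
                            gene_id=fields[0],
                            chrom=fields[1],
                            strand=fields[2],
                            gene_start=int(fields[3]),
                            gene_end=int(fields[4]),
                        )
                    )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_models_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GTF ``gene`` features."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tfusebind\tgene\t{g.gene_start + 1}\t{g.gene_end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Overlap arithmetic
# ---------------------------------------------------------------------------

def _build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def intersect_intervals(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    mode: Literal["report_a_overlapping_b", "report_overlap_segments"] = "report_a_overlapping_b",
) -> list[GenomicInterval]:
    """Strand-blind overlap of two interval sets.

    ``report_a_overlapping_b`` returns each a-interval with >= 1 bp overlap with
    any b-interval, at most once.  ``report_overlap_segments`` returns the
    pairwise intersection segments.  Output sorted by (chrom, start, end).
    """
    trees = _build_trees(b)
    out: list[GenomicInterval] = []
    if mode == "report_a_overlapping_b":
        for iv in a:
            tree = trees.get(iv.chrom)
            if tree is not None and tree.overlaps(iv.start, iv.end):
                out.append(iv)
    elif mode == "report_overlap_segments":
        for iv in a:
            tree = trees.get(iv.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                out.append(
                    GenomicInterval(
                        iv.chrom, max(iv.start, hit.begin), min(iv.end, hit.end)
                    )
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sorted(out, key=_sort_key)


def consensus_sites(
    sets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Intervals of the first set overlapping >= 1 interval in every other set.

    This is the iterated report-a intersection used to derive consensus binding
    sites from replicate or multi-antibody peak sets.
    """
    if len(sets) < 2:
        raise ValueError("consensus requires at least 2 interval sets")
    current = list(sets[0])
    for other in sets[1:]:
        current = intersect_intervals(current, other, "report_a_overlapping_b")
    return current


def three_way_overlap_counts(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    set_c: Sequence[GenomicInterval],
) -> dict[str, dict[str, int]]:
    """Venn-style membership tallies for three peak sets.

    For each anchor set, every interval is classified by which of the other two
    sets it overlaps (by >= 1 bp), giving four mutually exclusive pattern counts
    per anchor.  Membership is per anchor interval, so the three tallies need
    not agree on shared-region sizes when overlaps are many-to-many.
    """
    names = ("A", "B", "C")
    sets = {"A": set_a, "B": set_b, "C": set_c}
    trees = {n: _build_trees(sets[n]) for n in names}
    result: dict[str, dict[str, int]] = {}
    for anchor in names:
        others = [n for n in names if n != anchor]
        counts = {
            f"{anchor}_only": 0,
            f"{anchor}{others[0]}": 0,
            f"{anchor}{others[1]}": 0,
            f"{anchor}{others[0]}{others[1]}": 0,
        }
        for iv in sets[anchor]:
            pattern = anchor
            for other in others:
                tree = trees[other].get(iv.chrom)
                if tree is not None and tree.overlaps(iv.start, iv.end):
                    pattern += other
            key = f"{anchor}_only" if pattern == anchor else pattern
            counts[key] += 1
        result[anchor] = counts
    return result


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

class GeneIndex:
    """Chromosome-indexed gene models with promoter and gene-body trees."""

    def __init__(
        self, genes: Sequence[GeneModel], promoter_halfwidth: int = PROMOTER_HALFWIDTH
    ):
        self.genes = list(genes)
        self.promoter_halfwidth = promoter_halfwidth
        self.by_chrom: dict[str, list[GeneModel]] = {}
        self._promoters: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
            lo, hi = g.promoter_window(promoter_halfwidth)
            self._promoters.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(
                g.gene_start, g.gene_end, g
            )

    def promoter_hits(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._promoters.get(iv.chrom)
        if tree is None:
            return []
        return sorted((h.data for h in tree.overlap(iv.start, iv.end)),
                      key=lambda g: g.gene_id)

    def body_hits(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._bodies.get(iv.chrom)
        if tree is None:
            return []
        return sorted((h.data for h in tree.overlap(iv.start, iv.end)),
                      key=lambda g: g.gene_id)

    def nearest_by_tss(self, iv: GenomicInterval) -> GeneModel | None:
        candidates = self.by_chrom.get(iv.chrom)
        if not candidates:
            return None
        mid = iv.midpoint
        return min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))


def annotate_peak_location(
    peak: GenomicInterval,
    genes: GeneIndex | Sequence[GeneModel],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> PeakAnnotation:
    """Classify a peak as promoter, intragenic or intergenic.

    A peak overlapping the +/- ``promoter_halfwidth`` window of any TSS is
    promoter-associated; promoter takes precedence over gene-body overlap, so
    the three categories partition any peak set.  The nearest gene is the one
    minimizing |peak midpoint - TSS|; its distance is signed in gene
    orientation (negative = upstream of the TSS).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_halfwidth)
    if index.promoter_halfwidth != promoter_halfwidth:
        index = GeneIndex(index.genes, promoter_halfwidth)
    if peak.chrom not in index.by_chrom:
        logger.warning(
            "peak %s:%d-%d on chromosome absent from annotation; intergenic",
            peak.chrom, peak.start, peak.end,
        )
        return PeakAnnotation(peak, "intergenic", None, None)
    if index.promoter_hits(peak):
        category = "promoter"
    elif index.body_hits(peak):
        category = "intragenic"
    else:
        category = "intergenic"
    nearest = index.nearest_by_tss(peak)
    assert nearest is not None
    return PeakAnnotation(
        peak, category, nearest.gene_id, nearest.signed_distance(peak.midpoint)
    )


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel] | GeneIndex,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> list[PeakAnnotation]:
    """Annotate every peak; categories partition the peak set."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_halfwidth)
    return [annotate_peak_location(p, index, promoter_halfwidth) for p in peaks]


def nearest_genes(
    peak: GenomicInterval,
    genes: GeneIndex | Sequence[GeneModel],
    max_distance: int = NEAREST_GENE_MAX_DISTANCE,
    k: int = 2,
) -> GeneAssignment:
    """GREAT-style assignment to the nearest up-to-``k`` genes within ``max_distance``.

    Genes are ranked by |peak midpoint - TSS| with lexicographic gene_id
    tie-breaking; distances are signed in gene orientation.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    candidates = index.by_chrom.get(peak.chrom, [])
    mid = peak.midpoint
    ranked = sorted(
        (g for g in candidates if abs(mid - g.tss) <= max_distance),
        key=lambda g: (abs(mid - g.tss), g.gene_id),
    )[:k]
    return GeneAssignment(
        peak,
        tuple(g.gene_id for g in ranked),
        tuple(g.signed_distance(mid) for g in ranked),
    )


def map_peaks_to_promoters(
    peaks: Sequence[GenomicInterval],
    genes: GeneIndex | Sequence[GeneModel],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> tuple[list[tuple[GenomicInterval, str]], int]:
    """All (peak, gene) promoter-overlap pairs plus the unique-gene count.

    A peak may hit several promoters and a promoter may host several peaks,
    so the pair count can exceed both the peak and the gene tallies.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_halfwidth)
    if index.promoter_halfwidth != promoter_halfwidth:
        index = GeneIndex(index.genes, promoter_halfwidth)
    pairs: list[tuple[GenomicInterval, str]] = []
    for peak in peaks:
        for gene in index.promoter_hits(peak):
            pairs.append((peak, gene.gene_id))
    unique_genes = len({gene_id for _, gene_id in pairs})
    return pairs, unique_genes
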