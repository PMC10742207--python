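"""Chain-based interval liftover and reciprocal cross-species SE matching.

Coordinate translation follows the UCSC chain conventions: each chain aligns
blocks of a source assembly to a target assembly; negative target strands are
expressed in reverse-strand coordinates and flipped against the target
chromosome size on output.  An interval maps when a sufficient fraction of its
bases fall inside aligned blocks and all mapped bases agree on one target
chromosome.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .intervals import GeneModel, GenomicInterval, GeneIndex

logger = logging.getLogger(__name__)

__all__ = [
    "ChainAlignment",
    "ChainParseError",
    "LiftoverResult",
    "SyntenyMatch",
    "read_chain",
    "write_chain",
    "liftover_interval",
    "match_syntenic_ses",
    "orientation_distance_table",
    "MIN_MATCH",
]

#: Default minimum fraction of interval bases that must map (liftOver default).
MIN_MATCH = 0.95


class ChainParseError(ValueError):
    pass


@dataclass(frozen=True)
class ChainAlignment:
    """One chain: blockwise gapped alignment from source to target assembly."""

    score: float
    source_chrom: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    # (block_size, gap_after_in_source, gap_after_in_target); gaps of the
    # final block are zero.
    blocks: tuple[tuple[int, int, int], ...]
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if self.source_strand not in "+-" or self.target_strand not in "+-":
            raise ValueError("chain strands must be + or -")
        src_span = sum(b[0] + b[1] for b in self.blocks)
        tgt_span = sum(b[0] + b[2] for b in self.blocks)
        if src_span != self.source_end - self.source_start:
            raise ValueError(
                f"chain source span mismatch: blocks cover {src_span}, "
                f"header spans {self.source_end - self.source_start}"
            )
        if tgt_span != self.target_end - self.target_start:
            raise ValueError(
                f"chain target span mismatch: blocks cover {tgt_span}, "
                f"header spans {self.target_end - self.target_start}"
            )


def read_chain(path: str | Path) -> list[ChainAlignment]:
    """Parse a UCSC chain file, validating block bookkeeping against headers."""
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def close(lineno: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise ChainParseError(
                f"{path}:{lineno}: chain truncated (missing final bare-size line)"
            )
        try:
            chains.append(
                ChainAlignment(
                    score=float(header[1]),
                    source_chrom=header[2],
                    source_size=int(header[3]),
                    source_strand=header[4],
                    source_start=int(header[5]),
                    source_end=int(header[6]),
                    target_chrom=header[7],
                    target_size=int(header[8]),
                    target_strand=header[9],
                    target_start=int(header[10]),
                    target_end=int(header[11]),
                    blocks=tuple(blocks),
                    chain_id=header[12] if len(header) > 12 else None,
                )
            )
        except ValueError as exc:
            raise ChainParseError(f"{path}:{lineno}: {exc}") from None
        header, blocks = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if header is not None:
                    close(lineno)
                header = line.split()
                if len(header) < 12:
                    raise ChainParseError(
                        f"{path}:{lineno}: chain header has too few fields"
                    )
                blocks = []
            else:
                if header is None:
                    raise ChainParseError(
                        f"{path}:{lineno}: alignment line outside a chain"
                    )
                parts = line.split()
                if len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ChainParseError(
                        f"{path}:{lineno}: expected 1 or 3 alignment fields"
                    )
        close(lineno)
    return chains


def write_chain(chains: Sequence[ChainAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(chains, start=1):
            cid = c.chain_id or str(i)
            fh.write(
                f"chain {c.score:g} {c.source_chrom} {c.source_size} "
                f"{c.source_strand} {c.source_start} {c.source_end} "
                f"{c.target_chrom} {c.target_size} {c.target_strand} "
                f"{c.target_start} {c.target_end} {cid}\n"
            )
            for size, dsrc, dtgt in c.blocks[:-1]:
                fh.write(f"{size} {dsrc} {dtgt}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


@dataclass(frozen=True)
class LiftoverResult:
    """Outcome of lifting one interval; ``mapped`` is None when unmapped."""

    source: GenomicInterval
    mapped: GenomicInterval | None
    mapped_fraction: float
    target_strand: str | None = None
    reason: str | None = None


def _iter_block_coords(chain: ChainAlignment):
    """Yield (src_start, src_end, tgt_start) per block in chain coordinates."""
    src = chain.source_start
    tgt = chain.target_start
    for size, dsrc, dtgt in chain.blocks:
        yield src, src + size, tgt
        src += size + dsrc
        tgt += size + dtgt


def liftover_interval(
    interval: GenomicInterval,
    chains: Sequence[ChainAlignment],
    min_match: float = MIN_MATCH,
) -> LiftoverResult:
    """Map an interval through chain alignments.

    Every base inside an aligned block translates through the block offset;
    negative target strands flip against the target chromosome size.  Chains
    are consulted in descending score order and each base is claimed by the
    first chain covering it.  The result is the hull of mapped bases on the
    majority target chromosome/strand; the interval is unmapped when the
    mapped fraction falls below ``min_match`` or mapped bases split across
    target chromosomes.
    """
    length = len(interval)
    # per-base segment maps: (target_chrom, target_strand, tgt_lo, tgt_hi)
    segments: list[tuple[str, str, int, int]] = []
    claimed: list[tuple[int, int]] = []  # source sub-intervals already mapped

    def unclaimed(lo: int, hi: int) -> list[tuple[int, int]]:
        pieces = [(lo, hi)]
        for c_lo, c_hi in claimed:
            nxt = []
            for p_lo, p_hi in pieces:
                if c_hi <= p_lo or c_lo >= p_hi:
                    nxt.append((p_lo, p_hi))
                else:
                    if p_lo < c_lo:
                        nxt.append((p_lo, c_lo))
                    if c_hi < p_hi:
                        nxt.append((c_hi, p_hi))
            pieces = nxt
        return pieces

    for chain in sorted(chains, key=lambda c: -c.score):
        if chain.source_chrom != interval.chrom:
            continue
        for b_src_lo, b_src_hi, b_tgt_lo in _iter_block_coords(chain):
            lo = max(interval.start, b_src_lo)
            hi = min(interval.end, b_src_hi)
            if lo >= hi:
                continue
            for p_lo, p_hi in unclaimed(lo, hi):
                off_lo = p_lo - b_src_lo
                off_hi = p_hi - b_src_lo
                if chain.target_strand == "+":
                    t_lo = b_tgt_lo + off_lo
                    t_hi = b_tgt_lo + off_hi
                else:
                    # reverse-strand chain coordinates -> forward coordinates
                    t_hi = chain.target_size - (b_tgt_lo + off_lo)
                    t_lo = chain.target_size - (b_tgt_lo + off_hi)
                segments.append(
                    (chain.target_chrom, chain.target_strand, t_lo, t_hi)
                )
                claimed.append((p_lo, p_hi))

    mapped_bases = sum(hi - lo for _, _, lo, hi in segments)
    fraction = mapped_bases / length
    if mapped_bases == 0:
        return LiftoverResult(interval, None, 0.0, reason="no aligned bases")
    chrom_votes = Counter()
    for chrom, strand, lo, hi in segments:
        chrom_votes[(chrom, strand)] += hi - lo
    (maj_chrom, maj_strand), maj_bases = chrom_votes.most_common(1)[0]
    if len({chrom for chrom, _, _, _ in segments}) > 1:
        return LiftoverResult(
            interval, None, fraction, reason="split across target chromosomes"
        )
    if fraction < min_match:
        return LiftoverResult(
            interval, None, fraction,
            reason=f"mapped fraction {fraction:.3f} < min_match {min_match}",
        )
    maj_segments = [s for s in segments if (s[0], s[1]) == (maj_chrom, maj_strand)]
    hull_lo = min(lo for _, _, lo, _ in maj_segments)
    hull_hi = max(hi for _, _, _, hi in maj_segments)
    return LiftoverResult(
        interval,
        GenomicInterval(maj_chrom, hull_lo, hull_hi, name=interval.name,
                        score=interval.score),
        fraction,
        target_strand=maj_strand,
    )


@dataclass(frozen=True)
class SyntenyMatch:
    """A cross-species SE correspondence found by liftover overlap."""

    se_a: GenomicInterval
    se_b: GenomicInterval
    direction: str  # "A->B" or "B->A"
    mapped_interval: GenomicInterval
    reciprocal: bool


def match_syntenic_ses(
    ses_a: Sequence[GenomicInterval],
    ses_b: Sequence[GenomicInterval],
    chain_a_to_b: Sequence[ChainAlignment],
    chain_b_to_a: Sequence[ChainAlignment],
    min_match: float = MIN_MATCH,
) -> tuple[list[SyntenyMatch], dict[str, int]]:
    """Reciprocal SE synteny: lift each species' SEs onto the other and overlap.

    A pair is reciprocal when the A-SE lifts onto the B-SE and that B-SE lifts
    back onto the same A-SE.  Matching is many-to-many, so the distinct
    matched-SE counts may differ between the species.
    """
    from .intervals import _build_trees

    trees_b = _build_trees(ses_b)
    trees_a = _build_trees(ses_a)

    def lift_hits(ses, chains, trees):
        hits = set()
        for se in ses:
            res = liftover_interval(se, chains, min_match)
            if res.mapped is None:
                continue
            tree = trees.get(res.mapped.chrom)
            if tree is None:
                continue
            for h in tree.overlap(res.mapped.start, res.mapped.end):
                hits.add((se, h.data, res.mapped))
        return hits

    ab = lift_hits(ses_a, chain_a_to_b, trees_b)
    ba = lift_hits(ses_b, chain_b_to_a, trees_a)
    ab_pairs = {(a, b) for a, b, _ in ab}
    ba_pairs = {(a, b) for b, a, _ in ba}
    reciprocal_pairs = ab_pairs & ba_pairs

    matches: list[SyntenyMatch] = []
    for a, b, mapped in sorted(ab, key=lambda t: (t[0].chrom, t[0].start,
                                                  t[1].chrom, t[1].start)):
        matches.append(SyntenyMatch(a, b, "A->B", mapped, (a, b) in reciprocal_pairs))
    for b, a, mapped in sorted(ba, key=lambda t: (t[0].chrom, t[0].start,
                                                  t[1].chrom, t[1].start)):
        matches.append(SyntenyMatch(a, b, "B->A", mapped, (a, b) in reciprocal_pairs))

    summary = {
        "a_to_b_matches": len(ab_pairs),
        "b_to_a_matches": len(ba_pairs),
        "reciprocal_pairs": len(reciprocal_pairs),
        "matched_ses_a": len({a for a, _ in ab_pairs | ba_pairs}),
        "matched_ses_b": len({b for _, b in ab_pairs | ba_pairs}),
        "reciprocal_ses_a": len({a for a, _ in reciprocal_pairs}),
        "reciprocal_ses_b": len({b for _, b in reciprocal_pairs}),
    }
    return matches, summary


def orientation_distance_table(
    matches: Sequence[SyntenyMatch],
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    homologs: dict[str, str],
) -> "pd.DataFrame":
    """Signed TSS-to-SE distances per species for reciprocal SE matches.

    For each reciprocal match the nearest gene by TSS is found in each
    species; homologous gene pairs get a ``same_orientation`` flag (signs of
    the two signed distances agree).  Rows whose nearest genes are not
    homologs are emitted flagged ``non-homologous`` and excluded from
    orientation tallies downstream.
    """
    import pandas as pd

    index_a = GeneIndex(genes_a)
    index_b = GeneIndex(genes_b)
    rows = []
    seen = set()
    for m in matches:
        if not m.reciprocal:
            continue
        key = (m.se_a, m.se_b)
        if key in seen:
            continue
        seen.add(key)
        ga = index_a.nearest_by_tss(m.se_a)
        gb = index_b.nearest_by_tss(m.se_b)
        if ga is None or gb is None:
            continue
        dist_a = ga.signed_distance(m.se_a.midpoint)
        dist_b = gb.signed_distance(m.se_b.midpoint)
        homologous = homologs.get(ga.gene_id) == gb.gene_id
        rows.append(
            {
                "gene_a": ga.gene_id,
                "gene_b": gb.gene_id,
                "distance_a": dist_a,
                "distance_b": dist_b,
                "homologous": homologous,
                "same_orientation": (
                    (dist_a >= 0) == (dist_b >= 0) if homologous else None
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "distance_a", "distance_b",
                 "homologous", "same_orientation"],
    )
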