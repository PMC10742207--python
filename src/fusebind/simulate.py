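"""Seeded synthetic-data generators with machine-readable ground truth.

Every input the pipeline consumes can be generated here with planted, recorded
features: peak sets with controlled promoter/intragenic/intergenic
proportions, binding-site sequences with planted motifs and repeat tracts,
H3K27ac-like coverage with a hockey-stick signal distribution containing
planted super-enhancers, a derived second "species" with exact chain files and
a homolog table, and three differential-expression tables with a planted
shared-DEG core plus chromatin loops wired from super-enhancers to promoters.

Generators are pure functions of their configuration (including the seed):
the same config yields byte-identical output files.  Planted motifs overwrite
genome bases in place, so downstream coordinates never shift, and peak
windows are scrubbed of chance motif/tract occurrences before planting so
categorical ground truth is exact rather than statistical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import (
    GeneModel,
    GenomicInterval,
    write_bed,
    write_gene_models_gtf,
)
from .repeats import (
    AP1_MOTIF,
    CANONICAL_MOTIF,
    ScannerConfig,
    VARIANT_MOTIF,
    detect_repeat_tracts,
    scan_motif,
)
from .superenhancers import CoverageTrack, write_bedgraph
from .synteny import ChainAlignment, write_chain

__all__ = [
    "SimulationConfig",
    "gen_genome_and_genes",
    "gen_peaks_with_sequences",
    "gen_coverage",
    "gen_species_pair",
    "gen_de_tables_and_loops",
    "gen_promoter_binding_layout",
    "simulate_all",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults emulating the real one.

    Category proportions default to the observed genomic distribution of
    fusion-protein binding sites (34.7% promoter, 36.5% intragenic, 28.8%
    intergenic); motif planting rates default to the observed motif-class
    fractions of the 21,237-site set; the planted super-enhancer layout uses
    500 background regions with exponential signal and 20 high-signal supers;
    the shared-DEG core defaults to 432 up and 194 down genes.
    """

    seed: int = 0
    # genome & genes
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_600_000, "chr2": 1_000_000}
    )
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (4_000, 5_600)
    gene_slot: int = 12_000  # one gene per slot keeps promoters separable
    # peaks
    n_peaks: int = 1_000
    category_proportions: tuple[float, float, float] = (0.347, 0.365, 0.288)
    peak_length_range: tuple[int, int] = (150, 400)
    central_window: int = 100
    # motif planting rates (exclusive classes; remainder is "none")
    canonical_rate: float = 0.060
    variant_rate: float = 0.276   # TGANNTCA instances other than the canonical
    ap1_rate: float = 0.129
    repeat_prevalence: float = 0.30
    tract_units_range: tuple[int, int] = (4, 12)
    scanner: ScannerConfig = field(default_factory=ScannerConfig)
    # super-enhancer coverage
    n_background_regions: int = 500
    n_super_regions: int = 20
    background_signal_mean: float = 1.0       # exponential mean
    super_signal_mean: float = 50.0
    super_signal_sd: float = 5.0
    region_width: int = 2_000
    region_spacing: int = 20_000              # > stitch distance
    input_depth: float = 1.0
    # species pair / chains
    block_length_range: tuple[int, int] = (40_000, 80_000)
    inversion_rate: float = 0.15
    insertion_range: tuple[int, int] = (0, 500)
    deletion_range: tuple[int, int] = (0, 500)
    n_syntenic_se_pairs: int = 50
    n_decoy_ses_a: int = 10
    n_decoy_ses_b: int = 10
    se_width: int = 2_000
    # differential expression & loops
    n_expression_genes: int = 10_772
    n_shared_up: int = 432
    n_shared_down: int = 194
    n_private_up: int = 150
    n_private_down: int = 150
    n_looped_genes: int = 20
    n_looped_up: int = 5
    n_looped_down: int = 2
    n_decoy_loops: int = 15
    loop_anchor_width: int = 1_000

    def __post_init__(self) -> None:
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if any(p < 0 for p in self.category_proportions):
            raise ValueError("category proportions must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# genome & genes
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, bytearray], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = bytes(genome[chrom]).decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gen_genome_and_genes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, bytearray], list[GeneModel], dict]:
    """Random uniform-base chromosomes with non-overlapping, well-spaced genes.

    Each gene sits in its own slot with >= 3.2 kb clearance to the slot edges,
    so promoter windows of neighboring genes never merge and intragenic and
    intergenic space both remain available for peak placement.
    """
    rng = rng or config.rng()
    genome: dict[str, bytearray] = {}
    for chrom, length in config.chrom_lengths.items():
        genome[chrom] = bytearray(
            _BASES[rng.integers(0, 4, size=length)].tobytes()
        )
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_lengths.items():
        slots.extend((chrom, s) for s in range(0, length - config.gene_slot + 1,
                                               config.gene_slot))
    if config.n_genes > len(slots):
        raise ValueError(
            f"cannot place {config.n_genes} genes in {len(slots)} slots; "
            "increase chrom_lengths or reduce n_genes/gene_slot"
        )
    chosen = rng.choice(len(slots), size=config.n_genes, replace=False)
    genes: list[GeneModel] = []
    margin = 3_200  # leaves promoter windows inside the slot
    for i, slot_idx in enumerate(sorted(chosen)):
        chrom, slot_start = slots[slot_idx]
        lo, hi = config.gene_length_range
        max_len = min(hi, config.gene_slot - 2 * margin)
        length = int(rng.integers(lo, max_len + 1))
        offset = int(rng.integers(margin, config.gene_slot - margin - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"G{i:04d}",
                chrom=chrom,
                strand=strand,
                gene_start=slot_start + offset,
                gene_end=slot_start + offset + length,
            )
        )
    truth = {
        "chrom_lengths": dict(config.chrom_lengths),
        "genes": [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
             "start": g.gene_start, "end": g.gene_end, "tss": g.tss}
            for g in genes
        ],
    }
    return genome, genes, truth


# ---------------------------------------------------------------------------
# peaks with planted sequence features
# ---------------------------------------------------------------------------

def _subtract(segments: list[tuple[int, int]], cut: tuple[int, int]) -> list[tuple[int, int]]:
    out = []
    for lo, hi in segments:
        if cut[1] <= lo or cut[0] >= hi:
            out.append((lo, hi))
        else:
            if lo < cut[0]:
                out.append((lo, cut[0]))
            if cut[1] < hi:
                out.append((cut[1], hi))
    return out


def _sample_from_segments(
    segments: list[tuple[int, int]], length: int, rng: np.random.Generator
) -> int | None:
    eligible = [(lo, hi) for lo, hi in segments if hi - lo >= length]
    if not eligible:
        return None
    weights = np.array([hi - lo - length + 1 for lo, hi in eligible], dtype=float)
    idx = rng.choice(len(eligible), p=weights / weights.sum())
    lo, hi = eligible[idx]
    return int(rng.integers(lo, hi - length + 1))


def _scrub_window(
    window: bytearray,
    planted: list[tuple[int, int]],
    expected: dict[str, set[int]],
    expected_tracts: list[tuple[int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Mutate bases until the window's motif/tract content equals the plan.

    Only bases outside the planted spans are mutated, so planted features
    survive; the loop removes both pre-existing chance occurrences and
    occurrences created at planting junctions.
    """
    motifs = {
        "canonical": CANONICAL_MOTIF,
        "variant": VARIANT_MOTIF,
        "ap1": AP1_MOTIF,
    }
    for _ in range(400):
        seq = bytes(window).decode()
        offending: list[tuple[int, int]] = []
        for name, motif in motifs.items():
            for hit in scan_motif(seq, motif):
                if hit.offset not in expected[name]:
                    offending.append((hit.offset, hit.offset + len(motif)))
        for tract in detect_repeat_tracts(seq, config.scanner):
            if (tract.start, tract.end) not in expected_tracts:
                offending.append((tract.start, tract.end))
        if not offending:
            return
        lo, hi = offending[0]
        free = [
            p for p in range(lo, hi)
            if not any(a <= p < b for a, b in planted)
        ]
        if not free:  # offending span inside planted content: plan conflict
            raise RuntimeError("planted features conflict; cannot scrub window")
        pos = free[int(rng.integers(len(free)))]
        old = window[pos]
        choices = [b for b in b"ACGT" if b != old]
        window[pos] = choices[int(rng.integers(3))]
    raise RuntimeError("window scrubbing did not converge")


def _variant_instance(rng: np.random.Generator) -> str:
    """A TGANNTCA instance other than the canonical TGACGTCA."""
    while True:
        nn = "".join(chr(_BASES[int(rng.integers(4))]) for _ in range(2))
        if nn != "CG":
            return f"TGA{nn}TCA"


def gen_peaks_with_sequences(
    config: SimulationConfig,
    genome: dict[str, bytearray],
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomicInterval], dict]:
    """Place peaks per category proportions and plant sequence features.

    Placement enforces the categories definitionally: promoter peaks overlap a
    TSS +/- 3 kb window, intragenic peaks lie inside a gene body but outside
    every promoter window, intergenic peaks avoid both.  Motifs and repeat
    tracts are planted into the central window of each peak after the window
    is scrubbed of chance occurrences, so the recorded labels are exact ground
    truth.  Planting overwrites bases in-place in ``genome``.
    """
    rng = rng or config.rng()
    n = config.n_peaks
    props = config.category_proportions
    counts = [int(np.floor(p * n)) for p in props]
    for i in range(n - sum(counts)):  # distribute remainder deterministically
        counts[i % 3] += 1
    categories = (["promoter"] * counts[0] + ["intragenic"] * counts[1]
                  + ["intergenic"] * counts[2])

    promoter_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    body_segments: list[tuple[str, list[tuple[int, int]]]] = []
    for g in genes:
        promoter_windows[g.chrom].append(g.promoter_window())
    for g in genes:
        segs = [(g.gene_start, g.gene_end)]
        for w in promoter_windows[g.chrom]:
            segs = _subtract(segs, w)
        body_segments.append((g.chrom, segs))
    free_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in ((c, len(s)) for c, s in genome.items()):
        segs = [(0, length)]
        for w in promoter_windows[chrom]:
            segs = _subtract(segs, w)
        for g in genes:
            if g.chrom == chrom:
                segs = _subtract(segs, (g.gene_start, g.gene_end))
        free_by_chrom[chrom] = segs

    placed: dict[str, IntervalTree] = {c: IntervalTree() for c in genome}
    pad = 60

    def try_place(chrom: str, start: int, length: int) -> GenomicInterval | None:
        if start < 0 or start + length > len(genome[chrom]):
            return None
        if placed[chrom].overlaps(start - pad, start + length + pad):
            return None
        placed[chrom].addi(start, start + length)
        return GenomicInterval(chrom, start, start + length)

    peaks: list[GenomicInterval] = []
    peak_truth: list[dict] = []
    gene_list = list(genes)
    lo_len, hi_len = config.peak_length_range

    for category in categories:
        iv = None
        for _ in range(3_000):
            length = int(rng.integers(lo_len, hi_len + 1))
            if category == "promoter":
                g = gene_list[int(rng.integers(len(gene_list)))]
                center = g.tss + int(rng.integers(-2_500, 2_501))
                iv = try_place(g.chrom, center - length // 2, length)
            elif category == "intragenic":
                chrom, segs = body_segments[int(rng.integers(len(body_segments)))]
                start = _sample_from_segments(segs, length, rng)
                iv = try_place(chrom, start, length) if start is not None else None
            else:
                chrom = list(genome)[int(rng.integers(len(genome)))]
                start = _sample_from_segments(free_by_chrom[chrom], length, rng)
                iv = try_place(chrom, start, length) if start is not None else None
            if iv is not None:
                break
        if iv is None:
            raise RuntimeError(
                f"could not place a {category} peak; reduce n_peaks or "
                "grow chrom_lengths"
            )
        peaks.append(iv)
        peak_truth.append({"category": category})

    # assign motif classes and tracts, then plant
    u = rng.random(len(peaks))
    tract_flags = rng.random(len(peaks)) < config.repeat_prevalence
    c1 = config.canonical_rate
    c2 = c1 + config.variant_rate
    c3 = c2 + config.ap1_rate
    scored = rng.uniform(50, 500, size=len(peaks))
    out_peaks: list[GenomicInterval] = []
    for i, iv in enumerate(peaks):
        motif_label = (
            "canonical" if u[i] < c1
            else "variant" if u[i] < c2
            else "ap1" if u[i] < c3
            else "none"
        )
        has_tract = bool(tract_flags[i])
        width = min(config.central_window, len(iv))
        center = (iv.start + iv.end) // 2
        w_lo = max(0, center - width // 2)
        window = bytearray(genome[iv.chrom][w_lo : w_lo + width])

        planted: list[tuple[int, int]] = []
        expected = {"canonical": set(), "variant": set(), "ap1": set()}
        expected_tracts: list[tuple[int, int]] = []
        motif_seq = {
            "canonical": CANONICAL_MOTIF,
            "variant": _variant_instance(rng),
            "ap1": AP1_MOTIF,
            "none": None,
        }[motif_label]
        cursor = 2
        if motif_seq is not None:
            off = cursor
            window[off : off + len(motif_seq)] = motif_seq.encode()
            planted.append((off, off + len(motif_seq)))
            expected["ap1" if motif_label == "ap1" else motif_label].add(off)
            if motif_label == "canonical":
                expected["variant"].add(off)  # canonical matches the variant pattern
            cursor = off + len(motif_seq) + 8
        tract_record = None
        if has_tract:
            units = int(rng.integers(*config.tract_units_range))
            tract_seq = "TGA" * units
            max_off = width - len(tract_seq)
            if max_off < cursor:  # window too small for both; drop the tract
                has_tract = False
            else:
                off = int(rng.integers(cursor, max_off + 1))
                window[off : off + len(tract_seq)] = tract_seq.encode()
                planted.append((off, off + len(tract_seq)))
                expected_tracts.append((off, off + len(tract_seq)))
                tract_record = {
                    "window_offset": off,
                    "genome_start": w_lo + off,
                    "units": units,
                }
        _scrub_window(window, planted, expected, expected_tracts, config, rng)
        genome[iv.chrom][w_lo : w_lo + width] = window

        name = f"pk{i:04d}"
        out_peaks.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, ".", name,
                            float(np.round(scored[i], 1)))
        )
        if motif_label == "canonical":
            label = "canonical_TGACGTCA"
        elif motif_label == "variant":
            label = "variant_TGANNTCA"
        elif motif_label == "ap1":
            label = "AP1_TGAGTCA"
        elif has_tract:
            label = "repeat_TGA"
        else:
            label = "none"
        peak_truth[i].update(
            name=name,
            motif=motif_label,
            motif_label=label,
            has_tract=has_tract,
            tract=tract_record,
            window_start=w_lo,
            window_width=width,
        )
    truth = {"peaks": peak_truth,
             "category_counts": {c: categories.count(c)
                                 for c in ("promoter", "intragenic", "intergenic")}}
    return out_peaks, truth


# ---------------------------------------------------------------------------
# coverage with planted super-enhancers
# ---------------------------------------------------------------------------

def gen_coverage(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenomicInterval], CoverageTrack, CoverageTrack, dict]:
    """H3K27ac-like peak set and chip/input coverage with planted supers.

    Regions sit on a dedicated chromosome, spaced beyond the stitching
    distance so each stitched region corresponds to one planted region; a
    region holds 1-3 constituent peaks.  Background regions draw exponential
    net signal; planted supers draw from a high normal, producing the
    hockey-stick distribution that rank-ordering SE callers cut.
    """
    rng = rng or config.rng()
    n_total = config.n_background_regions + config.n_super_regions
    is_super = np.zeros(n_total, dtype=bool)
    super_idx = rng.choice(n_total, size=config.n_super_regions, replace=False)
    is_super[super_idx] = True
    signals = rng.exponential(config.background_signal_mean, size=n_total)
    signals[is_super] = rng.normal(
        config.super_signal_mean, config.super_signal_sd, size=config.n_super_regions
    )
    signals = np.maximum(signals, 1e-3)

    chrom = "chrE"
    peaks: list[GenomicInterval] = []
    chip_records: list[tuple[str, int, int, float]] = []
    input_records: list[tuple[str, int, int, float]] = []
    regions_truth = []
    pos = 10_000
    for i in range(n_total):
        start = pos
        end = start + config.region_width
        n_constituents = int(rng.integers(1, 4))
        width = config.region_width
        if n_constituents == 1:
            bounds = [(start, end)]
        elif n_constituents == 2:
            cut = start + int(rng.integers(width * 3 // 10, width * 7 // 10))
            bounds = [(start, cut - 50), (cut + 50, end)]
        else:
            c1 = start + int(rng.integers(width * 2 // 10, width * 4 // 10))
            c2 = start + int(rng.integers(width * 6 // 10, width * 8 // 10))
            bounds = [(start, c1 - 50), (c1 + 50, c2 - 50), (c2 + 50, end)]
        for j, (a, b) in enumerate(bounds):
            peaks.append(GenomicInterval(chrom, a, b, name=f"h3k{i:04d}_{j}"))
        depth = float(np.round(
            config.input_depth + signals[i] / config.region_width, 6
        ))
        chip_records.append((chrom, start, end, depth))
        input_records.append((chrom, start, end, config.input_depth))
        # record the signal implied by the written (rounded) depth
        net = (depth - config.input_depth) * config.region_width
        regions_truth.append(
            {"region_id": i, "start": start, "end": end,
             "net_signal": float(net),
             "is_super": bool(is_super[i])}
        )
        pos = end + config.region_spacing

    chip = CoverageTrack.from_records(chip_records)
    input_track = CoverageTrack.from_records(input_records)
    truth = {
        "chrom": chrom,
        "regions": regions_truth,
        "n_super": int(config.n_super_regions),
    }
    return peaks, chip, input_track, truth


# ---------------------------------------------------------------------------
# species pair: derived genome, exact chains, homologs, syntenic SEs
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPair:
    genome_b: dict[str, bytearray]
    chains_a_to_b: list[ChainAlignment]
    chains_b_to_a: list[ChainAlignment]
    homologs: dict[str, str]
    genes_b: list[GeneModel]
    ses_a: list[GenomicInterval]
    ses_b: list[GenomicInterval]
    truth: dict


def _revcomp_bytes(seq: bytes) -> bytes:
    return seq.translate(bytes.maketrans(b"ACGTN", b"TGCAN"))[::-1]


def gen_species_pair(
    config: SimulationConfig,
    genome_a: dict[str, bytearray],
    genes_a: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> SpeciesPair:
    """Derive a second species by blockwise rearrangement of genome A.

    Each chromosome of A is cut into alignment blocks; B is the concatenation
    of those blocks with random inter-block insertions in B, deletions of A
    sequence between blocks, and strand inversions at the configured rate.
    One chain per block is written in each direction, so the chain files are
    exact and interval liftover has an analytic oracle.  Genes and planted
    SE slots falling wholly inside one block acquire B-coordinates and enter
    the homolog table and the syntenic-SE ground truth.
    """
    rng = rng or config.rng()
    genome_b: dict[str, bytearray] = {}
    chains_ab: list[ChainAlignment] = []
    chains_ba: list[ChainAlignment] = []
    # per A chrom: list of (a_start, a_end, b_chrom, b_start, strand)
    block_maps: dict[str, list[tuple[int, int, str, int, str]]] = {}

    for chrom, seq in genome_a.items():
        b_chrom = chrom + "_b"
        blocks: list[tuple[int, int, str]] = []
        pos = 0
        length = len(seq)
        while pos < length:
            size = int(rng.integers(*config.block_length_range))
            end = min(pos + size, length)
            strand = "-" if rng.random() < config.inversion_rate else "+"
            blocks.append((pos, end, strand))
            pos = end + int(rng.integers(*config.deletion_range))  # deleted in B
        parts: list[bytes] = []
        b_pos = 0
        maps: list[tuple[int, int, str, int, str]] = []
        for a_start, a_end, strand in blocks:
            ins = int(rng.integers(*config.insertion_range))
            if ins:
                parts.append(_BASES[rng.integers(0, 4, size=ins)].tobytes())
                b_pos += ins
            chunk = bytes(seq[a_start:a_end])
            parts.append(chunk if strand == "+" else _revcomp_bytes(chunk))
            maps.append((a_start, a_end, b_chrom, b_pos, strand))
            b_pos += a_end - a_start
        genome_b[b_chrom] = bytearray(b"".join(parts))
        block_maps[chrom] = maps

    # one chain per block in each direction
    for chrom, maps in block_maps.items():
        a_size = len(genome_a[chrom])
        b_chrom = maps[0][2]
        b_size = len(genome_b[b_chrom])
        for a_start, a_end, _, b_start, strand in maps:
            size = a_end - a_start
            if strand == "+":
                tgt_start, tgt_end = b_start, b_start + size
            else:  # reverse-strand chain coordinates
                tgt_start = b_size - (b_start + size)
                tgt_end = b_size - b_start
            chains_ab.append(
                ChainAlignment(
                    score=size, source_chrom=chrom, source_size=a_size,
                    source_strand="+", source_start=a_start, source_end=a_end,
                    target_chrom=b_chrom, target_size=b_size,
                    target_strand=strand, target_start=tgt_start,
                    target_end=tgt_end, blocks=((size, 0, 0),),
                )
            )
            if strand == "+":
                s_start, s_end = b_start, b_start + size
                t_start, t_end = a_start, a_end
            else:
                s_start, s_end = b_start, b_start + size
                t_start = a_size - a_end
                t_end = a_size - a_start
            chains_ba.append(
                ChainAlignment(
                    score=size, source_chrom=b_chrom, source_size=b_size,
                    source_strand="+", source_start=s_start, source_end=s_end,
                    target_chrom=chrom, target_size=a_size,
                    target_strand=strand, target_start=t_start,
                    target_end=t_end, blocks=((size, 0, 0),),
                )
            )

    def map_point(chrom: str, pos: int) -> tuple[str, int, str] | None:
        for a_start, a_end, b_chrom, b_start, strand in block_maps[chrom]:
            if a_start <= pos < a_end:
                if strand == "+":
                    return b_chrom, b_start + (pos - a_start), strand
                return b_chrom, b_start + (a_end - 1 - pos), strand
        return None

    def map_interval(iv: GenomicInterval) -> tuple[GenomicInterval, str] | None:
        """Exact B-image of an A-interval wholly inside one block."""
        for a_start, a_end, b_chrom, b_start, strand in block_maps[iv.chrom]:
            if a_start <= iv.start and iv.end <= a_end:
                if strand == "+":
                    lo = b_start + (iv.start - a_start)
                    return GenomicInterval(b_chrom, lo, lo + len(iv),
                                           name=iv.name, score=iv.score), strand
                hi = b_start + (a_end - iv.start)
                return GenomicInterval(b_chrom, hi - len(iv), hi,
                                       name=iv.name, score=iv.score), strand
        return None

    homologs: dict[str, str] = {}
    genes_b: list[GeneModel] = []
    for g in genes_a:
        mapped = map_interval(
            GenomicInterval(g.chrom, g.gene_start, g.gene_end)
        )
        if mapped is None:
            continue  # gene spans a block boundary: no clean homolog
        iv_b, strand = mapped
        strand_b = g.strand if strand == "+" else ("-" if g.strand == "+" else "+")
        gene_b_id = g.gene_id + "_b"
        genes_b.append(
            GeneModel(gene_b_id, iv_b.chrom, strand_b, iv_b.start, iv_b.end)
        )
        homologs[g.gene_id] = gene_b_id

    # SE slots: disjoint intervals inside blocks, >= 4 kb from block edges and
    # clear of gene bodies and promoter windows so SE anchors never double as
    # promoter anchors downstream.
    slots: list[GenomicInterval] = []
    need = config.n_syntenic_se_pairs + config.n_decoy_ses_a + config.n_decoy_ses_b
    margin = 4_000
    spacing = 6_000
    avoid: dict[str, IntervalTree] = {}
    for g in genes_a:
        lo, hi = g.promoter_window()
        avoid.setdefault(g.chrom, IntervalTree()).addi(
            min(lo, g.gene_start), max(hi, g.gene_end)
        )
    candidates: list[tuple[str, int]] = []
    for chrom, maps in block_maps.items():
        for a_start, a_end, *_ in maps:
            lo = a_start + margin
            hi = a_end - margin - config.se_width
            p = lo
            while p <= hi:
                tree = avoid.get(chrom)
                if tree is None or not tree.overlaps(p, p + config.se_width):
                    candidates.append((chrom, p))
                p += config.se_width + spacing
    if len(candidates) < need:
        raise ValueError("not enough block interior space for SE slots")
    chosen = rng.choice(len(candidates), size=need, replace=False)
    for idx in sorted(chosen):
        chrom, start = candidates[idx]
        slots.append(GenomicInterval(chrom, start, start + config.se_width))

    ses_a: list[GenomicInterval] = []
    ses_b: list[GenomicInterval] = []
    pair_truth = []
    k = config.n_syntenic_se_pairs
    for i, slot in enumerate(slots[:k]):
        mapped = map_interval(slot)
        assert mapped is not None
        iv_b, strand = mapped
        a = GenomicInterval(slot.chrom, slot.start, slot.end, name=f"seA{i:03d}")
        b = GenomicInterval(iv_b.chrom, iv_b.start, iv_b.end, name=f"seB{i:03d}")
        ses_a.append(a)
        ses_b.append(b)
        pair_truth.append({"se_a": a.name, "se_b": b.name, "strand": strand})
    for i, slot in enumerate(slots[k : k + config.n_decoy_ses_a]):
        ses_a.append(GenomicInterval(slot.chrom, slot.start, slot.end,
                                     name=f"decoyA{i:03d}"))
    for i, slot in enumerate(slots[k + config.n_decoy_ses_a :]):
        mapped = map_interval(slot)
        assert mapped is not None
        iv_b, _ = mapped
        ses_b.append(GenomicInterval(iv_b.chrom, iv_b.start, iv_b.end,
                                     name=f"decoyB{i:03d}"))

    truth = {
        "n_blocks": {c: len(m) for c, m in block_maps.items()},
        "block_maps": {
            c: [{"a_start": a, "a_end": b, "b_chrom": bc, "b_start": bs,
                 "strand": s} for a, b, bc, bs, s in m]
            for c, m in block_maps.items()
        },
        "syntenic_pairs": pair_truth,
        "n_decoys_a": config.n_decoy_ses_a,
        "n_decoys_b": config.n_decoy_ses_b,
    }
    return SpeciesPair(genome_b, chains_ab, chains_ba, homologs, genes_b,
                       ses_a, ses_b, truth)


# ---------------------------------------------------------------------------
# DE tables and loops
# ---------------------------------------------------------------------------

def gen_de_tables_and_loops(
    config: SimulationConfig,
    genes: Sequence[GeneModel] | None = None,
    ses: Sequence[GenomicInterval] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, "pd.DataFrame"], list, dict]:
    """Three DE tables with a planted shared-DEG core, plus SE-promoter loops.

    The mouse-tumor table uses mouse gene ids translated through the emitted
    homolog map; the human-tumor and knockdown tables use the shared
    namespace.  Planted shared genes satisfy each dataset's own cutoff
    (|log2FC| > 1 for the tumor contrasts, > 0 for knockdown, padj < 0.05);
    dataset-private DEGs and null genes fill the rest of the universe.  When
    gene models and SE spans are supplied, loops wire a recorded subset of
    promoters to SEs, with decoy loops that touch neither.
    """
    import pandas as pd

    from .degs import LoopAnchorPair

    rng = rng or config.rng()
    n = config.n_expression_genes
    shared_ids = [f"E{i:05d}" for i in range(n)]
    mouse_ids = [f"m{g}" for g in shared_ids]
    homolog_map = dict(zip(mouse_ids, shared_ids))

    order = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = order[cursor : cursor + k]
        cursor += k
        return out

    shared_up = take(config.n_shared_up)
    shared_down = take(config.n_shared_down)
    private_up = {d: take(config.n_private_up) for d in ("mCCS", "hCCS", "knockdown")}
    private_down = {d: take(config.n_private_down) for d in ("mCCS", "hCCS", "knockdown")}

    tables: dict[str, pd.DataFrame] = {}
    for dataset in ("mCCS", "hCCS", "knockdown"):
        tumor = dataset in ("mCCS", "hCCS")
        fc = rng.normal(0.0, 0.3, size=n)
        padj = np.round(rng.uniform(0.06, 1.0, size=n), 6)
        sig_lo, sig_hi = (1.2, 5.0) if tumor else (0.2, 4.0)
        for idx_set, sign in ((shared_up, 1), (shared_down, -1),
                              (private_up[dataset], 1), (private_down[dataset], -1)):
            fc[idx_set] = sign * rng.uniform(sig_lo, sig_hi, size=len(idx_set))
            padj[idx_set] = np.round(rng.uniform(1e-8, 0.049, size=len(idx_set)), 6)
        ids = mouse_ids if dataset == "mCCS" else shared_ids
        tables[dataset] = pd.DataFrame(
            {"gene_id": ids, "log2fc": np.round(fc, 4), "padj": padj}
        )

    loops: list[LoopAnchorPair] = []
    looped_truth: dict = {}
    if genes is not None and ses is not None and len(ses) > 0:
        gene_list = list(genes)
        n_loop = min(config.n_looped_genes, len(gene_list))
        pick = rng.choice(len(gene_list), size=n_loop, replace=False)
        looped_genes = [gene_list[i] for i in sorted(pick)]
        w = config.loop_anchor_width
        for g in looped_genes:
            se = ses[int(rng.integers(len(ses)))]
            se_anchor = GenomicInterval(
                se.chrom, se.start, max(se.start + w, se.start + 1)
            )
            prom_anchor = GenomicInterval(
                g.chrom, max(0, g.tss - w // 2), g.tss + w // 2
            )
            if rng.random() < 0.5:
                loops.append(LoopAnchorPair(se_anchor, prom_anchor))
            else:
                loops.append(LoopAnchorPair(prom_anchor, se_anchor))
        # decoys: SE-SE loops, which should yield no gene
        for _ in range(config.n_decoy_loops):
            s1 = ses[int(rng.integers(len(ses)))]
            s2 = ses[int(rng.integers(len(ses)))]
            loops.append(
                LoopAnchorPair(
                    GenomicInterval(s1.chrom, s1.start, s1.start + w),
                    GenomicInterval(s2.chrom, s2.start, s2.start + w),
                )
            )
        up_genes = [g.gene_id for g in looped_genes[: config.n_looped_up]]
        down_genes = [
            g.gene_id
            for g in looped_genes[config.n_looped_up :
                                  config.n_looped_up + config.n_looped_down]
        ]
        fcs = {g: float(rng.uniform(2.5, 5.0)) for g in up_genes}
        fcs.update({g: float(-rng.uniform(2.5, 5.0)) for g in down_genes})
        # expression table in the genome-gene namespace for the loop join
        genome_fc = np.round(rng.normal(0.0, 0.3, size=len(gene_list)), 4)
        genome_padj = np.round(rng.uniform(0.06, 1.0, size=len(gene_list)), 6)
        genome_ids = [g.gene_id for g in gene_list]
        fc_series = {gid: fc for gid, fc in zip(genome_ids, genome_fc)}
        fc_series.update(fcs)
        tables["genomeA"] = pd.DataFrame(
            {
                "gene_id": genome_ids,
                "log2fc": [round(fc_series[g], 4) for g in genome_ids],
                "padj": genome_padj,
            }
        )
        looped_truth = {
            "looped_genes": [g.gene_id for g in looped_genes],
            "looped_up": up_genes,
            "looped_down": down_genes,
            "loop_gene_fc": {k: round(v, 4) for k, v in fcs.items()},
        }

    truth = {
        "homolog_map": homolog_map,
        "shared_up": sorted(shared_ids[i] for i in shared_up),
        "shared_down": sorted(shared_ids[i] for i in shared_down),
        "private_up": {d: sorted(shared_ids[i] for i in v)
                       for d, v in private_up.items()},
        "private_down": {d: sorted(shared_ids[i] for i in v)
                         for d, v in private_down.items()},
        **looped_truth,
    }
    return tables, loops, truth


def gen_promoter_binding_layout(
    genes: Sequence[GeneModel],
    n_genes: int,
    n_bound: int,
    rng: np.random.Generator,
    peak_length: int = 200,
) -> tuple[list[str], list[GenomicInterval]]:
    """A DEG set of ``n_genes`` genes with peaks planted in ``n_bound`` promoters."""
    if n_genes > len(genes):
        raise ValueError("not enough gene models for the requested layout")
    pick = rng.choice(len(genes), size=n_genes, replace=False)
    chosen = [genes[i] for i in sorted(pick)]
    peaks = []
    for g in chosen[:n_bound]:
        start = max(0, g.tss - peak_length // 2)
        peaks.append(GenomicInterval(g.chrom, start, start + peak_length))
    return [g.gene_id for g in chosen], peaks


# ---------------------------------------------------------------------------
# one-call full simulation to files
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input under ``outdir`` plus ground_truth.json.

    Writes genome FASTA, gene GTF, peak BED, chip/input bedGraph, H3K27ac
    peak BED, chain files in both directions, species-B FASTA and gene table,
    homolog TSV, SE BEDs, three DE TSVs and a loop BEDPE.  Deterministic in
    ``config`` including the seed.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    genome, genes, truth_genome = gen_genome_and_genes(config, rng)
    peaks, truth_peaks = gen_peaks_with_sequences(config, genome, genes, rng)
    cov_peaks, chip, input_track, truth_cov = gen_coverage(config, rng)
    pair = gen_species_pair(config, genome, genes, rng)
    tables, loops, truth_de = gen_de_tables_and_loops(
        config, genes, pair.ses_a, rng
    )

    write_fasta(genome, outdir / "genome_a.fa")
    write_fasta(pair.genome_b, outdir / "genome_b.fa")
    write_gene_models_gtf(genes, outdir / "genes_a.gtf")
    write_gene_models_gtf(pair.genes_b, outdir / "genes_b.gtf")
    write_bed(peaks, outdir / "binding_sites.bed")
    write_bed(cov_peaks, outdir / "h3k27ac_peaks.bed")
    write_bedgraph(chip, outdir / "h3k27ac_chip.bedgraph")
    write_bedgraph(input_track, outdir / "chip_input.bedgraph")
    write_chain(pair.chains_a_to_b, outdir / "a_to_b.chain")
    write_chain(pair.chains_b_to_a, outdir / "b_to_a.chain")
    write_bed(pair.ses_a, outdir / "ses_a.bed")
    write_bed(pair.ses_b, outdir / "ses_b.bed")
    pd.DataFrame(
        sorted(pair.homologs.items()), columns=["gene_id_a", "gene_id_b"]
    ).to_csv(outdir / "homologs_species.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth_de["homolog_map"].items()), columns=["gene_id_a", "gene_id_b"]
    ).to_csv(outdir / "homologs_expression.tsv", sep="\t", index=False)
    for dataset, df in tables.items():
        df.to_csv(outdir / f"de_{dataset}.tsv", sep="\t", index=False)
    with open(outdir / "loops.bedpe", "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\n"
            )

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()
                   if k != "scanner"},
        "genome": truth_genome,
        "binding_sites": truth_peaks,
        "coverage": truth_cov,
        "species_pair": pair.truth,
        "expression": truth_de,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
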