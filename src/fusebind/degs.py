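"""Differential-expression tables, three-dataset DEG intersection, and
binding/looping-expression integration.

Two tumor datasets (mouse and human tumors vs. muscle) and one knockdown
dataset (RNAi control vs. knockdown in a tumor cell line) feed a shared-DEG
intersection.  Each dataset keeps its own significance rule: |log2FC| > 1 for
the tumor contrasts and log2FC > 0 for the knockdown contrast, with adjusted
p < 0.05 everywhere.  Mouse gene identifiers are translated to the shared
namespace through a homolog table before set operations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GeneIndex,
    GeneModel,
    GenomicInterval,
    PROMOTER_HALFWIDTH,
    map_peaks_to_promoters,
)
from .superenhancers import StitchedRegion

logger = logging.getLogger(__name__)

__all__ = [
    "DEGRecord",
    "DatasetRule",
    "IntersectionResult",
    "LoopAnchorPair",
    "DEFAULT_RULES",
    "read_de_table",
    "read_homolog_table",
    "read_loops",
    "classify_deg",
    "intersect_degs",
    "promoter_binding_fraction",
    "score_by_expression_class",
    "se_loop_genes",
]


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result in one dataset."""

    gene_id: str
    log2fc: float
    padj: float | None  # missing = untestable = non-significant
    dataset: str


@dataclass(frozen=True)
class DatasetRule:
    """Per-dataset significance rule: |log2FC| > fc_cutoff and padj < padj_cutoff."""

    fc_cutoff: float
    padj_cutoff: float = 0.05


#: Tumor contrasts require |log2FC| > 1; the knockdown contrast any change (> 0).
DEFAULT_RULES: dict[str, DatasetRule] = {
    "mCCS": DatasetRule(fc_cutoff=1.0),
    "hCCS": DatasetRule(fc_cutoff=1.0),
    "knockdown": DatasetRule(fc_cutoff=0.0),
}


@dataclass(frozen=True)
class IntersectionResult:
    per_dataset_up: dict[str, frozenset[str]]
    per_dataset_down: dict[str, frozenset[str]]
    shared_up_all: frozenset[str]
    shared_down_all: frozenset[str]
    shared_up_two_or_more: frozenset[str]
    shared_down_two_or_more: frozenset[str]
    universe_size: int


@dataclass(frozen=True)
class LoopAnchorPair:
    """One chromatin loop as an unordered anchor pair."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    support: int | None = None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_de_table(
    path: str | Path, dataset_label: str, flip_sign: bool = False
) -> list[DEGRecord]:
    """Read a TSV of gene_id, log2fc, padj into labeled records.

    ``padj`` of NA/empty is kept as missing (treated non-significant).  For
    knockdown contrasts computed as knockdown-over-control, ``flip_sign``
    restores the convention that positive log2FC means higher in control
    (i.e. activated by the factor).  Duplicate gene ids are an error.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        padj = None if pd.isna(row.padj) else float(row.padj)
        fc = float(row.log2fc)
        if flip_sign:
            fc = -fc
        records.append(DEGRecord(str(row.gene_id), fc, padj, dataset_label))
    return records


def read_homolog_table(path: str | Path) -> dict[str, str]:
    """Read a two-column homolog TSV into a first-mapping-wins dict."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    mapping: dict[str, str] = {}
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, b = str(a), str(b)
        if a in mapping:
            logger.info("gene %s maps to multiple homologs; keeping first", a)
            continue
        mapping[a] = b
    return mapping


def read_loops(path: str | Path) -> list[LoopAnchorPair]:
    """Read BEDPE (6+ columns) chromatin loops."""
    loops: list[LoopAnchorPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            support = None
            if len(f) > 7 and f[7] not in {".", ""}:
                support = int(float(f[7]))
            loops.append(
                LoopAnchorPair(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                    support,
                )
            )
    return loops


# ---------------------------------------------------------------------------
# Classification and intersection
# ---------------------------------------------------------------------------

def classify_deg(
    record: DEGRecord, rules: Mapping[str, DatasetRule] = DEFAULT_RULES
) -> str:
    """Label a record ``up``, ``down`` or ``neither`` under its dataset's rule."""
    rule = rules.get(record.dataset)
    if rule is None:
        raise ValueError(f"unknown dataset label {record.dataset!r}")
    if record.padj is None or not (record.padj < rule.padj_cutoff):
        return "neither"
    if record.log2fc > rule.fc_cutoff:
        return "up"
    if record.log2fc < -rule.fc_cutoff:
        return "down"
    return "neither"


def intersect_degs(
    datasets: Sequence[Sequence[DEGRecord]],
    homolog_map: Mapping[str, str] | None = None,
    rules: Mapping[str, DatasetRule] = DEFAULT_RULES,
) -> IntersectionResult:
    """Shared up/down DEG sets across three datasets in a common namespace.

    Gene ids found in ``homolog_map`` are translated before set operations
    (mouse symbols to the shared human namespace); unmapped ids pass through
    unchanged.  Reports all-dataset and two-or-more sharing.
    """
    homolog_map = homolog_map or {}

    def translate(gene_id: str) -> str:
        return homolog_map.get(gene_id, gene_id)

    up: dict[str, frozenset[str]] = {}
    down: dict[str, frozenset[str]] = {}
    universe: set[str] = set()
    for records in datasets:
        if not records:
            continue
        label = records[0].dataset
        ups, downs = set(), set()
        for r in records:
            gid = translate(r.gene_id)
            universe.add(gid)
            cls = classify_deg(r, rules)
            if cls == "up":
                ups.add(gid)
            elif cls == "down":
                downs.add(gid)
        up[label] = frozenset(ups)
        down[label] = frozenset(downs)

    def shared(sets: dict[str, frozenset[str]], k: int) -> frozenset[str]:
        counts: dict[str, int] = {}
        for s in sets.values():
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        return frozenset(g for g, c in counts.items() if c >= k)

    n = max(len(up), 1)
    return IntersectionResult(
        per_dataset_up=up,
        per_dataset_down=down,
        shared_up_all=shared(up, n),
        shared_down_all=shared(down, n),
        shared_up_two_or_more=shared(up, 2),
        shared_down_two_or_more=shared(down, 2),
        universe_size=len(universe),
    )


# ---------------------------------------------------------------------------
# Integration with binding and looping
# ---------------------------------------------------------------------------

def promoter_binding_fraction(
    deg_sets: Mapping[str, Iterable[str]],
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel] | GeneIndex,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> pd.DataFrame:
    """Per DEG set: fraction of genes with >= 1 peak in their promoter window."""
    pairs, _ = map_peaks_to_promoters(peaks, genes, promoter_halfwidth)
    bound_genes = {gid for _, gid in pairs}
    rows = []
    for name, gene_ids in deg_sets.items():
        gene_ids = set(gene_ids)
        n = len(gene_ids)
        bound = len(gene_ids & bound_genes)
        rows.append(
            {
                "deg_set": name,
                "bound": bound,
                "total": n,
                "fraction": bound / n if n else math.nan,
            }
        )
    return pd.DataFrame(rows)


def score_by_expression_class(
    promoter_pairs: Sequence[tuple[GenomicInterval, str]],
    de_records: Sequence[DEGRecord],
    fc_cutoff: float = 1.0,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Mean promoter-peak score by the bound gene's expression class.

    Classes are log2FC > ``fc_cutoff`` (up), within +/- ``fc_cutoff``
    (unchanged), and < -``fc_cutoff`` (down); peaks on genes with no
    expression record are excluded.  All class pairs with >= 2 members are
    compared by two-sided Welch t-tests on peak scores.
    """
    fc_by_gene = {r.gene_id: r.log2fc for r in de_records}
    scores: dict[str, list[float]] = {"up": [], "unchanged": [], "down": []}
    for peak, gene_id in promoter_pairs:
        if gene_id not in fc_by_gene or peak.score is None:
            continue
        fc = fc_by_gene[gene_id]
        if fc > fc_cutoff:
            cls = "up"
        elif fc < -fc_cutoff:
            cls = "down"
        else:
            cls = "unchanged"
        scores[cls].append(peak.score)
    means = {k: float(np.mean(v)) if v else math.nan for k, v in scores.items()}
    rows = []
    names = list(scores)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = scores[names[i]], scores[names[j]]
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "class_a": names[i],
                    "class_b": names[j],
                    "t_statistic": float(t),
                    "p_value": float(p),
                }
            )
    return means, pd.DataFrame(rows, columns=["class_a", "class_b",
                                              "t_statistic", "p_value"])


def se_loop_genes(
    loops: Sequence[LoopAnchorPair],
    superenhancers: Sequence[StitchedRegion] | Sequence[GenomicInterval],
    genes: Sequence[GeneModel] | GeneIndex,
    de_records: Sequence[DEGRecord] | None = None,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    fc_cutoff: float = 2.0,
) -> dict[str, object]:
    """Genes whose promoters loop to a super-enhancer anchor.

    A loop connects an SE to a gene when one anchor overlaps the SE span and
    the other anchor overlaps the gene's promoter window; anchors are
    unordered.  When expression records are supplied, tallies of looped genes
    with log2FC above ``fc_cutoff`` and below ``-fc_cutoff`` are included.
    """
    from .intervals import _build_trees

    se_spans = [
        se.interval if isinstance(se, StitchedRegion) else se
        for se in superenhancers
    ]
    se_trees = _build_trees(se_spans)
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_halfwidth)
    if index.promoter_halfwidth != promoter_halfwidth:
        index = GeneIndex(index.genes, promoter_halfwidth)

    def hits_se(iv: GenomicInterval) -> bool:
        tree = se_trees.get(iv.chrom)
        return tree is not None and tree.overlaps(iv.start, iv.end)

    looped: set[str] = set()
    for loop in loops:
        for se_anchor, gene_anchor in (
            (loop.anchor1, loop.anchor2),
            (loop.anchor2, loop.anchor1),
        ):
            if not hits_se(se_anchor):
                continue
            for gene in index.promoter_hits(gene_anchor):
                looped.add(gene.gene_id)
    result: dict[str, object] = {
        "genes": sorted(looped),
        "n_genes": len(looped),
    }
    if de_records is not None:
        fc_by_gene = {r.gene_id: r.log2fc for r in de_records}
        fcs = [fc_by_gene[g] for g in looped if g in fc_by_gene]
        result["n_up"] = sum(fc > fc_cutoff for fc in fcs)
        result["n_down"] = sum(fc < -fc_cutoff for fc in fcs)
    return result
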