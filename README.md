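# fusebind

Regulatory-genomics analysis toolkit for fusion-oncoprotein binding sites,
built around the kind of study done on bZIP fusion transcription factors such
as EWSR1::ATF1 in clear cell sarcoma: where does the fusion bind relative to
genes, which sequence elements does it sit on, which super-enhancers does it
occupy, how conserved is that super-enhancer structure between a mouse model
and the human disease, and which differentially expressed genes does the
binding explain.

The package is aimed at computational biologists who have peak calls, gene
models, coverage tracks, chain files and differential-expression tables in
hand and want the downstream integration steps as tested, composable library
functions — plus a seeded synthetic-data generator that fabricates every one
of those inputs with machine-readable ground truth, so each stage can be
validated without any sequencing data.

## What it computes

**Binding-site annotation** (`fusebind.intervals`). Peaks are classified as
*promoter* (overlapping TSS ± 3 kb of any gene, taking precedence),
*intragenic* (overlapping a gene body) or *intergenic*; the three categories
partition any peak set. Signed distances to the nearest TSS are measured from
the peak midpoint in gene orientation (negative = upstream). GREAT-style
assignment reports the nearest two genes within 500 kb. Multi-set consensus
(iterated intersection) and three-way Venn tallies mirror the usual
`bedtools intersect` workflows, all in BED 0-based half-open coordinates.

**Repeat-tract scanning** (`fusebind.repeats`). The core bespoke algorithm: a
3-bp window slides 1 bp at a time looking for TGA or its reverse complement
TCA. Matched units chain while the inter-unit gap g satisfies g ≤ g_max
(default 5 bp; 2 bp is also in published use); a larger gap closes the chain
and re-seeds from the breaking unit; a chain is recorded as one repeat tract
iff it holds ≥ k units (default k = 4). Because {TGA, TCA} is closed under
reverse complementation, results are strand-symmetric. Fixed-motif
classification covers the canonical ATF/CREB palindrome TGACGTCA, the
center-flexible variant TGANNTCA (reported excluding canonical matches) and
the AP1 motif TGAGTCA, scanned double-stranded over IUPAC codes.

**Super-enhancer calling** (`fusebind.superenhancers`). ROSE-style: H3K27ac
peaks within 12.5 kb are stitched, each region is scored by
net = max(chip − input, 0) summed over its span, regions are rank-ordered and
the cutoff sits where a slope-one line is tangent to the scaled
signal-vs-rank hockey stick (the point maximizing scaled rank − scaled
signal); regions strictly above the cutoff signal are super-enhancers.
Tukey-HSD comparison of site-score groups (promoter / distal /
SE-associated) is included.

**Cross-species synteny** (`fusebind.synteny`). UCSC chain files drive
block-wise, strand-aware interval liftover (default min-match 0.95);
super-enhancers of two assemblies are matched by lifting each set onto the
other, with reciprocal pairs flagged, and nearest-gene orientation tables
report whether homologous genes sit on the same side of their SEs in both
species.

**Expression integration** (`fusebind.degs`). Three differential-expression
datasets are intersected under per-dataset rules (|log2FC| > 1 for tumor
contrasts, log2FC > 0 for the knockdown contrast, padj < 0.05 everywhere,
mouse genes translated through a homolog table). Downstream joins compute the
fraction of a DEG set with promoter binding, mean peak score by expression
class (Welch t-tests), and genes whose promoters loop to super-enhancer
anchors in HiChIP-style BEDPE loops.

**Synthetic data** (`fusebind.simulate`). Seeded generators produce the
genome, gene models, peak sets with controlled category proportions, planted
motifs and repeat tracts, hockey-stick coverage with planted super-enhancers,
a rearranged second "species" with exact chain files, homolog tables, DE
tables with a planted shared-DEG core, and SE-promoter loops — all recorded
in `ground_truth.json`, byte-identical for a fixed seed.

## Worked example

```python
from collections import Counter
from pyfaidx import Fasta
from fusebind import intervals, repeats, superenhancers
from fusebind.simulate import SimulationConfig, simulate_all

simulate_all(SimulationConfig(seed=1), "demo")

peaks = intervals.read_bed("demo/binding_sites.bed")
genes = intervals.read_gene_models("demo/genes_a.gtf", "gtf")
anns = intervals.annotate_peaks(peaks, genes)
counts = Counter(a.category for a in anns)
print({c: f"{100*v/len(peaks):.1f}%" for c, v in counts.items()})

genome = Fasta("demo/genome_a.fa")
seqs = [repeats.extract_central_window(p, genome) for p in peaks]
out = repeats.repeat_fraction(seqs)
print(f"binding sites with a TGA/TCA repeat tract: {100*out['fraction']:.1f}%")

h3k = intervals.read_bed("demo/h3k27ac_peaks.bed")
chip = superenhancers.read_bedgraph("demo/h3k27ac_chip.bedgraph")
inp = superenhancers.read_bedgraph("demo/chip_input.bedgraph")
regions = superenhancers.call_superenhancers(
    superenhancers.score_regions(superenhancers.stitch_peaks(h3k), chip, inp))
print(f"super-enhancers: {sum(r.is_super for r in regions)} "
      f"of {len(regions)} stitched regions")
```

prints

```
{'promoter': '34.7%', 'intragenic': '36.5%', 'intergenic': '28.8%'}
binding sites with a TGA/TCA repeat tract: 32.4%
super-enhancers: 27 of 520 stitched regions
```

The genomic-distribution percentages recover the planted category proportions
exactly; the repeat fraction reflects the planted 30% tract prevalence plus
sampling noise; the super-enhancer call recovers all 20 planted high-signal
regions (plus the top few background regions that the tangent cutoff of a
rank-ordered exponential background necessarily admits — see
`docs/methods.md`).

The same stages are available as CLI subcommands:

```bash
fusebind simulate --seed 1 --out demo
fusebind annotate --peaks demo/binding_sites.bed --genes demo/genes_a.gtf --out ann.tsv
fusebind scan-repeats --peaks demo/binding_sites.bed --fasta demo/genome_a.fa --out tracts.tsv
fusebind call-se --peaks demo/h3k27ac_peaks.bed --chip demo/h3k27ac_chip.bedgraph \
    --input demo/chip_input.bedgraph --out se.tsv
fusebind match-synteny --se-a demo/ses_a.bed --se-b demo/ses_b.bed \
    --chain-ab demo/a_to_b.chain --chain-ba demo/b_to_a.chain --out synteny.tsv
fusebind integrate --de-mccs demo/de_mCCS.tsv --de-hccs demo/de_hCCS.tsv \
    --de-kd demo/de_knockdown.tsv --homologs demo/homologs_expression.tsv --out integ/
```

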