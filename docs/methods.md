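# Methods

This note documents the models and procedures implemented in `fusebind`, the
parameters that matter, the numerical choices made where conventions differ,
and what the synthetic-data generator does and does not emulate.

## Coordinates and overlap

All interval arithmetic is BED-convention: 0-based, half-open `[start, end)`.
GTF input (1-based, closed) is converted on read. Overlap means at least one
shared base on the same chromosome and is strand-blind throughout, because
ChIP-seq peak calls carry no strand. Abutting intervals (`[a,b)` and `[b,c)`)
never overlap; every overlap and annotation result is invariant to shifting
all coordinates by a constant.

## Binding-site annotation

A gene's promoter window is TSS ± *h* with *h* = 3000 bp by default — the
window used by standard peak annotators. The TSS is the first transcribed
base: `gene_start` on the + strand, `gene_end − 1` on the −strand. A peak is

- **promoter** if it overlaps any gene's promoter window (any-overlap, not
  midpoint containment — precedence over the other categories, so the three
  labels are mutually exclusive and exhaustive);
- **intragenic** if it overlaps any gene body but no promoter window;
- **intergenic** otherwise.

The nearest gene minimizes |peak midpoint − TSS| (midpoint anchor; ties
broken lexicographically by gene id for determinism), and its distance is
signed in gene orientation, negative upstream. GREAT-style assignment ranks
genes the same way, keeps up to two, and drops genes beyond 500 kb. Peaks on
chromosomes absent from the annotation are intergenic with no nearest gene
and a logged warning.

## Repeat-tract scanning

The scanner slides a 3-bp window 1 bp at a time over the uppercased sequence
(N never matches). Windows equal to TGA or TCA are units; TGA/TCA matches can
never mutually overlap, so the unit list is well ordered. Consecutive units
chain while `next.start − previous.end ≤ g_max`; a larger gap closes the
chain and re-seeds scanning **from the unit that broke it**, which keeps
tracts maximal and non-overlapping. A closed chain is emitted iff it holds at
least *k* units.

Defaults: `g_max = 5` bp, `k = 4` ("4 or more" — the threshold is inclusive,
matching the operational definition used for the reported prevalence
statistic; both the 5 bp and the stricter 2 bp gap settings are in published
use and both are plain `ScannerConfig` parameters). Every emitted tract is
asserted to satisfy the threshold and gap bounds.

Properties relied on by the tests: strand symmetry (the pattern set is closed
under reverse complementation, so tract counts and unit counts are identical
on a sequence and its reverse complement, with mirrored spans); tract counts
non-increasing in *k*; total chained units non-decreasing in `g_max` (the
tract *count* is also non-decreasing on random-composition sequences, though
two long adjacent chains merging under a looser gap can in principle reduce
it); exact agreement with an independently written enumerate-then-chain
brute-force oracle on arbitrary inputs.

Tract detection defaults to the central 100 bp of each peak (window centered
on the peak midpoint, biased 1 bp left when parity forces a choice, clipped
to short peaks with a warning), since repeat elements concentrate at binding
summits; the full peak can be scanned instead.

## Motif classes

Fixed motifs are scanned double-stranded over IUPAC codes, one hit per offset
(palindromes are not double-counted). The exclusive partition gives the
canonical ATF/CREB palindrome TGACGTCA precedence over the variant TGANNTCA
(every canonical site also matches the variant pattern, so variant counts
exclude canonical), then AP1 TGAGTCA, then repeat tracts. Per-motif boolean
flags are reported independently of the partition.

## Super-enhancer calling

Peaks within the stitching distance (12.5 kb, inclusive gap comparison) are
merged transitively per chromosome; the region span is the hull of its
constituents, so stitching is idempotent. Optional promoter exclusion removes
peaks wholly inside supplied exclusion windows before stitching (off by
default; used for intergenic-SE analyses).

Region signal is input-normalized by subtraction, floored at zero:
`net = max(Σ chip·bp − Σ input·bp, 0)` over the span, with uncovered bases
reading zero. Subtraction (rather than ratio) is the rank-ordering
convention.

The cutoff: sort regions ascending by net signal, scale rank and signal each
to [0, 1], and take the point maximizing (scaled rank − scaled signal) — the
point of the hockey stick lying furthest below the diagonal, where a
slope-one line is tangent. Regions with signal strictly above that point's
signal are super-enhancers; ties in the maximization resolve toward the
higher-signal point (fewer supers). The super set is invariant to positive
rescaling of all signals; all-equal signals yield no supers with a warning.

A consequence worth knowing: with an exponential background the scaled slope
of the ranked curve at the *k*-th-from-top background point is roughly
`N·(1/k)/s_max`, so the tangent sits several order statistics below the
background maximum, and a handful of top background regions are admitted
alongside well-separated planted supers. The planted-truth tests therefore
assert complete recall of planted supers and exact agreement of the cutoff
with an exhaustive scan, not zero admission of background.

## Liftover and synteny

UCSC chain files are parsed with full header/block bookkeeping validation.
Every interval base falling in an aligned block maps through the block
offset; negative target strands are flipped against the target chromosome
size per the chain specification. Chains are consulted in descending score
order, each base claimed by the first chain covering it. The result is the
hull of mapped bases; an interval is unmapped when the mapped fraction is
below `min_match` (default 0.95, the liftOver convention) or mapped bases
split across target chromosomes.

SE synteny lifts each species' SEs onto the other and overlaps them with the
native set; a pair is reciprocal when both directions connect it. Matching is
many-to-many, so the two species' distinct-matched counts may differ. For
reciprocal pairs, the nearest gene per species (by TSS) and its signed
distance give a same-orientation flag when the genes are homologs; rows with
non-homologous nearest genes are emitted but flagged and excluded from
orientation tallies.

## Expression integration

Each dataset keeps its own significance rule — tumor contrasts |log2FC| > 1,
knockdown log2FC > 0, adjusted p < 0.05 everywhere, with missing p treated as
non-significant. The knockdown sign convention is positive = higher in
control = activated by the factor (a `flip_sign` flag accommodates the
opposite contrast direction). Mouse ids are translated through a
first-mapping-wins homolog table before set operations. Both all-three and
two-or-more sharing are reported, since "shared in two datasets" is used in
both senses in the field.

All unpaired t-tests are Welch (unequal variance) two-sided; group
comparisons of three or more site classes use Tukey's HSD
(`scipy.stats.tukey_hsd`), cross-checked in the tests against statsmodels'
independent implementation. Loop integration counts a gene when one loop
anchor overlaps an SE span and the other overlaps the gene's promoter window
(anchor order immaterial); expression tallies on looped genes use a separate
fold-change cutoff (default 2) without a significance filter, matching how
looped-gene volcano tallies are usually drawn.

## Synthetic data

The generator is a pure function of its configuration, seed included: same
config, byte-identical files.

- **Genome/genes:** uniform-base chromosomes (2.6 Mb over two chromosomes by
  default — a desk-scale stand-in for a mammalian assembly); one gene per
  12 kb slot with ≥ 3.2 kb clearance, so promoter windows never merge and
  all three peak categories have room.
- **Peaks:** category proportions default to 34.7 / 36.5 / 28.8 %
  (promoter / intragenic / intergenic), the observed genomic distribution of
  the fusion protein's binding sites; placement enforces each category
  definitionally, so annotation recovery is exact, not statistical.
- **Sequence features:** motif planting rates default to the observed
  motif-class fractions (canonical 6.0 %, variant 27.6 % excluding canonical,
  AP1 12.9 %); repeat prevalence defaults to 30 % with 4–12 planted units
  per tract (chosen as a realistic middle ground; published figures report
  the prevalence graphically). Peak central windows are scrubbed of chance
  motif/tract occurrences before planting (bases mutated outside planted
  spans until the window's detected content equals the plan), so categorical
  ground truth is exact. Planted features overwrite genome bases in place;
  coordinates never shift.
- **Coverage:** 500 background regions with Exp(mean 1) net signal and 20
  planted supers at N(50, 5) on a dedicated chromosome, regions spaced beyond
  the stitch distance with 1–3 constituent peaks each; the flat input track
  and the uniform chip depth make every region's net signal analytic.
- **Species pair:** genome B is a blockwise copy of genome A (blocks
  40–80 kb; 15 % inverted; small insertions/deletions between blocks), with
  one exact chain per block in each direction — liftover therefore has an
  analytic oracle. Genes and planted SE slots wholly inside one block get
  homologs/syntenic partners; 50 planted syntenic SE pairs plus decoy SEs
  private to each species.
- **Expression:** a 10,772-gene homolog universe with a planted shared core
  of 432 up / 194 down genes satisfying every dataset's own rule, plus
  per-dataset private DEGs; null genes are kept non-significant by
  construction, so intersection counts are exact. Loops wire 20 genes'
  promoters to SEs (5 with log2FC > 2, 2 with < −2 in the genome-gene
  expression table) plus SE–SE decoy loops.

What the generator does **not** emulate: read-level noise, GC/nucleosome
structure, peak-calling uncertainty, denylist artifacts, batch effects, or
realistic gene density and length distributions. Passing the planted-truth
tests demonstrates that the algorithms are correct on inputs whose answers
are known; it does not certify performance on real sequencing data, where
category boundaries, signal backgrounds and homology are all noisier.

## Problem sizes and determinism

Default sizes (1,000 peaks, 520 coverage regions, 60 SEs, 10,772 expression
genes, 10,000 oracle sequences) keep the full test suite and the acceptance
script inside seconds on one CPU while leaving every planted count large
enough to be meaningful. All randomness flows from `numpy`'s PCG64 through a
single seed; the acceptance script derives its sub-seeds from `--seed`, and
end-to-end determinism is itself one of the measured quantities.
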