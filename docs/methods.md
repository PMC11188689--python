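# Methods

## The measurement model

An RB-TnSeq experiment tracks a pooled library of barcoded transposon
mutants through selection. Strain *i* (one insertion, one unique 20-bp
barcode) enters the experiment at relative abundance `a_i(0)`; after
incubation under condition *c* until day *d* its abundance is observed only
through barcode counts at finite sequencing depth. The pipeline estimates,
for every gene, the log2 change in relative abundance of the mutants that
inactivate it.

**Strain fitness.** With control (Day-0) count `x` out of total `X` and
treatment count `y` out of total `Y`,

    f_s = log2((y + ε)/Y) − log2((x + ε)/X),      ε = 1 by default.

The pseudocount keeps strains that drop to zero counts finite; it is the
simplest choice consistent with a frequency log-ratio and is exposed in the
configuration (`pseudocount`). Totals are the per-sample column sums over
all pool barcodes.

**Strain variance.** Counts are treated as Poisson; the delta method gives
the variance of the log2 ratio as

    V_s = (1/(x + ε) + 1/(y + ε)) / (ln 2)²,

using the same ε as the fitness. This is a variance *proxy* for weighting,
not a full error model: it ignores overdispersion from PCR and growth
stochasticity.

**Gene fitness.** Only insertions inside a gene body count toward that
gene (an insertion's position is the reference base under the first flank
base after U2; gene bodies are inclusive of their first and last base, and
an optional central-fraction trim can exclude insertions near the
termini). Gene fitness is the inverse-variance-weighted mean
`f_g = Σ(f_s/V_s) / Σ(1/V_s)`, so deeply covered strains dominate. A
`min_strains` floor (default 1) controls which genes are reported; genes
with no eligible strain are absent from the output rather than NaN-filled.

**Chromosomal normalization.** Copy number along a bacterial chromosome is
not uniform (cells harvested while replicating carry more origin-proximal
DNA), which imprints a smooth positional bias on raw gene fitness. Genes
are ordered by chromosomal midpoint `(start+end)//2` (ties by start) and a
centered running median with window 251 genes and circular wrap is
subtracted; then the mode of the residuals — the center of the fullest
histogram bin, Freedman–Diaconis bin width with a 0.05 log2-unit fallback
when the IQR degenerates — is subtracted so that the neutral bulk of genes
sits at zero. When fewer genes than the window are present, the window
shrinks to the largest odd size that fits (with a warning). Technical
replicates are averaged (unweighted) after normalization; biological water
samples are never averaged — they are independent replicates for the
selection step.

## Selection of reproducible hits

Per water sample, the gene × (condition, day) matrix (2 conditions × days
2, 4, 8; Day 0 is the reference, not a column) is column-mean-centered —
not variance-scaled, since all columns share log2-fitness units (a
`scale` flag exists) — and decomposed by PCA (via scikit-learn's SVD
route; the test suite checks it against a brute-force covariance
eigendecomposition). SVD leaves each PC's sign arbitrary, so a
deterministic orientation is imposed:

1. flip PC1 so the mean PC1 loading over all six columns is negative —
   depleted genes then score positive on PC1;
2. flip PC2 so the mean PC2 loading of filtered-water columns exceeds that
   of non-filtered columns — filtered-specific enrichment then points into
   Quadrant II.

Quadrants of the oriented (PC1, PC2) plane carry the usual biplot
semantics: I and IV depletion, II and III enrichment; zeros count as
positive, so a gene exactly at the origin lands in Quadrant I. Genes are
ranked by Euclidean distance from the origin; the top-k% set contains
exactly `ceil(k%·n)` genes with ties broken lexicographically by gene id.
The consensus sets intersect the top-5% sets of all replicates: "blue"
genes are in quadrants I/IV everywhere, "red" genes in II/III everywhere;
genes mixing the two classes across replicates are excluded and reported.

## What the simulator emulates

`barfit.simulate` generates: a random circular chromosome tiled with
non-overlapping genes (one gene of ≥ 300 bp per equal slot, random length
and offset — guaranteeing ≥ 1 bp intergenic gaps); an insertion library
with unique positions (a configurable fraction uniform over coding bases,
default 0.9, the rest intergenic) and unique random barcodes; lognormal
initial abundances (σ = 1 by default, the heavy-tailed representation
typical of transposon pools); and selection modeled *directly* as a log2
abundance change per (condition, day) relative to Day 0 —
`a_i(c,d) ∝ a_i(0)·2^e` renormalized — because the fitness statistic is
itself a log2 ratio to Day 0, making this the minimal generative model
whose truth the estimator should recover exactly (up to the common
renormalization constant, which the mode subtraction removes).
Sequencing noise is multinomial at the configured depth, drawn
independently per technical replicate; mapping reads are
U1+barcode+U2+flank with uniform substitution errors confined to the
genomic flank and with seedable defect categories (missing U2, 19-bp
barcode, one Q30 barcode base, unalignable flank) recorded in a truth
sidecar. All randomness flows from one seed; identical configurations
yield byte-identical files.

Deliberately **not** modeled: PCR duplicates and chimeras, indels,
quality-score degradation along the read, overdispersion beyond
multinomial sampling, strain-specific growth interactions, and
read-layout details of any particular sequencing facility (the BarSeq
barcode offset and read length are parameters). Passing tests therefore
demonstrate correctness of the statistical machinery under Poisson-like
noise with known truth — not robustness to every artifact of real
libraries.

## Numerical and design choices

* **Flank placement** replaces an external aligner with an exact-seed
  (first 30 bp) + bounded-mismatch (≤ 3) extension over both strands of
  the circular reference. The contract is what matters: a unique best
  locus, or an explicit `ambiguous`/`none` result. A mismatch inside the
  seed region yields `none`; with clean reads the matcher is exhaustive
  (it agrees with a brute-force all-positions scan in the tests). It scans
  the whole reference per read and is intended for the moderate genome
  sizes used here, not for production-scale mapping.
* **Pool filters**: modal-position support ≥ 2 reads and purity ≥ 0.75
  (modal fraction of placed reads), both configurable; barcode↔locus ties
  break toward the lowest coordinate.
* **U1/U2 and barcode matching are exact** — no mismatch tolerance at
  either the mapping or the counting stage; BarSeq reads are not
  quality-filtered by default (a flag exists at the extraction call).
* **Mapped fraction** is reported as matched/extractable reads, with raw
  totals logged so either convention is recoverable.
* **Quality threshold is strict**: a barcode base at exactly Q30 fails.
* **Degenerate inputs**: empty FASTQ → empty pool with a warning; genes
  missing any (condition, day) cell are dropped (and counted) before PCA;
  PCA orientation raises on exactly-zero mean loadings instead of
  guessing; constant fitness vectors normalize to exact zeros.

## Problem sizes and validation

The package validates itself on synthetic studies with planted truth
(`barfit.benchmarks`, exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`):

* **Consensus recovery** — the full design (3 water samples × 2
  conditions × 3 days × 3 technical replicates, 3000 genes, 60 000
  insertions, 2×10⁶ reads per sample), 40 genes planted at −2 in both
  conditions and 40 at +1.5 in filtered water only, median over 10 seeds.
  Expected: blue sensitivity ≥ 0.90, red ≥ 0.80, ≤ 2 false-positive
  consensus genes.
* **Estimator accuracy** — 300 genes / 6000 insertions / depth 2×10⁶,
  effects spanning [−3, +2]; on genes with ≥ 10 strains of control count
  ≥ 50: RMSE ≤ 0.3 log2 units, |bias| ≤ 0.05.
* **Read QC exactness** — 3000 clean reads plus 50 bad-length, 50
  low-quality and 50 missing-U2 reads: rejection counts match the truth
  sidecar exactly and 100% of insertions are recovered at the correct
  position and strand.
* **Oracles** — PCA vs eigendecomposition (≤ 1e-8 up to sign, 100 random
  50×6 matrices); running median vs a naive O(n·w) scan (exact, vectors up
  to 5000).

These sizes keep the whole suite under a minute while giving every gene
enough strains and depth for the asymptotics the estimator relies on.

## Known limitations

Real headline statistics of a wet-lab study (hundreds of thousands of
insertions, genome-scale gene counts, facility-specific mapped-read
fractions) depend on the deposited sequencing data and are outside what a
synthetic desk-scale run can reproduce; the validation here is
property-based against planted truth. The Poisson weighting understates
variance for overdispersed counts; the mode estimator is accurate only to
its bin width; and the flank matcher's exact-seed requirement makes reads
with early sequencing errors unplaceable by design.
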