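# Methods

## Scope and data model

The pipeline begins at per-cytosine methylation call tables (chrom,
1-based position, strand, context, methylated-read count, total-read
count), i.e. after bisulfite alignment and methylation extraction, and at
per-gene FPKM tables, i.e. after RNA-seq quantification. Read QC,
alignment, and expression quantification are out of scope. Internally all
coordinates are 0-based half-open; call tables and GFF3 are converted at
the I/O boundary.

## Cytosine context classification

A cytosine's context is read 5′→3′ on its own strand: CG if the next base
is G, CHG if the base after next is G, CHH otherwise. CG is decided from a
single downstream base; CHG/CHH need two. When a required base is off the
chromosome end or is N, the context is undefined and the site is excluded
from analysis rather than guessed. The one-base CG rule is deliberate: it
is the only edge convention under which every CpG dyad yields exactly one
site per strand, so the palindromic-symmetry invariant (#CG on + equals
#CG on −) holds on arbitrary sequences, including chromosome ends.

## Conversion calibration and site calling

The unmethylated lambda spike-in gives the per-sample bisulfite conversion
rate c = Σ(total − mc)/Σ(total) over all lambda cytosines; its complement
p₀ = 1 − c is the non-conversion rate, the probability that an
unmethylated cytosine reads as methylated. Each genomic cytosine with ≥ 4
pooled reads is tested one-sided against that null:
p = P(X ≥ mc | X ~ Binomial(total, p₀)). Multiple testing is controlled
with Benjamini–Hochberg across all tested sites of the sample; a site is
methylated at q ≤ 0.05. Design choices made where the procedure was open:

- *One-sided upper tail* — non-conversion can only inflate, never deflate,
  the methylated count.
- *Replicates pooled before testing* (counts summed per site) — the
  binomial test needs integer counts and pooling triples the effective
  depth; per-replicate calling followed by voting was the alternative and
  is strictly less powerful at these depths.
- *Per-sample p₀*, matching the per-sample spike-ins, rather than a global
  rate.
- No beta-binomial overdispersion: at ~30× per replicate and p₀ ≈ 0.005
  the binomial null is conservative already (the discrete test's realized
  false-call fraction on an all-null genome is far below the nominal q).

## Windows, replicate merging, and DMR criteria

Replicate counts are summed per site; the two strands of a symmetric CG or
CHG site are merged into one site unit (the biological methylation state
is shared across the dyad and merging stabilizes per-window site counts),
while CHH, being asymmetric, stays strand-specific. Units with fewer than
4 pooled reads are dropped. Units are then pooled into 200 bp windows
advancing by 100 bp; a window's level is Σmc/Σtotal. Windows tile each
chromosome from position 0; if sequence remains past the last full-width
window, one short tail window closes the chromosome.

Two samples are compared per window with the 2×2 Pearson chi-square
statistic on (methylated, unmethylated) read counts, no continuity
correction, p from the χ²(1) upper tail; windows with a degenerate margin
are skipped and logged. q-values are Benjamini–Hochberg across the tested
windows of a context. A window is differential when its context criteria
all hold — CG/CHG: ≥ 5 site units and |Δlevel| ≥ 0.25; CHH: ≥ 15 and
≥ 0.15; all-C: ≥ 20 and ≥ 0.2; q ≤ 0.05 in every context — and
overlapping surviving windows of the same direction are merged into one
reported DMR spanning their union (reported statistics are those of the
most significant member window). The site-count floors are counts of
covered cytosine positions, not of reads. For a comparison "A vs B",
*hyper* means B (the later developmental stage) is more methylated; the
convention is stated in every output.

A gene is a DMG when a DMR overlaps its body extended by 2 kb on both
sides by more than 1 nt (≥ 2 nt); genes hit by both hyper and hypo DMRs
are labeled mixed.

## Descriptive profiles

All level aggregation is count-pooled (Σmc/Σtotal), never mean-of-ratios:
pooling is robust to uneven depth, and using one rule everywhere keeps
feature, window, bin, and stratum levels mutually comparable. Metaprofiles
scale each gene body to 20 equal-width bins with 2 kb flanks in 100 bp
bins (plot-granularity defaults; both are parameters), reversing
minus-strand features so bins run 5′→3′. Level histograms use ten 10%-wide
bins with the last bin closed. Sites inside overlapping features count
toward every feature they fall in.

## Expression integration

FPKM bins are half-open and disjoint: None (0, 1], Low (1, 10], Moderate
(10, 100], High (100, ∞) — the conventional thresholds overlap at exactly
100, which is resolved in Moderate's favor. Methylation tertiles are
computed per region × context over genes with ≥ 1 covered site, ranking by
level with gene-id tie-breaks; the thirds differ in size by at most one
gene. The Spearman stage uses average-rank ties and the large-sample
approximation, refusing n < 10. DEG calling is an input contract, not a
method; for synthetic fixtures a documented fold-change rule is provided
(|log2 FC| ≥ 1 between condition means, both means > 1 FPKM).

## The synthetic study generator

The generator emulates the statistical structure such a stem-methylome
study reports, not its sequence content:

- **Genome**: i.i.d. bases at a configurable GC fraction (default 0.34, a
  poplar-like value); genes placed non-overlapping with randomized
  intergenic gaps; each gene has 5′UTR/exons/introns/3′UTR drawn from
  configurable ranges; TEs placed in intergenic space with class weights
  over {LTR, LINE, SINE, DNA} and superfamily labels (Gypsy, Copia,
  Caulimovirus, L1, CMC-EnSpm, hAT-Tag1, hAT-Tip100 — labels only).
- **True levels**: per-context Beta mixtures. Defaults are three
  components per context — a near-zero "unmethylated" mode (mean 0.005), a
  broad intermediate mode, and a high mode (mean 0.95) — with low/high
  masses 0.45/0.40 (CG), 0.65/0.24 (CHG), and 0.83/0.02 (CHH), the
  reported bimodal-CG/CHG, low-CHH structure. The published material gives
  decile masses, not distributions; Beta components are a modeling choice,
  and the near-zero low mode reflects that "lowly methylated" sites are
  mostly truly unmethylated. Sites inside TEs get an additive boost
  (default +0.3, clamped), creating the TE-dense hypermethylated vs
  gene-rich hypomethylated contrast.
- **Planted DMRs** additively shift the true level in the second condition
  and clamp to [0, 1]. Under the default bimodal CG background a +0.4
  plant partially clamps (high-mode sites are already near 1), so the
  realized regional shift is smaller than the nominal delta; recovery
  experiments that require the nominal Δ to be the true Δ use a
  low-methylation background (single Beta component, mean 0.05), where the
  shift survives unclamped.
- **Counts**: per replicate, depth ~ Poisson(30) (reported coverage is
  ~30–34×; Poisson is the simplest overdispersion-free model and per-site
  depth/replicate variance are not reported); methylated reads ~
  Binomial(depth, level·(1−p₀) + (1−level)·p₀) with p₀ = 0.0049, matching
  the ~99.5% conversion rates — a symmetric error model in which
  unmethylated molecules escape conversion and methylated molecules are
  mis-read at the same small rate.
- **Lambda**: a random 48.5 kb sequence, every cytosine truly
  unmethylated, counts pure non-conversion noise at the pooled-replicate
  depth.
- **Expression**: a Gaussian copula links gene-body CG true-methylation
  ranks to log-FPKM with Pearson coefficient r = 2·sin(π·ρ/6), making the
  population Spearman correlation exactly the configured ρ (default 0.25,
  the gene-body CG figure). Other contexts/regions correlate only
  indirectly. log₁₀FPKM ~ Normal(0.5, 1) spans all four expression bins.
  A configurable fraction of genes (default 10%) receives a condition-1
  log2 fold-change drawn uniformly from [1, 3] with random sign;
  replicate FPKM adds lognormal noise (σ = 0.1).
- **Determinism**: every draw comes from a PCG64 stream keyed by
  (seed, stage, condition, replicate), so identical config + seed gives
  byte-identical outputs, and the two conditions share their base true
  levels exactly (the planted deltas are the only true difference).

What the generator does **not** emulate: real sequence composition
(isochores, repeats with actual sequence), read-level artifacts (M-bias,
PCR duplicates, mapping bias), depth overdispersion, spatial
autocorrelation of methylation outside TE/DMR block structure, and
biological replicate-to-replicate variance in true levels. Passing tests
therefore demonstrate the correctness of the statistical machinery under
the stated model, not performance on real libraries — on real data the
binomial caller and the χ² window test will be anti-conservative in
proportion to unmodeled overdispersion.

## Numerical and policy details

- Undefined levels (zero covered reads) are NaN, never 0; empty windows
  are emitted with site count 0 so tilings stay complete.
- BH q-values come from statsmodels; the χ² statistic is computed from the
  closed-form 2×2 expression and only the reference distribution comes
  from scipy. An independent χ² implementation and Fisher's exact test are
  used as oracles in the test suite, never in the pipeline.
- Tertile and tie policies are stable sorts with deterministic keys, so
  reruns reproduce bins exactly.
- The pipeline's resumability hashes input file contents and parameters;
  manifests store relative paths and no timestamps, making whole output
  trees byte-comparable across runs and locations.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale: a 400 kb genome
(~136 k cytosines) for distribution-recovery checks, a 2 Mb single
chromosome with 50 planted 600 bp CG DMRs (3 vs 3 replicates at 30×) for
recovery/precision, n = 5000 genes for the copula recovery, and a 200 kb
two-condition study for the end-to-end run. These sizes give the
concentration the assertions rely on (binomial/Fisher-z standard errors
well inside the stated tolerances) while keeping the full suite in the
minutes range.

## Known limitations

- Headline counts from any real study (absolute DMR/DMG/DEG numbers)
  depend on the deposited libraries and aligner stack and are not
  reproducible from synthetic data; the package reproduces the *methods*
  and verifies them property-by-property instead.
- The χ² window test treats pooled reads as independent Bernoulli trials;
  within-window site correlation makes nominal q-values optimistic on real
  data (the merged-replicate design of the original analysis shares this
  property).
- A published summary of this kind of study can carry internally
  inconsistent genome-wide percentages between its overview and its
  detailed sections (e.g. overall context methylation of ~53.6/37.7/8.5%
  vs ~48.78/30.39/5.72%); where such figures guided defaults, the detailed
  per-study values were used.
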