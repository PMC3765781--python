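# Methods

## The tissue-mixture model

A composite anatomical structure (e.g. an insect abdomen) contains tissues
t = 1..T with RNA mass fractions w_t ≥ 0, Σ w_t = 1. Gene g in tissue t under
condition c has expected relative transcript abundance λ(g,t,c) ≥ 0 in
arbitrary units; transcript lengths L_g (bp) convert molar abundance to
sequenced mass. The units of λ are arbitrary *per tissue*: only within-tissue
proportions matter, because each tissue's profile is normalized to its mass
share before mixing.

**Tissue-specific extraction.** The expected read share of gene g is

    s_t(g) = λ(g,t,c) · L_g / Σ_g' λ(g',t,c) · L_g'

**Composite extraction.** Each replicate draws realized fractions w' from the
homogenization model (below) and mixes the normalized per-tissue shares:

    s_comp(g) = Σ_t w'_t · s_t(g) / Σ_{t: expressed} w'_t

The renormalization over expressed tissues only matters in the degenerate
case of a tissue with no expressed gene in a condition. Two consequences the
concordance analyses rely on:

- expected composite RPKM of each gene equals Σ_t w_t · (expected RPKM in
  tissue t) under perfect homogenization;
- a gene exclusive to tissue t has expected composite RPKM w_t times its
  focal RPKM, i.e. a focal/composite dilution ratio of 1/w_t.

**Counts.** Given total depth d, counts are drawn independently per gene as
negative binomial with mean d·s(g) and per-tissue dispersion φ_t (variance
μ + φ_t μ²); the composite uses the mass-weighted mean dispersion Σ w_t φ_t,
which reduces correctly at w = (1, 0, ...). Sampling NB per gene rather than
multinomially across genes means column sums vary stochastically around d;
this matches the DE test's distributional assumption and keeps type-I-error
simulations clean. φ < 1e-8 falls back to Poisson.

**Homogenization.** The ground sample is modeled as G equally sized grains,
each independently belonging to tissue t with probability w_t; a replicate's
realized fraction is the grain share, so the small-tissue fraction has
binomial variance w(1−w)/G. G = "infinite" gives w' = w exactly. This is a
deliberately minimal model of the observation that grinding a large structure
to powder still leaves grains that are large relative to small glands, making
a small organ's representation in the extracted aliquot stochastic.

**Random streams.** All randomness derives from one master seed; each
sample's stream is keyed by SHA-256 of (extraction, condition, replicate), so
adding samples or reordering calls never changes existing counts, and equal
seeds give bit-identical matrices.

**Effect layout** (`EffectConfig` → `build_mixture_model`): per tissue, a
fraction of genes is differentially expressed with |log2FC| ~ Normal(loc,
scale) split symmetrically across the two conditions (×2^(±fc/2)); a fraction
of those are tissue-exclusive (λ = 0 elsewhere), and a fraction carries the
opposite effect in one other tissue. Per-tissue DE gene sets are kept
disjoint so that an exclusive gene in one tissue cannot be silenced by a
later assignment; `de_fraction × T ≤ 1` is therefore required. Baseline
abundance is log-normal (default meanlog 3.0, sdlog 1.2, natural-log scale)
modulated by an independent log-normal tissue factor (sdlog 0.5) so tissues
differ but overlap. Defaults: 10 000 genes, 5% DE per tissue, |log2FC| ~
N(2, 0.5), 30% exclusive, 5% opposite-direction — chosen as a plausible
insect-organ regime; the three-tissue demo uses mass fractions 0.02 / 0.30 /
0.68 (small gland, large organ, remainder) and φ = 0.05, a typical
biological-replicate dispersion for bulk RNA-seq. Depth defaults to 12
million reads per sample with 2 biological replicates per condition, matching
common equalized-depth designs for this kind of comparison.

## Quantification

RPKM(g, s) = 10⁹ · c(g,s) / (N_s · L_g), with N_s the column sum of the count
matrix (the natural library size at the count-matrix boundary; total aligned
reads are not available downstream of counting). No effective-length
correction is applied — the quantity is exactly RPKM.

A gene belongs to the transcriptome of an (extraction, condition) when its
**replicate-mean** RPKM is **strictly** greater than the threshold τ
(default 10). Averaging across replicates is one of two defensible readings
of a pooled design (the alternative being per-replicate AND/OR rules);
strictness fixes the boundary: mean RPKM exactly 10 is a non-member.

Depth is equalized by thinning each sample **without replacement** to exactly
the target total (multivariate hypergeometric per column), so each gene
retains its column fraction in expectation and column sums are exact.

## Differential expression

Both tests compare two conditions within one extraction.

**Exact negative-binomial test (`nb_exact`).** Replicate counts are scaled to
the geometric-mean library size, summed within condition, and rounded to the
nearest integer (NB support is integral; the rounding is the pooling
convention here, in place of heavier pseudo-data machinery). Under the null,
the condition sums are NB with means n_i·μ and dispersions φ/n_i. Conditional
on the total s, the two-sided p-value is the sum of the point probabilities
of all splits (a, s−a) whose probability does not exceed the observed one —
the minimum-likelihood rule, with ties kept using a 1e-7 relative tolerance.
Computation is in log space; s = 0 returns p = 1 (untestable). φ = 0 (below
1e-8) reduces to the exact binomial(s, n1/(n1+n2)) conditional test.
P-values are Benjamini–Hochberg adjusted (statsmodels' fdr_bh) and a gene is
called DE when q ≤ α (inclusive; default α = 0.05).

The common dispersion is estimated by method of moments on counts normalized
to the mean library size: per gene and condition with ≥ 2 replicates,
φ_g = max(0, (s² − μ̄)/μ̄²); per-gene estimates are averaged with
degrees-of-freedom weights and the common φ is the median over genes with
mean normalized count ≥ 5 (the floor avoids the low-count regime where the
moment ratio is dominated by Poisson noise). Users can supply φ directly;
with no replication anywhere, estimation raises and asks for an explicit φ.

**Nonparametric signal-vs-noise probability (`noiseq_like`).** On the RPKM
scale with pseudo-count k (default 0.5 RPKM, preventing infinite log
ratios): the per-gene signal is M = log2((x̄₁+k)/(x̄₂+k)) and D = |x̄₁ − x̄₂|;
the noise distribution pools (|M*|, D*) computed the same way between every
within-condition replicate pair, over all genes. q_g is the fraction of
noise points with |M*| < |M| **and** D* < D (strict on both, so a
zero-signal gene gets q_g = 0 exactly). A gene is called DE when q_g > 0.8
(strict). At least two replicates per condition are required to build the
noise pool; with two conditions of two replicates the pool has 2 pairs per
gene. This is the biological-replicate flavour of the signal/noise approach;
no technical-replicate simulation is performed.

Direction is the sign of M in both methods; a DE call with M = 0 cannot
occur (the exact test's modal split has p = 1; a zero-signal gene has
q_g = 0).

## Concordance analyses

For each gene called DE in the focal tissue, the composite verdict is one of
*not_sig* (not called, **or absent from the composite results entirely** —
absence of evidence is treated as a false-negative candidate, not a
contradiction), *same_direction*, or *opposite_direction*. Both result sets
must come from the same method and thresholds.

Dilution ratios use replicate-mean RPKM; r > 1 is counted strictly ("above
1"), r = 1 counts as not-above. A ratio is considered defined only when both
means are positive; genes with composite RPKM = 0 (or focal RPKM = 0) are
tracked separately as undefined and excluded from the above/below counts and
from Fisher comparisons.

Presence/absence tables bin (+focal, −composite) genes by their focal RPKM
and (−focal, +composite) genes by their composite RPKM on the intervals
(10, 30], (30, 100], (100, 300], (300, ∞) by default — round-number edges
with 100 RPKM marking "highly expressed yet missing", the diagnostic of
sampling error rather than insufficient depth.

Fisher's exact test on 2×2 tables enumerates the margin-fixed hypergeometric
support and sums point probabilities ≤ the observed one within 1e-7 relative
tolerance (so floating-point ties are never dropped); two-sided throughout
(the more conservative choice where sidedness is ambiguous). Odds ratio is
ad/bc, ∞ when bc = 0 (NaN for 0/0). `compare_focal_tissues` builds the 2×2
as (property present / absent) × (tissue A / B), the property being "not
significant in the composite" for concordance tables and "ratio > 1" for
dilution sets.

## What the simulator does and does not emulate

It reproduces the mechanisms the analyses measure: mass-fraction dilution,
homogenization stochasticity, overdispersed counts, tissue-exclusive and
opposite-direction gene classes. It does **not** model read-level artifacts
(mappability, GC bias, positional coverage), RNA degradation during
dissection, correlated gene-gene expression noise, isoform-level variation,
or the true (unknown) overdispersion structure of mixed tissues — composite
dispersion is a simple mass-weighted mean. Passing tests therefore show that
the analysis pipeline correctly measures the dilution phenomena under the
stated generative model, not that any particular real tissue behaves
quantitatively like the defaults.

## Problem sizes and numerical checks

The canned studies in `compseq.experiments` use sizes chosen to make their
expectations sharp: the dilution-ratio study runs 500 seeds of a 200-gene
model at depth 5×10⁵ and φ = 0.005, where the per-seed RPKM ratio is tightly
concentrated and its mean approaches the analytic 1/w (the ratio of two
noisy RPKMs is upward-biased by roughly its squared coefficient of
variation, so low noise matters); the false-negative study plants 50
focal-exclusive DE genes at |log2FC| = 2 among 2000 genes at depth 2×10⁶
with 2 replicates; the null-FDP study runs 20 seeds of 2000 null NB genes at
depth 10⁵ with the true φ = 0.05 supplied to the exact test. Test-suite
fixtures use the same constructions at smaller sizes.

Degenerate inputs: zero-total genes are untestable (p = 1, never DE);
zero-column samples are rejected at RPKM; empty gene lists and empty
concordance tables are validation errors or produce zero-count tables with
Fisher comparisons skipped; all validation failures raise `ValidationError`
(CLI exit code 2) with the offending entity named.
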