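# Methods

## Scope and model of the data

The pipeline operates on preprocessed log2 expression matrices
(features × samples) with a sample sheet (condition, time in hours,
replicate); no normalization, background correction or probe-level
preprocessing is performed or simulated. Genomic inputs are UCSC-style
database dumps — gene models in the `refGene.txt` dialect and conserved
transcription-factor binding sites in the `tfbsConsSites.txt` dialect —
with 0-based half-open coordinates preserved end to end. In-vivo inputs are
long-format two-arm tumor-volume tables.

## Differential expression

Each post-baseline time point is contrasted against 0 h. Per gene,
logFC = mean(later) − mean(baseline), and the pooled two-sample residual
variance s²_g (d_g = n_A + n_B − 2 df) is shrunk toward a prior:

    s̃²_g = (d₀·s²₀ + d_g·s²_g) / (d₀ + d_g)
    t_g  = logFC_g / (s̃_g · sqrt(1/n_A + 1/n_B)),  two-sided p from t(d₀+d_g)

When (d₀, s²₀) are not supplied they are estimated from the observed
variance distribution by moment matching on e_g = log s²_g − ψ(d_g/2) +
log(d_g/2): the excess of var(e) over ψ′(d_g/2) identifies ψ′(d₀/2)
(inverted by Newton iteration) and mean(e) then identifies s²₀. When the
observed spread does not exceed its sampling expectation, d₀ = ∞ (full
shrinkage; under genuinely homoscedastic noise this is the correct limit
and the test statistics are normal). d₀ = 0 may be forced to recover the
ordinary pooled-variance t exactly. The estimator was cross-checked against
an independent reference empirical-Bayes implementation on a fixed matrix;
agreement is to six significant digits in d₀, s²₀, t and p.

p-values are BH-adjusted within each contrast (step-up, capped at one,
returned in input order; backed by statsmodels). Threshold gene sets use
strict inequalities; the default p used for thresholds is the adjusted one,
switchable to raw.

**Probe filtering**: the detection-call algorithm of the original arrays is
proprietary to its platform, so low-expression filtering is a value/fraction
rule — keep features ≥ min_value in ≥ min_fraction of samples, defaults
min_value = pooled 20th percentile and min_fraction = 1 ("low everywhere" is
removed). **Per-gene collapse**: "most informative probe set" is defined as
largest interquartile range across samples, ties broken by lexicographically
smallest feature id — robust, scale-respecting, deterministic.

## Promoter windows and motif counting

TSS = txStart on +, txEnd on − (UCSC stores txStart < txEnd regardless of
strand). The promoter is the 1-kb (configurable) window upstream of the
TSS, clipped at coordinate 0; windows of transcripts sharing a gene symbol
on one chromosome are merged as an interval union (a "first transcript"
mode exists). A TFBS counts toward a gene when its midpoint
⌊(start+end)/2⌋ lies in a window segment (default; "full containment" and
"any overlap" are options). The midpoint rule assigns each site at most
once per gene and is insensitive to site length; a site may still count for
several genes where windows of different genes overlap. Counting has a
vectorized searchsorted path when all window segments are disjoint (the
synthetic landscapes) and an interval-tree path otherwise; both are checked
against a quadratic brute-force oracle in the tests.

Sequence-logo support is limited to per-position information content of a
position weight matrix, IC_j = 2 + Σ_b p_{jb} log2 p_{jb} (bits, 0·log 0 ≡ 0).

## The binned correlation statistic

Genes are sorted by logFC (ties by label, so the partition is
deterministic) and split into n_bins = 100 contiguous bins; when N is not
divisible by n_bins the first (lowest-logFC) remainder bins take one extra
gene. Per motif, Pearson r is computed between per-bin count sums and
per-bin mean logFC. Sums are used because the statistic is a motif *count*;
with equal bin sizes sums and means give identical r (asserted
numerically), so the choice is immaterial. Zero-variance vectors yield an
*undefined* r (reported as missing, never 0, so it cannot pose as "no
enrichment"); undefined values rank last. Correlations are computed for
every contrast of the course; 36 h is the conventional headline contrast.
No multiple-testing calibration is applied to per-motif r — the statistic
is reported raw, as a ranking.

## Gene-set overlaps

P(X ≥ k) for X ~ Hypergeometric(N, K, n) is summed over the tail in log
space (log-Γ binomial terms combined by logsumexp), giving finite log
probabilities far below 1e-300; the exported probability underflows to 0
only below ~1e-308, with log10 p always reported alongside. The universe N
defaults to the number of genes surviving filtering in the active run and
is overridable (`--universe`), since overlap significance depends on it;
the reported reproduction uses the printed post-filter feature count 8154.
Venn region cardinalities for up to three sets come from inclusion–
exclusion over exclusive regions.

## Growth-curve statistics

The two-arm permutation test uses T = |AUC(mean log(V+1), arm A) −
AUC(mean log(V+1), arm B)|, trapezoidal over the days measured in both
arms; log(V+1) guards zero volumes and makes T approximately invariant to
common volume rescaling for V ≫ 1. Missing days (censored animals)
contribute through the surviving animals' per-day mean — restricted, never
imputed. The null permutes animal labels; p = (1 + #{T_perm ≥ T_obs}) /
(1 + n_perm), so p ≥ 1/(n_perm+1) and identical arms give p = 1. A
final-day statistic is available by flag. Day-wise comparisons use a
two-sample rank-sum test — the arms are independent animals, so the
two-sample form (not the paired signed-rank) is the appropriate one —
exact by full enumeration of label assignments for n ≤ 12 (ties averaged
over the observed rank pattern, no mid-p), continuity- and tie-corrected
normal approximation beyond; two-sided p = min(1, 2·min(tail probs)). The
cc-normal tracks the exact doubled-tail p to ≲0.007 where p < 0.2 and to
≲0.016 mid-range (the exact distribution is discrete with pmf steps ≈0.02
there).

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
validated.

* **Time course** — default grid 0, 18, 36, 53, 72 h with 2 replicates per
  point (the emulated design measured each point at least twice), 2000
  genes, 15% activated + 15% repressed, planted |logFC| 1.5 at the final
  point, linear effect ramp from 0 at t=0 (onset is early in the emulated
  knockdown; linear is the neutral choice and is configurable per time
  point), homoscedastic Gaussian noise sd 0.5, baselines N(8, 2²) — all in
  log2 units. value = baseline + sign·effect·ramp(t) + noise with sign −1
  (activated: falls on knockdown), +1 (repressed: rises), 0 (null).
* **Promoter landscape** — one synthetic chromosome, alternating strands,
  TSS spacing 10 kb (> 2× the 1-kb window, so gene windows are disjoint);
  per gene × motif, record counts are Poisson: rate 3 for the planted motif
  in regulon genes (regulon = the repressed group), rate 1 elsewhere (small
  non-negative integers with analytic expectations). `n_motifs` counts the
  *background* motifs; planted ids come on top. Records are placed
  uniformly, wholly inside the gene's upstream window, so window counting
  reproduces the planted counts exactly. A multi-transcript mode (+200 bp
  shifted transcripts) exercises the per-gene window merge. Enrichment is
  planted at the count level only — no sequences and no PWM scanning.
* **Growth curves** — V(i,t) = V₀·exp(r_i·t)·LogNormal(0, σ),
  σ = sqrt(log(1+cv²)); defaults V₀ = 100 mm³, r = 0.15/day (a ~20-fold
  increase over 3 weeks, typical of an aggressive xenograft), 10 animals
  per arm, treated rate × 0.5, cv 0.2, measurement days 0–21 including the
  conventional endpoint days.

Each generator draws from its own seed-derived stream, so runs are
bit-reproducible and adding one generator call never shifts another.

What the simulations do **not** emulate: probe-level artifacts,
normalization residue, heteroscedastic or correlated between-replicate
noise (the homoscedastic assumption is surfaced as `noise_sd`),
mean-variance trends, multi-motif promoter grammar, conservation scores,
animal dropout patterns beyond simple missingness. Passing tests therefore
demonstrate correctness of the statistics and recovery of planted structure
under idealized noise, not performance on raw array or animal data.

## Numerical choices and degenerate inputs

* Binning requires at least as many genes as bins; ties in logFC are broken
  by gene label.
* A gene with zero posterior variance and zero logFC gets t = 0 (p = 1);
  with nonzero logFC, t = ±∞ (p = 0). If every gene has zero variance and
  no prior was injected, a fixed prior (d₀ = ∞, s²₀ = 1) is used and logged.
* Gene-model/TFBS rows with degenerate spans or unparseable strands are
  rejected with a logged count, never silently dropped one by one; the
  leading UCSC bin column is auto-detected per file.
* An empty expression filter result warns rather than errors.
* The hypergeometric tail returns exactly 1.0 whenever k is at or below the
  support minimum.

## Problem sizes

The validation suite uses 2000-gene landscapes with 51 motifs (≈10⁵ TFBS
records) across 50 seeds for planted-motif recovery, 10⁴-gene null courses
for type-I calibration, 200 seeds × 999 permutations for permutation-null
uniformity, and exhaustive enumeration oracles up to N = 20 (plus seeded
random draws to N = 60) for the hypergeometric tail and n ≤ 8 for the
rank-sum test. These sizes give tight Monte-Carlo resolution for every
asserted band while keeping a full run fast on a single CPU.

## Known limitations

* The moment estimator assumes a common d_g across genes (true for complete
  two-group designs; missing values are not supported in the matrix).
* The binned correlation inherits the arbitrariness of n_bins = 100; the
  equal-size contiguous split is the documented convention, and r is not
  calibrated against a permutation null in the headline pipeline (a
  permutation option exists in the tests' methodology).
* The permutation test's AUC statistic summarizes whole curves; crossing
  curves with equal AUC are invisible to it (the final-day statistic is the
  provided alternative).
* Venn regions are limited to three sets; overlaps beyond pairwise are not
  assigned probabilities.
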