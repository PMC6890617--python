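# Methods

## Model and estimation

Every stage assumes the single-trait animal model
y = Xα + g + e with g ~ N(0, G σg²) and e ~ N(0, I σe²), where G is the
VanRaden method-1 genomic relationship matrix built from centered dosages
and X holds an intercept and a sex indicator. Heritability is
h² = σg²/(σg² + σe²) and the GBLUP shrinkage ratio λ = σe²/σg².

**REML.** One eigendecomposition of ZGZ′ rotates the model so the
phenotypic covariance is diagonal in the components; each iteration is
then O(n p²). Updates are average-information steps taken on log(σg²,
σe²) — positivity is automatic and boundary fits are approached
geometrically — with step halving when a step would decrease the
restricted likelihood and a monotone EM-REML step as fallback.
Components are floored at 1e-8 × var(y). Convergence is declared on a
relative parameter change below 1e-8 or (for AI) a restricted-likelihood
change below 1e-9 relative; hitting 200 iterations returns the current
estimates flagged unconverged. Standard errors come from the inverse AI
matrix; se(h²) by the delta method. A `reml_loglik` evaluator is public
so the optimum can be checked against grid/profile searches.

**Confidence intervals for h²** use the normal approximation with the
critical value rounded to three decimals as conventionally tabulated
(2.576 at 99%), truncated to [0, 1]; this reproduces hand-checked
intervals exactly at the printed precision.

**GBLUP** is solved in the variance-component form α̂ = (X′V⁻¹X)⁻¹X′V⁻¹y,
ĝ = σg² G Z′V⁻¹(y − Xα̂) with V = ZGZ′σg² + Iσe². This is algebraically
the mixed-model-equation solution but remains defined when G is
singular — which the sample GRM always is, because centered dosage
columns sum to zero. When G is full-rank the two routes agree to machine
precision (tested), and with matching centering and λ_marker = λ ×
(2Σp(1−p)) GBLUP and RRBLUP GEBVs are identical; that identity is the
module's primary correctness oracle. By default G is blended with
0.01·I before model fitting (n ≪ m makes near-singularity the common
case); the blend is exposed and can be disabled.

**Bayesian samplers.** A single compiled Gibbs kernel covers four
priors: BayesA (per-marker scaled-inv-χ²(v, s²) effect variances),
BayesB (spike-and-slab, fixed π, per-marker slab variances), BayesCπ
(common slab variance, π ~ Beta posterior) and a two-component normal
scale mixture in which every marker carries an effect from a large- or
small-variance class. The inclusion/class indicator is sampled from the
marginal likelihood with the effect integrated out; fixed effects have
flat priors; the residual variance a scaled-inv-χ² with v_e = 4 and
scale var(y)/2. Default hyperparameters: v = 4.2, π = 0.01, 10,000
iterations with 2,000 burn-in and thinning 10 (library default; the
analysis scripts use 3,000/1,000/4, which reproduces the same ordering
of methods at a fraction of the cost). The prior scale follows
s² = σβ²(v − 2)/v with σβ² = σg²/(π · 2Σp(1−p)), so the prior mean of
the effect variance equals the per-marker share of the genetic
variance. The scale-mixture model's variance ratio is not identified by
its one-line description in the literature; we fix small:large at 1:100
with the large-class probability sampled, and expose both as
hyperparameters. Chains are deterministic given a seed.

**GWAS scan.** EMMAX-style two-stage scan: null-model REML once, then
each marker tested by generalized least squares with the covariance
structure fixed at the null fit and the residual scale re-estimated per
marker; with G = I this reduces exactly to the ordinary regression
t-test. The p-values exist to rank markers for informative panels
(smallest first, ties broken by genome order, so panels are nested).

**HWE exact test** (Levene–Haldane, no mid-p): the conditional weights
n!/(n₁!k!n₂!)·2^k are computed as exact integers, so tie comparisons
against the observed configuration are exact and the p-value carries a
single final rounding.

**Cross-validation.** Individuals are split at test fraction 0.1 —
the printed group sizes of the motivating design (~334 reference, ~37
testing of 371) correspond to 9:1, which we take over the loosely
stated "5:1" — for 100 replicates by default. Variance components are
re-estimated on each replicate's reference set, and informative panels
are ranked on reference individuals only; a `paper_mode` switch instead
fits/ranks once on the whole data, reproducing the cheaper design at
the cost of test-set leakage. Ability is the Pearson correlation of
test-set GEBVs with raw phenotypes (a sex-adjusted option exists); the
reported SE is SD/√n_reps.

**Reference sizing** inverts the deterministic accuracy
r = √(N h²/(N h² + Me)) to N = Me r²/(h²(1 − r²)), rounded up. For
simulated cohorts the markers are unlinked, so the effective number of
independent segments Me is taken as the marker count.

## The synthetic cohort

The generator emulates the post-QC shape of a GBS-genotyped hatchery
cohort: 371 individuals of two near-balanced sexes, biallelic SNPs with
allele frequencies drawn uniformly from (0.01, 0.5], Hardy–Weinberg
genotype draws (or one generation of sire×dam gene dropping when family
structure is requested), 3.32% missing calls at random, a sex fixed
effect, and an additive trait from n_qtl markers with normal effects.
The residual SD is set to √(var(g)(1 − h²)/h²) after the genetic values
are realized, so the in-sample heritability matches the target in
expectation (h² = 0 is handled by making the residual variance 1e8-fold
dominant rather than zeroing the effects, keeping the ground truth
usable). Defaults: 50 QTL with normal effects and target h² covering
0.3–0.85 in the analysis scripts — the trait architectures of the real
traits are unknown, so these are stated conventions, not estimates.

What the simulator does **not** carry: linkage disequilibrium beyond
family co-segregation, allele-frequency spectra shaped by selection,
genotyping error, or multi-generation pedigrees. Consequently passing
tests demonstrate internal correctness and calibration under an
idealized architecture; they do not certify real-data predictive
abilities. Two visible consequences: with 50 QTL behind 3,000 unlinked
markers, variable-selection priors (BayesB/Cπ) beat GBLUP by far more
than the ~9–24% spreads typical of real polygenic traits, and the
single-cohort REML h² carries a standard error near 0.2 — matching the
0.14–0.17 SEs such sample sizes produce in practice — so individual
estimates scatter widely around the simulated value even though the
estimator is centred (the acceptance run reports a 10-cohort mean to
show this).

## Problem sizes

The default test and acceptance runs use 300–500 individuals and
1,000–3,000 markers, 8–50 cross-validation replicates and 3,000–5,000
Gibbs iterations. These sizes were chosen so that every distributional
claim is already stable (the identities are exact at any size), and the
code paths are identical at genome-wide density — only the matrix
dimensions grow.

## Known limitations

- Single-trait analyses only; no pedigree/H-matrix, no dominance.
- Mean/mode imputation is a deliberate stand-in for haplotype-based
  imputation and ignores linkage information entirely.
- The scan holds the null covariance fixed (no per-marker variance
  re-estimation), the standard trade-off of two-stage mixed-model GWAS.
- `method_spread` reduces multi-variant methods by their best variant,
  which is optimistically biased for the winning method; it mirrors the
  comparison convention it implements rather than correcting it.
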