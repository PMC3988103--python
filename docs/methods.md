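# Methods

## Data model and transformations

The analysis operates on a species-level table: body mass (g), testes mass
(mg), spermatophore trunk volume (mm³), sperm-package length (µm) and
polyandry level (mean males accepted per female per season, ≥ 1). All four
morphological traits are log10-transformed before modelling; polyandry
enters untransformed. Testes mass is converted mg → g before the log, so
intercepts of testes-mass models are on the gram scale (the bundled
dataset's regression intercepts are only interpretable under that
convention); the conversion factor lives in one table
(`trait_data.LOG_COLUMNS`).

The gonadosomatic index is GSI = 100 × (testes mass in g)/(body mass in g).
At species level it is computed from species means (ratio of means). The
alternative convention — average the per-male ratios — differs whenever
individuals vary (Jensen's inequality: E[tm/bm] > E[tm]/E[bm] for
independent positive draws); the individual-level simulator exposes both so
the discrepancy can be studied mechanically (`analysis/04`).

Normality of the log-transformed traits is checked by Shapiro–Wilk
(Royston's approximation, via `scipy.stats.shapiro`; cross-validated in the
test suite against R's independent `shapiro.test` implementation to 1e-6).

## Tree and covariance

The default tree is a cladogram of the eight species with **every branch
length equal to 1** (a punctuated-evolution convention: divergence is
proportional to cladogenesis events). Congeners form clades; the
above-genus arrangement ((Bothriurus, Brachistosternus), (Timogenes,
Urophonius)) is a working assumption that downstream code never relies on —
any user Newick replaces it. With equal branch lengths the tree is
non-ultrametric (the *Urophonius* tip is shallower), so the covariance
diagonal is not constant and is used as-is.

The VCV matrix is built in one postorder pass (each internal node assigns
its depth as the covariance of tip pairs split across its children); the
test suite checks it against brute-force enumeration of shared root-path
edges on random trees. Pagel's transform V(λ) = λV + (1−λ)diag(V) is a
convex combination of two PSD matrices and therefore PSD for all λ ∈ [0,1],
including on non-ultrametric trees.

## Likelihood core

ML throughout, never REML: model selection compares models with different
fixed effects, and REML likelihoods are not comparable across those. At
fixed λ, β̂ and σ̂² (divisor n) are closed-form GLS; the profile
log-likelihood is maximized over λ ∈ [1e-4, 0.9999] by a 25-point coarse
grid scan followed by bounded Brent refinement in the bracketing interval
(profiles on 8-tip trees are flat and occasionally bimodal; the grid keeps
the optimizer out of the wrong basin, and tests require agreement with a
1000-point grid search to 0.01). The interval bounds are deliberately
interior — estimates printed as 0.0001/0.9999 mean "at the bound" — and are
configurable. λ is re-estimated for every candidate model, never shared.

Likelihood-ratio statistics against λ = 0 and λ = 1 are 2·ΔlnL, clipped at
zero (the bounded λ̂ can sit infinitesimally inside the fixed value), with
plain χ²(1) upper-tail p-values; no 50:50 boundary mixture is applied,
matching the convention of the comparative-methods literature this design
follows.

Coefficient-level Wald tests use the unbiased variance (divisor n − k).
Sequential (Type I) ANOVA whitens y and X by the Cholesky factor of the
full model's fitted V(λ̂) and decomposes the whitened regression sum of
squares in predictor order; each term's F uses the full model's residual
mean square with n − k df. Conditioning on the *full* model's λ̂ (rather
than re-estimating λ per nested submodel) keeps the Type-I decomposition
exact — the sequential sums of squares add up to the total by construction.
Callers who want a different conditioning can pass any fixed λ.

## Model selection

AICc = −2lnL + 2k + 2k(k+1)/(n−k−1). What k counts is a genuine convention
choice on which reasonable software disagrees. The default here counts
**regression coefficients only**, the convention under which an interaction
model y ~ a*b is a "four-parameter" model and under which the bundled
dataset's published best-model identities reproduce; `k_counting` can
instead add the variance, or the variance and λ
(`coefficients+variance[+lambda]`), and all three modes are exercised in
the tests. With n = 8 the correction term is large (k = 3 adds 6), so the
choice materially reorders small candidate sets — which is why it is a
visible switch rather than a buried constant.

Akaike weights are computed after subtracting the minimum AICc (numerical
stability; weights are shift-invariant). Models with ΔAICc strictly below 2
are flagged as selected; the best model is always selected.

## Synthetic data

Species-level: y = Xβ + Lz with L the Cholesky factor of σ²V(λ) — exactly
the model the estimator assumes. This validates the machinery (recovery,
power, calibration), not the biology: real traits need not be Gaussian on
the log scale, branch lengths are conventions, and polyandry is treated as
a fixed covariate, so passing tests show correctness of the inference
chain, not truth of the Brownian model for scorpions.

Individual-level: per species, n_males males (defaulting to the study's
per-species sample sizes, 6–19), per-male body and testes masses drawn
**lognormally**, moment-matched to the target arithmetic mean and SD
(traits are positive and SDs are of the same order as means, so Gaussian
draws would go negative). Each male gets 10 sperm-package lengths around a
lognormal per-male mean; the within-male coefficient of variation is not
reported in the source design and defaults to 0.05 (measurement-level
scatter, small relative to between-male SD). Spermatophores (1–3 per
species) are emitted as (trunk area, width) pairs whose product is the
volume; with no published SD for volume the default within-species CV is 0,
so derived volumes are exact. The species table is derived by the study's
own averaging chain (package → male mean → species mean), and per-male GSI
is averaged per species alongside the ratio-of-means value.

Randomness: one root seed; each species' stream is
`SeedSequence(root, spawn_key=sha256(name))`, so adding or removing a
species never perturbs the draws of the others.

## Problem sizes and determinism

The study itself is tiny (8 species, 18 models) and fully deterministic:
regenerating a report from identical inputs is byte-identical (reports
carry a config hash, no timestamps). Simulation-based checks use 200
replicates for λ recovery (8-tip and 64-tip trees), 500 replicates for
coefficient recovery, and 10⁴ replicates/males for Monte-Carlo moment
checks; these sizes put Monte-Carlo error well below the tested margins
while keeping any single test in seconds.

## Known limitations

- λ estimated on 8 tips is weakly identified; profiles are flat and
  estimates pile up at the search bounds. The package reports bound-valued
  λ̂ honestly rather than treating it as a point estimate with meaningful
  precision.
- Shapiro–Wilk W computed from the bundled species means differs in the
  third decimal from some previously tabulated values for the same traits
  (0.967 vs 0.968 for log body mass; 0.929 vs 0.928 for log spermatophore
  volume); two independent implementations (scipy and R) agree with each
  other, so the differences trace to rounding of the underlying species
  means, whose unrounded individual-level source data are not available.
- No measurement-error model, no Ornstein–Uhlenbeck/κ/δ transforms, no
  phylogenetically independent contrasts, no model averaging of
  coefficients: out of scope by design.
- The default cladogram's above-genus topology and equal branch lengths are
  conventions, not estimates; conclusions that depend on them should be
  re-run with user-supplied trees.
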