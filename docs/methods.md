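# Methods

`felhip` implements the quantitative-genetic analysis of an ordinal
hip-dysplasia screening programme: pedigree relationship algebra, threshold
(liability) animal models, scale transformations for heritability, selection-
response regressions, and a generative simulator with known truth. This note
records the models, the numerical choices, and what the synthetic data do and
do not establish.

## Pedigree algebra

The additive relationship matrix `A` is built by the tabular method
(`a_ij = ½(a_{i,s(j)} + a_{i,d(j)})`, `a_jj = 1 + ½ a_{s(j)d(j)}`); unknown
parents contribute zero and are treated as unrelated, non-inbred founders (no
genetic groups). Inbreeding coefficients use the Meuwissen–Luo traversal of
the generalized Cholesky decomposition `A = L D Lᵀ`, so no dense matrix is
needed; the sparse inverse follows Henderson's rules with the inbreeding
(Quaas) adjustment, `A⁻¹ = Wᵀ D_m⁻¹ W`, where `W = I − ½P` maps each
individual onto itself minus half of each known parent and `D_m` holds the
Mendelian-sampling variances. That factorisation is used throughout: a draw
from `N(0, A⁻¹)` is a single sparse mat-vec, and quadratic forms `aᵀA⁻¹a`
reduce to a scaled residual sum of squares.

**Mean ancestor score.** "Generations of previously screened ancestors" is
not a uniquely defined quantity when screening is incomplete. The default
recursion is `g(x) = 1 + ½(g(sire) + g(dam))` for an ancestor screened
strictly before the subject's assessment and `0` otherwise, averaged over the
maternal and paternal side. It returns exact integers on fully screened
ancestries and discounts smoothly through gaps. A `strict` mode
(`1 + min(g(sire), g(dam))`) counts only unbroken fully screened generations.
Ties in assessment date count as *not previous*.

## Threshold animal model

For a 0–3 hip grade the model is a probit threshold model: latent liability
`l = Xβ + a + pe + e`, `e ~ N(0, 1)`, cut at ordered thresholds
`γ = (0, γ₂, γ₃)` into the observed grade. Identification fixes the residual
variance at 1 and the first cutpoint at 0, with a free intercept. `a ~ N(0,
V_A A)` is the additive-genetic effect; `pe ~ N(0, V_PE I)` is an individual
(permanent-environment) effect shared by repeated records of the same cat —
in per-hip format, the two hips of one cat.

The Gibbs sampler uses:

* liability augmentation — truncated-normal draws given the grade;
* a *joint* draw of `(a, pe)` per iteration: the PE block has a diagonal
  conditional precision and is eliminated by Schur complement, leaving a
  genetic system `S = A⁻¹/V_A + D` that is sampled exactly through the
  perturbation identity `a = S⁻¹(b + u)` with `u ~ N(0, S)` (cheap via the
  `WᵀD_m^{-1/2}` factor above); the solve uses Jacobi-preconditioned
  conjugate gradients (`rtol 1e-10`), so nothing is ever factorised and an
  iteration on a ~3000-member pedigree costs a few milliseconds;
* fixed effects from their exact low-dimensional Gaussian conditional;
* conjugate scaled-inverse-χ² updates for `V_A` and `V_PE`, each interweaved
  with a non-centred (ASIS) rescale drawn by slice sampling — without the
  interweaving the variance scales mix an order of magnitude more slowly;
* slice-sampled free cutpoints on their liability-marginal conditionals
  (each cutpoint only touches the two adjacent grade classes), which needs
  no proposal tuning;
* a translation interweaving that shifts probability mass between the
  intercept and the mean genetic (and PE) level — the likelihood is invariant
  along this ridge, so the shift has an exact Gaussian conditional; this
  repairs the notoriously slow intercept mixing of blocked samplers.

Starting values matter for short chains: variance components start from a
moment estimate based on the within-individual correlation of repeated
scores, `ρ̂/(1−ρ̂)` split equally between `V_A` and `V_PE`, and cutpoints
from the marginal grade frequencies.

**Priors.** Scaled-inverse-χ²(ν = 1, s² = 0.5) on `V_A` and `V_PE` by
default (heavy-tailed, weakly informative), inverse-Wishart(ν = 3, I) on the
bivariate `G`; all configurable. The parameter-expanded updates above give
the sampler half-Cauchy-like behaviour near zero without a separate expanded
parameterisation.

**Gaussian and bivariate variants.** The Gaussian animal model (residual
body mass) is the same machinery with the observed response and an estimated
residual variance. The bivariate model stacks two traits (each ordinal or
Gaussian) on a shared 2-per-individual genetic vector with prior
`G ⊗ A` (precision `G⁻¹ ⊗ A⁻¹`, sampled jointly as one sparse system),
inverse-Wishart conjugate updates for `G`, optional PE per ordinal trait, and
the residual cross-covariance fixed at 0 — with one record per cat per trait
it is weakly identified on the liability scale (a flag could estimate it;
deliberately not implemented). Genetic correlations are computed per draw,
`r_G = g₁₂/√(g₁₁g₂₂)`, excluding (and counting) draws with non-positive
variances.

**Identifiability.** With unrelated individuals and single records, the
total liability scale is unidentified: a free intercept plus two free
cutpoints can absorb any `V_A + V_PE` while matching all category
frequencies. Only scale-free functions (standardised cutpoints, and — once
relatives or repeats exist — the variance ratios) are then estimable; the
test suite checks exactly that. Real analyses should use per-hip (repeated)
records, which anchor the scale through the unit per-record residual.

**Convergence.** `mcmc_diagnostics` wraps split-R̂ and effective sample size
(ArviZ); the fitting front-ends can gate summaries on R̂ < 1.1 across ≥ 2
chains. Chain-length defaults (2 chains × 3000 iterations, 1000 burn-in,
thin 2) are sized for desk-scale data sets of a few thousand individuals;
the parameter-recovery studies below use single chains of 2000 iterations
(600 burn-in), which the diagnostics show is ample for posterior means at
these data sizes.

## Latent- to observed-scale heritability

Latent-scale heritability is `h²_lat = V_A/(V_A + V_PE + 1)`, applied per
posterior draw (the mean of ratios, not the ratio of means). The data-scale
transformation integrates the expected grade
`ψ(ℓ) = Σ_k k·[Φ(γ_{k+1} − ℓ) − Φ(γ_k − ℓ)]` and its derivative over
`ℓ ~ N(μ, V_A + V_PE)` by Gauss–Hermite quadrature (48 nodes; `μ` is the
mean fixed-effect predictor). Then `V_P,obs = Var ψ + E v` with `v` the
conditional categorical variance, `V_A,obs = V_A (E ψ′)²`, and
`h²_obs = V_A,obs/V_P,obs`. In the two-category limit this reduces exactly
to the classical dichotomous back-transformation `h²_lat·z²/(p(1−p))`; the
general case is verified against 10⁶-draw Monte-Carlo integration.

## Truncated-Poisson selection-response model

Scores bounded at 3 are modelled as a right-truncated Poisson,
`P(k|λ) ∝ λ^k/k!` on `{0..3}` with `log λ = xᵀβ` ("truncation", not
censoring — the pmf is renormalised). The MLE uses Newton steps with the
analytic score `x(y − E[Y|λ])` and truncated-variance information, with
step-halving (the log-likelihood never decreases) and a ridge-stabilised
fallback for singular information. Credible intervals come from adaptive
random-walk Metropolis over `β` (flat priors, proposal seeded by the inverse
information, 4 chains). Covariates are standardised internally and reported
back on their original scale. Expected-score curves use
`E[Y] = Σ k P(k)`; the percent reduction between two covariate values is
`1 − E[g₂]/E[g₁]`, summarised over posterior draws. The companion Gaussian
regression of residual mass on generations of selection is ordinary least
squares (statsmodels), reporting the slope in kg/generation and its
8-generation implication.

The year-trend analysis of grade proportions uses a purpose-written Newton
multinomial logistic fitter (reference category 0, step-halving, ridge 1e-6
refit under complete separation) with year as a continuous covariate and sex
as a main effect; the proportional-odds diagnostic is a likelihood-ratio
comparison against a cumulative-logit fit (statsmodels `OrderedModel`).

## Synthetic breeding programme

The generator emulates a two-decade screening programme with discrete
generations. Per cat: liability `ℓ = μ + a + pe`; each hip's grade is
`ℓ + eₕ` (independent unit-normal per hip) cut at fixed generative
thresholds; body mass is a sex-specific Gompertz curve
`m(a) = A_sat·exp(−b·e^{−ca})` (defaults `A_sat` 4.6/6.8 kg for
females/males, `b = 3`, `c = 0.008 d⁻¹`, i.e. near-adult mass by ~18 months)
plus a genetic deviate correlated with hip liability and Gaussian noise.
Assessment ages are log-normal with median 520 days; submission
(phenotyping) is female-biased (80% vs 43%) to mirror the roughly 65/35
female/male split of real submissions, and body mass is recorded for a
configurable fraction of submitted cats.

Selection: breeding candidates come from the previous generation's
*submitted* cats; cats with grade ≥ 2 on either hip are excluded
(configurable threshold), and grade-1 cats are paired only with grade-0
mates. Breeding values descend the pedigree as midparent plus Mendelian
deviation scaled by `½(1 − (F_s + F_d)/2)`, with inbreeding tracked
incrementally.

Pinning the latent h² and the cross-sectional score distribution fixes the
data-scale heritability implicitly: for the calibrated truth it is ≈ 0.31
(per-hip grades), somewhat below typical published data-scale estimates for
maximum scores — the data scale depends on the grade distribution and on
which response (per-hip vs worse-hip) is transformed, so the two are not
interchangeable.

**Calibration.** The default cutpoints `(1.470, 3.413, 5.508)` and liability
standard deviation (`V_A = 4.239`, `V_PE = 3.073`, i.e. latent h² = 0.51)
were solved by Gauss–Hermite quadrature so that the *unselected* (founder)
distribution reproduces the published cross-sectional anatomy: 37.4%
prevalence, maximum-grade shares 22/12/4%, and 36.9% unilateral involvement
among affected cats. Matching the strong bilateral predominance forces a
large shared-liability variance relative to the per-hip residual — the hips
of one cat are highly correlated (≈ 0.88), consistent with the published
left:right genetic correlation of 0.98. Under selection the programme-wide
prevalence falls below the cross-sectional figure by design; the published
cross-section stayed flat because of continual outside recruitment, which
the simulator does not model. The `selection_study_config` preset raises the
baseline liability so the generation-1 cohort has an expected maximum score
of ~0.85, the starting point of the selection-response analysis; its
reduction by generation 8 then *emerges* from the selection dynamics rather
than being imposed.

What passing recovery tests on these data do **not** show: robustness to
non-Gaussian liabilities, observer drift, overlapping generations,
litter-shared environments, immigration, or informative submission (cats
submitted *because* they look affected). The generator is deliberately
faithful to the model the estimators assume, so the tests validate the
estimators, not the model.

## Reference study conditions

Parameter-recovery studies use ~3000-cat pedigrees (150 founders, 8
generations × 360 kittens), per-hip records of submitted cats, selection
active, truth at the published magnitudes (latent h² exactly 0.5;
mass h² 0.57; r_G 0.285; for the genetic-correlation study all submitted
cats carry mass so ~2000 massed cats enter the bivariate model). These sizes
keep a full 20-replicate study within minutes on one CPU while leaving the
posterior informative (CI half-widths ≈ 0.1 for h², ≈ 0.12 for r_G). At
150 founders the *realized* founder-generation genetic correlation varies
around its expectation with sd ≈ 0.075, which is the dominant source of
seed-to-seed spread in r_G recovery.

## Known limitations

* No REML/frequentist animal models; no genomic relationships; no maternal
  effects or genetic groups.
* The bivariate sampler supports exactly two traits.
* Residual cross-covariance between traits is fixed at zero.
* Conjugate-gradient solves make per-iteration cost low, but extremely
  ill-conditioned systems (|r_G| → 1 with large pedigrees) will slow them.
* The multinomial trend model offers only year and sex as covariates through
  the convenience API (the underlying fitter accepts any design matrix).
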