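# Methods

## Model

Each brain structure's relative volume (% of total brain volume, TBV) is
analysed with a Gaussian linear mixed model with a single random intercept
per litter:

    y = Xβ + Zb + ε,   b ~ N(0, σ_l² I_L),   ε ~ N(0, σ_r² I_n)

Fixed effects are intercept, paternal diet, offspring sex and their
interaction. Diet is coded CD = 0, HFHSS = 1; sex is effect-coded
F = −0.5, M = +0.5, so the diet coefficient is the diet effect averaged
over sexes and the intercept is the CD mean averaged over sexes. Percent
change for a structure is reported as 100·β̂_diet/β̂_0, i.e. relative to the
model-implied CD mean averaged over sexes. With treatment-coded sex the
diet coefficient would instead be the female-specific effect; the
effect-coded choice matches reporting diet effects "independent of sex".

The random litter intercept is essential, not decorative: paternal diet is
assigned at the litter level, so pup-level OLS treats correlated littermates
as independent and inflates type-I error severely (the test suite
demonstrates >10% empirical rejection at a nominal 5% level under
litter ICC 0.5, while the mixed model stays at ~5%).

## Estimation

REML, with the variance ratio λ = σ_l²/σ_r² profiled out. For fixed λ the
criterion has the closed form

    (n−p)·log(σ̂_r²(λ)) + log|H(λ)| + log|X'H(λ)⁻¹X|,   H = I + λZZ'

minimised by a bounded scalar search over log λ ∈ [−12, 12]
(`scipy.optimize.minimize_scalar`, xatol 1e-8) plus an explicit boundary
evaluation at λ = 0; ties prefer the boundary, and boundary fits are
flagged. All quadratic forms are evaluated in the eigenbasis of ZZ'
(ZZ' = U diag(d) U'), which depends only on the design — an `LmeWorkspace`
therefore amortises one n×n eigendecomposition over arbitrarily many
response vectors, which is what makes 20,000-replicate power simulations
cheap (~1.6 ms per fit at n ≈ 100). Exactly noiseless responses are guarded
by flooring the residual sum of squares at the smallest positive float; the
fit then returns the exact fixed effects with (numerically) zero variances.

Agreement with independent implementations is part of the test suite: the
profiled optimum matches a 10,000-point brute-force λ grid (dense-matrix
oracle) on 20 random small datasets, and fixed effects, variance components,
Satterthwaite df and p-values match frozen reference values computed with
lme4/lmerTest on a regenerable synthetic dataset (df to ~1e-5 relative).

## Satterthwaite degrees of freedom

For a contrast c, df = 2(c'Ĉc)²/Var̂(c'Ĉc) with Ĉ the fixed-effect
covariance. The denominator uses the delta method: the analytic gradient of
c'C(σ_l², σ_r²)c in the variance components, and the inverse of the observed
REML information, computed as half the central-finite-difference Hessian of
the −2·REML criterion (step 1e-5 × the variance scale, shrunk near the
boundary). df is clamped to (0, n−p]; a singular information matrix falls
back to the residual df n−p with a warning.

At the boundary σ̂_l² = 0 the model degenerates to OLS and df is set to
n−p exactly. Note this makes df *discontinuous* in σ̂_l² at 0: the
delta-method value retains the (non-vanishing) uncertainty contribution of
the estimated litter variance, so it does not tend to n−p as σ̂_l² → 0.
lmerTest shows the same behaviour; the boundary rule is a deliberate
convention, not a continuity limit.

`welch_t_test` (used for body-weight comparisons) is the standard
unequal-variance t-test with Welch–Satterthwaite df. One degenerate case is
defined by convention: two constant samples with equal means return
t = 0, p = 1 (no signal, no noise); constant samples with unequal means have
no variance scale and raise.

## Multiplicity

Benjamini–Hochberg step-up adjustment (via `statsmodels.stats.multitest`)
across all converged structures in the run — the family is whatever was
actually tested, not a hard-coded 185. Default FDR level 0.10; uncorrected
screen threshold 0.05, with the chance expectation m·α reported alongside
(185 × 0.05 = 9.25). Non-converged structures are excluded and listed in the
report. Ties in p are broken by structure id for stable report ordering.

## Synthetic cohorts

The generator emulates the hierarchical design of a two-group paternal-diet
mouse MRI study:

- **Litters**: `n_litters_per_group` per diet (default 20, matching 20
  breeding pairs per diet). Litter size is categorical on 1..6 with default
  mass (0.02, 0.04, 0.09, 0.20, 0.35, 0.30) — concentrated on 4–6 pups,
  a realistic post-culling distribution; only the 6-pup cap is given by the
  study design, the shape is this package's choice and is configurable.
- **Sex**: alternating within litter from a seeded coin flip, so every
  litter is even to within one pup. `study_cohort` deterministically trims
  the largest litters to the imaged group sizes (CD 23M/24F,
  HFHSS 25M/26F; 98 pups over 40 litters); trimming can leave individual
  litters slightly unbalanced, which is why sex balance is an invariant of
  *generation*, not a validation error on arbitrary rosters.
- **Volumes**: per structure s and pup i,
  y_is = μ_s(sex_i)·(1 + δ_s/100·[HFHSS]) + b_litter + ε, with
  b ~ N(0, σ_l,s²) per litter and ε ~ N(0, σ_r,s²). Structures are
  simulated independently on the relative scale and are *not* renormalised
  to sum to 100 — mirroring a per-structure simulation design and avoiding
  compositional coupling. Effects are multiplicative on the sex-specific
  HFHSS mean.
- **Structure parameters**: means log-uniform on 0.01–5 %TBV with mild
  (±5–8%) sex dimorphism; litter SD 1–15% and residual SD 3–15% of the
  structure mean. These ranges bracket the litter ICCs (~0.05–0.5) typical
  of inbred-mouse volumetrics.
- **Weights**: weekly sire weights over weeks 0–8, linear growth
  (defaults 0.625 vs 0.85 g/week, so the HFHSS eight-week gain exceeds CD
  by exactly 36%) plus N(0, 0.7 g) per record. Per-subject growth-rate
  heterogeneity is *not* modelled; gains are therefore slightly
  better-behaved than real cohorts.
- **Randomness**: every stream derives from
  (base seed, purpose, structure id[, replicate]) via `SeedSequence`, so
  per-structure results are reproducible and independent of evaluation
  order; removing a structure never perturbs another's draws.

What passing tests on these cohorts show — and what they do not: the
generator produces exactly the Gaussian two-level hierarchy the model
assumes, so the suite validates the *statistics* (calibration, power,
recovery), not robustness to segmentation error, non-Gaussian biological
variation, missingness mechanisms or structure-to-structure correlation,
none of which are simulated.

## I/O conventions

UTF-8 TSV with header, "." decimal separator. Canonical volume dialect is
wide (first column `sample_id`, one column per structure); long
(`sample_id, structure_id, volume_mm3`) is accepted for interchange. Floats
are written with `%.17g` and parsed with round-trip precision, so
write→read is value-exact. TBV is defined as the **sum of the segmented
structure volumes of that sample** — an explicit convention, since any
change to the denominator changes every relative volume. Samples with any
missing structure volume are dropped (with a warning) before the relative
conversion, because a partial sum would bias the denominator of every
remaining structure.

`extract_structure_params` returns *model-implied* sex means at the
reference diet (intercept ± half the sex effect), not raw group means: the
model-implied means are consistent with the variance components that
accompany them and are robust to litter imbalance between sexes.

## MDVC procedure

Per structure: simulate both diet arms on a fixed template design (CD at
baseline, HFHSS mean scaled by 1 + δ/100), fit the full LME, test the diet
main effect, and record the rejection fraction at α = 0.001 over the effect
grid 0, 0.5, 1, 1.5, 2, 3, 5, 7, 11, 15, 20, 40%. The MDVC is the first
upward crossing of 80% power, linearly interpolated; later dips (Monte-Carlo
noise) are ignored. Curves saturated at the grid minimum are left-censored,
curves never reaching the target right-censored. Production default is
3000 iterations per grid point; tests and examples use 150–800, with
Monte-Carlo envelopes (3 binomial SEs) derived from the iteration count in
every comparison. The template design is held fixed across replicates —
power is conditional on the realised breeding structure, not averaged over
hypothetical ones. Both arms are simulated (rather than re-using one arm's
real data) to keep the procedure self-contained and symmetric. The
per-replicate test is the single diet main-effect contrast from the full
interaction model.

The analytic oracle computes the same power without simulation: the exact
GLS standard error from the true variance components, noncentrality
δ/100·(μ_F+μ_M)/2 / SE, Satterthwaite df at the true components (expected
REML information, computed via the projection-matrix trace identities), and
the two-sided noncentral-t tail probability. scipy's `nct` far tail can
underflow to NaN at moderate noncentrality; a non-finite tail is replaced by
its Gaussian approximation, which is negligible exactly where the problem
occurs. At σ_l = 0 the oracle reduces to the textbook fixed-effects
noncentral-t power formula (verified to 1e-6).

`volume_to_linear_change` converts a percent volume change to the
equivalent percent change in linear dimension under isotropic scaling:
100·((1+δ/100)^{1/3} − 1); a 1.4% volume change is a 0.5% linear change.

## Canonical test structure

Calibration and self-consistency checks use one fixed synthetic structure:
mean 0.8/0.84 %TBV (F/M), litter SD 0.05, residual SD 0.10 (litter ICC
0.2) on the 98-pup study template. Its MDVC under the default procedure is
≈ 14%, comfortably interior to the effect grid, and its null rejection rate
at p < 0.001 over 20,000 replicates is statistically indistinguishable from
nominal.

## Known limitations

- Single random intercept only: no random slopes, no crossed or nested
  factors, no ML (non-REML) estimation.
- Structures are analysed and simulated independently; the compositional
  constraint (relative volumes summing to 100) and inter-structure
  correlations are ignored.
- The Satterthwaite boundary convention (df = n−p at σ̂_l² = 0) is
  anti-conservative relative to the delta-method value in near-boundary
  designs, though empirically calibration at study scale is nominal.
- Weight simulation has no subject-level growth heterogeneity.
- No image or segmentation I/O: the pipeline starts from volume tables.
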