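# Methods

## Growth-rate estimation

The primary quantity is the exponential growth-rate constant α (d⁻¹) of
cumulative metastatic volume between the last pretreatment scan (TP₋₁) and
the treatment-initiation baseline (TP₀). With exactly two observations the
least-squares exponential fit has the closed form α = ln(V₀/V₋₁)/Δt, and
`fit_exponential_two_point` evaluates it directly; `fit_growth_model` runs
the general bounded nonlinear least-squares path (trajectory integrated from
the first observation, residuals on raw volume in cc) and reproduces the
closed form to better than 10⁻⁶ relative — the two routes are kept separate
so each can check the other. Residuals can optionally be taken on log-volume
(`log_scale=True`); raw volume is the default because the estimand is a
volume trajectory and the two-point fit is insensitive to the choice.

Six alternative growth laws are registered (forms of Murphy, Jaafari &
Dobrovolny, BMC Cancer 2016): Mendelsohn dV/dt = aV^b, logistic
aV(1 − V/b), linear aV/(V+b), surface aV/(V+b)^{1/3}, Gompertz aV·ln(b/V),
Bertalanffy aV^{2/3} − bV. They are solved with LSODA (rtol 10⁻⁹); the
exponential uses its analytic solution. Volumes are floored at 10⁻³ cc
inside log-based right-hand sides so evaluation stays finite. Default
bounds keep solutions biologically plausible: rate-like parameters in
[−1, 1] d⁻¹, capacities in (max observed volume, 10⁶ cc]; default inits are
α = 0.01 d⁻¹ and capacity = 10 × max observed volume. Only the exponential
rate is identifiable from two timepoints; a fit with fewer free residuals
than parameters (the trajectory anchor consumes one observation) is returned
with `underdetermined=True` rather than refused, since univariate
two-point fits of multi-parameter laws are a legitimate descriptive
exercise as long as the caveat is explicit.

A note on the capacity limit: logistic trajectories converge to the
exponential uniformly as b → ∞ (error O(V/b)). The Gompertz law does not
converge under fixed a; with the rate matched at the initial volume
(a = α/ln(b/v₀)) the log-scale discrepancy is ≈ (αt)²/(2 ln b), so the
"reduces to exponential" property is only meaningful at modest total
log-growth, and the tests check it there plus the monotone shrinkage in b.

## Cohort model and imputation

Input is lesion-level: each contoured lesion's volume per timepoint, summed
exactly per patient per timepoint. All times are day offsets from TP₀.
De-novo metastatic patients (no measurable disease at TP₋₁) carry no TP₋₁
rows; `impute_pretreatment` inserts the assumed state — 0.1 cc at −90 days
by default, i.e. just-detectable disease one surveillance interval before
baseline. The operation is idempotent and total on valid timelines. An
imputation volume above the patient's baseline volume forces α negative by
construction and triggers a warning (the imputed state would exceed the
minimal detectable volume). Pretreatment intervals outside −363…−6 days are
admitted with a warning — the range is descriptive of typical surveillance
imaging, not a validity rule. Only TP₋₁/TP₀ ever enter α; on-treatment
scans (TP₊₁/TP₊₂) feed the response metric exclusively.

## Survival machinery

OS, PFS and PFS2 are days from treatment initiation; death counts as an
event for all three, so PFS ≤ OS and PFS ≤ PFS2 row-wise (enforced at
load). The Kaplan–Meier product-limit estimator and the two-group
Mantel–Haenszel log-rank test are implemented directly on arrays:
tied events share one risk-set update, censorings tied with events remain
at risk for that update, the per-time variance is hypergeometric, no
continuity correction, p from the χ²(1) upper tail. Zero pooled events give
statistic 0, p 1. "3-year" rates are evaluated at 1095 days. Median
survival is the smallest event time with Ŝ ≤ 0.5, with an explicit
not-reached signal (None) otherwise. The implementation is cross-checked in
the tests against a naive O(n²) statistic, an exact permutation oracle at
n = 8 (agreement within the χ² approximation error, 0.15 on p, set in
advance), the lifelines reference implementation (10⁻¹⁰ on Ŝ, 10⁻⁸ on p),
and a 1000-replicate null simulation of its size.

## Stratification and sensitivity

Quartiles use linear interpolation between order statistics (the numpy
default convention; configurable, since conventions differ at these sample
sizes). Slow/fast is dichotomized at the upper quartile with the boundary in
the slow group (α ≤ q₃). With 86 distinct values this puts 21–22 patients
in the fast group, which then coincides with Q4. All quartile pairs plus Q4
vs pooled Q1–3 are compared; metastasis-count subgroups split at ≤ 5
lesions (the conventional OMD cutoff).

The sensitivity grid re-imputes de-novo patients over volumes
{0.01, 0.1, 1} cc × offsets −150…−30 d in 30-day steps, recomputes their α
(measured patients' α never changes), re-derives the quartile threshold per
cell by default (a fixed threshold is available via config — the published
style of threshold is itself a cohort upper quartile, so re-derivation is
the self-consistent choice), and re-runs the slow/fast log-rank per
endpoint. Cell-wise α follows ln(V₀/V_imp)/|offset|: strictly decreasing in
the imputed volume always; in |offset| the magnitude shrinks as the
interval grows, so α increases with shorter intervals exactly when
V₀ > V_imp and decreases when V₀ < V_imp (possible at the 1 cc grid edge for
sub-cc baselines). The tests assert this complete algebra rather than the
positive-numerator special case.

## Association panel

Volumetric response is 100·(V_TP₊₁ − V_TP₀)/V_TP₀, clamped at −100%.
Spearman ρ uses midranks; the two-sided p is an exact full-enumeration
permutation value for n ≤ 9 without ties and the t approximation otherwise.
Cramér's V = √(χ²/(n·(min(r,c) − 1))) from the contingency table; for α
against categorical covariates, α is discretized into its cohort quartiles
(the slow/fast binary is available by passing groups instead). Coefficients
map to strength labels through configurable ordered bands; defaults are
|ρ| ≥ 0.8/0.6/0.4/0.2 (very strong/strong/moderate/weak) and
V ≥ 0.25/0.15/0.10/0.05.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline targets, with a
single seed expanded into per-patient substreams (cohorts extend without
reshuffling). Defaults: 86 patients; 51% de novo; α log-normal around
median 0.0471 d⁻¹ (σ = 1.0) with a 5% uniform negative component on
(−0.0062, 0); baseline volume log-normal around 28.4 cc (σ = 1.2) clamped
to 0.4–1194.8 cc; pretreatment interval log-normal around 90 days clamped
to 6–363; metastasis count log-normal around 7 clamped to 1–73. Baseline
volume and metastasis count share a latent normal with α (Gaussian copula,
rank correlation 0.5 each): faster-growing disease is detected at higher
burden and lesion count, which is also what makes the imputed α of de-novo
patients informative about their true pace. True volumes satisfy
V(t) = V₀·e^{αt} exactly; observed volumes carry multiplicative log-normal
noise (σ = 0.15 by default), split into lesions by a Dirichlet draw that
conserves the total.

Survival: event times are exponential with rate h₀·exp(β·α), defaults
h₀ = 1/1500 d⁻¹ and β = 15 per unit α; progression runs at 1.5× the death
rate, PFS = min(progression, death), PFS2 adds an independent exponential
second-progression gap capped at death — the simplest structure giving the
OS > PFS2 > PFS ordering. Censoring is uniform on 365–1765 days (median
follow-up ≈ 35 months). Best-response labels derive from the true
post-treatment trajectory (α reduced by a normal treatment effect,
mean 0.05, σ 0.05) with volumetric CR/PR/SD/PD cutoffs of −95/−30/+20%.

What the generator does **not** emulate: inter-lesion growth heterogeneity
(all lesions share the patient's α), non-exponential true kinetics,
informative censoring, measurement error correlated across timepoints, or
any treatment-effect dependence on burden. Passing tests therefore
demonstrate that the pipeline recovers parameters and effects under its own
model assumptions at realistic sample sizes — not that the exponential model
is correct for real tumors.

## Problem sizes and numerical choices

Simulation-based tests use: 1000 random fits for closed-form agreement,
100 seeds for the noise-propagation bound (median |α̂ − α| within
2σ/median|Δt|), 1000 replicates for the log-rank null size, 200 replicates
each for effect recovery (power ≥ 0.8 at β = 15; measured ≈ 0.92) and the
β = 0 null, 500 replicates for p-value uniformity, and 120 seeds for
generator calibration (cohort medians within a factor-2 band of the
emulated study's descriptives). Ties in the waterfall table break by
patient_id; all pipeline outputs are pure functions of (inputs, config), so
report bundles are byte-identical across reruns.

## Known limitations

Two-timepoint α has no within-patient uncertainty estimate (no residual
degrees of freedom); the quartile threshold is cohort-relative, so it is not
transportable across cohorts without recalibration; no multivariable
adjustment (Cox or otherwise) is provided; the exact-permutation Spearman p
is limited to n ≤ 9 by enumeration cost; and the log-rank p uses the
asymptotic χ²(1) reference, which is rough below ~10 events per group.
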