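# Methods

## The problem

A longitudinal MRI study samples each participant's trajectory at a handful
of acquisition times. Given a dense schedule (five scans at 4-week
intervals over six months), any 3-scan subset that keeps the baseline is a
candidate cheaper design. Whether a subset is "good" is judged against the
full schedule on three criteria: does it estimate the same
participant-specific change, does it need more participants for the same
statistical power, and does it find the same MRI–clinical associations?
This package implements that evaluation loop, driven by a simulator because
the dense patient cohorts this question arises from are rarely shareable.

## Generative model (simulator)

For participant *i*, bundle–measure cell (b, k), at acquisition week
*w<sub>it</sub>*:

    y_itbk = mu_bk + beta_bk * w_it + x_i' gamma + a_ibk + b_ibk * w_it + e_itbk

with (a, b) bivariate normal — standard deviations `intercept_sd`,
`slope_sd`, correlation `intercept_slope_corr` — and i.i.d. Gaussian
residuals `noise_sd`. The recorded "true slope" is beta + b. Acquisition
weeks are the nominal schedule plus Uniform(−jitter, +jitter) (default ±7
days, baseline pinned at week 0 and never jittered: with 4-week gaps and
±1-week jitter, acquisition order cannot invert). Covariate coefficients
gamma default to zero: the analysis *adjusts* for age/sex/disease duration,
but no credible published effect sizes exist for these bundle-averaged
measures, so the simulator does not invent them (they are configurable).

Defaults emulate a 6-month monthly-scan cohort: 20 participants (4 M / 16 F,
age 36 ± 4.7 y, disease duration 7 ± 5.9 y), sessions at weeks
{0, 4, 8, 12, 16} (100 scans), 5 bundles × 8 diffusion/myelin measures.
Measure values sit on a normalized scale: baseline level 1.0, population
slope −0.002/week, between-participant slope spread 0.004/week, residual
noise 0.01. These were chosen once as a *high-information regime* — the
per-participant OLS slope standard error over 5 sessions (≈0.0008) is small
against the slope spread, giving individual-slope reliability ≈0.96 — i.e.
a setting where design differences are attributable to the schedule rather
than to hopeless measurement noise. Noise sweeps are exposed through
`noise_sd` (scalar or per-measure/`bundle:measure` mapping).

Clinical change scores are coupled to the true slopes of an anchor
(bundle, measure) on the **rank scale**: normal scores of the slope ranks
enter a Gaussian copula with latent Pearson r = 2·sin(π·ρ_s/6), so the
population Spearman correlation equals the target ρ_s exactly; marginals
are Gaussian with the configured change mean/sd (defaults: EDSS 0 ± 0.25,
SDMT 4.4 ± 13.8, 9HPT −0.9 ± 3.5, T25FW −0.12 ± 1.0, with matching baseline
marginals). The default coupling ρ_s = 0.5 is a deliberate middle ground:
strong enough that a 20-participant cohort has reference associations to
preserve, weak enough that subsampled designs can lose them.

What the simulator does **not** emulate: non-linear trajectories (lesion
dynamics plateau in reality; everything here is linear in time),
measure-to-measure correlation within a scan, session-level artifacts
shared across bundles, floor/ceiling effects in clinical scores, and
informative dropout. Passing tests therefore demonstrate that the
*machinery* is correct and that design effects emerge under linear truth —
not that any particular real cohort behaves this way.

## Designs

A design is an ordered baseline-anchored subset of session indices, named
by its digits (`D_014`) with `D_R` for the full set. `enumerate_designs(n, k)`
yields the reference plus all C(n−1, k−1) subsets; for (5, 3) that is the
canonical menu {D_R, D_012, D_013, D_014, D_023, D_024, D_034}. Duration is
the nominal week of the last retained session; interval type (balanced /
unbalanced short-first / unbalanced long-first) is judged on **nominal**
session weeks, not jittered acquisition times — it is a property of the
planned schedule, not of one realization.

## Participant slopes

Per (bundle, measure, design): `value ~ 1 + week (+ covariates)` with
correlated random intercept and slope per participant, REML via statsmodels
MixedLM. The participant's change over time is the fixed `week` coefficient
plus the conditional mode (BLUP) of their random slope — a deliberate
interpretation; a per-participant refit would forgo shrinkage and is
available implicitly via the OLS helpers. Time is continuous weeks from
baseline (jittered acquisition weeks by default; `time="nominal_week"`
switches to the schedule clock, since which clock the analyst uses is a
genuine choice). The response is centred before fitting so estimates are
exactly location-invariant; the centring is restored in the reported
intercept.

Three-timepoint random-slope fits are fragile, so estimation cascades:

1. correlated random intercept + slope (REML, BFGS);
2. independent random intercept and slope (off-diagonal fixed at 0) when
   (1) fails to converge or its random-effects covariance is singular
   (relative eigenvalue < 1e-4);
3. random intercept only, with participant slopes = fixed slope + centred
   per-participant OLS slope deviations.

The route taken is recorded in `fit_meta`. One extra short-circuit: when
every participant's data are exactly collinear (zero residual sum of
squares, e.g. noise-free simulations), REML is a 0/0 problem and the
conditional modes coincide with per-participant OLS slopes, which are
returned exactly (`ols_exact_degenerate`). This is what makes zero-noise
recovery exact to machine precision rather than optimizer tolerance.

## Design comparison

Change vectors (participants × designs, complete cases) feed a one-way
within-subjects ANOVA: subject effects are removed, F = MS_cond/MS_error
with df (m−1), (n−1)(m−1). Sphericity is tested with Mauchly's W on an
orthonormal contrast basis (chi-square approximation with the standard
small-sample correction factor); when Mauchly rejects at 0.05 the
Greenhouse–Geisser ε = (Σλ)²/((m−1)Σλ²) multiplies both dfs (`correction=
"always"`/`"never"` bypass the conditional test, for users wary of the
test-then-correct critique; when n ≤ m−1 leaves Mauchly undefined, ε is
applied unconditionally). Tukey post-hoc comparisons reuse the
within-subjects MS_error and its df in the studentized-range statistic —
the standard coupling to RM-ANOVA. BH-FDR (statsmodels step-up) adjusts
each (bundle, measure) sweep's post-hoc family and the ANOVA family across
cells; the family definition is a documented choice, configurable at the
call sites. Pairwise design similarity is plain Pearson correlation of
slope vectors; zero-variance columns yield NaN with a warning rather than
a crash.

## Power and sample size

Within-subjects one-group ANOVA power uses the noncentral-F convention

    df1 = (m-1) eps,  df2 = (n-1)(m-1) eps,  lambda = f^2 n m eps / (1-rho)

with f = sigma_means/sigma (sigma the within-cell total sd) and rho the
average correlation between repeated measurements. The 1/(1−ρ) factor is
where repeated-measures correlation buys power: subtracting the shared
subject component shrinks the error term. The convention is validated
in-package against `mc_power_rm_anova`, a vectorized Monte-Carlo oracle
that draws compound-symmetric data (unit total variance, subject-component
variance ρ, condition means of spread f·σ_total) and computes the F test
directly from sums of squares — agreement holds across an
(n, m, f, ρ) grid at Monte-Carlo precision, which pins down the scaling
of f and the placement of ε. ε defaults to 1 at the planning stage.
At f = 0 the central-F branch returns power = α exactly.

ρ is estimated from data as the Fisher-z average (back-transformed) of all
m(m−1)/2 pairwise Pearson correlations between session columns; arithmetic
averaging is an option. Per-design ρ estimation is the default
interpretation (a pooled ρ is possible by estimating on the reference and
passing it explicitly). The solver brackets and bisects the monotone power
curve and certifies minimality (power(n) ≥ target > power(n−1)).

## Associations

Clinical change is always last-study-visit minus baseline, regardless of
the MRI design under evaluation — mirroring how a real study would have
assessed outcomes once, at the end. Slope–clinical associations use
Spearman correlation; significance is p < 0.01 uncorrected (configurable).
Small samples get exact inference: the Wilcoxon signed-rank test enumerates
the 2^n sign-assignment distribution for n ≤ 15 untied differences
(normal approximation with tie/zero corrections otherwise), and Spearman p
comes from the full n! permutation distribution for n ≤ 9 (t approximation
above). The preservation ledger classifies each tested-design cell against
the reference: preserved (significant in both, same sign), inverse
(significant in both, opposite sign), lost (reference only), new (tested
only); preserved + inverse + lost = reference total by construction, and
frequencies are percentages of that total. Requiring sign agreement for
"preserved" is the default because an opposite-direction association is a
qualitatively different failure; `require_sign_match=False` relaxes it.

## Pipeline and reproducibility

`run_study` executes simulate → fit → compare → power → associate, writing
tidy CSVs plus a manifest (package/library versions, seed, config hash,
per-stage seeds). All randomness derives from one root seed through named
SHA-256 substreams (< 2³¹), so stages are independently re-runnable and a
rerun is bit-identical. Every output table carries the seed and config
hash. Config validation happens before any compute.

## Problem sizes in tests and the acceptance script

Replicate studies (slope recovery, similarity ordering, preservation
frequencies) run on a single bundle–measure cell — the generative model is
i.i.d. across cells, so extra cells multiply cost without adding
information about the estimator. The test suite uses 200 replicates for
slope recovery and the D_034-vs-D_012 similarity ordering, 1000 null
matrices for type-I calibration, 5000 Monte-Carlo replicates per power-grid
cell, and 120 randomized matrices against the brute-force ANOVA oracles;
the acceptance script uses 100 replicates for recovery/similarity, 20 for
association preservation (2 bundles × 2 measures), and 20 000 for the
single power cross-check. Monte-Carlo checks are judged at 2 standard
errors per cell with the binomially expected allowance when many cells are
tested simultaneously (a correct method still leaves ~5% of cells outside
2 SE by chance; every cell must stay within 4 SE).

## Known limitations

- Linear trajectories only; no plateau/relapse dynamics, so designs are
  never penalized for missing curvature — the very effect that makes
  mid-schedule scans valuable in some real cohorts.
- The power model assumes compound symmetry with a single ρ; real session
  covariance decays with lag.
- The mixed model assumes Gaussian residuals and shares one residual
  variance across participants.
- Mauchly's chi-square approximation is poor at very small n (the code
  refuses n ≤ m−1 and falls back to unconditional ε-correction).
- Exact Spearman permutation enumerates n!; it is capped at n ≤ 9 by
  design.
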