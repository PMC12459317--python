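# Methods

## The model

Glycemic progression is modelled as a time-homogeneous continuous-time
Markov chain on three states — normoglycemia (NORMO), one prediabetes
phenotype (PRE = iIFG or IGT, fitted as separate pathway models), and
diabetes (DM, absorbing). The transition-intensity matrix Q (year⁻¹) has
free off-diagonals NORMO→PRE, NORMO→DM, PRE→DM and, in the bidirectional
base case, PRE→NORMO; diagonals are the negated row sums. Homogeneity means
rates do not change with age or calendar time within a stratum; stratified
analyses (age ≤60/>60 years at baseline, sex, BMI <23 / 23–<25 / ≥25 kg/m²)
fit a separate Q per stratum with no pooling, which relaxes this assumption
between but not within strata.

States are observed only at scheduled visits (a panel design), so the
likelihood of an observed pair (i at t, j at t+dt) is the matrix-exponential
probability `P_ij(dt)`, and the data reduce to aggregated counts over
(from, to, dt) cells. DM is treated as panel-observed like any other state:
we know it was present at the first visit that showed it, not when it began.
An exact-onset-time likelihood is deliberately not implemented.

Direct transitions NORMO→DM are allowed even though biologically the path
passes through prediabetes: with biennial observation a NORMO→DM pair is
common (the PRE episode fell between visits), and the three-state model
absorbs it as an apparent direct rate rather than misattributing it.

## Fitting

The log-likelihood is maximised over θ = log q for the allowed transitions
(positivity by construction) with L-BFGS-B, gradient tolerance 1e-8, from
three starts: crude-rate initial values (count_ij / person-time in i,
person-time approximated by total interval length starting in i), and the
same scaled by 0.5 and 2. θ is boxed to [−12, 3] (≈ e⁻¹² to e³ events/year);
a solution at the lower box edge means the transition is effectively
unobserved and is flagged with a warning, as is non-convergence — flagged
fits are reported, never dropped. The covariance of θ̂ is the inverse of a
central-difference Hessian of the negative log-likelihood (step 1e-4),
symmetrised and, if needed, projected onto the positive-semidefinite cone.

Matrix exponentials use scipy's scaling-and-squaring `expm`; an independent
uniformization-series implementation lives only in the test suite as an
oracle. The inverse map from an annual probability matrix to a generator
uses the principal matrix logarithm `logm` and enforces embeddability:
eigenvalues must be real and positive, off-diagonal log entries below
−1e-8 are an error, tiny negatives above that (rounding in printed inputs)
are clipped to zero with rows re-zeroed, and the result must reproduce the
input under `expm` to 1e-8.

### Confidence intervals

All functionals (ATP, residence times) get percentile 95% CIs from B = 1,000
draws of θ ~ Normal(θ̂, Cov θ̂) pushed through exp → Q → functional. Normal
simulation was chosen over the delta method because one mechanism serves
every functional, including the nonlinear fundamental-matrix entries; it is
seeded and reproducible. A degenerate (zero or singular) covariance
collapses the CI to the point estimate and flags it. Calibration is checked
in the test suite: at n = 1,000 subjects, nominal-95% CIs for the q_ij cover
the generating truth in ≥ 85% of 40 seeded replicates.

## Classification and cohort assembly

Thresholds (mg/dL; HbA1c %): DM iff FPG ≥ 126 or 2h-PG ≥ 200 or
HbA1c ≥ 6.5 or anti-diabetic medication; else IGT iff 2h-PG ∈ [140, 200);
else iIFG iff FPG ∈ [100, 126); else NORMO. The combined IFG+IGT phenotype
classifies as IGT, so "iIFG" is genuinely isolated IFG. A follow-up visit
with FPG but no OGTT is classified on the remaining criteria (the 2h-PG
clause is skipped); a strict mode errors instead, for analyses that require
complete OGTTs.

The exclusion cascade removes, in order: (1) missing baseline demographics
or labs, (2) no follow-up glycemic assessment, (3) prior or baseline
diabetes, (4) cardiovascular disease history, (5) cancer history. A subject
failing several steps is tallied at the first; the cascade is idempotent.

Missed internal visits are filled by last observation carried forward
(LOCF): the most recent observed state is retained until the next
observation. Nothing is extrapolated past the last attended visit, and
histories are truncated at the first DM observation. Visits classified as
the *other* phenotype (e.g. IGT inside the iIFG-pathway model) follow a
configurable off-state policy: `merge` (default) maps them to NORMO — such
a visit is "not prediabetic in this model" — while `censor` splits the
history at the off-state visit. `merge` keeps every included subject in both
pathway models; row totals under either policy are reported so the choice
is auditable.

### Interval grids: `locf` vs `raw`

Two reductions of a history to interval counts are supported. `locf`
(default for data ingestion) places every filled grid point on the biennial
schedule, so all intervals have dt = 2. `raw` keeps only attended visits at
their actual times, so a missed visit yields one dt = 4 interval instead of
two dt = 2 intervals through an imputed state.

These are not statistically equivalent. LOCF-filled states are measurement
error whenever the true state changed during the gap, and this attenuates
fitted intensities; the package's own simulations at 20% per-visit
missingness show recovered NORMO→IGT annual probabilities biased low by
roughly 15% under `locf`, while `raw` — the exact interval-censored
likelihood for the attendance pattern — is unbiased. Consequently the
simulate-and-refit validation protocol (acceptance script and recovery
tests) uses `grid="raw"`: a recovery check must use a likelihood consistent
with the observation scheme, or estimator bias would be indistinguishable
from implementation error. `locf` remains the ingestion default because it
mirrors how such panel studies commonly prepare their analysis grids; users
with non-trivial missingness should prefer `raw`.

### Unidirectional sensitivity variant

With regression PRE→NORMO removed from the model, an *observed* PRE→NORMO
pair has probability exactly zero and would send the likelihood to −∞. The
package drops such inadmissible pairs from the unidirectional fit and
reports their number in the fit diagnostics (`n_dropped`). This treats the
observed regressions as censored rather than re-labelling them (e.g.
monotonizing histories), which would fabricate PRE person-time. The
unidirectional variant is therefore a sensitivity analysis, not a nested
likelihood-ratio comparison.

### Residence times

Expected total years in each transient state before absorption is the
start-state row of the fundamental matrix `(−Q_TT)⁻¹`, equal to
∫₀^∞ P_{start,j}(t) dt (verified against quadrature to 0.1% in tests).
Reported residence times condition on starting in normoglycemia by default;
the start state is an explicit argument because a single "total length"
figure is only meaningful relative to a stated starting state. Note the
horizon is infinite and mortality is not a competing risk, so residence
times are model-based extrapolations, not restricted means.

## The synthetic cohort generator

The generator emulates the panel design the analysis assumes: latent
trajectories Gillespie-sampled from Q (holding times Exponential(−q_ii),
jumps ∝ q_ij), biennial observation over a 20-year horizon, baseline always
attended, later waves attended independently with per-wave probabilities
(default declining linearly 0.95 → 0.60 over ten waves; configurable,
including a constant rate). Defaults: 10,000 subjects; baseline
prediabetes probability 3.5% (iIFG pathway) or 23.5% (IGT); age ~
Uniform(40, 69); P(male) = 0.469; BMI ~ Normal(24.5, 3.1); exclusion strata
at rates 20.2% prior diabetes, 1.77% CVD, 0.73% cancer, 0.7% missing
baseline labs, 0.13% no follow-up — magnitudes typical of the middle-aged
East Asian community cohorts this design mirrors. The reference generators
are principal matrix logarithms of annual matrices in the published range
for such cohorts (`ANNUAL_P_IIFG`, `ANNUAL_P_IGT`).

Biomarkers are drawn from truncated normals confined to the latent state's
defining region (means/SDs loosely matched to published baseline tables;
only the truncation region is contract-bearing), so classification
round-trips the latent state exactly. DM emission satisfies one criterion
chosen uniformly among FPG, 2h-PG, HbA1c and medication — so some diabetes
is detectable only by medication with normal-range glucose — and the
medication flag persists once set.

What the generator does **not** emulate: informative dropout (attendance is
independent of health state, i.e. missing at random), covariate-dependent
intensities (strata are homogeneous unless simulated as separate configs),
mortality as a competing risk, biomarker measurement error spanning state
boundaries, and within-subject biomarker autocorrelation. Passing recovery
tests therefore demonstrates correctness of the estimator under the model's
own assumptions, not robustness to their violation in real cohorts.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use 8,000-subject cohorts (≈ 45,000
visit-pair intervals), which puts Monte-Carlo error of recovered annual
probabilities near or below the width of published CIs from comparable
cohorts; CI-calibration replicates use n = 1,000 for breadth (40 replicates)
over depth. Row-sum and stochasticity tolerances are 1e-10; probability
entries are floored at 1e-300 inside the optimiser (the public likelihood
returns −∞ for structural zeros); visit times must sit on the scheduled grid
to 1e-9 years in `locf` mode. Ties at classification boundaries follow the
inclusive conventions above; BMI bins are left-closed ([23, 25)); age 60
belongs to the ≤60 stratum.

## Known limitations

* Time-homogeneous intensities within stratum; no proportional-intensity
  covariate model, no hidden-Markov misclassification layer.
* The unidirectional variant discards observed regressions (see above), so
  its PRE sojourn estimates are conditional on non-regression.
* Residence times extrapolate beyond the observation horizon and ignore
  death; in older cohorts they overstate time genuinely available.
* The normal-simulation CIs are asymptotic in spirit; with very few
  intervals per cell (small strata) they can undercover, and fits there are
  flagged rather than suppressed.
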