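# Methods

## The exposure–response model

The primary analysis is a linear mixed-effect regression of the
placebo-corrected, baseline-adjusted Fridericia-corrected QT change (ΔΔQTcF,
ms) on the time-matched plasma concentration C (ng/mL):

ΔΔQTcF_ij = (θ₀ + η₀ᵢ) + (θ₁ + η₁ᵢ)·C_ij + θ₂·(Bᵢ − B̄) + ε_ij

* θ₀ (ms): population intercept — the drug-attributable QTc change in the
  absence of drug; near 0 when the placebo correction is unbiased.
* θ₁ (ms per ng/mL): the concentration slope, the quantity of primary
  interest.
* θ₂ (ms/ms): coefficient of the subject's baseline QTcF Bᵢ, centred at the
  mean B̄ of the subject-level baselines over subjects contributing rows.
  Centring makes θ₀ interpretable at a typical baseline; fixed effects are
  invariant to the centring constant up to the implied intercept shift
  (θ₀ changes by θ₂·Δcentre), which a test verifies.
* (η₀ᵢ, η₁ᵢ) ~ N(0, Ω) with Ω unstructured (2×2, positive semi-definite by
  construction); ε ~ N(0, σ²) independent.

A direct-effect model of this form presumes no hysteresis and an
approximately linear exposure–response relationship; both assumptions have
dedicated pre-modeling checks (below).

### Regulatory read-outs

`predict_ddqtcf(fit, c, level)` evaluates the mean θ₀ + θ₁·c at centred
baseline 0 with variance v₀₀ + c²v₁₁ + 2c·v₀₁ from the fixed-effect
covariance, and a two-sided CI (default level 0.90) using the t distribution
with df = n_subjects − n_fixed — a deliberately conservative, configurable
rule, since between-within and Satterthwaite conventions differ across mixed
model implementations while point estimates do not. Verdicts are strict
inequalities: *no prolongation* requires the CI upper bound < 10 ms at the
concentration of interest (2 × steady-state geometric-mean Cmax, the factor
2 covering intrinsic/extrinsic exposure increases such as drug–drug
interactions); *assay sensitivity* requires the positive-control
(moxifloxacin) lower bound > 5 ms at its observed geometric-mean Cmax. The
moxifloxacin analysis reuses the identical model with moxifloxacin
concentration as the regressor.

### REML estimation

Both the fixed effects and σ² are profiled out of the restricted likelihood,
leaving a 3-parameter optimization over the scaled covariance G = Ω/σ² in a
log-Cholesky parameterization (log diagonal, free sub-diagonal), which
enforces positive semi-definiteness without constraints. Random-effect design
columns are standardized internally so all optimizer coordinates are O(1).
Via the Woodbury identity every likelihood evaluation reduces to per-subject
cross-products computed once, so cost is O(subjects) small-matrix operations
per evaluation regardless of the number of observations.

Determinism: three fixed starts (scaled-identity G at 0.5, 0.05, 2.0),
Nelder-Mead (bounds: diagonal coordinates in [−12, 6], off-diagonal in
[−30, 30]) followed by an L-BFGS-B polish; best criterion wins, ties to the
first start. Degenerate data are handled by a floor on the profiled residual
sum of squares, so noise-free inputs return σ² ≈ 0 and Ω ≈ 0 rather than
failing. Rank-deficient fixed designs (e.g. a single distinct concentration)
raise an estimation error naming the deficiency.

The implementation is validated three ways: against closed-form balanced
one-way ANOVA variance components (rel. tol. 1e-6), against OLS under the
Ω = 0 constraint, and against statsmodels `MixedLM` as an independent
oracle — including a criterion comparison, since on ill-scaled problems the
oracle's default optimizer can stop at a worse restricted likelihood than
this implementation attains. A local-optimality audit asserts the returned
criterion beats 32 fixed perturbations of the variance parameters.

## Derivation chain

* HR = 60/(RR/1000); QTcF = QT/(RR/1000)^(1/3). QTcF is strictly decreasing
  in RR at fixed QT and homogeneous of degree 1 in QT (property-tested).
* Baseline = arithmetic mean of the pre-dose (time ≤ 0) QTcF replicates of
  that subject × treatment × period; by default the Day-1 baseline applies to
  all days of a period (`baseline_rule="per_day"` switches to day-specific
  pre-dose baselines — the choice matters only for multi-day designs, and
  multi-day studies rarely publish which convention they used).
* Crossover correction subtracts the same subject's placebo ΔQTcF at the
  identical nominal time; parallel correction subtracts the pooled placebo
  mean matched on day and nominal time (per-cohort matching available via
  `match_cols`). Time matching is exact on the nominal grid — both designs
  use fixed nominal schedules, so no tolerance window is needed.
* ΔHR/ΔΔHR run through the identical adjust/correct chain.
* Concentration pairing is exact on (subject, arm, period, day, time) with
  the analyte implied by the arm; pre-dose rows carry concentration 0. Every
  drop (missing placebo match, missing concentration) is counted, and
  rows out + dropped = eligible rows in, enforced by tests.
* Units are fixed (ms, ng/mL, h); no auto-detection, so coefficients are
  directly comparable across runs at full precision.
* Below-LLOQ concentrations are set to 0 and flagged, pre- and post-dose
  alike; with a single-dose design and a long half-life relative to the
  sampling window the rule rarely triggers.

## Diagnostics

Hysteresis and linearity are graphical judgements in regulatory practice;
here they are made machine-checkable with documented, configurable
thresholds that are *artifact policy, not regulatory constants*:

* HR effect: every timepoint's |mean ΔΔHR| < 10 bpm (strict), justifying a
  fixed HR correction.
* Hysteresis: peak of the mean ΔΔQTcF course must not trail the peak of the
  mean concentration course by more than `lag_tolerance_h` (default 1 h) on
  the shared nominal grid; peaks use earliest-maximum tie-breaking so flat
  courses are deterministic.
* Linearity: max |LOESS − linear| over an even concentration grid, flagged
  above 0.5 × the linear fit's residual SD (with a floating-point floor so
  exactly linear data never flag). LOESS is statsmodels lowess (tricube,
  local linear, span 0.75). The flag decision is invariant to affine
  concentration rescaling.
* Covariate-impact (e.g. challenge-test or diet groups): max between-group
  difference of mean ΔQTcF time courses against the same 0.5 × pooled-SD
  rule; a pass supports omitting the covariate from the model.
* Decile table: positive-concentration rows ranked and split into 10
  near-equal groups, remainder spread over the lowest groups; per-group mean
  concentration and t-based CI of mean ΔΔQTcF.

## Non-compartmental analysis

Linear-up/log-down trapezoid (log interpolation only between positive,
declining samples — identical to the plain trapezoid on non-decreasing
segments); Cmax/tmax at the earliest observed maximum; λz by log-linear
regression over the best-adjusted-R² contiguous window of ≥ 3 points
strictly after tmax, ties to the longer window. When no such window exists
(e.g. very short profiles) the last two positive samples are used, including
tmax only if unavoidable; a numerically flat tail reports λz as undefined
with a reason rather than a near-zero value. AUC∞ = AUC_last + C_last/λz;
the extrapolated fraction is reported so short sampling windows are visible
in the output. Geometric summaries use gmean = exp(mean ln v) and
gCV% = 100·√(exp(s²)−1); dose proportionality flags dose-normalized gmean
ratios outside 0.8–1.25.

## The simulator

The generator emulates the two study designs end to end with known truth.

* PK: two-compartment, first-order oral absorption, closed-form
  three-exponential solution; q = 0 selects the one-compartment limit and
  coincident rate constants use the exponential limiting form. Reference
  typical values — ka 1.2 /h, CL/F 3.0 L/h, V1 58 L, V2 45 L, Q 6 L/h — were
  chosen once so a 32 mg single dose gives Cmax ≈ 410 ng/mL, tmax ≈ 2 h, and
  a biphasic decline with terminal half-life ≈ 26 h (CL/F ≈ dose/AUC∞);
  inter-individual variability is log-normal on CL/F, V1 and ka at 25% CV,
  keeping PK variability under 30%. MAD mode superposes once-daily doses
  (steady-state accumulation ratio 1/(1 − 2^(−24/t½)) ≈ 2.3 at this
  half-life), with later-day pre-dose samples carrying the accumulated
  trough.
* QTc: QTcF(t) = Bᵢ + diurnal(clock) + [θ₀ + η₀ᵢ + (θ₁ + η₁ᵢ)·C(t)]·1{active,
  post-dose} + ε, with Bᵢ ~ N(412, 12²) ms, a two-harmonic cosine diurnal
  rhythm (24 h and 12 h periods, amplitudes 5 and 2 ms — a standard circadian
  QTc representation), Ω = diag(4 ms², (0.002 ms/ng/mL)²) and residual SD
  6 ms. The random intercept η₀ applies to post-dose active-arm records only,
  so it survives baseline adjustment and placebo correction and is
  recoverable as the model's random intercept; applying it to the arm's
  pre-dose baseline as well would cancel in the difference and make Ω₀₀
  unidentifiable from the truth record. The diurnal term is shared across
  arms, so time-matched crossover correction cancels it exactly — the
  zero-noise null chain yields ΔΔQTcF ≡ 0 to machine precision, and with a
  nonzero slope the chain returns exactly slope × concentration (both
  tested).
* QT is back-computed from QTcF and a simulated RR (900 ± 30 ms, with an
  optional HR-effect hook that shifts RR on chosen days so the ΔΔHR gate can
  be exercised both ways) through the inverse Fridericia transform, so
  re-derivation is exact.
* The positive-control arm uses a one-compartment moxifloxacin profile
  (Cmax ≈ 2370 ng/mL at 400 mg), slope 0.0044 ms per ng/mL and a fixed 2.6 ms
  offset, so the synthetic assay-sensitivity verdict behaves like a real
  positive control.
* Design: crossover uses the Williams square A/B/C/D, B/D/A/C, C/A/D/B,
  D/C/B/A with n a multiple of 4 (28 → 7 per sequence); washout is assumed
  complete (no carryover), consistent with ≥ 7-day washouts and a ~29 h
  half-life. MAD uses five cohorts randomized 3:1 active:placebo
  (2.5/5.0/1.5/2.5/0.5 mg; 42 active, 14 placebo), 10 days of dosing,
  ECG/PK days 1 and 10.
* Randomness: one global seed; each subject draws from
  `default_rng([seed, subject_index])`, so datasets are bit-identical per
  seed and independent of subject-generation order.

What the generator does **not** emulate: beat-level QT/RR measurement and
smoothing (intervals are generated per timepoint), assay error on
concentrations, dropout and missed visits, carryover, nonlinear (Emax) or
effect-compartment (hysteresis) pharmacodynamics, and outlier/arrhythmia
phenomena. Passing recovery tests therefore demonstrates the correctness of
the derivation and estimation chain under the stated generative model, not
robustness to those real-data features. One modeled-versus-generated
mismatch is deliberate: the two active arms of a crossover share the
placebo period's noise at matched times, inducing a residual correlation the
model does not represent — as in real TQT analyses — which is why CI
coverage is validated empirically (93–94% observed for the nominal 90% CI
at the reference configuration) rather than assumed exact.

## Simulation study sizes

Recovery studies use 200 replicates per design (crossover n = 28 with 4
arms × 11 sampling times; MAD n = 56 with 2 ECG days × 7 times), a size at
which the Monte-Carlo standard error of the replicate-mean slope is ≈ 5% of
the crossover generating value and ≈ 1% of the MAD generating value — small
enough to detect meaningful bias while keeping a full validation run in the
low minutes on one core.

## Known limitations

* The CI degrees-of-freedom rule is a convention; alternatives
  (Satterthwaite, between-within) would widen or narrow intervals slightly.
* λz from short profiles (the 2-point fallback) has no goodness-of-fit
  measure; `n_lambda_points` and `extrapolated_fraction` expose this.
* The parallel-design placebo correction pools placebo subjects across
  cohorts by default; per-cohort matching is available but reduces the
  placebo pool sharply in small cohorts.
* One published table cell the package intentionally does not reproduce: a
  source report of this analysis type prints a positive mean ΔΔQTcF at its
  high-dose Cmax whose own coefficients imply the negated value (the CI is
  centred near the negative value); the package reproduces the
  coefficient-implied number, treating the printed cell as a sign typo.
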