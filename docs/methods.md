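# Methods

`driftband` implements a joint behavioral–EEG analysis of perceptual
decision making: a hierarchical Bayesian drift-diffusion model (DDM) of
dot-motion choices whose drift and boundary depend on obsessive-compulsive
(Padua) and worry (PSWQ) questionnaire scores and on the slopes of an
aggregate gamma/beta band-power measure, plus the machinery that produces
those slopes from multichannel band power. Because no human dataset ships
with the package, a first-class synthetic-data module generates studies
with the same statistical structure and known ground truth; every
statistical claim the package makes is demonstrated by recovering planted
parameters.

## The decision model

Choices and reaction times are modeled with the simple DDM: evidence
accumulates from `a/2` (unbiased start, fixed because motion direction is
a fair coin) toward absorbing boundaries `0` and `a` with drift `v`, unit
diffusion SD (the standard identifiability convention), and a non-decision
time `ndt` added to the first-passage time. There is no trial-to-trial
parameter variability; the simple form trades the ability to capture
error/correct RT asymmetries for more robust parameter recovery.

The likelihood is the exact Wiener first-passage-time (WFPT) density,
evaluated through its small-time and large-time series expansions with the
expansion chosen per evaluation by comparing the number of terms each
needs for an absolute tolerance of 1e-10 on the normalized-time density.
Gradients with respect to drift, boundary, and non-decision time are
derived term-by-term from the same series, so gradient-based MCMC runs on
the exact likelihood. An RT at or below `ndt` yields a log density of
−∞ rather than an exception, which samplers treat as an ordinary
rejection.

### Regression structure

For subject `s` and condition `c` (six coherence levels in ascending
order), the full model sets

    drift[s,c] = drift_c[c] + drift_s[s]
               + drift_padua[c]·padua_z[s] + drift_worry[c]·worry_z[s]
               + drift_gamma[c]·gamma_z[s,c] + drift_beta[c]·beta_z[s,c]

with the boundary defined analogously. Symptom scores are z-scored once
across subjects; band slopes are z-scored across subjects within each
condition. Reduced variants drop the symptom block, the neural block, or
both. Subject effects `drift_s`, `boundary_s` are Gaussian with estimated
SDs (partial pooling; sampled non-centered), and subject non-decision
times share a Gaussian population prior.

Condition-level locations and every coefficient block are sampled on a
cumulative scale — the condition-1 value plus per-condition increments —
to reduce posterior correlation; all reported draws are mapped back to the
original scale.

### Priors

Normal(0, 20) on every cumulative-scale location and coefficient, except
the condition-1 boundary location, Normal(1, 20), biased positive because
separation must be positive. Subject-effect SDs have half-Normal(20)
priors; the non-decision group mean has Normal(0.5, 1) (seconds — RTs are
in seconds throughout) and its group SD half-Normal(1). Scale parameters
are sampled on the log scale with the Jacobian included. Subject
non-decision times are mapped through a scaled logistic to (0,
0.999·min RT of that subject), which keeps the posterior smooth where the
likelihood would otherwise hit the `rt ≤ ndt` cliff; the Gaussian
population prior is evaluated on the constrained value with the transform
Jacobian. On simulated data these priors are dominated by the likelihood
(widening them 10× moves medians by less than sampling error).

### Sampling and diagnostics

The package carries its own No-U-Turn sampler: slice-variant tree
doubling, dual-averaging step-size adaptation to a 0.8 target acceptance,
and Stan-style expanding-window adaptation of a diagonal mass matrix, with
divergence flagged at an energy error of 1000. The analysis configuration
is 4 chains, 1,000 warmup and 3,000 retained iterations per chain.
Convergence is summarized by split R-hat and effective sample size
(computed by arviz) over the reported-scale parameters; a maximum split
R-hat above 1.05 flags the fit as non-converged without aborting it, so
reduced-scale runs remain inspectable. At the reference configuration
(12 subjects × 240 trials, full variant) the fit runs in about ten
minutes on one CPU with no divergences and max split R-hat ≈ 1.001.

## Band power

Time-frequency power uses DPSS multitapers on a fixed 250 ms window with
±8 Hz smoothing — a time-bandwidth product of 4 and hence 3 tapers —
at 32–100 Hz (gamma) and 12–28 Hz (beta), both in 4 Hz steps, delegated to
mne's array multitaper with `n_cycles = freqs × 0.25 s`. Power is
log-transformed and z-scored per subject/condition/channel/frequency
against statistics pooled over the trials and samples of the 200 ms
pre-stimulus baseline, then averaged across each band's frequencies.
Output lands on a 50 ms grid (the grid the slope statistic needs; the
finer grid is an implementation detail of the engine), and windows that
would extend past the epoch are dropped rather than zero-padded to avoid
edge-biased baselines.

## Aggregate whole-brain measure

A hierarchical Bayesian logistic regression predicts trial difficulty
(hard = two lowest coherences = 0, easy = two highest = 1, middle two left
out) from band power at all electrodes, read out at each subject's median
hard-trial RT snapped to the nearest grid point. Channel predictors are
standardized before fitting, and coefficients get weakly informative
Normal(0, 2.5) priors on that scale with per-subject deviations pooled
through half-Normal(1) scales; per-subject intercepts are likewise pooled
(both hierarchy choices are this package's documented reading of a
"participant coefficients from a common Gaussian" model). The posterior
draws of the group-level channel coefficients then weight every channel,
trial, and time point — intercepts excluded — and the weighted sums are
averaged within subject × condition, giving the aggregate time course per
draw. Because the weighting comes from a logistic discrimination, the
aggregate is positive whenever power at the electrodes is more extreme for
easy decisions regardless of each channel's ramp sign.

The slope statistic is the mean of the ten consecutive 50 ms increments
between 300 and 800 ms (algebraically, `(y(800) − y(300)) / 10`), computed
per draw and subject and then reduced to the marginal median per
subject × condition for use as a covariate. Scalp maps come from `X·Y`
per subject (X = channel × time power, Y = time × draw aggregate), each
draw's column normalized by `YᵀY`, averaged across subjects, median across
draws — equivalently, per-channel regression of the channel's time course
on the aggregate through the origin. All analyses can be re-run after
excluding the 16 frontal channels (Fp/AF/F rows) as a robustness check.

The two-stage procedure (weights fit first, point-summary slopes passed to
the DDM regressions) is deliberate; a single overarching model coupling
the logistic weighting to the DDM is out of scope, matching the staged
design the analysis follows.

## Slope-on-symptoms regression

Per condition, `slope[s,c] = b0[c] + b_padua[c]·padua_z[s] +
b_worry[c]·worry_z[s] + ε`, with Normal(0, 20) coefficient priors,
half-Normal(20) residual SDs (per condition), and intercepts pooled
hierarchically with Normal(0, 20) hyperpriors. The same NUTS machinery
fits it; with 60 subjects the planted coefficients are recovered within
their credible intervals in seconds of compute.

## Effects and mediation

Reported summaries are posterior medians with central 95% credible
intervals; an effect is flagged "significant" when more than 95% of its
mass lies on one side of zero — a reporting convention only, never a
branch in the code, and deliberately uncorrected across the six conditions
to match the per-condition reporting style. Condition contrasts are
draw-wise differences. The mediation test compares a coefficient between
the full model and a reduced model fit independently: since the two
posteriors are independent, draws are paired by index after a random
permutation and the full-minus-reduced distribution is summarized like any
other effect. Formal indirect/direct-effect decompositions are out of
scope; only the coefficient change is tested.

## Synthetic data

The generator's defaults are the study conditions. A cohort of 67
subjects covers Padua bins 0–16 / 17–33 / 34–50 / 51+ with 19/18/15/15
subjects (reduced runs keep the bin structure at smaller counts); bin
scores are uniform within bins. Worry scores are drawn through a Gaussian
copula (correlation 0.4 with the Padua latent — a free parameter, not an
estimate) with a Beta(5, 2) marginal mapped to the 16–80 questionnaire
range, giving the documented right skew toward the upper range. Behavior
is 120 trials per coherence level (0.025–0.7) simulated from the DDM by
1 ms Euler–Maruyama with a Brownian-bridge crossing correction (without
the correction the boundary-overshoot bias of discrete stepping visibly
distorts the RT distribution); drifts and boundaries are assembled from
exactly the regression the sampler fits. Default truth: drifts rising
0.4→4.2 with coherence, boundaries near 1.6 and slightly smaller for easy
conditions, subject SDs 0.3 (drift) and 0.15 (boundary), non-decision
times near 0.4 s.

Band slopes are generated from the slope-on-symptoms regression on the
scale of the aggregate measure, which ramps upward in both bands; the
channel-effect map carries the sign and topography of the raw ramps
(positive posterior/lateral gamma, negative parieto-occipital beta, small
opposite-sign frontal effects). The planted pattern mirrors the headline
phenomenon: the OCD-score coefficient on drift is negative and
concentrated in easy conditions (0 → −0.35 across conditions), worry
coefficients are null, drift couples positively (0.25) to both bands'
aggregate slopes, the OCD coefficient on the beta slope is −0.04 per
z-unit (about −0.45 after per-condition z-scoring) and null for gamma.
Per-trial power tensors are baseline noise (SD 1, the natural scale of
baseline-z-normalized power) plus a post-stimulus linear ramp of
channel-effect × slope per 50 ms; raw oscillation epochs place a
band-carrier sinusoid under a ramping amplitude envelope for end-to-end
tests of the multitaper stage.

What the generator does **not** emulate: volume conduction and sensor
covariance, eye blinks and other artifacts, 1/f spectral background,
non-stationary ramps, RT-locked (rather than stimulus-locked) dynamics,
and any realistic joint distribution of symptom scores. Passing recovery
tests therefore demonstrates that the estimation machinery is correct and
calibrated under the model's own assumptions — not that the pipeline is
robust to the full messiness of real EEG.

## Numerical choices and problem sizes

Fixed seeds thread through every generator and sampler
(`numpy.random.SeedSequence` substreams per chain and stage), so all runs
are exactly reproducible. Series truncation uses the standard term-count
bounds at tolerance 1e-10; the simulator caps paths at 10 s and flags
censored trials (which the RT filter then removes). The test suite runs
every MCMC-backed check at deliberately reduced sizes — typically 6–32
subjects, 20–60 trials per condition, 2 chains with a few hundred
iterations — chosen so the whole suite exercises every claim in minutes;
the acceptance script runs the reference configuration (12 subjects, 40
trials per condition, 4 chains × 1,000 + 3,000) in full.

## Known limitations

The boundary regression can in principle drive `a ≤ 0` for extreme
covariates; such proposals are rejected as divergences rather than
reparameterized, which is harmless near the posterior but would slow
sampling under absurd truths. The logistic weighting standardizes
predictors at one time point; when the weights are applied to all time
points, only the per-channel scale is carried over (mean offsets belong
to the intercept, and dragging them into the aggregate would shift the
whole time course by a constant and corrupt the through-the-origin scalp
projection). A per-time-point scaling would break the linearity of the
aggregate in power. Mediation pairing by permuted index is one documented construction
for comparing independently fitted models; any pairing of independent
draws yields the same distribution in expectation.
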