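# Methods

`longdcm` estimates longitudinal changes in directed (effective) connectivity
of a small brain network from resting-state BOLD, and tests whether those
changes are transient, sustained, or coupled to clinical symptom scores.
Because the kind of patient data this targets (multi-session resting-state
fMRI around a focal intervention) is rarely public, the package ships a
first-class synthetic-cohort generator whose statistical structure matches
the inference model, so every stage is testable end to end.

## Generative model

### Neural dynamics

Each region's hidden neural state follows a linear stochastic differential
equation

    dx/dt = A_eff x + v

where `A_eff` is the effective coupling matrix (row = target region). The
stored matrix `A` uses the standard convention that off-diagonal entries are
coupling rates in 1/s, while diagonal entries are *log-scale* self-connection
parameters: the effective self-inhibition rate is `-0.5 exp(a_ii)`, negative
by construction, so `a_ii = 0` means a self-rate of -0.5/s and positive
`a_ii` means stronger self-inhibition. Stability of `A_eff` (all eigenvalues
with negative real part) is required everywhere and enforced by the cohort
generator with bounded rejection sampling.

Endogenous fluctuations `v` are scale-free: independent per region with
two-sided spectral density `alpha_v f^-beta_v` (default exponent 1).  All
spectra in the package are two-sided densities in signal²/Hz on grids in Hz;
with white noise this makes the stationary variance of a single node
`alpha_v / (2 * 0.5)`, which is one of the unit-test oracles.

Integration uses the exact matrix-exponential propagator for the linear
drift with the synthesized noise held constant over each step (dt = 0.05 s
default), and noise is synthesized in the frequency domain so its spectrum
is exact in expectation. Burn-in (at least 32 s neural, 64 s joint
neural+hemodynamic) is discarded so records are stationary and free of onset
transients.

### Hemodynamics

Observation runs through the Balloon–Windkessel model per region
(vasodilatory signal, inflow, venous volume, deoxyhemoglobin), driven by
`epsilon * x`, integrated by classical fixed-step RK4 on the simulation
grid. Defaults are the canonical values kappa = 0.64/s, gamma = 0.32/s,
tau = 2 s, alpha = 0.32, E0 = 0.4, epsilon = 1, V0 = 0.04. The static output
equation uses the classic constants k1 = 7·E0, k2 = 2, k3 = 2·E0 − 0.2
(recorded in every run manifest, since different field strengths imply
different constants). Hemodynamics are homogeneous across regions by
default; per-region transit-time and gain deviations are free parameters of
the inversion.

The default neuronal noise amplitude (3e-5) was chosen so simulated BOLD
fluctuates at roughly 1% signal change — typical for ROI-averaged
resting-state data — and, importantly, keeps the Balloon model in its
near-linear regime. With 1/f state noise most variance sits at very low
frequencies; large slow excursions drive inflow far from its fixed point
and the simulated spectrum then departs from the linearized prediction that
spectral fitting relies on. At the default amplitude that bias is a few
percent in band.

### Acquisition

Sessions are sampled at TR = 2 s for 165 volumes (330 s), with power-law
observation noise (default amplitude 0.02, exponent 0.5, i.e. a noise floor
a few percent of the in-band signal density), linear+quadratic drifts, and
fifteen confound regressors (six motion-like random walks, their first
differences, three slow nuisance components) that leak into the data with
small random gains so confound regression is a real operation, not a no-op.

## Cohort hierarchy

Ground truth follows the same three-level linear hierarchy used for
inference. Group-level coefficients `beta3` hold a baseline row (a weakly
coupled stable random network, off-diagonals N(0, 0.05²), diagonals 0) and
transient/sustained rows that are zero except where effects are planted.
Per-subject coefficients are `beta2_j = beta3 + N(0, sigma3²)` entry-wise
(random effects on all coupling entries), and per-session matrices are
`theta_js = X1[s] · beta2_j + N(0, sigma2²)` with the session design

    baseline  [1  1  1  1]
    transient [1 -1 -1  1]
    sustained [1  1 -1 -1]

Effect sizes in `effect_spec` are regression *coefficients*: a planted
sustained effect of +0.3 moves each session's coupling ±0.3 around baseline
according to the design column (so the two session groups differ by 0.6).
Unstable draws are re-jittered in the session-level random component only,
up to 100 times, and failures name the offending subject and session.

Symptom scores exist at three time points (pre-treatment, day 7, month 3 —
the day-1 session is unscored): score = baseline + sum of designated
couplings times the session's coupling values + Gaussian noise, clipped at
zero because clinical scales are non-negative.

## Preprocessing

Order: discard the first 5 volumes, regress the confound matrix (plus
intercept; linearly dependent columns dropped with a warning), remove
linear and quadratic trends, then high-pass at 0.009 Hz by regression on
the discrete-cosine components below the cutoff. DCT regression was chosen
over IIR filtering to avoid edge transients on 160-sample records. No
low-pass is applied by default (frequencies above 0.1 Hz are retained); an
optional low-pass exists in the config. Voxel blocks are summarized by the
principal eigenvariate: the first left singular vector of the demeaned
time-by-voxel matrix, scaled so its variance is the leading covariance
eigenvalue over the voxel count, signed to correlate positively with the
voxel mean.

## Spectral data features and the first-level model

Inversion targets the complex cross-spectral density (CSD), not the time
series. The default estimator fits a multivariate autoregression by least
squares and evaluates its rational spectrum `TR · T(f)^-1 Σ T(f)^-H` on a
logarithmic grid; a Welch cross-periodogram is available as a
non-parametric cross-check. For ~160-sample sessions the pipeline uses MAR
order 4 — chosen by simulation during development as the bias–variance
sweet spot for 3–6 region sessions (higher orders overfit and visibly
destabilize single-session inversions); `estimate_csd` itself defaults to
order 8, appropriate for longer records, and the order is a config knob.
Single-session fits use 24 log-spaced frequencies on 0.01–0.25 Hz; the
cohort pipeline uses 16 for speed at its reduced scale.

The generative CSD model linearizes the coupled neural+hemodynamic system
at its fixed point. With `J` the full-system Jacobian (assembled
analytically and validated against finite differences of the nonlinear
vector field), `B` the injection of state noise and `L` the BOLD output
gradient,

    H(f) = L (i 2π f I − J)^-1 B
    G_y(f) = H G_v H^H + G_e,   G_v = e^{la_v} f^{-b_v} I,  G_e = e^{la_e} f^{-b_e} I.

Free parameters: all n² coupling entries, per-region log deviations of
transit time and neurovascular gain, and the four noise parameters. Priors:
off-diagonal couplings N(0, 1/64), diagonal log-scales N(0, 1/256),
hemodynamic log-deviations N(0, 1/256), spectral exponents N(1, 1/64).
Noise log-amplitudes get weakly informative priors — N(0, 1) for state
noise and N(0, 4) for observation noise. The data CSD is rescaled before
fitting so its overall level matches the prior-mean prediction (the scale
is recorded and folded back into the reported amplitudes); this centres the
state-noise amplitude, but the observation-to-signal ratio is a genuine
unknown that a tight amplitude prior would forbid the model from learning,
which in practice forces a permanent misfit of the spectral floor.

### Variational Laplace

The likelihood treats real and imaginary CSD parts as Gaussian channels
with two log-precision hyperparameters (diagonal vs off-diagonal entries).
Because CSD magnitudes span several decades across frequency, features are
whitened by a fixed per-frequency scale derived from the data's diagonal
(generalized least squares with known diagonal structure) — without this,
the low-frequency residuals dominate and the precision hyperparameters
collapse instead of fitting. Optimization is damped (Levenberg-style)
Gauss–Newton on the parameters interleaved with Newton updates of the
hyperparameters; a step is accepted only if the free energy does not
decrease, so the free-energy trace is non-decreasing by construction.
Log precisions are bounded to ±8 — without the bound, a perfectly fit
channel class drives its precision to numerical infinity and freezes the
Gauss–Newton system. Convergence: free-energy change below 0.01 nat for 3
consecutive iterations, or 128 iterations (flagged). The feature Jacobian
uses central differences (step 1e-4), batched across parameters and
frequencies. Unstable candidate couplings are rejected inside the line
search.

## Hierarchical (PEB) inference

Per subject, the four session posteriors (means *and* covariances over the
n² coupling entries; hemodynamic and noise parameters stay first-level) are
pooled in a Bayesian GLM with the session design; per group, the subjects'
stacked effect posteriors are pooled with an all-ones design ("PEB of
PEB"). The between-level random effect is `exp(-gamma) I` with a single
shared log-precision `gamma` per level, hyperprior N(4, 1) — centring the
between-level sd at 0.14 coupling units with the generator's 0.05 well
inside two sd. The effect coefficients have N(0, 1) priors.

Because the model is jointly Gaussian given `gamma`, the coefficient
posterior and the marginal likelihood are available in closed form; the
single hyperparameter is optimized by bounded scalar search on the exact
free energy (log marginal plus hyperprior). This replaces an approximate EM
loop and makes free-energy ascent trivially monotone; with `gamma` fixed
the E-step equals the generalized-least-squares solution, which is a
release test.

One downward pass is performed by default: each subject's session
posteriors are re-evaluated under the empirical priors implied by the
subject-level fit (Gaussian prior swap on the carried block — an
approximation, since the swap ignores cross-covariance with the uncarried
parameters), and the session and group levels are refit. The pass count is
configurable.

Symptom-covariate analysis restricts to the three scored sessions, builds a
per-subject design [ones, within-subject-centred score], and pools the
score-association coefficients across subjects; posture and action scores
are analysed separately. With constant scores the centred column is zero
and the association posterior collapses to its prior — this degenerate
design deliberately bypasses the full-rank check that session designs must
pass.

Thresholding: an effect survives if zero lies outside the central 95%
credible interval (z = 1.959964); no multiplicity correction, as all
intervals derive from one multivariate posterior.

## What the synthetic data does and does not emulate

Emulated: the session/subject hierarchy with planted transient and
sustained effects, scale-free neuronal fluctuations, Balloon hemodynamics,
TR sampling, observation noise, drifts, leaking confounds, score coupling.
Not emulated: spatial/image-domain structure (motion is a regressor, not a
realignment problem), physiological (cardiac/respiratory) noise,
inter-regional hemodynamic latency differences beyond transit-time
deviations, non-linear neural effects, and session-varying hemodynamics
(hemodynamic parameters are fixed per region within subject — an explicit
assumption). Passing tests therefore demonstrate the estimator chain is
correct and well calibrated under the stated model, not that it is robust
to every artifact of real fMRI.

## Validation experiments and problem sizes

`longdcm.validate` holds the release experiments; the test suite and
`scripts/acceptance.py` call the same functions.

- Spectral oracle: a 3-region network with one 0.2 coupling, 2000 s of
  noiseless-observation BOLD, Welch CSD (250-s Hann segments, 50% overlap)
  vs the analytic prediction over 0.01–0.25 Hz. Residuals are normalized
  per bin by the geometric mean of predicted diagonal powers, averaged over
  the band (signed, so estimator noise cancels), and their magnitudes
  averaged over the 9 matrix entries. A 2000-s record carries only ~480
  independent spectral samples in band, so this normalized band-average is
  the statistically appropriate comparison at this record length; typical
  error is ~4–6%.
- AR(1) closed form: MAR spectrum vs the analytic AR(1) spectrum, T=2000.
- Inversion recovery: 10 single sessions (165 volumes) with one +0.4
  coupling among zeros; the planted coupling must be positive and dominate
  all true-zero couplings in at least 8.
- Longitudinal recovery: 10 cohorts of 8 subjects × 4 sessions × 3 regions
  with a sustained +0.3 effect on one connection (sigma2 = sigma3 = 0.05),
  plus 5 null cohorts; the planted group effect must survive at 95% with
  the correct sign in at least 8, the score-coupled connection likewise,
  and null cohorts must keep surviving session effects at or below ~10%.
- Determinism: identical config and seed reproduce all effect tables byte
  for byte.

The 3-region scale for the recovery experiments keeps a full 15-cohort
experiment around two minutes; the pipeline defaults (6 regions, the motor
network labels) run the same code paths.

## Known limitations

- The downward (empirical-prior) pass uses a marginal Gaussian prior swap
  on the coupling block rather than the full joint reduction.
- Between-level covariance is isotropic per level; per-connection
  components would need the config hook left for them.
- Single-session inversions at paper scale (160 volumes) are genuinely
  noisy; group conclusions should come from the hierarchical level, which
  is the design's point.
- The Balloon linearization underlying spectral prediction is accurate
  only for small fluctuations; simulating much stronger neuronal noise
  will produce spectra the linear model cannot match.
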