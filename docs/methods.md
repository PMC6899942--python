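# Methods

## The model

Intravoxel incoherent motion (IVIM) imaging separates the diffusion-weighted
MRI signal into a tissue compartment and a microvascular ("perfusion")
compartment. The conventional bi-exponential IVIM model assumes the
pseudo-diffusion limit — blood traverses many randomly oriented capillary
segments during the diffusion-encoding time `T` — which does not hold in
abdominal organs, where the characteristic segment traversal time `tau` is
comparable to or longer than achievable `T`. The flow-compensated (FC) IVIM
model drops that assumption. The signal at acquisition setting `(b, T, beta)`
(diffusion weighting, diffusion time, gradient shape; `beta = 0` bipolar,
`beta = 1` flow-compensated) is

    S(b, T, beta) = S0 * [ (1 - f) * exp(-b D)
                         + f * F(b, T, beta, tau, v) * exp(-b * D_blood(beta)) ]

with tissue diffusivity `D` (mm²/s), perfusion signal fraction `f`, blood
speed `v` (mm/s), segment time `tau` (ms), and fixed blood ADCs
`D_blood = 1.30e-3 / 1.54e-3 mm²/s` for bipolar / FC encoding. `F` is the
perfusion attenuation factor: the ensemble average of `cos(phase)` over blood
spins moving at constant speed along straight segments whose direction is
redrawn isotropically every `tau` (first boundary offset uniform in
`[0, tau)`), under the actual gradient waveform. Useful limits, used as test
oracles:

* ballistic (`T/tau -> 0`): `F -> sinc(v * m1)` for bipolar (with `m1` the
  first-moment phase sensitivity of the waveform) and `F -> 1` for FC;
* diffusive (`T/tau -> inf`): `F -> exp(-b D*)` with `D* = tau v² / 6`,
  independent of the gradient shape.

`F` may be negative in near-ballistic bipolar regimes (sinc lobes); it is
passed to the signal model unchanged.

## Waveforms

Effective (post-refocusing) gradients are ideal trapezoids with slew-limited
ramps (`ramp = g / slew_max`), sampled at 10 µs as exact cell averages of the
piecewise-linear shape, so the discrete moments are exact: the FC pattern
`+ - - +` (four lobes of `T/4`) nulls the first moment to floating-point
precision, and the bipolar pattern `+ -` (two lobes of `T/2`) refocuses the
zeroth moment exactly. The lobe amplitude is solved by bisection so the
recomputed `b = gamma² ∫ q(t)² dt` hits the requested value to ≪0.1%;
requests beyond the full-amplitude `b` raise an infeasibility error. Defaults
mirror a 1.5 T system with `g_max = 45 mT/m`, `slew_max = 200 mT/m/ms` and
diffusion times 40–100 ms.

## Computing F: Monte Carlo and the cached table

`fcivim.phase` provides two routes, kept deliberately independent:

* **Direct Monte Carlo** (`sample_phases` / `attenuation`): spins with
  uniformly random first-boundary offsets and i.i.d. uniform direction
  cosines accumulate `phase = -v Σ_k cosθ_k ∫_seg q dt`; `F` is the mean of
  `cos(phase)` (the imaginary part vanishes by symmetry and is checked
  against 4 MC standard errors — a 3-sigma assert would trip by chance in
  ~0.3% of calls). Defaults: 10⁴ spins inside quick evaluations, 10⁵ in
  tests.
* **Cached table** (`PhaseTable`): for a fixed normalized waveform shape,
  `F` depends only on `T/tau` and the dimensionless scale
  `x = v sqrt(b T)` (SI). Conditional on the segment layout the direction
  average is exact: `E[cos(x Σ u_k Q_k)] = Π_k sinc(x Q_k)`; only the 1-D
  periodic offset integral remains and is evaluated with a 256-point
  midpoint rule. The table (64 log-spaced ratios in 10⁻²–10², 384 x-nodes
  to 1.2×10³, per shape) is therefore deterministic — no Monte-Carlo noise —
  and is interpolated with a bicubic spline in `(log10 T/tau, asinh(x/2))`.
  Beyond the ratio grid the diffusive closed form continues it smoothly.
  Agreement with direct MC at 10⁵ spins is ≤10⁻³ across the tested grid
  (tolerance documented as 1%); the residual error is the shape perturbation
  from amplitude-dependent ramp times (≲0.5% of the lobe duration).

Fits and simulations evaluate `F` (and its analytic partial derivatives for
the Jacobian) through the table; building both tables takes ~4 s per process
and the result is cached.

## Fitting

The estimator follows the published procedure: signals are normalized to the
mean `b = 0` signal; `D` and `f` are initialized by a log-linear fit to the
bipolar points with `b >= 150 s/mm²` (`D` from the slope, `f = 1 -
exp(intercept)`, clipped into bounds — out-of-bound initials are clipped, not
redrawn); `S0 = 1`, `tau = 200 ms`, `v = 4 mm/s` complete the start vector.
All five parameters are then estimated by bound-constrained trust-region
least squares (`scipy.optimize.least_squares`, trf, analytic Jacobian,
`ftol = xtol = 1e-8`, ≤500 evaluations). Box constraints ship in three
flavours: the standard estimation bounds (`0.5–3.0e-3 mm²/s`, `f` 0–60%,
`tau` 20–500 ms, `v` 0.2–15 mm/s), broad bounds used inside protocol design
(`0–4e-3`, 0–100%, 1–1000 ms, 0–20 mm/s), and organ-specific bounds for
liver, spleen and kidneys. Non-convergence is reported in the result object,
never silently; uncertainties come from the Gauss–Newton covariance
`σ²(JᵀJ)⁻¹`. `f` is carried internally as a fraction and reported in percent,
`D` in 10⁻³ mm²/s.

Inside the design simulations the same estimator runs with `ftol = xtol =
1e-6` and ≤150 evaluations: the measured quantities are percent-scale
parameter errors, and the looser settings change estimates by ~10⁻⁵ relative
while cutting the fit time about fourfold (noisy broad-bound fits otherwise
crawl along flat `tau`/`v` valleys to the evaluation cap).

## Protocol design

Acquisitions are added greedily: candidates form a feasibility-checked
`(b, T, beta)` grid (denser `b` below 40 s/mm², a coarser `T` grid for
bipolar than FC, per the observation that `T` matters little for bipolar
encoding); for each candidate, tissues are drawn uniformly from
`D = 1–2e-3 mm²/s`, `f = 10–40%`, `tau = 20–500 ms`, `v = 1–10 mm/s`,
curves are simulated, Rician noise is added, the model is refitted with the
broad bounds, and errors are normalized by the interval means
(`1.5e-3, 25%, 260 ms, 5.5 mm/s`). The per-repeat aggregate is
`sqrt(mean of the four squared percent errors)` (a mean-of-squares variant is
selectable; rankings are near-identical); the candidate with the lowest mean
aggregate is appended. All candidates within a step see identical tissue and
noise draws; draws are refreshed between steps. Scheme performance is
reported as 5/25/50/75/95 error percentiles under fresh draws, with
truth-relative normalization when a single literature tissue is evaluated.

Noise model: per direction, `S -> sqrt((S + e1)² + e2²)` with Gaussian `e` of
SD `sqrt(n_directions)/SNR_eff`, then averaged over the (default six)
directions, so `SNR_eff` is the post-averaging SNR of the `b = 0` signal.
A per-direction interpretation (`sigma = 1/SNR`) is available as a switch;
the printed reference percentiles are numerically closer to that reading,
while the default follows the stated "effective SNR".

Desk-scale defaults keep a laptop run practical: 500 repeats per cost
evaluation and ~150 grid candidates (full scale — 5000 repeats, finer grids,
45 additions — is reachable through the same configuration objects). The
shipped 50-point protocol (`reference_scheme_50`) is a synthetic stand-in
hand-built to the published description of the optimum (FC points
concentrated at `T = 100 ms` with `b = 60–150 s/mm²`, bipolar points mostly
at `b = 0–30 s/mm²`, b = 0 acquisitions interleaved for drift tracking); the
exact published table is not deposited. The 5-point base set is likewise a
labelled non-canonical choice spanning both shapes, both `T` extremes, one
high-b bipolar point and `b = 0`.

## Repeatability statistics

* **Drift correction**: ordinary least squares of the `b = 0` ROI signals on
  acquisition time; if the slope is significantly nonzero (two-sided t-test,
  `p < 0.05`) every signal is divided by `(a + b t)`. Requires ≥3 `b = 0`
  points spread over the scan.
* **wCV**: root mean square over subjects of (within-subject SD /
  within-subject mean), in percent — the standard repeated-measures
  definition; a pooled-variance variant is available since the original
  estimator is not written out anywhere.
* **ICC**: two-way ANOVA decomposition, absolute agreement, average of k
  measurements: `ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n)`;
  values ≥0.75 flag good reliability; negative estimates (or a non-positive
  denominator) are flagged `n.a.` as dominated by within-subject variance.
* **Protocol bias**: mean percent deviation of a test protocol's estimates
  from a reference protocol's, paired per subject/occasion.
* **T2 rescaling of f**: the measured perfusion fraction is a signal
  fraction, so compartment odds `f/(1-f)` rescale by
  `exp((TE' - TE)(1/T2_tissue - 1/T2_blood))` between echo times; with liver
  tissue T2 = 46 ms and venous blood T2 = 181 ms this maps 45.0% at
  TE = 122 ms to 20.3% at TE = 50 ms.

## Synthetic study

`fcivim.study` generates a complete in-silico repeatability experiment:
7 subjects; per subject and organ a ground truth drawn from a truncated
normal around published volunteer means (liver `D = 1.61±0.16e-3 mm²/s`,
`f = 45.0±4.7%`, `tau = 171±19 ms`, `v = 8.4±0.6 mm/s`; spleen and kidneys
analogous), truncated at the organ fit bounds to keep truths identifiable;
three occasions (two intrasession repeats, one intersession visit) with a
multiplicative session-level parameter jitter of 5% CV — an assumed value,
since the true day-to-day biological variation is unknown; a linear scanner
drift `1 + slope*t` with slope uniform in ±2e-4 /s applied to a random half
of the ROIs (so the significance gate exercises both branches); and Rician
noise at effective SNR 20. Acquisitions are spaced 19.2 s apart (a 50-point
protocol then takes 16 min, matching the scan-time envelope the protocol was
designed for).

What the generator does **not** emulate: respiratory motion and registration
residuals, partial-volume mixing at organ boundaries, spatially correlated
noise after parallel-imaging reconstruction, T1/T2 relaxation differences
across acquisitions (echo time is held constant by design), and
between-organ parameter correlations. Passing tests therefore demonstrate
that the estimator and statistics recover the variance structure the model
itself generates — not that the model captures every source of in-vivo
variability.

## Numerical choices and limitations

* All randomness flows from `numpy.random.SeedSequence`; fixed seeds give
  bit-identical ensembles (chunked sampling uses a fixed 16384-spin block
  size so results do not depend on memory layout).
* Ties in the greedy argmin resolve to the first (lowest-index) candidate.
* Degenerate inputs fail loudly: schemes need ≥5 distinct points and a
  `b = 0` entry; drift testing needs ≥3 timed `b = 0` points; ICC refuses
  missing cells rather than imputing.
* The tabulated `F` assumes a single normalized waveform shape per gradient
  type; amplitude-dependent ramps make this approximate at the ≲10⁻³ level.
  Exact per-waveform evaluation is available through the MC route.
* Parameter recovery statements are self-consistency results (data generated
  and fitted with the same forward model). `tau` and `v` are weakly
  identified at SNR ≲20 and small `f`; their estimates cluster at the box
  constraints in those regimes, which is the behaviour the protocol
  optimization is designed to mitigate.
* The error-versus-protocol-size study in the acceptance tests runs at desk
  scale (a ~20-candidate grid, 32–128 repeats, ≤20 added points); the
  configuration objects scale to the full study without code changes.
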