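# Methods

## Scope and definitions

The package estimates *linear* Fisher information for a two-condition
(fine or coarse) discrimination from trial-by-neuron response matrices.
Throughout, T is the number of trials per condition, N the number of
neurons, and dθ = θ⁺ − θ⁻ the **full** stimulus separation; the tuning
derivative is always the finite difference (μ⁺ − μ⁻)/dθ, with sampling
variance 2Σ/(T·dθ²).  Information is reported in stimulus-units⁻²
(deg⁻² in the examples).

## Estimators

**Naive (plug-in).** Î_nv = (dμ/dθ)ᵀ S⁻¹ (dμ/dθ) with S the pooled
unbiased covariance (S⁺+S⁻)/2.  Under Gaussian variability its
expectation is (2T−2)/(2T−N−3) · (I + 2N/(T·dθ²)): a multiplicative
inverse-Wishart factor from inverting S plus an additive term from the
sampling noise of the derivative.  Both factors are verified by Monte
Carlo in the test suite.

**Bias-corrected.** Î_bc = Î_nv·(2T−N−3)/(2T−2) − 2N/(T·dθ²).
Unbiased (Gaussian oracle) whenever S is invertible, i.e.
T > (N+2)/2; below that the code refuses with an explicit error.  Its
sampling variance is

    Var Î_bc = 2I²/(2T−N−5) · [1 + 4(2T−3)/(T·I·dθ²) + 4N(2T−3)/(T²·I²·dθ⁴)],

implemented in expanded form so I = 0 yields the finite limit
8N(2T−3)/((2T−N−5)·T²·dθ⁴).  The variance diverges at T = (N+5)/2:
between (N+2)/2 and (N+5)/2 the estimate is returned with no variance
attached.  Error bars use the plug-in Î_bc (clipped at zero inside the
variance formula, where a negative plug-in could make the quadratic
negative).  Negative estimates are returned as-is — they occur when
sampling noise exceeds the signal, and a warning is attached whenever
|Î| is below the analytic standard error.

**Shuffled information.** Î_shuffle = Σᵢ (dμᵢ/dθ)²/sᵢ² · (T−2)/(T−1)
− 2N/(T·dθ²), with sᵢ² the pooled marginal variances.  Computed from
marginals only; no data shuffling is performed (shuffling a finite
number of trials leaves residual correlations, a noise source this
form avoids entirely).

**Crossed information I_AB** (decoder optimal for A, evaluated on B).
The population quantity is (f'_BᵀΣ_A⁻¹f'_A)² / (f'_AᵀΣ_A⁻¹Σ_BΣ_A⁻¹f'_A).
Numerator and denominator are de-biased separately: the unbiased
inverse covariance Ŝ_A⁻¹ = S_A⁻¹·(2T−N−3)/(2T−2) is used everywhere,
and the denominator's expectation λ + ρ + (1+c)·den_true — with λ, ρ
computable from Tr(Ŝ_A⁻¹S_B) and Î_bc,A, and
c = (2T−N−1)/((2T−N−2)(2T−N−5)) — is inverted to give

    Î_AB = num² · (1+c) / (den − λ̂ − ρ̂).

The O(1/T) bias from squaring the scalar numerator and dividing is *not*
corrected (it is an order N smaller than the biases that are); tests
verify it is small at moderate T and decays as 1/T.  When sampling noise
drives the corrected denominator non-positive (possible at small T) the
estimate is returned with a `degenerate` flag and the uncorrected
denominator, rather than raising.

**Factorized-decoder information I_diag.**  The crossed estimator with
A = a trial-shuffled copy of the data (per-neuron, per-condition
independent permutations, seeded; one realization by default,
averaging available) and B = the original data, plus an extra
− 2N/(T·dθ²) inside the numerator because A and B share the same tuning
derivative (shuffling preserves column means exactly).

**Percent correct.** 100·Φ(dθ·√I/2): the optimal linear readout is
Gaussian around each stimulus with variance 1/I, and an ideal observer
picks the nearer stimulus value.  Verified against explicit Monte-Carlo
decoding in the tests.

## The decoding baseline

The conventional estimate regresses the (centered) stimulus on the
(centered) response by full-batch gradient descent, with early
stopping: the data are split per-condition into training/test/
validation thirds (largest-remainder rounding, seeded), descent runs on
the training set, and stops when the test error rises.  Information is
read out on the validation set as [wᵀ(μ⁺−μ⁻)/dθ]² / (wᵀS̄w) — exactly
invariant to the scale of w, so early-stopped (shrunk) weights are not
penalized for their length, only their direction.

Choices the procedure leaves open, fixed here as defaults:

- learning rate 1/L with L = 2·λ_max(XᵀX) of the training design
  (largest stable step; the top mode converges in one step);
- weights initialized i.i.d. normal at 10⁻³ of the response scale, seeded;
- stopping on the *smoothed* test error (window 5) rising above its
  running minimum, returning the weights at the minimum — equivalent to
  the raw first-sign-change rule on noiseless curves but robust to
  numerical wiggles; an iteration cap (default 10⁵) and a plateau
  detector (training error static for 200 iterations with no test
  improvement) terminate non-overfitting runs, with the reason recorded;
- training and test sets are centered on their own means; the read-out
  is shift-invariant so this affects nothing downstream.

Gradients and errors are evaluated from precomputed N×N Gram matrices,
so a fit costs O(TN²) once plus O(N²) per iteration — typically
milliseconds.

## Population models

**Gaussian (oracle).**  r± ~ N(f±, Σ) with exact ground truth
f'ᵀΣ⁻¹f'.  All unbiasedness and variance-calibration claims are tested
on this model, where the Wishart theory behind the corrections holds
verbatim.  A `random` constructor produces reproducible test
populations with a prescribed information value.

**Doubly stochastic V1 model.**  Input: a 32×32 Gabor image J(θ)
(envelope std P/5, wavelength P/1.5 pixels, phase 0, contrast 0.75) on
a centered integer pixel grid, plus white pixel noise of std σ₀ = 0.2.
Neurons: N Gabor filters with the same geometry, preferred orientations
evenly spaced over [−180°, 180°), each rescaled to zero mean and unit
norm, with effective amplitudes g·a_k, a_k log-normal (log-mean 0,
log-std 0.25) and gain g = 30 by default.  Per trial the noisy image is
filtered, half-rectified, and drives independent Poisson spiking.  The
pixel noise is drawn directly in filter space (its exact N-dimensional
projection) rather than as a P² image — identical in distribution,
much cheaper.  Ignoring rectification the moments are
f_k = g_k·F_k·J and Σ_kl = σ₀²g_k g_l F_k·F_l + δ_kl f_k; with phase 0
the filter outputs are almost never negative, and the large-T direct
estimate agrees with this analytic ground truth within ~2% at default
parameters (covered by a test).  Shared input noise makes the
correlations information-limiting: the population information stays
below the input bound |J'|²/σ₀² and grows sublinearly with N.  A
variant population ("B": envelope P/8, wavelength P/3) provides the
mismatched-decoder scenario for I_AB.  At low gain (g = 1) the
rectification approximation degrades, so the ground truth there is
*operational*: the bias-corrected estimate at T = 100,000.

Known limitation: the mean spike count of this model is exactly
proportional to g (signal and filtered noise share the amplitude
g_k = g·a_k), so absolute counts depend on the image-amplitude unit,
which the model leaves free; we use the raw image convention above.
Count-based comparisons across gains are therefore reliable only up to
this overall unit, and the package treats reported absolute counts as
descriptive output of the model, not calibration targets.

**Von Mises / Poisson.**  Independent Poisson neurons with tuning
b + gain·exp(κ(cos(θ−θᵢ)−1)); defaults κ = 2, b = 0.05, gain = 2.43,
chosen to give a population mean of ≈0.8 spikes/neuron/trial — a
low-count, decidedly non-Gaussian regime with exact diagonal ground
truth Σᵢ f'ᵢ²/fᵢ, used to probe robustness of the Gaussian-derived
corrections.

What the simulations do *not* emulate: real recordings have
non-stationarities, shared gain fluctuations beyond the stimulus-driven
correlations modeled here, spike sorting artifacts, and tuning that
drifts over a session.  Passing tests demonstrate correctness of the
estimators under the stated generative assumptions (plus robustness to
the Poisson/rectification deviations built into the Gabor and Von Mises
models), not performance guarantees on arbitrary cortical data.

## Sweep harness and statistics

`run_sweep` simulates n independent experiments per trial count
(default 200), applies every configured estimator to the same data, and
aggregates mean, SD, MSE against ground truth, and relative error
defined as √MSE / I_true.  MSE is computed both directly and as
bias² + variance; the identity is asserted in tests.  Per-replicate
seeds derive from (master seed, T, replicate index) via
`numpy.random.SeedSequence`, so results are independent of execution
order and safe to parallelize.  Bootstrap bands (seeded, default 1000
resamples) are mean ± bootstrap SE of the mean by default; a
`of="distribution"` switch gives the spread of the estimates instead.
Estimator-regime failures (e.g. T below invertibility) are recorded as
missing cells, not fatal errors.  `subsample_protocol` draws repeated
without-replacement per-condition subsamples from a fixed dataset for
learning curves on recorded data.  Reports are written as JSON (full
per-replicate record, config hash, seed) plus a fixed 7-column CSV.

Problem sizes used in the shipped checks: unbiasedness is verified on a
grid N ∈ {5, 20, 50}, T ∈ {N, 2N, 5N} at 10⁴ replicates; variance
calibration at N = 20, T = 100, 10⁴ replicates; the Gabor benchmark
numbers at 50–200 replicates per condition, with decoder-based
quantities at the lower end of that range and direct-estimator
quantities at 200.

## Numerical choices

- Symmetric systems are solved directly (`numpy.linalg.solve`) after
  symmetrizing S ← (S + Sᵀ)/2; no pseudo-inverses.
- Covariances use the unbiased 1/(T−1) normalization everywhere.
- Batched Monte-Carlo paths (`batched_moments`, `*_kernel`) share the
  exact same arithmetic as the per-dataset API.
- All randomness flows through `numpy.random.Generator` seeds; every
  simulator, split, shuffle and bootstrap is bit-reproducible.
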