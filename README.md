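# fisherinfo

Direct, bias-corrected estimation of **linear Fisher information** in
correlated neural populations, with the cross-validated decoding
baseline it replaces and generative population models for validating
both.

## The problem

How much information about a stimulus does a recorded neural population
carry?  For a fine discrimination between two stimuli θ⁺ and θ⁻
separated by dθ, the standard answer is the linear Fisher information

    I = f'ᵀ Σ⁻¹ f',      f' = (f(θ⁺) − f(θ⁻)) / dθ,

the inverse variance of the best unbiased *linear* readout of the
stimulus (f are the tuning curves, Σ the noise covariance).  Estimating
I from T trials per condition is deceptively hard: plugging the
empirical means and covariance into the formula overestimates I
grossly (the covariance is inverted and the derivative squared — both
nonlinear), while the traditional alternative — train a linear decoder,
cross-validate, invert its variance — underestimates I unless T ≫ N
and is painfully slow.

Under Gaussian response variability both plug-in biases have exact
closed forms (the empirical covariance is Wishart, its inverse
inverse-Wishart; the derivative estimate is Gaussian), so they can be
removed exactly:

    Î_bc = (dμ/dθ)ᵀ S⁻¹ (dμ/dθ) · (2T−N−3)/(2T−2) − 2N/(T·dθ²)

where μ± and S = (S⁺+S⁻)/2 are the empirical means and pooled
covariance.  Î_bc is unbiased for any T > (N+2)/2, its sampling
variance has a closed form (finite for T > (N+5)/2) usable for error
bars, and in simulations it is robust to realistic non-Gaussian (e.g.
Poisson-like) variability.  The same machinery yields unbiased
estimators of:

- **I_shuffle** — the information of a fictitious independent population
  with the same marginal statistics (Σ diagonal), computed from the
  marginal variances alone, no actual shuffling required;
- **I_AB** — the information a decoder optimal for dataset A extracts
  from dataset B (context-dependent decoding);
- **I_diag** — the information recovered by a correlation-blind
  (factorized) decoder, as the special case A = shuffled data,
  B = original data.

## Worked example

Simulate a V1-like population (50 Gabor-filter neurons, shared image
noise plus Poisson spiking — a model with information-limiting
correlations and a known ground truth), then estimate:

```python
import fisherinfo as fi

pop = fi.build_filter_bank(N=50, gain=30.0, seed=0)
print(pop.ground_truth(0.0, -7.0).info_true)      # 0.2852 deg^-2

data = pop.simulate_pair(theta_plus=0.0, theta_minus=-7.0, T=500, seed=1)
res = fi.LinearFisherInfo(data).fit()             # bias-corrected direct estimate
print(res.summary())
```

```
                Linear Fisher Information
==========================================================
Method:                                     bias_corrected
Trials per condition (T):                              500
Neurons (N):                                            50
Stimulus separation:                                     7
----------------------------------------------------------
Information (units^-2):                           0.303994
Analytic std. error:                             0.0173497
95% CI:                                   [0.26999, 0.338]
Implied percent correct:                            97.32%
==========================================================
```

The estimate (0.304 ± 0.017 deg⁻²) brackets the ground truth 0.2852;
the "percent correct" line converts the information into the accuracy
of an ideal two-alternative discrimination at this 7° separation,
100·Φ(dθ·√I/2).  The decoding baseline on the same data:

```python
dec = fi.EarlyStoppingDecoder(data).fit(seed=2)
print(dec.info_validation.value)                  # 0.2976
print(dec.info_training.value)                    # 0.3017
```

Validation- and training-set estimates bracket the truth from below
and above; their gap shrinks as T grows.  `fit(method="shuffle")`,
`"diag"` and `"crossed"` (with `data_B=...`) give the correlation
analyses; `fisherinfo.run_sweep` compares estimators over a T grid with
mean-squared errors and bootstrap bands.

A command-line interface mirrors the library:

```
fisherinfo simulate --model gabor --n 50 --t 500 --seed 0 --out data.npz
fisherinfo estimate --data data.npz --method bc
fisherinfo decode   --data data.npz --mode plain
fisherinfo sweep    --config cfg.yaml --out sweep_report
fisherinfo subsample --data data.npz --tsub 100 --reps 100
```

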