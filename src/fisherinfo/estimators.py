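"""Closed-form estimators of linear Fisher information from finite samples.

Linear Fisher information of a population with tuning derivative f' and
noise covariance Sigma is I = f'^T Sigma^-1 f' — the inverse variance of
the locally optimal unbiased linear stimulus estimator.  Plugging the
empirical moments into this expression (the *naive* estimator) is badly
biased at finite trial counts because the covariance is inverted and the
derivative squared.  Under Gaussian variability the sampling distribution
of the pooled covariance is Wishart, its inverse is inverse-Wishart with a
known mean, and the derivative estimate is Gaussian with variance
2*Sigma/(T*dtheta^2); both biases can therefore be removed exactly:

    I_bc = dmu/dtheta^T S^-1 dmu/dtheta * (2T-N-3)/(2T-2) - 2N/(T*dtheta^2)

The same machinery yields unbiased estimators for the shuffled
(independent-marginals) information, for the information a decoder
optimized on dataset A extracts from dataset B, and for the information
recovered by a correlation-blind (factorized) decoder.

All kernels accept leading batch dimensions so Monte-Carlo calibration
runs vectorize over experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import MomentSummary, TrialSet, summarize_trials

__all__ = [
    "CorrectionFactors",
    "InfoEstimate",
    "naive_info",
    "bc_info",
    "bc_info_variance",
    "bc_info_shuffle",
    "bc_info_crossed",
    "bc_info_diag",
    "true_linear_info",
    "optimal_weights",
    "info_to_percent_correct",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Pooled covariance is singular (requires N <= 2(T-1))."""


class DivergentVarianceError(ValueError):
    """The analytic estimator variance diverges (2T - N - 5 <= 0)."""


class UnusableRegimeError(ValueError):
    """Too few trials for the empirical covariance to be invertible."""


@dataclass(frozen=True)
class CorrectionFactors:
    """Finite-sample correction constants for T trials per condition, N neurons.

    ``c_cov`` rescales the inverse pooled covariance to make it unbiased
    (inverse-Wishart mean); ``gamma`` is the variance 2/(T*dtheta^2) of each
    coordinate of the derivative estimate per unit Sigma; ``alpha`` and
    ``beta`` parameterize the covariance of the elements of the unbiased
    inverse covariance.
    """

    T: int
    N: int
    dtheta: float

    @property
    def c_cov(self) -> float:
        return (2 * self.T - self.N - 3) / (2 * self.T - 2)

    @property
    def gamma(self) -> float:
        return 2.0 / (self.T * self.dtheta**2)

    @property
    def alpha(self) -> float:
        return 2.0 / ((2 * self.T - self.N - 2) * (2 * self.T - self.N - 5))

    @property
    def beta(self) -> float:
        return (2 * self.T - self.N - 3) / (
            (2 * self.T - self.N - 2) * (2 * self.T - self.N - 5)
        )


@dataclass
class InfoEstimate:
    """A scalar information value (stimulus-units^-2) with provenance.

    ``value`` may be negative for bias-corrected methods: the correction
    subtracts a positive term and noisy estimates occasionally land below
    zero.  Negative values are returned as-is, never clipped.
    """

    value: float
    method: str
    T: int
    N: int
    dtheta: float
    analytic_variance: float | None = None
    degenerate: bool = False

    @property
    def se(self) -> float | None:
        if self.analytic_variance is None:
            return None
        return float(np.sqrt(self.analytic_variance))

    def percent_correct(self) -> float:
        return info_to_percent_correct(max(self.value, 0.0), self.dtheta)


# ---------------------------------------------------------------------------
# batched numerical kernels
# ---------------------------------------------------------------------------

def _sym(S: np.ndarray) -> np.ndarray:
    return 0.5 * (S + np.swapaxes(S, -1, -2))


def _solve_quad(S: np.ndarray, v: np.ndarray) -> np.ndarray:
    """v^T S^-1 v for batched symmetric S (..., N, N) and v (..., N)."""
    x = np.linalg.solve(_sym(S), v[..., None])[..., 0]
    return np.einsum("...i,...i->...", v, x)


def batched_moments(
    rp: np.ndarray, rm: np.ndarray, dtheta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Moments of a stack of experiments: ``rp``/``rm`` are (..., T, N)
    response arrays; returns (dmu_dtheta, S_pooled, S_plus, S_minus) with
    unbiased covariances — the vectorized counterpart of
    :func:`~fisherinfo.data.summarize_trials` for Monte-Carlo runs."""
    T = rp.shape[-2]
    mu_p, mu_m = rp.mean(-2), rm.mean(-2)
    cp = rp - mu_p[..., None, :]
    cm = rm - mu_m[..., None, :]
    Sp = np.swapaxes(cp, -1, -2) @ cp / (T - 1)
    Sm = np.swapaxes(cm, -1, -2) @ cm / (T - 1)
    return (mu_p - mu_m) / dtheta, 0.5 * (Sp + Sm), Sp, Sm


def naive_info_kernel(dmu: np.ndarray, S: np.ndarray) -> np.ndarray:
    return _solve_quad(S, dmu)


def bc_info_kernel(dmu: np.ndarray, S: np.ndarray, T: int, dtheta: float) -> np.ndarray:
    N = dmu.shape[-1]
    naive = naive_info_kernel(dmu, S)
    return naive * (2 * T - N - 3) / (2 * T - 2) - 2 * N / (T * dtheta**2)


def shuffle_info_kernel(
    dmu: np.ndarray, s2: np.ndarray, T: int, dtheta: float
) -> np.ndarray:
    N = dmu.shape[-1]
    naive = np.sum(dmu**2 / s2, axis=-1)
    return naive * (T - 2) / (T - 1) - 2 * N / (T * dtheta**2)


def crossed_info_kernel(
    dmu_A: np.ndarray,
    S_A: np.ndarray,
    dmu_B: np.ndarray,
    S_B: np.ndarray,
    T: int,
    dtheta: float,
    diag_numerator_correction: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Bias-corrected crossed information from batched moment arrays.

    Returns ``(value, degenerate)`` where ``degenerate`` flags replicates
    whose corrected denominator came out non-positive (small-T sampling
    noise); for those the uncorrected-denominator ratio is returned.
    """
    N = dmu_A.shape[-1]
    if 2 * T - N - 5 <= 0:
        raise DivergentVarianceError(
            f"crossed estimator needs 2T - N - 5 > 0, got T={T}, N={N}"
        )
    cf = CorrectionFactors(T, N, dtheta)
    SA = _sym(S_A)
    # Shat_A^-1 = c_cov * S_A^-1, applied through solves
    x = np.linalg.solve(SA, dmu_A[..., None])[..., 0] * cf.c_cov  # Shat_A^-1 dmu_A
    num = np.einsum("...i,...i->...", dmu_B, x)
    den = np.einsum("...i,...ij,...j->...", x, S_B, x)
    SAinv_SB = np.linalg.solve(SA, S_B) * cf.c_cov
    tr = np.trace(SAinv_SB, axis1=-2, axis2=-1)
    bc_A = bc_info_kernel(dmu_A, S_A, T, dtheta)
    d2, d5 = 2 * T - N - 2, 2 * T - N - 5
    lam = cf.gamma * (1 + (2 * T - N - 1 + N * (2 * T - N - 3)) / (d2 * d5)) * tr
    rho = (2 * T - N - 3) / (d2 * d5) * tr * bc_A
    corr = 1 + (2 * T - N - 1) / (d2 * d5)
    if diag_numerator_correction:
        num = num - 2 * N / (T * dtheta**2)
    den_corrected = den - lam - rho
    degenerate = den_corrected <= 0
    safe_den = np.where(degenerate, den, den_corrected)
    value = num**2 / safe_den * corr
    return value, degenerate


# ---------------------------------------------------------------------------
# public estimators on MomentSummary / TrialSet
# ---------------------------------------------------------------------------

def _check_invertible(m: MomentSummary) -> None:
    if m.T <= (m.N + 2) / 2:
        raise UnusableRegimeError(
            f"empirical covariance not invertible: T={m.T} <= (N+2)/2 with N={m.N}; "
            "direct estimation needs T > (N+2)/2"
        )


def naive_info(m: MomentSummary) -> InfoEstimate:
    """Plug-in estimator dmu^T S^-1 dmu, no bias correction.

    Overestimates the true information by the factor (2T-2)/(2T-N-3) and
    the additive derivative-noise term; kept as a baseline and as the
    building block of the corrected estimator.
    """
    if m.N > 2 * (m.T - 1):
        raise RankDeficiencyError(
            f"pooled covariance is singular: N={m.N} > 2(T-1)={2 * (m.T - 1)}"
        )
    try:
        value = float(naive_info_kernel(m.dmu_dtheta, m.S_pooled))
    except np.linalg.LinAlgError as e:
        raise RankDeficiencyError(
            f"pooled covariance is singular (N={m.N}, need N <= 2(T-1)={2 * (m.T - 1)})"
        ) from e
    return InfoEstimate(value, "naive", m.T, m.N, m.dtheta)


def bc_info(m: MomentSummary, warn_noisy: bool = True) -> InfoEstimate:
    """Bias-corrected direct estimator of linear Fisher information.

    Unbiased under Gaussian variability for any T > (N+2)/2; its analytic
    variance (attached, evaluated with the plug-in estimate) is finite
    only for 2T - N - 5 > 0.
    """
    _check_invertible(m)
    value = float(bc_info_kernel(m.dmu_dtheta, m.S_pooled, m.T, m.dtheta))
    var: float | None = None
    if 2 * m.T - m.N - 5 > 0:
        var = bc_info_variance(max(value, 0.0), m.T, m.N, m.dtheta)
        if warn_noisy and abs(value) < np.sqrt(var):
            warnings.warn(
                "information estimate smaller than its analytic standard error; "
                "the estimate is dominated by sampling noise",
                stacklevel=2,
            )
    est = InfoEstimate(value, "bias_corrected", m.T, m.N, m.dtheta, analytic_variance=var)
    return est


def bc_info_variance(info: float, T: int, N: int, dtheta: float) -> float:
    """Analytic sampling variance of the bias-corrected estimator.

    Var = 2 I^2/(2T-N-5) * (1 + 4(2T-3)/(T I dtheta^2) + 4N(2T-3)/(T^2 I^2 dtheta^4)),
    evaluated in expanded form so I = 0 has the finite limit
    8N(2T-3)/((2T-N-5) T^2 dtheta^4).  Diverges as T -> (N+5)/2.
    """
    if 2 * T - N - 5 <= 0:
        raise DivergentVarianceError(
            f"analytic variance diverges for T = (N+5)/2; got T={T}, N={N} "
            f"with 2T-N-5 = {2 * T - N - 5}"
        )
    g = (2 * T - 3) / (T * dtheta**2)
    return 2.0 / (2 * T - N - 5) * (info**2 + 4 * g * info + 4 * N * g / (T * dtheta**2))


def bc_info_shuffle(m: MomentSummary) -> InfoEstimate:
    """Unbiased estimator of the shuffled information sum_i f_i'^2 / sigma_i^2.

    Uses only the marginal variances — no actual shuffling is performed,
    which avoids the residual-correlation noise of shuffle-then-decode.
    """
    if m.T < 3:
        raise UnusableRegimeError("shuffle estimator needs T >= 3")
    s2 = m.marginal_variances
    zero = np.flatnonzero(s2 <= 0)
    if zero.size:
        raise ZeroDivisionError(
            f"neuron(s) {zero.tolist()} have zero marginal variance; "
            "shuffled information is undefined"
        )
    value = float(shuffle_info_kernel(m.dmu_dtheta, s2, m.T, m.dtheta))
    return InfoEstimate(value, "shuffle", m.T, m.N, m.dtheta)


def bc_info_crossed(mA: MomentSummary, mB: MomentSummary) -> InfoEstimate:
    """Bias-corrected information extracted from dataset B by the decoder
    optimal for dataset A (w proportional to Sigma_A^-1 f'_A).

    Both datasets must share N, T and dtheta.  The numerator and the
    denominator of the population quantity
    I_AB = (f'_B^T Sigma_A^-1 f'_A)^2 / (f'_A^T Sigma_A^-1 Sigma_B Sigma_A^-1 f'_A)
    are de-biased separately (the denominator via the second moments of the
    inverse-Wishart distribution); residual O(1/T) bias from the final
    ratio is not corrected.
    """
    if mA.N != mB.N or mA.dtheta != mB.dtheta:
        raise ValueError("datasets A and B must share N and dtheta")
    if mA.T != mB.T:
        raise ValueError("datasets A and B must have the same number of trials")
    _check_invertible(mA)
    value, degenerate = crossed_info_kernel(
        mA.dmu_dtheta, mA.S_pooled, mB.dmu_dtheta, mB.S_pooled, mA.T, mA.dtheta
    )
    return InfoEstimate(
        float(value), "crossed", mA.T, mA.N, mA.dtheta, degenerate=bool(degenerate)
    )


def bc_info_diag(
    data: TrialSet, seed: int | np.random.Generator | None = 0, n_shuffles: int = 1
) -> InfoEstimate:
    """Bias-corrected estimator of the factorized-decoder information I_diag.

    Dataset A is a trial-shuffled copy of ``data`` (per-neuron,
    per-condition independent permutations, so its covariance carries only
    the residual correlations of a finite shuffle), dataset B the original
    data; the crossed correction is applied with an extra subtraction of
    2N/(T dtheta^2) in the numerator because A and B share the same tuning
    derivative.  ``n_shuffles`` > 1 averages over shuffle realizations.
    """
    from .decoders import shuffle_trials  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    mB = summarize_trials(data)
    _check_invertible(mB)
    values, flags = [], []
    for _ in range(max(1, n_shuffles)):
        mA = summarize_trials(shuffle_trials(data, rng))
        v, d = crossed_info_kernel(
            mA.dmu_dtheta, mA.S_pooled, mB.dmu_dtheta, mB.S_pooled,
            mA.T, mA.dtheta, diag_numerator_correction=True,
        )
        values.append(float(v))
        flags.append(bool(d))
    return InfoEstimate(
        float(np.mean(values)), "diag", mB.T, mB.N, mB.dtheta, degenerate=any(flags)
    )


# ---------------------------------------------------------------------------
# ground-truth / analytic helpers
# ---------------------------------------------------------------------------

def true_linear_info(
    f_prime: np.ndarray, Sigma_bar: np.ndarray, dtheta: float | None = None
) -> float:
    """Population linear Fisher information f'^T Sigma_bar^-1 f'.

    ``f_prime`` is the tuning derivative (already divided by dtheta when it
    comes from a finite difference).  For coarse discrimination pass the raw
    mean difference d_f and the separation ``dtheta``; the result is then
    d_f^T Sigma_bar^-1 d_f / dtheta^2.
    """
    f_prime = np.asarray(f_prime, dtype=float)
    Sigma_bar = _sym(np.asarray(Sigma_bar, dtype=float))
    try:
        np.linalg.cholesky(Sigma_bar)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("Sigma_bar must be positive definite") from e
    value = float(_solve_quad(Sigma_bar, f_prime))
    if dtheta is not None:
        value /= dtheta**2
    return value


def optimal_weights(
    f_prime: np.ndarray, Sigma: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Locally optimal unbiased linear readout w = Sigma^-1 f' / (f'^T Sigma^-1 f').

    With these weights the linear stimulus estimator is unbiased and its
    variance equals 1/I exactly.  ``normalize=False`` returns the
    unnormalized direction Sigma^-1 f'.
    """
    f_prime = np.asarray(f_prime, dtype=float)
    Sigma = _sym(np.asarray(Sigma, dtype=float))
    try:
        w = np.linalg.solve(Sigma, f_prime)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("covariance is singular") from e
    if normalize:
        w = w / float(f_prime @ w)
    return w


def info_to_percent_correct(info: float, separation: float) -> float:
    """Two-alternative percent correct implied by information ``info`` at
    stimulus separation ``separation``: 100 * Phi(separation * sqrt(info) / 2).

    The optimal linear readout of either stimulus is Gaussian with
    variance 1/info around the true value; an ideal observer choosing the
    nearer of the two stimulus values is correct whenever the readout
    falls on the correct side of the midpoint.
    """
    if info < 0:
        raise ValueError("information must be non-negative; clip or propagate noise upstream")
    return float(100.0 * stats.norm.cdf(separation * np.sqrt(info) / 2.0))
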