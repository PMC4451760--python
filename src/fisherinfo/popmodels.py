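"""Generative population models with analytic ground truth.

Three simulators, in decreasing order of realism:

* a doubly stochastic V1-like model — Gabor-filter neurons driven by a
  noisy Gabor image, half-rectified, with Poisson spiking.  Shared pixel
  noise induces information-limiting noise correlations, so the
  population information saturates below the information in the input
  image, |J'|^2 / sigma_0^2;
* independent Poisson neurons with Von Mises orientation tuning (exact
  diagonal ground truth, used for low-count robustness checks);
* an exact multivariate Gaussian population (the oracle model for the
  unbiasedness and variance calibration of the direct estimators).

Orientations are degrees at the API surface and converted to radians
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import TrialSet
from .estimators import optimal_weights, true_linear_info

__all__ = [
    "GaborStimulusParams",
    "GaborPopulation",
    "VonMisesPopulation",
    "GaussianPopulation",
    "PopulationGroundTruth",
    "make_gabor_image",
    "build_filter_bank",
    "build_population_B",
]


@dataclass(frozen=True)
class GaborStimulusParams:
    """Geometry of the input Gabor image and its pixel noise.

    Defaults: 32x32 pixels, envelope std P/5, wavelength P/1.5 pixels per
    cycle, phase 0, Michelson contrast 0.75, pixel-noise std 0.2.
    """

    P: int = 32
    sigma_env: float | None = None      # defaults to P/5
    wavelength: float | None = None     # defaults to P/1.5
    phase: float = 0.0
    contrast: float = 0.75
    sigma0: float = 0.2

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValueError("image side length must be >= 4 pixels")
        if self.sigma_env is None:
            object.__setattr__(self, "sigma_env", self.P / 5)
        if self.wavelength is None:
            object.__setattr__(self, "wavelength", self.P / 1.5)
        if self.sigma_env <= 0 or self.wavelength <= 0 or self.sigma0 < 0:
            raise ValueError("sigma_env, wavelength must be > 0 and sigma0 >= 0")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


def _gabor_patch(
    P: int, theta_deg: float, sigma: float, wavelength: float, phase: float,
    contrast: float = 1.0,
) -> np.ndarray:
    """Gabor patch on a centered integer grid, returned as a flat P^2 vector."""
    half = (P - 1) / 2.0
    coords = np.arange(P) - half
    x, y = np.meshgrid(coords, coords, indexing="xy")
    th = np.deg2rad(theta_deg)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    carrier = np.cos(2 * np.pi / wavelength * (x * np.cos(th) + y * np.sin(th)) + phase)
    return (contrast * envelope * carrier).ravel()


def make_gabor_image(params: GaborStimulusParams, theta_deg: float) -> np.ndarray:
    """Noise-free input image J(theta) as a flat P^2 vector."""
    return _gabor_patch(
        params.P, theta_deg, params.sigma_env, params.wavelength,
        params.phase, params.contrast,
    )


@dataclass
class PopulationGroundTruth:
    """Analytic tuning, covariances and true linear information for a
    simulated two-condition discrimination."""

    f_plus: np.ndarray
    f_minus: np.ndarray
    f_prime: np.ndarray
    Sigma_plus: np.ndarray
    Sigma_minus: np.ndarray
    Sigma_bar: np.ndarray
    dtheta: float
    info_true: float


@dataclass
class GaborPopulation:
    """Bank of N orientation-selective Gabor filters with log-normal
    amplitudes and Poisson output, driven by a noisy Gabor image.

    Each filter is rescaled to zero mean and unit norm; preferred
    orientations are evenly spaced over [-180, 180) in steps of 360/N.
    The effective tuning amplitude of neuron k is g_k = gain * a_k with
    a_k ~ LogNormal(log-mean 0, log-std 0.25).
    """

    filters: np.ndarray            # (N, P^2), zero-mean unit-norm rows
    amplitudes: np.ndarray         # a_k
    gain: float
    preferred_orientations: np.ndarray
    stimulus: GaborStimulusParams
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.filters.shape[0]

    @property
    def effective_amplitudes(self) -> np.ndarray:
        """g_k = gain * a_k, the amplitude entering tuning and covariance."""
        return self.gain * self.amplitudes

    # -- analytic moments (rectification ignored) -----------------------

    def analytic_moments(self, theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
        """Tuning f_k = g_k F_k . J(theta) and covariance
        Sigma_kl = sigma0^2 g_k g_l F_k.F_l + delta_kl f_k.

        These ignore the half-rectification; with phase 0 the filter
        outputs are essentially never negative so the approximation is
        accurate at the default parameters.
        """
        g = self.effective_amplitudes
        J = make_gabor_image(self.stimulus, theta_deg)
        f = g * (self.filters @ J)
        G = self.filters @ self.filters.T
        Sigma = self.stimulus.sigma0**2 * np.outer(g, g) * G + np.diag(f)
        return f, Sigma

    def ground_truth(self, theta_plus: float, theta_minus: float) -> PopulationGroundTruth:
        if theta_plus == theta_minus:
            raise ValueError("the two orientations must differ")
        dtheta = theta_plus - theta_minus
        f_p, S_p = self.analytic_moments(theta_plus)
        f_m, S_m = self.analytic_moments(theta_minus)
        f_prime = (f_p - f_m) / dtheta
        Sigma_bar = 0.5 * (S_p + S_m)
        info = true_linear_info(f_prime, Sigma_bar)
        return PopulationGroundTruth(
            f_p, f_m, f_prime, S_p, S_m, Sigma_bar, dtheta, info
        )

    def input_information(self, theta_plus: float, theta_minus: float) -> float:
        """Information in the noisy input image, |J'|^2 / sigma0^2, with J'
        the finite-difference image derivative.  An upper bound on the
        information in any downstream population."""
        Jp = make_gabor_image(self.stimulus, theta_plus)
        Jm = make_gabor_image(self.stimulus, theta_minus)
        Jprime = (Jp - Jm) / (theta_plus - theta_minus)
        return float(Jprime @ Jprime) / self.stimulus.sigma0**2

    # -- simulation ------------------------------------------------------

    def simulate(
        self, theta_deg: float, T: int, seed: int | np.random.Generator | None = 0
    ) -> np.ndarray:
        """T trials of spike counts at orientation ``theta_deg``.

        Per trial: noisy image J~ = J + N(0, sigma0^2 I); half-rectified
        drive max(g_k F_k . J~, 0); independent Poisson counts.
        """
        if T < 1:
            raise ValueError("need T >= 1 trials")
        rng = np.random.default_rng(seed)
        J = make_gabor_image(self.stimulus, theta_deg)
        g = self.effective_amplitudes
        drive_mean = g * (self.filters @ J)              # (N,)
        # shared pixel noise projected through the filters: exact and cheaper
        # than materializing the P^2 noise image per trial
        proj = self.stimulus.sigma0 * (self.filters * g[:, None])   # (N, P^2)
        C = proj @ proj.T
        if np.trace(C) > 0:
            L = np.linalg.cholesky(
                C + 1e-12 * np.trace(C) / self.n_neurons * np.eye(self.n_neurons)
            )
            drive = drive_mean + rng.standard_normal((T, self.n_neurons)) @ L.T
        else:
            drive = np.broadcast_to(drive_mean, (T, self.n_neurons))
        rates = np.clip(drive, 0.0, None)
        return rng.poisson(rates).astype(float)

    def simulate_pair(
        self,
        theta_plus: float,
        theta_minus: float,
        T: int,
        seed: int | np.random.Generator | None = 0,
    ) -> TrialSet:
        rng = np.random.default_rng(seed)
        rp = self.simulate(theta_plus, T, rng)
        rm = self.simulate(theta_minus, T, rng)
        return TrialSet(rp, rm, theta_plus - theta_minus)


def build_filter_bank(
    N: int = 50,
    gain: float = 30.0,
    stimulus: GaborStimulusParams | None = None,
    seed: int | np.random.Generator | None = 0,
    filter_sigma: float | None = None,
    filter_wavelength: float | None = None,
    amplitude_log_std: float = 0.25,
) -> GaborPopulation:
    """Construct the default V1-like filter bank.

    Filters share the stimulus geometry (envelope P/5, wavelength P/1.5,
    phase 0) unless ``filter_sigma``/``filter_wavelength`` override it;
    preferred orientations are [-180 : 360/N : 180(N-1)/N]; amplitudes
    a_k are log-normal with log-std ``amplitude_log_std``.
    """
    if N < 1:
        raise ValueError("need at least one filter")
    stimulus = stimulus or GaborStimulusParams()
    f_sigma = filter_sigma if filter_sigma is not None else stimulus.sigma_env
    f_lambda = filter_wavelength if filter_wavelength is not None else stimulus.wavelength
    rng = np.random.default_rng(seed)
    prefs = -180.0 + 360.0 / N * np.arange(N)
    F = np.empty((N, stimulus.P**2))
    for k, th in enumerate(prefs):
        patch = _gabor_patch(stimulus.P, th, f_sigma, f_lambda, stimulus.phase)
        patch = patch - patch.mean()
        F[k] = patch / np.linalg.norm(patch)
    a = rng.lognormal(mean=0.0, sigma=amplitude_log_std, size=N)
    return GaborPopulation(F, a, gain, prefs, stimulus)


def build_population_B(
    N: int = 50,
    gain: float = 30.0,
    stimulus: GaborStimulusParams | None = None,
    seed: int | np.random.Generator | None = 0,
) -> GaborPopulation:
    """Variant population for crossed decoding: smaller envelope (P/8) and
    shorter wavelength (P/3), same input images."""
    stimulus = stimulus or GaborStimulusParams()
    return build_filter_bank(
        N, gain, stimulus, seed,
        filter_sigma=stimulus.P / 8, filter_wavelength=stimulus.P / 3,
    )


@dataclass
class VonMisesPopulation:
    """Independent Poisson neurons with Von Mises orientation tuning
    f_i(theta) = baseline + gain * exp(kappa * (cos(theta - theta_i) - 1)).

    Defaults give a population-average count of about 0.8 spikes per
    neuron per trial, the low-count regime.
    """

    N: int = 50
    baseline: float = 0.05
    gain: float = 2.43
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.gain < 0 or self.baseline + self.gain <= 0:
            raise ValueError("rates must be positive somewhere")

    @property
    def preferred_orientations(self) -> np.ndarray:
        return -180.0 + 360.0 / self.N * np.arange(self.N)

    def tuning(self, theta_deg: float) -> np.ndarray:
        d = np.deg2rad(theta_deg - self.preferred_orientations)
        return self.baseline + self.gain * np.exp(self.kappa * (np.cos(d) - 1.0))

    def ground_truth(self, theta_plus: float, theta_minus: float) -> PopulationGroundTruth:
        dtheta = theta_plus - theta_minus
        f_p = self.tuning(theta_plus)
        f_m = self.tuning(theta_minus)
        f_prime = (f_p - f_m) / dtheta
        S_p, S_m = np.diag(f_p), np.diag(f_m)
        Sigma_bar = 0.5 * (S_p + S_m)
        info = float(np.sum(f_prime**2 / np.diag(Sigma_bar)))
        return PopulationGroundTruth(f_p, f_m, f_prime, S_p, S_m, Sigma_bar, dtheta, info)

    def simulate_pair(
        self,
        theta_plus: float,
        theta_minus: float,
        T: int,
        seed: int | np.random.Generator | None = 0,
    ) -> TrialSet:
        rng = np.random.default_rng(seed)
        rp = rng.poisson(self.tuning(theta_plus), size=(T, self.N)).astype(float)
        rm = rng.poisson(self.tuning(theta_minus), size=(T, self.N)).astype(float)
        return TrialSet(rp, rm, theta_plus - theta_minus)


@dataclass
class GaussianPopulation:
    """Exact multivariate Gaussian responses N(f_plus, Sigma), N(f_minus, Sigma):
    the oracle model for unbiasedness and variance calibration (ground truth
    is exact and the Wishart sampling theory applies verbatim)."""

    f_plus: np.ndarray
    f_minus: np.ndarray
    Sigma: np.ndarray
    dtheta: float

    _chol: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.f_plus = np.asarray(self.f_plus, dtype=float)
        self.f_minus = np.asarray(self.f_minus, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.Sigma)
        except np.linalg.LinAlgError as e:
            raise ValueError("Sigma must be positive definite") from e

    @property
    def N(self) -> int:
        return self.f_plus.size

    @property
    def f_prime(self) -> np.ndarray:
        return (self.f_plus - self.f_minus) / self.dtheta

    @property
    def info_true(self) -> float:
        return true_linear_info(self.f_prime, self.Sigma)

    @property
    def info_shuffle_true(self) -> float:
        return float(np.sum(self.f_prime**2 / np.diag(self.Sigma)))

    @property
    def info_diag_true(self) -> float:
        """Information of the correlation-blind readout w ~ D^-1 f',
        D = diag(Sigma): (f'^T D^-1 f')^2 / (f'^T D^-1 Sigma D^-1 f')."""
        d = np.diag(self.Sigma)
        u = self.f_prime / d
        return float((self.f_prime @ u) ** 2 / (u @ self.Sigma @ u))

    def ground_truth(self) -> PopulationGroundTruth:
        return PopulationGroundTruth(
            self.f_plus, self.f_minus, self.f_prime,
            self.Sigma, self.Sigma, self.Sigma, self.dtheta, self.info_true,
        )

    def simulate(
        self, T: int, seed: int | np.random.Generator | None = 0
    ) -> TrialSet:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((2, T, self.N))
        rp = self.f_plus + z[0] @ self._chol.T
        rm = self.f_minus + z[1] @ self._chol.T
        return TrialSet(rp, rm, self.dtheta)

    def simulate_batch(
        self, T: int, n_rep: int, seed: int | np.random.Generator | None = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """(n_rep, T, N) response arrays for both conditions — vectorized
        Monte-Carlo driver for the estimator calibration tests."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((2, n_rep, T, self.N))
        return self.f_plus + z[0] @ self._chol.T, self.f_minus + z[1] @ self._chol.T

    @classmethod
    def random(
        cls,
        N: int,
        info: float | None = None,
        dtheta: float = 0.1,
        seed: int | np.random.Generator | None = 0,
        correlated: bool = True,
    ) -> "GaussianPopulation":
        """A reproducible random test population; if ``info`` is given the
        tuning derivative is rescaled so the true information equals it."""
        rng = np.random.default_rng(seed)
        if correlated:
            A = rng.standard_normal((N, max(2 * N, N + 2)))
            Sigma = A @ A.T / max(2 * N, N + 2) + 0.5 * np.eye(N)
        else:
            Sigma = np.diag(rng.uniform(0.5, 2.0, size=N))
        f_prime = rng.standard_normal(N)
        if info is not None:
            cur = true_linear_info(f_prime, Sigma)
            f_prime *= np.sqrt(info / cur)
        base = rng.uniform(5.0, 10.0, size=N)
        return cls(base + 0.5 * dtheta * f_prime, base - 0.5 * dtheta * f_prime,
                   Sigma, dtheta)
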