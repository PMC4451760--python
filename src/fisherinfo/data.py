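"""Containers for two-condition trial data and their moment summaries.

A discrimination experiment presents two stimuli ``theta_plus`` and
``theta_minus`` separated by ``dtheta`` (full separation, in stimulus
units such as degrees of orientation) and records the responses of N
neurons over T trials per condition.  Everything downstream — the direct
information estimators and the decoder baseline — operates either on the
raw :class:`TrialSet` or on its :class:`MomentSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialSet", "MomentSummary", "summarize_trials"]


@dataclass
class TrialSet:
    """Responses of N neurons over T trials for each of two stimulus conditions.

    Parameters
    ----------
    responses_plus, responses_minus : (T, N) arrays
        Spike counts (or rates) for conditions theta_plus and theta_minus.
    dtheta : float
        Full stimulus separation theta_plus - theta_minus, > 0.
    labels : tuple of str, optional
        Condition labels, purely descriptive.
    """

    responses_plus: np.ndarray
    responses_minus: np.ndarray
    dtheta: float
    labels: tuple[str, str] = ("theta+", "theta-")

    def __post_init__(self) -> None:
        self.responses_plus = np.asarray(self.responses_plus, dtype=float)
        self.responses_minus = np.asarray(self.responses_minus, dtype=float)
        if self.responses_plus.ndim != 2 or self.responses_minus.ndim != 2:
            raise ValueError("responses must be T x N matrices")
        if self.responses_plus.shape != self.responses_minus.shape:
            raise ValueError(
                "condition matrices must have the same shape, got "
                f"{self.responses_plus.shape} and {self.responses_minus.shape}"
            )
        if self.n_trials < 2:
            raise ValueError("need at least T = 2 trials per condition")
        if not (np.isfinite(self.responses_plus).all() and np.isfinite(self.responses_minus).all()):
            raise ValueError("responses contain non-finite entries")
        if not self.dtheta > 0:
            raise ValueError("dtheta must be positive (full separation theta+ - theta-)")

    @property
    def n_trials(self) -> int:
        return self.responses_plus.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.responses_plus.shape[1]

    # -- I/O ------------------------------------------------------------

    def to_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            responses_plus=self.responses_plus,
            responses_minus=self.responses_minus,
            dtheta=self.dtheta,
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "TrialSet":
        with np.load(path) as f:
            return cls(f["responses_plus"], f["responses_minus"], float(f["dtheta"]))

    def to_csv(self, path_plus: str | Path, path_minus: str | Path) -> None:
        """One row per trial, one column per neuron, one file per condition."""
        cols = [f"neuron_{i}" for i in range(self.n_neurons)]
        pd.DataFrame(self.responses_plus, columns=cols).to_csv(path_plus, index=False)
        pd.DataFrame(self.responses_minus, columns=cols).to_csv(path_minus, index=False)

    @classmethod
    def from_csv(cls, path_plus: str | Path, path_minus: str | Path, dtheta: float) -> "TrialSet":
        rp = pd.read_csv(path_plus).to_numpy(dtype=float)
        rm = pd.read_csv(path_minus).to_numpy(dtype=float)
        return cls(rp, rm, dtheta)

    def subset(self, idx_plus: np.ndarray, idx_minus: np.ndarray) -> "TrialSet":
        return TrialSet(
            self.responses_plus[idx_plus], self.responses_minus[idx_minus],
            self.dtheta, self.labels,
        )

    def summarize(self) -> "MomentSummary":
        return summarize_trials(self)


@dataclass
class MomentSummary:
    """Empirical first and second moments of a two-condition experiment.

    ``S_plus``/``S_minus`` are the unbiased (1/(T-1)) per-condition sample
    covariances, ``S_pooled`` their average, and ``dmu_dtheta`` the
    finite-difference tuning derivative (mu_plus - mu_minus)/dtheta.
    """

    mu_plus: np.ndarray
    mu_minus: np.ndarray
    S_plus: np.ndarray
    S_minus: np.ndarray
    S_pooled: np.ndarray
    dmu_dtheta: np.ndarray
    T: int
    N: int
    dtheta: float

    @property
    def marginal_variances(self) -> np.ndarray:
        """Pooled per-neuron variances s_i^2 = (s_i+^2 + s_i-^2)/2."""
        return 0.5 * (np.diag(self.S_plus) + np.diag(self.S_minus))

    def rescaled(self, c: float) -> "MomentSummary":
        """Summary under the reparameterization dtheta -> c*dtheta (same data)."""
        return MomentSummary(
            self.mu_plus, self.mu_minus, self.S_plus, self.S_minus,
            self.S_pooled, self.dmu_dtheta / c, self.T, self.N, c * self.dtheta,
        )


def summarize_trials(data: TrialSet) -> MomentSummary:
    """Compute means, unbiased covariances, pooled covariance and the
    finite-difference derivative from a :class:`TrialSet`."""
    rp, rm = data.responses_plus, data.responses_minus
    mu_p = rp.mean(axis=0)
    mu_m = rm.mean(axis=0)
    S_p = np.cov(rp, rowvar=False, ddof=1)
    S_m = np.cov(rm, rowvar=False, ddof=1)
    S_p = np.atleast_2d(S_p)
    S_m = np.atleast_2d(S_m)
    return MomentSummary(
        mu_plus=mu_p,
        mu_minus=mu_m,
        S_plus=S_p,
        S_minus=S_m,
        S_pooled=0.5 * (S_p + S_m),
        dmu_dtheta=(mu_p - mu_m) / data.dtheta,
        T=data.n_trials,
        N=data.n_neurons,
        dtheta=data.dtheta,
    )
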