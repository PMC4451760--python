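"""Model/Results front end over the direct estimators and the decoder.

`LinearFisherInfo` is built from a :class:`~fisherinfo.data.TrialSet`
(or raw arrays) and its :meth:`~LinearFisherInfo.fit` dispatches to the
closed-form estimators; `EarlyStoppingDecoder` wraps the cross-validated
decoding baseline.  Both return results objects carrying the estimate,
its uncertainty when available, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import decoders as _dec
from . import estimators as _est
from .data import MomentSummary, TrialSet, summarize_trials

__all__ = ["LinearFisherInfo", "InfoResults", "EarlyStoppingDecoder", "DecoderResults"]

_METHODS = ("bias_corrected", "naive", "shuffle", "diag", "crossed")


class LinearFisherInfo:
    """Linear Fisher information of a two-condition population recording.

    Parameters
    ----------
    data : TrialSet
        Trial-by-neuron responses for the two stimulus conditions.

    Examples
    --------
    >>> model = LinearFisherInfo.from_arrays(r_plus, r_minus, dtheta=7.0)
    >>> res = model.fit()                    # bias-corrected direct estimate
    >>> res.value, res.se
    """

    def __init__(self, data: TrialSet):
        self.data = data
        self.moments: MomentSummary = summarize_trials(data)

    @classmethod
    def from_arrays(
        cls, responses_plus, responses_minus, dtheta: float
    ) -> "LinearFisherInfo":
        return cls(TrialSet(responses_plus, responses_minus, dtheta))

    @property
    def nobs(self) -> int:
        return self.data.n_trials

    @property
    def n_neurons(self) -> int:
        return self.data.n_neurons

    def fit(
        self,
        method: str = "bias_corrected",
        data_B: TrialSet | None = None,
        seed: int | None = 0,
        n_shuffles: int = 1,
        warn_noisy: bool = True,
    ) -> "InfoResults":
        """Estimate the information with one of the closed-form methods.

        ``method``: ``bias_corrected`` (default), ``naive``, ``shuffle``
        (independent-marginals information), ``diag`` (factorized-decoder
        information; uses a seeded trial shuffle), or ``crossed`` (requires
        ``data_B``: information in B for the decoder optimal for this data).
        """
        m = self.moments
        if method == "bias_corrected":
            est = _est.bc_info(m, warn_noisy=warn_noisy)
        elif method == "naive":
            est = _est.naive_info(m)
        elif method == "shuffle":
            est = _est.bc_info_shuffle(m)
        elif method == "diag":
            est = _est.bc_info_diag(self.data, seed=seed, n_shuffles=n_shuffles)
        elif method == "crossed":
            if data_B is None:
                raise ValueError("method 'crossed' needs data_B")
            est = _est.bc_info_crossed(m, summarize_trials(data_B))
        else:
            raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
        return InfoResults(self, est)


@dataclass
class InfoResults:
    """Estimation results: the information value, its analytic sampling
    variance when the method provides one, and derived quantities."""

    model: LinearFisherInfo
    estimate: _est.InfoEstimate

    @property
    def value(self) -> float:
        return self.estimate.value

    @property
    def method(self) -> str:
        return self.estimate.method

    @property
    def analytic_variance(self) -> float | None:
        return self.estimate.analytic_variance

    @property
    def se(self) -> float | None:
        return self.estimate.se

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-theory interval from the analytic variance."""
        if self.se is None:
            raise ValueError(f"no analytic variance for method {self.method!r}")
        z = stats.norm.ppf(1 - alpha / 2)
        return self.value - z * self.se, self.value + z * self.se

    def percent_correct(self) -> float:
        """Implied two-alternative percent correct at the recorded dtheta."""
        return self.estimate.percent_correct()

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Linear Fisher Information".center(58),
            "=" * 58,
            f"{'Method:':<28}{e.method:>30}",
            f"{'Trials per condition (T):':<28}{e.T:>30d}",
            f"{'Neurons (N):':<28}{e.N:>30d}",
            f"{'Stimulus separation:':<28}{e.dtheta:>30.4g}",
            "-" * 58,
            f"{'Information (units^-2):':<28}{e.value:>30.6g}",
        ]
        if e.se is not None:
            lo, hi = self.conf_int()
            lines.append(f"{'Analytic std. error:':<28}{e.se:>30.6g}")
            lines.append(f"{'95% CI:':<28}{f'[{lo:.5g}, {hi:.5g}]':>30}")
        if e.value >= 0:
            lines.append(f"{'Implied percent correct:':<28}{self.percent_correct():>29.2f}%")
        if e.degenerate:
            lines.append("Warning: degenerate denominator after bias correction")
        if e.value < 0:
            lines.append("Note: negative estimate (sampling noise exceeds signal)")
        lines.append("=" * 58)
        return "\n".join(lines)


class EarlyStoppingDecoder:
    """Cross-validated linear decoder baseline.

    Splits the data into training/test/validation sets, fits the readout
    by gradient descent with early stopping, and reads information out on
    the validation (and training) set.
    """

    def __init__(
        self,
        data: TrialSet,
        split: _dec.SplitConfig | None = None,
        mode: str = "plain",
        data_B: TrialSet | None = None,
        lr: float | None = None,
        max_iter: int = 100_000,
    ):
        self.data = data
        self.split = split or _dec.SplitConfig()
        self.mode = mode
        self.data_B = data_B
        self.lr = lr
        self.max_iter = max_iter

    def fit(self, seed: int | np.random.Generator | None = 0) -> "DecoderResults":
        info_tr, info_val = _dec.decoder_pipeline(
            self.data, mode=self.mode, cfg=self.split, seed=seed,
            data_B=self.data_B, lr=self.lr, max_iter=self.max_iter,
        )
        return DecoderResults(self, info_tr, info_val)


@dataclass
class DecoderResults:
    model: EarlyStoppingDecoder
    info_training: _est.InfoEstimate
    info_validation: _est.InfoEstimate

    @property
    def value(self) -> float:
        """The headline (validation-set) information estimate."""
        return self.info_validation.value

    def summary(self) -> str:
        v, t = self.info_validation, self.info_training
        return "\n".join([
            "Early-Stopping Decoder Information".center(58),
            "=" * 58,
            f"{'Mode:':<28}{self.model.mode:>30}",
            f"{'Trials per condition (T):':<28}{self.model.data.n_trials:>30d}",
            f"{'Neurons (N):':<28}{self.model.data.n_neurons:>30d}",
            "-" * 58,
            f"{'Validation information:':<28}{v.value:>30.6g}",
            f"{'Training information:':<28}{t.value:>30.6g}",
            "=" * 58,
        ])
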