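"""Cross-validated linear decoding baseline with early stopping.

The conventional route to linear Fisher information is to train a linear
stimulus decoder and invert the variance of its cross-validated readout.
Training is a least-squares regression of the (centered) stimulus value
on the (centered) population response, optimized by full-batch gradient
descent and regularized by early stopping: the data are split into
training, test and validation thirds, gradient descent runs on the
training set, and stops when the test-set error starts to rise.  The
information is then read out on the validation set through the
scale-invariant ratio of Eq-of-motion form

    I_hat = [w^T (mu+ - mu-) / dtheta]^2 / (w^T S_bar w)

with S_bar the average per-condition sample covariance of the evaluation
set, which is immune to miscalibrated scaling of w.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TrialSet, summarize_trials
from .estimators import InfoEstimate

__all__ = [
    "SplitConfig",
    "DecoderFit",
    "split_trials",
    "train_early_stopping",
    "decoder_info",
    "shuffle_trials",
    "decoder_pipeline",
]


@dataclass(frozen=True)
class SplitConfig:
    """Training/test/validation split fractions (default equal thirds)."""

    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (3,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be three positive numbers summing to 1")


@dataclass
class DecoderFit:
    """Weights and diagnostics of an early-stopping gradient-descent fit."""

    weights: np.ndarray
    center: np.ndarray          # response mean used to center the regressors
    learning_rate: float
    n_iter: int                 # iteration at which the returned weights were taken
    train_errors: np.ndarray
    test_errors: np.ndarray
    stopping_reason: str        # "test_error_increase" or "max_iter"


def _split_sizes(T: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of T trials into three splits."""
    quotas = np.asarray(fractions) * T
    sizes = np.floor(quotas).astype(int)
    rem = T - sizes.sum()
    order = np.argsort(-(quotas - sizes))
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes.tolist()


def split_trials(
    data: TrialSet, cfg: SplitConfig | None = None, seed=None
) -> tuple[TrialSet, TrialSet, TrialSet]:
    """Disjoint, exhaustive, per-condition stratified random partition into
    training, test and validation sets; reproducible from the seed."""
    cfg = cfg or SplitConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    T = data.n_trials
    sizes = _split_sizes(T, cfg.fractions)
    if min(sizes) < 2:
        raise ValueError(
            f"each split needs >= 2 trials per condition; T={T} with fractions "
            f"{cfg.fractions} gives {sizes}"
        )
    perm_p = rng.permutation(T)
    perm_m = rng.permutation(T)
    out = []
    start = 0
    for size in sizes:
        sl = slice(start, start + size)
        out.append(data.subset(perm_p[sl], perm_m[sl]))
        start += size
    return tuple(out)


def _design(data: TrialSet, center: np.ndarray | None = None):
    """Stacked centered responses X and centered targets y = +-dtheta/2."""
    X = np.vstack([data.responses_plus, data.responses_minus])
    if center is None:
        center = X.mean(axis=0)
    X = X - center
    T = data.n_trials
    y = np.concatenate([np.full(T, data.dtheta / 2), np.full(T, -data.dtheta / 2)])
    return X, y, center


def train_early_stopping(
    train: TrialSet,
    test: TrialSet,
    lr: float | None = None,
    seed: int | np.random.Generator | None = 0,
    max_iter: int = 100_000,
    smooth_window: int = 5,
    init_scale: float = 1e-3,
) -> DecoderFit:
    """Full-batch gradient descent on the training squared error, stopped
    when the (smoothed) test-set error first rises above its running minimum.

    The learning rate defaults to 1/L with L the curvature of the training
    loss (twice the largest eigenvalue of X^T X).  Weights are initialized
    from a small random draw scaled by ``init_scale`` times the response
    scale; the weights at the test-error minimum are returned.
    """
    rng = np.random.default_rng(seed)
    X_tr, y_tr, center = _design(train)
    X_te, y_te, _ = _design(test)

    # precomputed Gram form: gradients and errors in O(N^2) per iteration
    G_tr = X_tr.T @ X_tr
    b_tr = X_tr.T @ y_tr
    c_tr = float(y_tr @ y_tr)
    G_te = X_te.T @ X_te
    b_te = X_te.T @ y_te
    c_te = float(y_te @ y_te)

    lam_max = float(np.linalg.eigvalsh(G_tr)[-1])
    if lr is None:
        lr = 1.0 / (2.0 * lam_max) if lam_max > 0 else 1.0
    elif lr * lam_max * 2.0 >= 2.0:
        raise ValueError(
            f"learning rate {lr} exceeds the stability bound 1/lambda_max = "
            f"{1.0 / lam_max if lam_max > 0 else np.inf}; training would diverge"
        )

    scale = float(np.std(X_tr)) or 1.0
    w = rng.normal(0.0, init_scale * (train.dtheta / 2) / scale, size=train.n_neurons)

    train_errors = np.empty(max_iter + 1)
    test_errors = np.empty(max_iter + 1)
    smoothed = np.empty(max_iter + 1)
    best_val = np.inf
    best_w = w.copy()
    best_iter = 0
    reason = "max_iter"
    n_worse_train = 0
    it = 0
    for it in range(max_iter + 1):
        Gw = G_tr @ w
        train_errors[it] = c_tr - 2.0 * (w @ b_tr) + w @ Gw
        test_errors[it] = c_te - 2.0 * (w @ b_te) + w @ (G_te @ w)
        lo = max(0, it - smooth_window + 1)
        smoothed[it] = test_errors[lo : it + 1].mean()
        if smoothed[it] < best_val * (1 - 1e-12):
            best_val = smoothed[it]
            best_w = w.copy()
            best_iter = it
        elif it >= smooth_window and smoothed[it] > best_val * (1 + 1e-9):
            reason = "test_error_increase"
            break
        if it > 0 and train_errors[it] > train_errors[it - 1] * (1 + 1e-12):
            n_worse_train += 1
            if n_worse_train > 10:
                raise ValueError(
                    "training error increases persistently; reduce the learning rate"
                )
        # converged: training error no longer moving and test error flat
        if (
            it >= 200
            and it - best_iter > 200
            and train_errors[it - 200] - train_errors[it]
            < 1e-12 * max(train_errors[it], 1e-300)
        ):
            reason = "converged"
            break
        w = w - 2.0 * lr * (Gw - b_tr)

    return DecoderFit(
        weights=best_w,
        center=center,
        learning_rate=lr,
        n_iter=best_iter,
        train_errors=train_errors[: it + 1],
        test_errors=test_errors[: it + 1],
        stopping_reason=reason,
    )


def decoder_info(
    fit: DecoderFit | np.ndarray, eval_set: TrialSet, method: str = "decoder_validation"
) -> InfoEstimate:
    """Information read out by weights ``fit`` on ``eval_set``:

    [w^T (mu+ - mu-)/dtheta]^2 / (w^T S_bar w), S_bar the average of the two
    per-condition sample covariances of the evaluation set.  Invariant to
    any rescaling of w.
    """
    w = fit.weights if isinstance(fit, DecoderFit) else np.asarray(fit, dtype=float)
    m = summarize_trials(eval_set)
    denom = float(w @ m.S_pooled @ w)
    if denom <= 0:
        raise ZeroDivisionError("w^T S_bar w is not positive; degenerate readout")
    signal = float(w @ m.dmu_dtheta)
    return InfoEstimate(signal**2 / denom, method, m.T, m.N, m.dtheta)


def shuffle_trials(
    data: TrialSet, seed: int | np.random.Generator | None = 0
) -> TrialSet:
    """Destroy noise correlations: within each condition, independently
    permute each neuron's responses across trials.  Marginal histograms per
    neuron per condition are exactly preserved."""
    rng = np.random.default_rng(seed)
    T = data.n_trials

    def _shuffle(R: np.ndarray) -> np.ndarray:
        cols = np.argsort(rng.random((T, R.shape[1])), axis=0)
        return np.take_along_axis(R, cols, axis=0)

    return TrialSet(
        _shuffle(data.responses_plus), _shuffle(data.responses_minus),
        data.dtheta, data.labels,
    )


def decoder_pipeline(
    data: TrialSet,
    mode: str = "plain",
    cfg: SplitConfig | None = None,
    seed: int | np.random.Generator | None = 0,
    data_B: TrialSet | None = None,
    **fit_kwargs,
) -> tuple[InfoEstimate, InfoEstimate]:
    """End-to-end decoding estimate; returns (training, validation) estimates.

    Modes: ``plain`` — train/test/validate on the original data;
    ``shuffle`` — all three on (independently) shuffled data;
    ``diag`` — train and test on shuffled data, validate on the original;
    ``crossed`` — train and test on ``data``, validate on ``data_B``.
    """
    if mode not in {"plain", "shuffle", "diag", "crossed"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "crossed" and data_B is None:
        raise ValueError("crossed mode needs a second TrialSet")
    rng = np.random.default_rng(seed)
    train, test, val = split_trials(data, cfg, seed=rng)
    if mode in {"shuffle", "diag"}:
        train = shuffle_trials(train, rng)
        test = shuffle_trials(test, rng)
        if mode == "shuffle":
            val = shuffle_trials(val, rng)
    elif mode == "crossed":
        # validation drawn from B; same split-size convention
        _, _, val = split_trials(data_B, cfg, seed=rng)
    fit = train_early_stopping(train, test, seed=rng, **fit_kwargs)
    info_tr = decoder_info(fit, train, method="decoder_training")
    info_val = decoder_info(fit, val, method="decoder_validation")
    return info_tr, info_val
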