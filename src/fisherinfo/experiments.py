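"""Reproducible Monte-Carlo sweeps comparing estimators across T and N.

A sweep simulates many independent experiments from a population model at
each trial count T, applies a chosen set of information estimators to the
same simulated data, and aggregates mean, spread, mean squared error
against ground truth and the relative error sqrt(MSE)/I_true, with
seeded bootstrap bands.  Per-replicate seeds are derived deterministically
from (master seed, T, replicate index) so results do not depend on
execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import TrialSet, summarize_trials
from .decoders import SplitConfig, decoder_pipeline
from .estimators import (
    bc_info,
    bc_info_crossed,
    bc_info_diag,
    bc_info_shuffle,
    naive_info,
    true_linear_info,
)

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "run_sweep",
    "bootstrap_bands",
    "subsample_protocol",
    "report",
    "load_report",
    "operational_ground_truth",
]

DIRECT_ESTIMATORS = ("bc", "naive", "shuffle", "diag", "crossed")
DECODER_ESTIMATORS = (
    "decoder",
    "decoder_training",
    "decoder_shuffle",
    "decoder_diag",
    "decoder_crossed",
)


@dataclass
class ExperimentConfig:
    """Specification of one sweep.

    ``population`` must expose ``simulate_pair(theta_plus, theta_minus, T,
    seed)`` and (for analytic truth) ``ground_truth(theta_plus,
    theta_minus)``; the Gaussian population's signature without angles is
    also accepted.  ``population_B`` supplies the second population for
    crossed estimators.  ``ground_truth_override`` substitutes operational
    (large-T) truths where the analytic value is unreliable.
    """

    population: object
    theta_plus: float = 0.0
    theta_minus: float = -7.0
    T_values: tuple[int, ...] = (250,)
    n_rep: int = 200
    estimators: tuple[str, ...] = ("bc", "decoder")
    n_rep_decoder: int | None = None      # defaults to n_rep
    decoder_kwargs: dict = field(default_factory=dict)
    split: SplitConfig | None = None
    master_seed: int = 0
    population_B: object | None = None
    ground_truth_override: dict[str, float] | None = None
    n_boot: int = 1000

    def __post_init__(self) -> None:
        unknown = set(self.estimators) - set(DIRECT_ESTIMATORS) - set(DECODER_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")
        if any(e in {"crossed", "decoder_crossed"} for e in self.estimators):
            if self.population_B is None:
                raise ValueError("crossed estimators need population_B")
        if self.n_rep_decoder is None:
            self.n_rep_decoder = self.n_rep

    # -- seeding --------------------------------------------------------

    def replicate_seed(self, T: int, rep: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.master_seed, spawn_key=(T, rep))

    def config_hash(self) -> str:
        desc = repr((
            type(self.population).__name__, self.theta_plus, self.theta_minus,
            self.T_values, self.n_rep, self.estimators, self.master_seed,
        ))
        return hashlib.sha256(desc.encode()).hexdigest()[:16]


def _simulate(pop, theta_plus, theta_minus, T, seed) -> TrialSet:
    try:
        return pop.simulate_pair(theta_plus, theta_minus, T, seed)
    except AttributeError:
        return pop.simulate(T, seed)  # GaussianPopulation carries its own angles


def _analytic_truths(cfg: ExperimentConfig) -> tuple[dict[str, float], str]:
    """Ground truth per estimator family, with provenance."""
    pop = cfg.population
    provenance = "analytic"
    truths: dict[str, float] = {}
    if hasattr(pop, "info_true"):          # GaussianPopulation
        gt_I = pop.info_true
        gt_shuf = pop.info_shuffle_true
        gt_diag = pop.info_diag_true
        f_prime, Sigma = pop.f_prime, pop.Sigma
    else:
        gt = pop.ground_truth(cfg.theta_plus, cfg.theta_minus)
        f_prime, Sigma = gt.f_prime, gt.Sigma_bar
        gt_I = gt.info_true
        d = np.diag(Sigma)
        gt_shuf = float(np.sum(f_prime**2 / d))
        u = f_prime / d
        gt_diag = float((f_prime @ u) ** 2 / (u @ Sigma @ u))
    for name in ("bc", "naive", "decoder", "decoder_training"):
        truths[name] = gt_I
    truths["shuffle"] = truths["decoder_shuffle"] = gt_shuf
    truths["diag"] = truths["decoder_diag"] = gt_diag
    if cfg.population_B is not None:
        gtB = cfg.population_B.ground_truth(cfg.theta_plus, cfg.theta_minus)
        wA = np.linalg.solve(Sigma, f_prime)
        num = float(gtB.f_prime @ wA) ** 2
        den = float(wA @ gtB.Sigma_bar @ wA)
        truths["crossed"] = truths["decoder_crossed"] = num / den
    if cfg.ground_truth_override:
        provenance = "operational"
        truths.update(cfg.ground_truth_override)
    return truths, provenance


def operational_ground_truth(
    pop, theta_plus: float, theta_minus: float, T: int = 100_000, seed=0
) -> float:
    """Ground truth defined operationally as the bias-corrected estimate at
    a very large trial count — used where the analytic moments are
    unreliable (e.g. the Gabor model at low gain, where rectification is
    often active)."""
    data = pop.simulate_pair(theta_plus, theta_minus, T, seed)
    return bc_info(summarize_trials(data), warn_noisy=False).value


@dataclass
class SweepResult:
    """All estimates of a sweep plus aggregates.

    ``estimates[(name, T)]`` is the vector of per-experiment estimates
    (NaN where an estimator refused to run).  Aggregates are exposed via
    :meth:`to_dataframe` with the fixed columns
    (estimator, T, mean, std, mse, rel_err, n).
    """

    estimates: dict[tuple[str, int], np.ndarray]
    ground_truth: dict[str, float]
    provenance: str
    master_seed: int
    n_boot: int = 1000
    config_hash: str = ""

    def _cell(self, name: str, T: int) -> np.ndarray:
        x = self.estimates[(name, T)]
        return x[np.isfinite(x)]

    def mean(self, name: str, T: int) -> float:
        return float(np.mean(self._cell(name, T)))

    def std(self, name: str, T: int) -> float:
        x = self._cell(name, T)
        return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")

    def mse(self, name: str, T: int) -> float:
        x = self._cell(name, T)
        return float(np.mean((x - self.ground_truth[name]) ** 2))

    def mse_decomposed(self, name: str, T: int) -> float:
        """bias^2 + variance (population variance); equals mse exactly."""
        x = self._cell(name, T)
        bias = np.mean(x) - self.ground_truth[name]
        return float(bias**2 + np.var(x))

    def rel_err(self, name: str, T: int) -> float:
        """sqrt(MSE) / ground truth."""
        return float(np.sqrt(self.mse(name, T)) / self.ground_truth[name])

    def band(self, name: str, T: int) -> tuple[float, float, float]:
        return bootstrap_bands(
            self._cell(name, T), n_boot=self.n_boot,
            seed=np.random.SeedSequence(entropy=self.master_seed, spawn_key=(T, 1 << 20)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (name, T), x in self.estimates.items():
            n = int(np.isfinite(x).sum())
            rows.append({
                "estimator": name,
                "T": T,
                "mean": self.mean(name, T) if n else float("nan"),
                "std": self.std(name, T) if n else float("nan"),
                "mse": self.mse(name, T) if n else float("nan"),
                "rel_err": self.rel_err(name, T) if n else float("nan"),
                "n": n,
            })
        return pd.DataFrame(rows, columns=["estimator", "T", "mean", "std", "mse", "rel_err", "n"])


def run_sweep(cfg: ExperimentConfig, verbose: bool = False) -> SweepResult:
    """Run the full sweep: for every T and replicate, simulate one
    experiment and apply every configured estimator to the same data."""
    truths, provenance = _analytic_truths(cfg)
    estimates: dict[tuple[str, int], np.ndarray] = {
        (name, T): np.full(
            cfg.n_rep_decoder if name in DECODER_ESTIMATORS else cfg.n_rep, np.nan
        )
        for name in cfg.estimators
        for T in cfg.T_values
    }
    want_training = "decoder_training" in cfg.estimators
    for T in cfg.T_values:
        n_max = max(
            cfg.n_rep_decoder if name in DECODER_ESTIMATORS else cfg.n_rep
            for name in cfg.estimators
        )
        for rep in range(n_max):
            ss = cfg.replicate_seed(T, rep)
            seeds = ss.spawn(4)
            data = _simulate(cfg.population, cfg.theta_plus, cfg.theta_minus, T,
                             np.random.default_rng(seeds[0]))
            data_B = None
            if cfg.population_B is not None:
                data_B = _simulate(cfg.population_B, cfg.theta_plus, cfg.theta_minus,
                                   T, np.random.default_rng(seeds[1]))
            m = summarize_trials(data)
            for name in cfg.estimators:
                limit = cfg.n_rep_decoder if name in DECODER_ESTIMATORS else cfg.n_rep
                if rep >= limit or name == "decoder_training":
                    continue
                try:
                    if name == "bc":
                        val = bc_info(m, warn_noisy=False).value
                    elif name == "naive":
                        val = naive_info(m).value
                    elif name == "shuffle":
                        val = bc_info_shuffle(m).value
                    elif name == "diag":
                        val = bc_info_diag(data, seed=np.random.default_rng(seeds[2])).value
                    elif name == "crossed":
                        # decoder optimal for this data (A), evaluated on B
                        val = bc_info_crossed(m, summarize_trials(data_B)).value
                    elif name in DECODER_ESTIMATORS:
                        mode = {"decoder": "plain"}.get(name, name.removeprefix("decoder_"))
                        tr, va = decoder_pipeline(
                            data, mode=mode, cfg=cfg.split,
                            seed=np.random.default_rng(seeds[3]),
                            data_B=data_B if mode == "crossed" else None,
                            **cfg.decoder_kwargs,
                        )
                        val = va.value
                        if want_training and mode == "plain" and rep < cfg.n_rep_decoder:
                            estimates[("decoder_training", T)][rep] = tr.value
                    estimates[(name, T)][rep] = val
                except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                    pass  # regime errors recorded as NaN, not fatal
            if verbose and (rep + 1) % 50 == 0:
                print(f"T={T}: {rep + 1}/{n_max} replicates")
    return SweepResult(
        estimates=estimates,
        ground_truth=truths,
        provenance=provenance,
        master_seed=cfg.master_seed,
        n_boot=cfg.n_boot,
        config_hash=cfg.config_hash(),
    )


def bootstrap_bands(
    estimates: np.ndarray,
    n_boot: int = 1000,
    seed=0,
    of: str = "mean",
) -> tuple[float, float, float]:
    """Seeded bootstrap band around the mean of ``estimates``.

    ``of="mean"``: band half-width is the bootstrap std of the mean
    (scales as sd/sqrt(n)); ``of="distribution"``: the bootstrap estimate
    of the std of the estimates themselves (the visual spread).
    Returns (mean, lower, upper).
    """
    x = np.asarray(estimates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 estimates to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    if of == "mean":
        stat = x[idx].mean(axis=1)
        half = float(np.std(stat, ddof=1))
    elif of == "distribution":
        stat = x[idx].std(axis=1, ddof=1)
        half = float(np.mean(stat))
    else:
        raise ValueError("of must be 'mean' or 'distribution'")
    m = float(x.mean())
    return m, m - half, m + half


def subsample_protocol(
    data: TrialSet, T_sub: int, n_rep: int = 100, seed=0
) -> list[TrialSet]:
    """``n_rep`` random per-condition subsamples of ``T_sub`` trials drawn
    without replacement — learning curves from a fixed recorded dataset."""
    if T_sub > data.n_trials:
        raise ValueError(f"T_sub={T_sub} exceeds available T={data.n_trials}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_rep):
        ip = rng.permutation(data.n_trials)[:T_sub]
        im = rng.permutation(data.n_trials)[:T_sub]
        out.append(data.subset(ip, im))
    return out


def report(result: SweepResult, path: str | Path) -> dict[str, Path]:
    """Write a sweep to ``<path>.json`` (full numeric record) and
    ``<path>.csv`` (the 7-column aggregate table)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = result.to_dataframe()
    csv_path = path.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    payload = {
        "version": __version__,
        "config_hash": result.config_hash,
        "master_seed": result.master_seed,
        "provenance": result.provenance,
        "ground_truth": result.ground_truth,
        "estimates": {
            f"{name}@{T}": np.asarray(x).tolist()
            for (name, T), x in result.estimates.items()
        },
        "table": df.to_dict(orient="records"),
    }
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=1))
    return {"json": json_path, "csv": csv_path}


def load_report(path: str | Path) -> dict:
    """Load a JSON report written by :func:`report`."""
    payload = json.loads(Path(path).with_suffix(".json").read_text())
    payload["estimates"] = {
        k: np.asarray(v, dtype=float) for k, v in payload["estimates"].items()
    }
    return payload


def plot_sweep(result: SweepResult, path: str | Path, estimators=None):
    """Optional two-panel figure (estimates with bands; MSE vs T)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.to_dataframe()
    names = estimators or sorted({name for name, _ in result.estimates})
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for name in names:
        sub = df[df.estimator == name].sort_values("T")
        band = np.array([result.band(name, T) for T in sub["T"]])
        ax1.plot(sub["T"], band[:, 0], label=name)
        ax1.fill_between(sub["T"], band[:, 1], band[:, 2], alpha=0.25)
        ax2.loglog(sub["T"], sub["mse"], marker="o", label=name)
    gt = result.ground_truth.get(names[0])
    if gt is not None:
        ax1.axhline(gt, ls="--", c="k", lw=0.8, label="ground truth")
    ax1.set_xlabel("trials per condition")
    ax1.set_ylabel("information")
    ax2.set_xlabel("trials per condition")
    ax2.set_ylabel("MSE")
    ax1.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
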