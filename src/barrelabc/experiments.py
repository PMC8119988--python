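"""Scripted experiment grids: confusion matrices, noise x measurement-fraction
robustness, leave-one-out model exclusion, ER/EXP-LSM interpolation, and the
annotation-budget calculator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abcsmc import ABCConfig, run_abc_smc
from .core import BarrelConfig, Connectome, ReconstructionBudget
from .models import sample_connectome, sample_from_prior
from .perturb import biased_noise, restrict_subvolume, rewire_noise, subsample_neurons
from .priors import MODELS, Prior, default_prior

__all__ = [
    "ConfusionMatrix", "AccuracyGrid", "BudgetEstimate",
    "make_target", "run_confusion", "map_accuracy", "avg_posterior_accuracy",
    "leave_one_out", "interpolation_sweep", "run_grid", "annotation_budget",
]


@dataclass
class ConfusionMatrix:
    """Rows: generating model; columns: mean posterior mass per candidate."""

    models: tuple[str, ...]
    matrix: np.ndarray                      # mean posterior, rows sum to 1
    reps: list[dict] = field(default_factory=list)  # per-target records
    n_reps: int = 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.models),
                            columns=list(self.models))

    def plot(self, ax=None):
        from .plotting import plot_confusion
        return plot_confusion(self, ax=ax)


@dataclass
class AccuracyGrid:
    """Average-posterior and MAP accuracy over a noise x fraction grid."""

    xi_values: tuple[float, ...]
    f_m_values: tuple[float, ...]
    avg_accuracy: np.ndarray        # shape (len(xi), len(f_m))
    map_accuracy: np.ndarray
    config_snapshot: dict = field(default_factory=dict)

    def to_dataframe(self, which: str = "avg") -> pd.DataFrame:
        mat = self.avg_accuracy if which == "avg" else self.map_accuracy
        return pd.DataFrame(mat, index=list(self.xi_values),
                            columns=list(self.f_m_values))


@dataclass(frozen=True)
class BudgetEstimate:
    hours: float
    n_connected_pairs: float
    n_synapses: float


def _cell_seed(root_seed: int, *parts) -> int:
    """Reproducible independent seed per experiment cell (< 2**31).

    Uses a CRC of the stringified cell coordinates (process-stable, unlike
    the built-in string hash)."""
    import zlib
    ss = np.random.SeedSequence(
        [root_seed & 0x7FFFFFFF]
        + [zlib.crc32(str(p).encode()) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_target(model: str, config: BarrelConfig, prior: Prior, seed: int, *,
                xi: float = 0.0, noise_mode: str = "rewire",
                f_m: float = 1.0, params: dict | None = None,
                subvolume_side: float | None = None,
                p_keep: float = 1.0) -> Connectome:
    """Generate a corrupted target connectome: prior parameter draw (unless
    given), measurement noise, then fractional subsampling or subvolume
    restriction."""
    rng = np.random.default_rng(seed)
    if params is None:
        _, params, conn = sample_from_prior(prior, config, rng, model=model)
    else:
        conn = sample_connectome(model, params, config, rng)
    if xi > 0.0:
        if noise_mode == "rewire":
            conn = rewire_noise(conn, xi, rng)
        else:
            conn = biased_noise(conn, xi, noise_mode, rng)
    if subvolume_side is not None:
        conn = restrict_subvolume(conn, subvolume_side, p_keep, rng)
    elif f_m < 1.0:
        conn = subsample_neurons(conn, f_m, rng)
    return conn


def run_confusion(models=MODELS, config: BarrelConfig | None = None,
                  abc_config: ABCConfig | None = None,
                  prior: Prior | None = None, n_reps: int = 1,
                  seed: int = 0, xi_target: float = 0.0,
                  noise_mode: str = "rewire",
                  f_m_target: float | None = None) -> ConfusionMatrix:
    """Confusion matrix: for each generating model, sample targets from the
    prior, corrupt them, run ABC-SMC over all candidate models, and average
    the posteriors per row.

    The measurement fraction of the targets defaults to the ABC config's
    f_m so that inference is matched to the measurement protocol.
    """
    config = config if config is not None else BarrelConfig()
    abc_config = abc_config if abc_config is not None else ABCConfig()
    prior = (prior if prior is not None
             else default_prior(models))
    prior = prior.restricted(models)
    f_m = abc_config.f_m if f_m_target is None else f_m_target
    mat = np.zeros((len(models), len(models)))
    reps: list[dict] = []
    for i, true_model in enumerate(models):
        for rep in range(n_reps):
            s = _cell_seed(seed, true_model, xi_target, f_m, rep)
            target = make_target(true_model, config, prior, s, xi=xi_target,
                                 noise_mode=noise_mode, f_m=f_m)
            res = run_abc_smc(target, prior, config, abc_config, seed=s)
            post = np.array([res.model_posterior.get(m, 0.0)
                             for m in models])
            mat[i] += post
            reps.append({"true_model": true_model, "rep": rep, "seed": s,
                         "posterior": dict(zip(models, post.tolist())),
                         "map": models[int(post.argmax())],
                         "termination": res.termination})
    mat /= n_reps
    return ConfusionMatrix(tuple(models), mat, reps, n_reps)


def avg_posterior_accuracy(cm: ConfusionMatrix) -> float:
    """Mean posterior mass on the generating model (mean of the diagonal)."""
    return float(np.mean(np.diag(cm.matrix)))


def map_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of individual targets whose maximum-a-posteriori model is the
    generating model."""
    if cm.reps:
        hits = [r["map"] == r["true_model"] for r in cm.reps]
        return float(np.mean(hits))
    return float(np.mean(np.argmax(cm.matrix, axis=1)
                         == np.arange(len(cm.models))))


def leave_one_out(true_model: str, config: BarrelConfig | None = None,
                  abc_config: ABCConfig | None = None,
                  prior: Prior | None = None, seed: int = 0,
                  models=MODELS) -> dict[str, float]:
    """Posterior over the remaining models when the generating model is
    excluded from the hypothesis set."""
    config = config if config is not None else BarrelConfig()
    abc_config = abc_config if abc_config is not None else ABCConfig()
    prior = prior if prior is not None else default_prior(models)
    remaining = tuple(m for m in models if m != true_model)
    if len(remaining) < 2:
        raise ValueError("need at least two remaining models")
    s = _cell_seed(seed, "loo", true_model)
    target = make_target(true_model, config, default_prior(models), s,
                         f_m=abc_config.f_m)
    res = run_abc_smc(target, prior.restricted(remaining), config,
                      abc_config, seed=s)
    return {m: res.model_posterior.get(m, 0.0) for m in remaining}


def interpolation_sweep(d_exp_values, config: BarrelConfig | None = None,
                        abc_config: ABCConfig | None = None,
                        prior: Prior | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Posteriors for targets interpolated between the pairwise-random and
    the distance-dependent model (d_exp in [0, 1]); rows indexed by d_exp."""
    config = config if config is not None else BarrelConfig()
    abc_config = abc_config if abc_config is not None else ABCConfig()
    prior = prior if prior is not None else default_prior()
    rows = {}
    for d_exp in d_exp_values:
        if not 0.0 <= d_exp <= 1.0:
            raise ValueError("d_exp must lie in [0, 1]")
        s = _cell_seed(seed, "interp", round(float(d_exp), 6))
        target = make_target("EXP_LSM", config, prior, s,
                             params={"d_exp": float(d_exp)},
                             f_m=abc_config.f_m)
        res = run_abc_smc(target, prior, config, abc_config, seed=s)
        rows[float(d_exp)] = res.model_posterior
    return pd.DataFrame.from_dict(rows, orient="index")[list(prior.models)]


def run_grid(xi_values, f_m_values, models=MODELS,
             config: BarrelConfig | None = None,
             abc_config: ABCConfig | None = None,
             prior: Prior | None = None, n_reps: int = 1,
             seed: int = 0) -> AccuracyGrid:
    """Noise x measurement-fraction accuracy grid (one confusion per cell)."""
    abc_config = abc_config if abc_config is not None else ABCConfig()
    avg = np.zeros((len(xi_values), len(f_m_values)))
    mapacc = np.zeros_like(avg)
    for a, xi in enumerate(xi_values):
        for b, f_m in enumerate(f_m_values):
            from dataclasses import replace
            cfg_cell = replace(abc_config, f_m=float(f_m))
            cm = run_confusion(models, config, cfg_cell, prior, n_reps,
                               seed=_cell_seed(seed, "grid", xi, f_m),
                               xi_target=float(xi))
            avg[a, b] = avg_posterior_accuracy(cm)
            mapacc[a, b] = map_accuracy(cm)
    return AccuracyGrid(tuple(float(x) for x in xi_values),
                        tuple(float(f) for f in f_m_values), avg, mapacc,
                        {"models": list(models), "n_reps": n_reps,
                         "seed": seed})


def annotation_budget(budget: ReconstructionBudget,
                      config: BarrelConfig | None = None) -> BudgetEstimate:
    """Annotation time and synapse count of a (fractional) reconstruction.

    T = V * d / v, scaled by the measured neuron fraction f_m (reconstructing
    a fraction of the neurons traces the same fraction of the path length);
    the connected-pair count is N = n (n_e p_e + n_i p_i) and the synapse
    count N * f.
    """
    config = config if config is not None else BarrelConfig()
    path_mm = budget.volume_mm3 * budget.path_density * 1e6  # km -> mm
    hours = path_mm / budget.speed_mm_h * budget.measured_fraction
    n_pairs = config.n * (config.n_e * config.p_e + config.n_i * config.p_i)
    return BudgetEstimate(hours=hours, n_connected_pairs=n_pairs,
                          n_synapses=n_pairs * budget.synapses_per_connection)
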