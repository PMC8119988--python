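"""Approximate Bayesian Computation with Sequential Monte Carlo over the
candidate circuit models.

Given a measured (or simulated) connectome, particles (model, parameters,
noise level) are drawn from the joint prior, each particle simulates a
connectome through the full measurement pipeline (generate, rewire by xi,
subsample to f_m), and is accepted if the normalized L1 distance between its
six summary statistics and the target's is below the acceptance threshold
epsilon.  Across generations particles are resampled and perturbed with a
Gaussian kernel while epsilon shrinks to the (weighted) median of the
previous generation's distances.

The user-facing entry point is :class:`ConnectomeModelSelection`, a model
object built from the target connectome whose ``fit`` returns a
:class:`ModelSelectionResults` carrying the posterior over models, the
parameter particle clouds, and diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BarrelConfig, Connectome
from .models import SimulationError, sample_connectome
from .perturb import rewire_noise, subsample_neurons
from .priors import MODELS, Distribution, PointMass, Prior, default_prior
from .stats import DistanceNorms, SummaryStats, calibrate_norms, distance, summarize

__all__ = [
    "ABCConfig", "Particle", "Population", "PosteriorResult",
    "simulate_for_target", "initialize_population", "propose_particle",
    "update_epsilon", "run_abc_smc", "posterior_over_models",
    "ConnectomeModelSelection", "ModelSelectionResults",
]


@dataclass(frozen=True)
class ABCConfig:
    """ABC-SMC settings.

    The defaults are the full "replication" profile (2000 particles, 8
    generations, candidate networks of 2000 neurons); :meth:`reduced` is the
    desk-scale profile used throughout the test suite (500-neuron candidate
    networks with the expensive FEVER / STDP-SORN simulations internally
    scaled down further).
    """

    n_particles: int = 2000
    max_generations: int = 8
    epsilon_min: float = 0.175
    min_accepted: int = 1000
    model_keep_prob: float = 0.85
    attempt_cap: int = 2000
    kernel_factor: float = 2.0
    kernel_fallback_frac: float = 0.05
    noise_prior: Distribution = PointMass(0.0)
    f_m: float = 1.0
    weighting: str = "smc"            # or "uniform"
    sim_n: int = 2000
    sim_n_overrides: dict = field(default_factory=dict)
    sorn_tau_end: int = 10_000

    @classmethod
    def reduced(cls, **kwargs) -> "ABCConfig":
        base = dict(
            n_particles=200, max_generations=3, min_accepted=100,
            sim_n=500, sim_n_overrides={"FEVER": 150, "STDP_SORN": 200},
            sorn_tau_end=1000,
        )
        base.update(kwargs)
        return cls(**base)

    @classmethod
    def replication(cls, **kwargs) -> "ABCConfig":
        return cls(**kwargs)


@dataclass
class Particle:
    """One unit of ABC evidence: a model draw with parameters, latent noise
    level, the summary statistics of its simulated connectome, its distance
    to the target, and its importance weight."""

    model: str
    params: dict
    xi: float
    stats: SummaryStats | None
    dist: float
    weight: float = 0.0


@dataclass
class Population:
    """One SMC generation: accepted particles and acceptance threshold."""

    generation: int
    epsilon: float
    particles: list[Particle]

    def model_masses(self) -> dict[str, float]:
        masses: dict[str, float] = {}
        for p in self.particles:
            masses[p.model] = masses.get(p.model, 0.0) + p.weight
        total = sum(masses.values())
        return {m: v / total for m, v in masses.items()}

    def by_model(self) -> dict[str, list[Particle]]:
        out: dict[str, list[Particle]] = {}
        for p in self.particles:
            out.setdefault(p.model, []).append(p)
        return out

    def normalize_weights(self) -> None:
        total = sum(p.weight for p in self.particles)
        if total <= 0:
            raise RuntimeError("non-positive total particle weight")
        for p in self.particles:
            p.weight /= total


@dataclass
class PosteriorResult:
    """Outcome of an ABC-SMC run."""

    model_posterior: dict[str, float]
    final_population: Population
    epsilon_trajectory: list[float]
    n_generations: int
    termination: str
    models: tuple[str, ...]

    @property
    def map_model(self) -> str:
        return max(self.model_posterior, key=self.model_posterior.get)

    def param_cloud(self, model: str) -> pd.DataFrame:
        rows = [dict(p.params, xi=p.xi, weight=p.weight, dist=p.dist)
                for p in self.final_population.particles if p.model == model]
        return pd.DataFrame(rows)


def _task_rng(seed: int, generation: int, task: int) -> np.random.Generator:
    # deterministic per (root seed, generation, task index)
    return np.random.default_rng([seed, generation, task])


def simulate_for_target(model: str, params: dict, xi: float,
                        config: BarrelConfig, abc_config: ABCConfig,
                        rng: np.random.Generator) -> SummaryStats | None:
    """Run the full generative measurement pipeline for one particle:
    generate the connectome, apply rewiring noise xi, subsample to the
    measured fraction f_m, summarize.  Returns None when the simulation
    fails or any statistic is undefined (the particle is then discarded)."""
    size = abc_config.sim_n_overrides.get(model, abc_config.sim_n)
    cfg = config.scaled(size) if size != config.n else config
    eff = dict(params)
    if model == "STDP_SORN":
        eff.setdefault("tau_end", abc_config.sorn_tau_end)
    try:
        conn = sample_connectome(model, eff, cfg, rng)
        if xi > 0.0:
            conn = rewire_noise(conn, xi, rng)
        if abc_config.f_m < 1.0:
            conn = subsample_neurons(conn, abc_config.f_m, rng)
    except (SimulationError, ValueError):
        return None
    stats = summarize(conn)
    return stats if stats.defined else None


def initialize_population(target_stats: SummaryStats, prior: Prior,
                          config: BarrelConfig, abc_config: ABCConfig,
                          seed: int) -> tuple[Population, DistanceNorms]:
    """Generation 0: draw n_particles from the joint prior, calibrate the
    distance normalization on the defined draws, set epsilon to the median
    distance to the target, and accept the below-median half with uniform
    weights."""
    drawn: list[tuple[str, dict, float, SummaryStats]] = []
    for i in range(abc_config.n_particles):
        rng = _task_rng(seed, 0, i)
        model = prior.sample_model(rng)
        params = prior.sample_params(model, rng)
        xi = abc_config.noise_prior.sample(rng)
        stats = simulate_for_target(model, params, xi, config, abc_config,
                                    rng)
        if stats is not None:
            drawn.append((model, params, xi, stats))
    if not drawn:
        raise RuntimeError("all prior draws produced undefined statistics")
    norms = calibrate_norms([s for *_, s in drawn])
    dists = np.array([distance(target_stats, s, norms) for *_, s in drawn])
    epsilon = float(np.median(dists))
    particles = [Particle(m, p, xi, s, float(d), 1.0)
                 for (m, p, xi, s), d in zip(drawn, dists) if d < epsilon]
    if not particles:
        raise RuntimeError("no particle below the initial epsilon")
    pop = Population(0, epsilon, particles)
    pop.normalize_weights()
    return pop, norms


def update_epsilon(population: Population) -> float:
    """Weighted median of the accepted particles' distances (the next
    generation's acceptance threshold)."""
    dists = np.array([p.dist for p in population.particles])
    weights = np.array([p.weight for p in population.particles])
    order = np.argsort(dists)
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(dists[order][min(idx, len(dists) - 1)])


class _GenerationKernel:
    """Per-generation proposal machinery: model proposal probabilities,
    per-model resampling weights and Gaussian kernel widths."""

    def __init__(self, population: Population, prior: Prior,
                 abc_config: ABCConfig):
        self.prior = prior
        self.cfg = abc_config
        self.masses = population.model_masses()
        self.models = prior.models
        self.noise_free = isinstance(abc_config.noise_prior, PointMass)
        self.per_model: dict[str, dict] = {}
        for model, parts in population.by_model().items():
            names = prior.free_params(model)
            coords = names + ([] if self.noise_free else ["xi"])
            vals = np.array(
                [[p.params[c] if c != "xi" else p.xi for c in coords]
                 for p in parts], dtype=float)
            w = np.array([p.weight for p in parts], dtype=float)
            w = w / w.sum()
            stds = []
            for j, c in enumerate(coords):
                mean = float(np.sum(w * vals[:, j]))
                var = float(np.sum(w * (vals[:, j] - mean) ** 2))
                if var > 0:
                    stds.append(math.sqrt(abc_config.kernel_factor * var))
                else:
                    span = (abc_config.noise_prior.span if c == "xi"
                            else prior.params[model][c].span)
                    stds.append(max(abc_config.kernel_fallback_frac * span,
                                    1e-12))
            self.per_model[model] = {
                "particles": parts, "weights": w, "values": vals,
                "coords": coords, "stds": np.array(stds),
            }

    def model_proposal_prob(self, model: str) -> float:
        keep = self.cfg.model_keep_prob
        return (keep * self.masses.get(model, 0.0)
                + (1.0 - keep) / len(self.models))

    def draw_model(self, rng: np.random.Generator) -> str:
        models = list(self.masses)
        probs = np.array([self.masses[m] for m in models])
        m = models[int(rng.choice(len(models), p=probs))]
        if rng.random() >= self.cfg.model_keep_prob:
            m = self.models[int(rng.integers(len(self.models)))]
        return m

    def perturb(self, model: str, rng: np.random.Generator):
        info = self.per_model[model]
        j = int(rng.choice(len(info["weights"]), p=info["weights"]))
        src = info["values"][j]
        out_params: dict = dict(info["particles"][j].params)
        xi = info["particles"][j].xi
        for k, c in enumerate(info["coords"]):
            val = src[k] + rng.normal(0.0, info["stds"][k])
            if c == "xi":
                xi = float(val)
            else:
                dist_c = self.prior.params[model][c]
                if dist_c.discrete:
                    val = float(round(val))
                out_params[c] = (int(val) if dist_c.discrete else float(val))
        # fill point-mass parameters untouched (copied from source particle)
        if not self.prior.in_support(model, out_params):
            return None
        if not self.noise_free and self.cfg.noise_prior.pdf(xi) <= 0.0:
            return None
        if self.noise_free:
            xi = self.cfg.noise_prior.sample(rng)
        return out_params, xi

    def smc_weight(self, model: str, params: dict, xi: float) -> float:
        num = (self.prior.model_probability(model)
               * self.prior.param_density(model, params))
        if not self.noise_free:
            num *= self.cfg.noise_prior.pdf(xi)
        info = self.per_model[model]
        coords = info["coords"]
        x = np.array([params[c] if c != "xi" else xi for c in coords],
                     dtype=float)
        if len(coords) == 0:
            kern = 1.0
        else:
            z = (x[np.newaxis, :] - info["values"]) / info["stds"]
            dens = np.exp(-0.5 * np.sum(z ** 2, axis=1)) / np.prod(
                info["stds"] * math.sqrt(2.0 * math.pi))
            kern = float(np.sum(info["weights"] * dens))
        den = self.model_proposal_prob(model) * max(kern, 1e-300)
        return num / den


def propose_particle(kernel: _GenerationKernel, target_stats: SummaryStats,
                     norms: DistanceNorms, epsilon: float,
                     config: BarrelConfig, abc_config: ABCConfig,
                     rng: np.random.Generator) -> Particle | None:
    """One proposal task: up to attempt_cap perturb-simulate-accept attempts;
    returns the first accepted particle or None (give-up)."""
    for _ in range(abc_config.attempt_cap):
        model = kernel.draw_model(rng)
        guard = 0
        while model not in kernel.per_model:
            model = kernel.draw_model(rng)
            guard += 1
            if guard > 1000:  # pragma: no cover
                return None
        prop = kernel.perturb(model, rng)
        if prop is None:
            continue
        params, xi = prop
        stats = simulate_for_target(model, params, xi, config, abc_config,
                                    rng)
        if stats is None:
            continue
        d = distance(target_stats, stats, norms)
        if d < epsilon:
            w = (kernel.smc_weight(model, params, xi)
                 if abc_config.weighting == "smc" else 1.0)
            return Particle(model, params, xi, stats, float(d), w)
    return None


def posterior_over_models(population: Population) -> dict[str, float]:
    return population.model_masses()


def run_abc_smc(target: Connectome | SummaryStats, prior: Prior | None = None,
                config: BarrelConfig | None = None,
                abc_config: ABCConfig | None = None,
                seed: int = 0) -> PosteriorResult:
    """Full ABC-SMC loop.

    Terminates when a single model holds all posterior mass, the maximum
    number of generations is reached, epsilon has shrunk to epsilon_min, or
    a generation yields fewer than min_accepted particles.
    """
    prior = prior if prior is not None else default_prior()
    config = config if config is not None else BarrelConfig()
    abc_config = abc_config if abc_config is not None else ABCConfig()
    if isinstance(target, Connectome):
        target_stats = summarize(target)
    else:
        target_stats = target
    if not target_stats.defined:
        raise ValueError("target connectome has undefined summary statistics")

    pop, norms = initialize_population(target_stats, prior, config,
                                       abc_config, seed)
    eps_traj = [pop.epsilon]
    termination = "max_generations"
    for gen in range(1, abc_config.max_generations + 1):
        masses = pop.model_masses()
        if max(masses.values()) >= 1.0 and len(masses) == 1:
            termination = "single_model"
            break
        epsilon = min(update_epsilon(pop), pop.epsilon)
        if epsilon <= abc_config.epsilon_min:
            termination = "epsilon_min"
            break
        kernel = _GenerationKernel(pop, prior, abc_config)
        accepted: list[Particle] = []
        for task in range(abc_config.n_particles):
            rng = _task_rng(seed, gen, task)
            p = propose_particle(kernel, target_stats, norms, epsilon,
                                 config, abc_config, rng)
            if p is not None:
                accepted.append(p)
        if len(accepted) < abc_config.min_accepted:
            termination = "too_few_accepted"
            break
        pop = Population(gen, epsilon, accepted)
        pop.normalize_weights()
        eps_traj.append(epsilon)
    return PosteriorResult(
        model_posterior={m: pop.model_masses().get(m, 0.0)
                         for m in prior.models},
        final_population=pop,
        epsilon_trajectory=eps_traj,
        n_generations=pop.generation,
        termination=termination,
        models=prior.models,
    )


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class ConnectomeModelSelection:
    """Bayesian model selection for a measured connectome.

    Parameters
    ----------
    target : Connectome
        The measured (or simulated) connectome to explain.
    prior : Prior, optional
        Joint prior over models and parameters (default: all seven models
        with their default priors).
    config : BarrelConfig, optional
        Circuit constraints shared by the candidate generators.
    abc_config : ABCConfig, optional
        SMC settings; defaults to the full replication profile.

    Examples
    --------
    >>> from barrelabc import (BarrelConfig, ABCConfig,
    ...                        ConnectomeModelSelection, sample_er_esn)
    >>> cfg = BarrelConfig().scaled(500)
    >>> target = sample_er_esn(cfg, seed=7)
    >>> sel = ConnectomeModelSelection(target, config=cfg,
    ...                                abc_config=ABCConfig.reduced())
    >>> res = sel.fit(seed=1)          # doctest: +SKIP
    >>> res.map_model                  # doctest: +SKIP
    'ER_ESN'
    """

    def __init__(self, target: Connectome, prior: Prior | None = None,
                 config: BarrelConfig | None = None,
                 abc_config: ABCConfig | None = None):
        self.target = target
        self.prior = prior if prior is not None else default_prior()
        self.config = config if config is not None else BarrelConfig()
        self.abc_config = (abc_config if abc_config is not None
                           else ABCConfig())
        self.target_stats = summarize(target)

    def fit(self, seed: int = 0) -> "ModelSelectionResults":
        result = run_abc_smc(self.target_stats, self.prior, self.config,
                             self.abc_config, seed=seed)
        return ModelSelectionResults(self, result)


class ModelSelectionResults:
    """Posterior over circuit models with parameter clouds and diagnostics."""

    def __init__(self, model: ConnectomeModelSelection,
                 result: PosteriorResult):
        self.model = model
        self.result = result

    @property
    def posterior(self) -> dict[str, float]:
        return dict(self.result.model_posterior)

    @property
    def posterior_series(self) -> pd.Series:
        return pd.Series(self.result.model_posterior, name="posterior")

    @property
    def map_model(self) -> str:
        return self.result.map_model

    @property
    def epsilon_trajectory(self) -> list[float]:
        return list(self.result.epsilon_trajectory)

    @property
    def termination(self) -> str:
        return self.result.termination

    def param_cloud(self, model: str) -> pd.DataFrame:
        return self.result.param_cloud(model)

    def summary(self) -> str:
        lines = [
            "Connectome model selection (ABC-SMC)",
            "=" * 44,
            f"target: n={self.model.target.n} "
            f"(e={self.model.target.n_e}, i={self.model.target.n_i}), "
            f"edges={self.model.target.n_edges}",
            f"generations: {self.result.n_generations}   "
            f"termination: {self.result.termination}",
            "epsilon: " + " -> ".join(
                f"{e:.3f}" for e in self.result.epsilon_trajectory),
            "-" * 44,
            f"{'model':<12}{'posterior':>12}",
        ]
        for m, v in sorted(self.result.model_posterior.items(),
                           key=lambda kv: -kv[1]):
            lines.append(f"{m:<12}{v:>12.4f}")
        lines.append("-" * 44)
        lines.append(f"MAP model: {self.result.map_model}")
        return "\n".join(lines)

    def plot_posterior(self, ax=None):
        from .plotting import plot_posterior
        return plot_posterior(self.result, ax=ax)

    def plot_epsilon(self, ax=None):
        from .plotting import plot_epsilon
        return plot_epsilon(self.result, ax=ax)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<ModelSelectionResults MAP={self.map_model} "
                f"termination={self.termination}>")
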