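"""Parameter priors for the candidate circuit models.

Each model has a dictionary of named parameter distributions; the model
itself is drawn from a flat categorical distribution.  Scale-dependent
parameters (pool size ``s_pool``, feature dimension ``d_f``) are specified at
the full barrel scale (1800 excitatory + 200 inhibitory neurons) and rescaled
inside the samplers when networks are generated at reduced size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "Uniform", "DiscreteUniform", "LogUniform", "BetaDist", "PointMass",
    "Prior", "default_prior", "MODELS",
]

MODELS = ("ER_ESN", "EXP_LSM", "LAYERED", "SYNFIRE", "FEVER", "API",
          "STDP_SORN")


class Distribution:
    discrete = False

    def sample(self, rng: np.random.Generator):  # pragma: no cover
        raise NotImplementedError

    def pdf(self, x) -> float:  # pragma: no cover
        raise NotImplementedError

    def in_support(self, x) -> bool:
        return self.pdf(x) > 0

    @property
    def span(self) -> float:
        """Width of the support; used for zero-variance kernel fallbacks."""
        raise NotImplementedError


@dataclass(frozen=True)
class Uniform(Distribution):
    low: float
    high: float

    def sample(self, rng):
        return float(rng.uniform(self.low, self.high))

    def pdf(self, x):
        return 1.0 / (self.high - self.low) if self.low <= x <= self.high else 0.0

    @property
    def span(self):
        return self.high - self.low


@dataclass(frozen=True)
class DiscreteUniform(Distribution):
    """Uniform over the integers low..high inclusive."""

    low: int
    high: int
    discrete = True

    def sample(self, rng):
        return int(rng.integers(self.low, self.high + 1))

    def pdf(self, x):
        if float(x).is_integer() and self.low <= x <= self.high:
            return 1.0 / (self.high - self.low + 1)
        return 0.0

    @property
    def span(self):
        return float(self.high - self.low)


@dataclass(frozen=True)
class LogUniform(Distribution):
    low: float
    high: float

    def sample(self, rng):
        return float(np.exp(rng.uniform(math.log(self.low),
                                        math.log(self.high))))

    def pdf(self, x):
        if self.low <= x <= self.high:
            return 1.0 / (x * (math.log(self.high) - math.log(self.low)))
        return 0.0

    @property
    def span(self):
        return self.high - self.low


@dataclass(frozen=True)
class BetaDist(Distribution):
    a: float
    b: float

    def sample(self, rng):
        return float(rng.beta(self.a, self.b))

    def pdf(self, x):
        if 0.0 <= x <= 1.0:
            return float(sps.beta.pdf(x, self.a, self.b))
        return 0.0

    @property
    def span(self):
        return 1.0


@dataclass(frozen=True)
class PointMass(Distribution):
    value: float

    def sample(self, rng):
        return self.value

    def pdf(self, x):
        return 1.0 if x == self.value else 0.0

    @property
    def span(self):
        return 0.0


@dataclass
class Prior:
    """Joint prior: flat over models, independent per-parameter distributions.

    ``params[model]`` maps parameter name -> Distribution.  Only free
    (non-point-mass) parameters are perturbed by the SMC kernel.
    """

    params: dict[str, dict[str, Distribution]] = field(default_factory=dict)

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(self.params.keys())

    def restricted(self, models) -> "Prior":
        missing = set(models) - set(self.params)
        if missing:
            raise KeyError(f"models not in prior: {sorted(missing)}")
        return Prior({m: self.params[m] for m in models})

    def sample_model(self, rng: np.random.Generator) -> str:
        return self.models[int(rng.integers(len(self.models)))]

    def sample_params(self, model: str, rng: np.random.Generator) -> dict:
        return {name: dist.sample(rng)
                for name, dist in self.params[model].items()}

    def model_probability(self, model: str) -> float:
        return 1.0 / len(self.models)

    def param_density(self, model: str, values: dict) -> float:
        dens = 1.0
        for name, dist in self.params[model].items():
            dens *= dist.pdf(values[name])
        return dens

    def in_support(self, model: str, values: dict) -> bool:
        return all(dist.in_support(values[name])
                   for name, dist in self.params[model].items())

    def free_params(self, model: str) -> list[str]:
        return [name for name, dist in self.params[model].items()
                if not isinstance(dist, PointMass)]


def default_prior(models=MODELS) -> Prior:
    """Default priors over model parameters.

    LAYERED and API ranges are the ones quoted in the source constraints
    (n_l in {2,3,4}, p_e,f in [0.19, 0.57], p_e,l in [0.26, 0.43],
    n_pow in [4, 6]).  The remaining supports are package defaults chosen to
    keep every model inside the barrel connectivity/reciprocity constraints;
    replace them here if better-constrained supports are available.
    ``s_pool`` and ``d_f`` are expressed at the full scale of 1800 excitatory
    neurons / 2000 neurons and rescaled when sampling smaller networks.
    """
    table: dict[str, dict[str, Distribution]] = {
        "ER_ESN": {},
        "EXP_LSM": {"d_exp": PointMass(1.0)},
        "LAYERED": {
            "n_l": DiscreteUniform(2, 4),
            "p_e_f": Uniform(0.19, 0.57),
            "p_e_l": Uniform(0.26, 0.43),
        },
        "SYNFIRE": {"s_pool": DiscreteUniform(80, 300)},
        "FEVER": {
            "f_r": Uniform(0.0, 1.0),
            "d_f": DiscreteUniform(50, 400),
        },
        "API": {
            "n_pow": Uniform(4.0, 6.0),
            "d_f": DiscreteUniform(50, 400),
        },
        "STDP_SORN": {
            "eta_stdp": LogUniform(1e-3, 1e-1),
            "eta_i": LogUniform(1e-3, 1e-1),
        },
    }
    return Prior({m: table[m] for m in models})
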