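"""Generative models of barrel circuit connectivity.

Seven candidate models are implemented, all constrained to the same pairwise
connectivities (excitatory p_e = 0.2, inhibitory p_i = 0.6 by default):

ER_ESN     directed Erdos-Renyi random graph (echo state network).
EXP_LSM    soma positions uniform in the barrel cube; connection probability
           decays exponentially with inter-soma distance (liquid state
           machine); the decay constants are calibrated so the overall
           connectivities match the targets.
LAYERED    excitatory neurons partitioned into layers with lateral
           (within-layer) and forward (next-layer) random connectivity;
           inhibitory neurons unstructured.
SYNFIRE    embedded synfire chain: a chain of uniformly drawn excitatory
           pools connected all-to-all pool-to-pool; pools may overlap, which
           is what produces reciprocal connections.
FEVER      feature-vector recombination: each neuron carries a unit feature
           vector; outgoing weights are re-optimised from a pre-drawn random
           graph so that the neuron's feature is reconstructed by its
           targets' features (L1-anchored positive lasso).
API        antiphase inhibition: connection probabilities derived from the
           cosine similarity of feature vectors (excitatory neurons prefer
           similar, inhibitory neurons dissimilar partners).
STDP_SORN  self-organising recurrent network: a random graph shaped by
           10,000 steps of threshold-unit dynamics with STDP, intrinsic,
           and structural plasticity.

Scale-dependent parameters (``s_pool``, ``d_f``) are specified at the full
barrel scale (1800 excitatory / 2000 total neurons) and rescaled
proportionally by :func:`sample_connectome` when a smaller network is drawn.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .core import BarrelConfig, Connectome
from .priors import Prior

__all__ = [
    "SimulationError", "FitError",
    "sample_er_esn", "sample_exp_lsm", "sample_layered", "sample_synfire",
    "sample_fever", "sample_api", "sample_stdp_sorn",
    "sample_connectome", "sample_from_prior", "calibrate_decay",
    "synfire_n_iterations", "expected_layered_stats", "expected_synfire_stats",
    "check_barrel_constraints", "max_feasible_layers",
]

FULL_N = 2000
FULL_NE = 1800


class SimulationError(RuntimeError):
    """A generator could not produce a valid connectome."""


class FitError(SimulationError):
    """A connectivity-matching fit failed to reach its target."""


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _types(config: BarrelConfig) -> np.ndarray:
    return np.concatenate([np.ones(config.n_e, dtype=np.int8),
                           -np.ones(config.n_i, dtype=np.int8)])


def _finalize(support: np.ndarray, config: BarrelConfig, positions=None,
              provenance=None) -> Connectome:
    """Boolean support [post, pre] -> signed binary Connectome."""
    np.fill_diagonal(support, False)
    types = _types(config)
    signed = support.astype(np.int8) * types[np.newaxis, :]
    prov = dict(provenance or {})
    prov.setdefault("barrel_side", config.barrel_side)
    return Connectome(sp.csr_matrix(signed), types, positions, binary=True,
                      provenance=prov)


def _per_column_probability(config: BarrelConfig) -> np.ndarray:
    p = np.empty(config.n)
    p[:config.n_e] = config.p_e
    p[config.n_e:] = config.p_i
    return p


# ---------------------------------------------------------------------------
# ER-ESN
# ---------------------------------------------------------------------------

def sample_er_esn(config: BarrelConfig, seed) -> Connectome:
    """Directed Erdos-Renyi graph: every excitatory projection realised with
    probability p_e, every inhibitory projection with p_i."""
    rng = _rng(seed)
    p = _per_column_probability(config)
    support = rng.random((config.n, config.n)) < p[np.newaxis, :]
    return _finalize(support, config,
                     provenance={"model": "ER_ESN", "params": {},
                                 "seed": _seed_repr(seed)})


def _seed_repr(seed):
    return None if isinstance(seed, np.random.Generator) else int(seed)


# ---------------------------------------------------------------------------
# EXP-LSM
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _unit_cube_distance_quadrature(n_nodes: int = 48):
    """Quadrature nodes/weights of the distance between two uniform points in
    the unit cube: each coordinate difference has triangular density
    2(1 - u) on [0, 1], independent across the three coordinates."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (x + 1.0)          # map to [0, 1]
    wu = 0.5 * w * 2.0 * (1.0 - u)
    dx, dy, dz = np.meshgrid(u, u, u, indexing="ij")
    ww = (wu[:, None, None] * wu[None, :, None] * wu[None, None, :]).ravel()
    d = np.sqrt(dx**2 + dy**2 + dz**2).ravel()
    return d, ww


@lru_cache(maxsize=None)
def calibrate_decay(p_target: float, p_0: float, side: float,
                    tol: float = 1e-4) -> float:
    """Decay constant lambda such that the expected connection probability
    E[p_0 exp(-d / lambda)] over the inter-soma distance distribution of two
    uniform points in the cube of the given side equals ``p_target``.

    Returns ``math.inf`` when the target equals p_0 (distance-independent
    limit).  Raises :class:`FitError` for unreachable targets.
    """
    if not 0.0 < p_target <= p_0:
        raise FitError(
            f"target connectivity {p_target} unreachable from p_0={p_0}")
    if p_target == p_0:
        return math.inf
    d, w = _unit_cube_distance_quadrature()

    def expected(u: float) -> float:  # u = side / lambda
        return p_0 * float(np.sum(w * np.exp(-d * u)))

    from scipy.optimize import brentq
    lo, hi = 1e-9, 1.0
    while expected(hi) > p_target:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover
            raise FitError("decay calibration failed to bracket")
    u = brentq(lambda v: expected(v) - p_target, lo, hi, xtol=1e-12,
               rtol=1e-12)
    assert abs(expected(u) - p_target) < tol
    return side / u


def sample_exp_lsm(config: BarrelConfig, d_exp: float, seed, *,
                   lambdas: tuple[float, float] | None = None,
                   calibrate: bool = True) -> Connectome:
    """Distance-dependent random graph p_t(d) = p_0 exp(-d / lambda_t) with
    p_0 = p_t + (1 - p_t) d_exp; soma positions uniform in the barrel cube.

    ``d_exp`` interpolates between the pairwise-random limit (0) and the
    fully distance-dependent model (1).
    """
    rng = _rng(seed)
    L = config.barrel_side
    p0_e = config.p_e + (1.0 - config.p_e) * d_exp
    p0_i = config.p_i + (1.0 - config.p_i) * d_exp
    if lambdas is None:
        if not calibrate:
            raise ValueError("decay constants not given and calibration "
                             "disabled")
        lam_e = calibrate_decay(config.p_e, p0_e, L)
        lam_i = calibrate_decay(config.p_i, p0_i, L)
    else:
        lam_e, lam_i = lambdas
    pos = rng.uniform(0.0, L, size=(config.n, 3))
    diff = pos[:, np.newaxis, :] - pos[np.newaxis, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    p = np.empty((config.n, config.n))
    for cols, p0, lam in ((slice(0, config.n_e), p0_e, lam_e),
                          (slice(config.n_e, config.n), p0_i, lam_i)):
        if math.isinf(lam):
            p[:, cols] = p0
        else:
            p[:, cols] = p0 * np.exp(-dist[:, cols] / lam)
    support = rng.random((config.n, config.n)) < p
    return _finalize(support, config, positions=pos, provenance={
        "model": "EXP_LSM", "params": {"d_exp": d_exp},
        "seed": _seed_repr(seed)})


# ---------------------------------------------------------------------------
# LAYERED
# ---------------------------------------------------------------------------

def _layer_sizes(n_e: int, n_l: int) -> list[int]:
    """Split n_e into n_l near-equal layers (sizes differ by at most 1)."""
    return [len(a) for a in np.array_split(np.arange(n_e), n_l)]


def sample_layered(config: BarrelConfig, n_l: int, p_e_f: float,
                   p_e_l: float, seed) -> Connectome:
    """Layered excitatory circuit: within-layer connectivity p_e_l, forward
    (layer k -> k+1) connectivity p_e_f, no backward or skip connections;
    inhibitory neurons unstructured (receive with p_e, project with p_i)."""
    if n_l < 1:
        raise ValueError("n_l must be >= 1")
    rng = _rng(seed)
    n, n_e = config.n, config.n_e
    prob = np.zeros((n, n))
    bounds = np.cumsum([0] + _layer_sizes(n_e, n_l))
    for k in range(n_l):
        a, b = bounds[k], bounds[k + 1]
        prob[a:b, a:b] = p_e_l
        if k + 1 < n_l:
            c, d = bounds[k + 1], bounds[k + 2]
            prob[c:d, a:b] = p_e_f
    prob[n_e:, :n_e] = config.p_e      # excitatory -> inhibitory
    prob[:, n_e:] = config.p_i         # inhibitory -> all
    support = rng.random((n, n)) < prob
    return _finalize(support, config, provenance={
        "model": "LAYERED",
        "params": {"n_l": n_l, "p_e_f": p_e_f, "p_e_l": p_e_l},
        "seed": _seed_repr(seed)})


# ---------------------------------------------------------------------------
# SYNFIRE
# ---------------------------------------------------------------------------

def synfire_n_iterations(config: BarrelConfig, s_pool: int) -> int:
    """Number of pool-to-pool iterations: round(log(1-p_e) /
    log(1 - s_pool^2 / n_e^2)), chosen so the chain construction hits the
    target excitatory connectivity p_e."""
    if s_pool ** 2 >= config.n_e ** 2:
        raise SimulationError("s_pool >= n_e: iteration count undefined")
    return int(round(math.log(1.0 - config.p_e)
                     / math.log(1.0 - s_pool ** 2 / config.n_e ** 2)))


def sample_synfire(config: BarrelConfig, s_pool: int, seed) -> Connectome:
    """Embedded synfire chain: iteratively draw uniform excitatory target
    pools (size s_pool) and inhibitory target pools (size (n_i/n_e) s_pool),
    connect the current source pool all-to-all to both, and make the
    excitatory target pool the next source.  Pools may overlap across
    iterations.  Inhibitory neurons project uniformly with p_i."""
    if not 1 <= s_pool <= config.n_e:
        raise SimulationError("s_pool must lie in [1, n_e]")
    rng = _rng(seed)
    n, n_e, n_i = config.n, config.n_e, config.n_i
    n_iter = synfire_n_iterations(config, s_pool)
    s_pool_i = int(round(n_i / n_e * s_pool))
    support = np.zeros((n, n), dtype=bool)
    source = rng.choice(n_e, size=s_pool, replace=False)
    for _ in range(n_iter):
        target_e = rng.choice(n_e, size=s_pool, replace=False)
        support[np.ix_(target_e, source)] = True
        if s_pool_i > 0:
            target_i = n_e + rng.choice(n_i, size=s_pool_i, replace=False)
            support[np.ix_(target_i, source)] = True
        source = target_e
    support[:, n_e:] = rng.random((n, n_i)) < config.p_i
    return _finalize(support, config, provenance={
        "model": "SYNFIRE", "params": {"s_pool": s_pool},
        "seed": _seed_repr(seed)})


# ---------------------------------------------------------------------------
# FEVER
# ---------------------------------------------------------------------------

def _unit_sphere(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    v = rng.normal(size=(n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class _FeverNeuronProblem:
    """Sparse feature reconstruction of one neuron's outgoing weights.

    Solves the positive lasso

        min_{c >= 0} ||d_k - sum_{p != k} d_p c_p||_2^2 + lambda ||c||_1

    so that neuron k's unit feature vector is reconstructed by the feature
    vectors of the neurons it newly projects to; the resulting support is
    merged with the anchor support c_k^0 of the pre-drawn random graph.
    (The printed anchored objective ||c_k^0 - c||_1 with unit anchor weights
    is ill-conditioned: the anchor term then dominates the unit-norm
    reconstruction target.  Penalising only the deviations that add
    connections — keeping the anchor edges — preserves the model's intent:
    a random graph with feature-recombination connections layered on top.)
    The lasso model is kept warm across alpha values for the connectivity
    fit.
    """

    def __init__(self, F: np.ndarray, support0: np.ndarray, k: int,
                 lasso_cls):
        n = F.shape[0]
        self.n = n
        self.k = k
        self.others = np.concatenate([np.arange(k), np.arange(k + 1, n)])
        self.anchor = support0[:, k].copy()
        self.anchor[k] = False
        self.X = F[self.others].T            # d_f x (n-1)
        self.y = F[k]
        self.model = lasso_cls(alpha=1.0, positive=True, max_iter=5_000,
                               tol=1e-3, fit_intercept=False,
                               warm_start=True)

    def support(self, alpha: float) -> np.ndarray:
        self.model.alpha = alpha
        self.model.fit(self.X, self.y)
        out = self.anchor.copy()
        out[self.others] |= self.model.coef_ > 1e-10
        return out


def sample_fever(config: BarrelConfig, f_r: float, d_f: int, seed, *,
                 fit_tol: float = 0.005, fit_subset: int = 16,
                 max_bisect: int = 12) -> Connectome:
    """Feature-vector recombination model.

    An initial random graph is drawn with reduced connectivities
    p_t^0 = p_t - f_r d_f / n; each neuron's outgoing weights are then
    re-optimised so that its unit feature vector is reconstructed by the
    feature vectors of its targets, under an L1 penalty anchored at the
    initial weights.  The per-population penalty weights are fitted by
    bisection so the excitatory/inhibitory connectivities match p_e/p_i.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import Lasso

    if not 0.0 <= f_r <= 1.0:
        raise ValueError("f_r must lie in [0, 1]")
    rng = _rng(seed)
    n, n_e = config.n, config.n_e
    p0 = {"e": config.p_e - f_r * d_f / n, "i": config.p_i - f_r * d_f / n}
    for t, v in p0.items():
        if v < -1e-12:
            raise SimulationError(
                f"initial connectivity p_{t}^0 = {v:.4f} negative; "
                "reduce f_r or d_f")
    p0 = {t: max(0.0, v) for t, v in p0.items()}
    p_col = np.where(np.arange(n) < n_e, p0["e"], p0["i"])
    support0 = rng.random((n, n)) < p_col[np.newaxis, :]
    np.fill_diagonal(support0, False)
    F = _unit_sphere(rng, n, d_f)

    pops = {"e": np.arange(n_e), "i": np.arange(n_e, n)}
    targets = {"e": config.p_e, "i": config.p_i}
    alphas: dict[str, float] = {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)

        for t in ("e", "i"):
            idx = pops[t]
            if len(idx) > fit_subset:
                idx = rng.choice(idx, size=fit_subset, replace=False)
            problems = [_FeverNeuronProblem(F, support0, int(k), Lasso)
                        for k in idx]

            def subset_connectivity(alpha: float) -> float:
                return float(np.mean([p.support(alpha).sum() / (n - 1)
                                      for p in problems]))

            target = targets[t]
            lo, hi = 1e-6, 1e-2
            c_hi = subset_connectivity(hi)
            while c_hi > target and hi < 1e4:
                hi *= 10.0
                c_hi = subset_connectivity(hi)
            c_lo = subset_connectivity(lo)
            if c_lo < target - 5 * fit_tol and c_lo <= c_hi + fit_tol:
                raise FitError(
                    f"FEVER connectivity target {target} unreachable for "
                    f"population {t} (max approx {c_lo:.3f})")
            alpha = hi
            for _ in range(max_bisect):
                mid = math.sqrt(lo * hi)
                c_mid = subset_connectivity(mid)
                if abs(c_mid - target) <= fit_tol:
                    alpha = mid
                    break
                if c_mid > target:
                    lo = mid
                else:
                    hi = mid
                alpha = math.sqrt(lo * hi)
            alphas[t] = alpha

        support = np.zeros((n, n), dtype=bool)
        for k in range(n):
            t = "e" if k < n_e else "i"
            support[:, k] = _FeverNeuronProblem(F, support0, k,
                                                Lasso).support(alphas[t])
    return _finalize(support, config, provenance={
        "model": "FEVER", "params": {"f_r": f_r, "d_f": d_f},
        "seed": _seed_repr(seed), "alphas": alphas})


# ---------------------------------------------------------------------------
# API
# ---------------------------------------------------------------------------

def api_connection_probability(cos_sim, s_j, n_pow: float,
                               n_binomial: float):
    """p_ij = 1 - (1 - ((C_ij s_j + 1)/2)^n_pow)^n_binomial."""
    base = np.clip((cos_sim * s_j + 1.0) / 2.0, 0.0, 1.0)
    return 1.0 - (1.0 - base ** n_pow) ** n_binomial


def sample_api(config: BarrelConfig, n_pow: float, d_f: int, seed, *,
               fit_tol: float = 1e-4) -> Connectome:
    """Antiphase inhibition model: connection probability is a sharpened
    function of the cosine similarity between the postsynaptic and
    presynaptic feature vectors (sign-flipped for inhibitory presynaptic
    neurons); the binomial exponents are fitted so the mean excitatory and
    inhibitory connectivities match p_e and p_i."""
    if d_f < 2:
        raise ValueError("d_f must be >= 2")
    from scipy.optimize import brentq

    rng = _rng(seed)
    n, n_e = config.n, config.n_e
    F = _unit_sphere(rng, n, d_f)
    cos = F @ F.T
    off_diag = ~np.eye(n, dtype=bool)

    def fit_exponent(cols: slice, s_j: float, target: float) -> float:
        base = np.clip((cos[:, cols] * s_j + 1.0) / 2.0, 0.0, 1.0)
        q = 1.0 - base ** n_pow
        mask = off_diag[:, cols]

        def mean_p(log_nb: float) -> float:
            return float(np.mean(1.0 - q[mask] ** (10.0 ** log_nb)))

        lo, hi = -8.0, 8.0
        if not mean_p(lo) < target < mean_p(hi):
            raise FitError(f"API exponent fit fails to bracket target "
                           f"{target}")
        log_nb = brentq(lambda v: mean_p(v) - target, lo, hi, xtol=1e-10)
        return 10.0 ** log_nb

    nb_e = fit_exponent(slice(0, n_e), +1.0, config.p_e)
    nb_i = fit_exponent(slice(n_e, n), -1.0, config.p_i)
    p = np.empty((n, n))
    p[:, :n_e] = api_connection_probability(cos[:, :n_e], +1.0, n_pow, nb_e)
    p[:, n_e:] = api_connection_probability(cos[:, n_e:], -1.0, n_pow, nb_i)
    support = rng.random((n, n)) < p
    return _finalize(support, config, provenance={
        "model": "API", "params": {"n_pow": n_pow, "d_f": d_f},
        "seed": _seed_repr(seed),
        "n_binomial": {"e": nb_e, "i": nb_i}})


# ---------------------------------------------------------------------------
# STDP-SORN
# ---------------------------------------------------------------------------

def sample_stdp_sorn(config: BarrelConfig, eta_stdp: float, eta_i: float,
                     seed, *, tau_end: int = 10_000, sigma: float = 0.05,
                     f0: float = 0.1,
                     return_state: bool = False):
    """Self-organising recurrent network shaped by plasticity.

    Starting from a random signed graph with incoming excitatory weights
    normalised to +1 and inhibitory to -1 per neuron, the network is run for
    ``tau_end`` steps of: threshold-unit propagation with Gaussian input
    noise; intrinsic plasticity of the firing thresholds toward target rate
    f0; re-normalisation of incoming excitatory weights; additive STDP on
    the existing excitatory-excitatory synapses; pruning of
    excitatory-excitatory weights below 1/n; and structural plasticity that
    inserts new excitatory-excitatory synapses at weight 1/n to keep their
    count near n_e^2 p_e.  The final graph is binarized by support.
    """
    if eta_stdp < 0 or eta_i < 0:
        raise ValueError("learning rates must be non-negative")
    rng = _rng(seed)
    n, n_e = config.n, config.n_e
    p_col = _per_column_probability(config)
    support = rng.random((n, n)) < p_col[np.newaxis, :]
    np.fill_diagonal(support, False)
    types = _types(config)
    W = support * rng.uniform(0.0, 1.0, size=(n, n)) * types[np.newaxis, :]
    initial_support = support.copy()
    # excitatory synapses occupy columns 0..n_e-1 (>= 0 throughout the run),
    # inhibitory synapses columns n_e..n-1 (<= 0, static support)
    We = W[:, :n_e]
    Wi = W[:, n_e:]

    def normalize_exc() -> None:
        s = We.sum(axis=1)
        nz = s > 0
        We[nz] /= s[nz, np.newaxis]

    normalize_exc()
    s_i = -Wi.sum(axis=1)
    nz = s_i > 0
    Wi[nz] /= s_i[nz, np.newaxis]

    Wee = W[:n_e, :n_e]
    t = np.ones(n)
    x = np.zeros(n)
    x_old = np.zeros(n)
    w_min = 1.0 / n
    target_ns = n_e ** 2 * config.p_e
    for _ in range(tau_end):
        # (1) propagation
        x = (W @ x + rng.normal(0.0, sigma, size=n) - t >= 0).astype(float)
        # (2) intrinsic plasticity
        t += eta_i * (x - f0)
        # (3) normalization of incoming excitatory weights
        normalize_exc()
        # (4) STDP on existing e->e synapses (active rows only)
        if eta_stdp > 0:
            xe, xoe = x[:n_e], x_old[:n_e]
            rows_pot = np.flatnonzero(xe)       # postsynaptic fired now
            if rows_pot.size:
                block = Wee[rows_pot]
                inc = eta_stdp * (xoe + xe)
                block[block > 0] += np.broadcast_to(
                    inc, block.shape)[block > 0]
                Wee[rows_pot] = block
            rows_dep = np.flatnonzero(xoe)      # postsynaptic fired before
            if rows_dep.size:
                block = Wee[rows_dep]
                dec = eta_stdp * xe
                mask = block > 0
                block[mask] = np.maximum(
                    block[mask] - np.broadcast_to(dec, block.shape)[mask],
                    0.0)
                Wee[rows_dep] = block
        x_old = x
        # (5) pruning of weak e->e synapses
        Wee[(Wee > 0) & (Wee < w_min)] = 0.0
        # (6) structural plasticity
        n_s = np.count_nonzero(Wee)
        n_add = int(round((target_ns - n_s) / (1.0 - config.p_e)))
        if n_add > 0:
            ks = rng.integers(0, n_e, size=n_add)
            ls = rng.integers(0, n_e, size=n_add)
            ok = (ks != ls) & (Wee[ks, ls] == 0.0)
            Wee[ks[ok], ls[ok]] = w_min
    np.fill_diagonal(W, 0.0)
    out_support = W != 0
    conn = _finalize(out_support, config, provenance={
        "model": "STDP_SORN",
        "params": {"eta_stdp": eta_stdp, "eta_i": eta_i,
                   "tau_end": tau_end},
        "seed": _seed_repr(seed)})
    if return_state:
        return conn, {"weights": W, "thresholds": t, "x": x,
                      "initial_support": initial_support}
    return conn


# ---------------------------------------------------------------------------
# Dispatch and prior sampling
# ---------------------------------------------------------------------------

def _rescaled_params(model: str, params: dict, config: BarrelConfig) -> dict:
    """Map full-scale parameters to the generation scale of ``config``."""
    out = dict(params)
    if model == "SYNFIRE" and config.n_e != FULL_NE:
        out["s_pool"] = max(2, int(round(params["s_pool"]
                                         * config.n_e / FULL_NE)))
    if model in ("FEVER", "API") and config.n != FULL_N:
        out["d_f"] = max(2, int(round(params["d_f"] * config.n / FULL_N)))
    return out


def sample_connectome(model: str, params: dict, config: BarrelConfig,
                      seed) -> Connectome:
    """Draw a connectome from a named model; rescales scale-dependent
    parameters when ``config`` is smaller than the full barrel."""
    eff = _rescaled_params(model, params, config)
    rng = _rng(seed)
    if model == "ER_ESN":
        conn = sample_er_esn(config, rng)
    elif model == "EXP_LSM":
        conn = sample_exp_lsm(config, eff.get("d_exp", 1.0), rng)
    elif model == "LAYERED":
        conn = sample_layered(config, int(eff["n_l"]), eff["p_e_f"],
                              eff["p_e_l"], rng)
    elif model == "SYNFIRE":
        conn = sample_synfire(config, int(eff["s_pool"]), rng)
    elif model == "FEVER":
        conn = sample_fever(config, eff["f_r"], int(eff["d_f"]), rng)
    elif model == "API":
        conn = sample_api(config, eff["n_pow"], int(eff["d_f"]), rng)
    elif model == "STDP_SORN":
        conn = sample_stdp_sorn(config, eff["eta_stdp"], eff["eta_i"], rng,
                                tau_end=int(eff.get("tau_end", 10_000)))
    else:
        raise KeyError(f"unknown model {model!r}")
    conn.provenance["params"] = dict(params)
    conn.provenance["effective_params"] = eff
    if not isinstance(seed, np.random.Generator):
        conn.provenance["seed"] = int(seed)
    return conn


def sample_from_prior(prior: Prior, config: BarrelConfig, seed, *,
                      model: str | None = None, max_retries: int = 10):
    """Draw (model, params, connectome) from the joint prior.

    Invalid parameter combinations (generator preconditions violated, fit
    failures) are resampled up to ``max_retries`` times.
    """
    rng = _rng(seed)
    m = model if model is not None else prior.sample_model(rng)
    last_err: Exception | None = None
    for _ in range(max_retries):
        params = prior.sample_params(m, rng)
        try:
            return m, params, sample_connectome(m, params, config, rng)
        except SimulationError as err:
            last_err = err
    raise SimulationError(
        f"could not draw a valid {m} connectome in {max_retries} attempts"
    ) from last_err


# ---------------------------------------------------------------------------
# Analytic constraint-compliance expectations
# ---------------------------------------------------------------------------

def expected_layered_stats(config: BarrelConfig, n_l: int, p_e_f: float,
                           p_e_l: float) -> tuple[float, float]:
    """Closed-form expected excitatory pairwise connectivity and reciprocity
    of the layered construction (near-equal layer sizes).

    Only within-layer connections can be reciprocated (forward edges have no
    backward counterpart), so
    E[p_ee] = (A p_e_l + B p_e_f) / (n_e (n_e - 1)) and
    E[r_ee] = A p_e_l^2 / (A p_e_l + B p_e_f), with A the number of ordered
    within-layer pairs and B the number of ordered forward pairs.
    """
    if n_l < 1:
        raise ValueError("n_l must be >= 1")
    sizes = _layer_sizes(config.n_e, n_l)
    A = sum(m * (m - 1) for m in sizes)
    B = sum(sizes[k] * sizes[k + 1] for k in range(n_l - 1))
    n_pairs = config.n_e * (config.n_e - 1)
    e_edges = A * p_e_l + B * p_e_f
    p_ee = e_edges / n_pairs
    r_ee = 0.0 if e_edges == 0 else A * p_e_l ** 2 / e_edges
    return p_ee, r_ee


def expected_synfire_stats(config: BarrelConfig, s_pool: int, *,
                           disjoint: bool = False) -> tuple[float, float]:
    """Expected excitatory connectivity and reciprocity of the embedded
    synfire chain.

    Pools are i.i.d. uniform subsets of size s_pool; the edge a->b exists
    iff a is in pool t and b in pool t+1 for some iteration t.  The joint
    probability of forward and backward edges for an ordered neuron pair is
    computed exactly by dynamic programming over the pool-membership
    sequence.  In the disjoint-chain limit pools cannot overlap and no
    reciprocal connection exists.
    """
    n_e, s = config.n_e, int(s_pool)
    if not 1 <= s <= n_e:
        raise ValueError("s_pool must lie in [1, n_e]")
    if disjoint:
        # non-overlapping ordered pools: forward edges only
        return config.p_e, 0.0
    n_iter = 1 if s == n_e else max(1, synfire_n_iterations(config, s))
    # membership of a fixed ordered pair (a, b) in one pool (hypergeometric)
    p11 = s * (s - 1) / (n_e * (n_e - 1))
    p10 = s * (n_e - s) / (n_e * (n_e - 1))
    p00 = (n_e - s) * (n_e - s - 1) / (n_e * (n_e - 1))
    memb = {(1, 1): p11, (1, 0): p10, (0, 1): p10, (0, 0): p00}
    # DP state: (a in current pool, b in current pool, fwd seen, bwd seen)
    state: dict[tuple, float] = {}
    for (ma, mb), pm in memb.items():
        state[(ma, mb, 0, 0)] = state.get((ma, mb, 0, 0), 0.0) + pm
    for _ in range(n_iter):
        new: dict[tuple, float] = {}
        for (ma, mb, f, b), pr in state.items():
            for (na, nb), pm in memb.items():
                nf = f or (ma and nb)   # a in pool t, b in pool t+1
                nb_flag = b or (mb and na)
                key = (na, nb, int(nf), int(nb_flag))
                new[key] = new.get(key, 0.0) + pr * pm
        state = new
    p_fwd = sum(pr for (ma, mb, f, b), pr in state.items() if f)
    p_both = sum(pr for (ma, mb, f, b), pr in state.items() if f and b)
    r_ee = 0.0 if p_fwd == 0 else p_both / p_fwd
    return p_fwd, r_ee


def check_barrel_constraints(p_ee: float, r_ee: float,
                             config: BarrelConfig) -> bool:
    """True iff (p_ee, r_ee) lies in the experimentally established window
    (excitatory connectivity and reciprocity ranges)."""
    p_lo, p_hi = config.p_ee_range
    r_lo, r_hi = config.r_ee_range
    return (p_lo <= p_ee <= p_hi) and (r_lo <= r_ee <= r_hi)


def max_feasible_layers(config: BarrelConfig, n_l_max: int = 30,
                        grid: int = 101) -> int:
    """Largest layer count for which some (p_e_l, p_e_f) in [0,1]^2 satisfies
    the barrel constraints under the equal-layer convention."""
    p_el = np.linspace(0.0, 1.0, grid)
    p_ef = np.linspace(0.0, 1.0, grid)
    PL, PF = np.meshgrid(p_el, p_ef, indexing="ij")
    best = 0
    n_pairs = config.n_e * (config.n_e - 1)
    for n_l in range(1, n_l_max + 1):
        sizes = _layer_sizes(config.n_e, n_l)
        A = sum(m * (m - 1) for m in sizes)
        B = sum(sizes[k] * sizes[k + 1] for k in range(n_l - 1))
        edges = A * PL + B * PF
        p_ee = edges / n_pairs
        with np.errstate(invalid="ignore", divide="ignore"):
            r_ee = np.where(edges > 0, A * PL ** 2 / np.maximum(edges, 1e-300),
                            0.0)
        ok = ((config.p_ee_range[0] <= p_ee) & (p_ee <= config.p_ee_range[1])
              & (config.r_ee_range[0] <= r_ee)
              & (r_ee <= config.r_ee_range[1]))
        if ok.any():
            best = n_l
    return best
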