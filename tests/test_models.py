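"""Generator correctness: connectivity targets, construction rules, analytic
expectations against Monte-Carlo sampling, and prior plumbing."""

import math

import numpy as np
import pytest

from barrelabc import (
    BarrelConfig,
    calibrate_decay,
    check_barrel_constraints,
    expected_layered_stats,
    expected_synfire_stats,
    max_feasible_layers,
    reciprocity,
    sample_api,
    sample_connectome,
    sample_er_esn,
    sample_exp_lsm,
    sample_fever,
    sample_from_prior,
    sample_layered,
    sample_stdp_sorn,
    sample_synfire,
    summarize,
    synfire_n_iterations,
    validate,
)
from barrelabc.models import FitError, SimulationError, api_connection_probability
from barrelabc.priors import MODELS, default_prior


def exc_connectivity(conn):
    ee = conn.support()[:conn.n_e, :conn.n_e]
    return ee.nnz / (conn.n_e * (conn.n_e - 1))


def inh_connectivity(conn):
    col = conn.support()[:, conn.n_e:]
    return col.nnz / (conn.n_i * (conn.n - 1))


# ---------------------------------------------------------------------------
# shared invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model", MODELS)
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_generators_produce_valid_connectomes(model, seed):
    """No self-connections, sign consistency, in-cube positions."""
    n = 150 if model == "FEVER" else 200
    cfg = BarrelConfig().scaled(n)
    prior = default_prior()
    rng = np.random.default_rng(100 + seed)
    params = prior.sample_params(model, rng)
    if model == "STDP_SORN":
        params["tau_end"] = 300
    conn = sample_connectome(model, params, cfg, seed)
    assert validate(conn) == []
    assert conn.binary
    assert conn.n_e == cfg.n_e and conn.n_i == cfg.n_i


def test_prior_draws_mostly_satisfy_barrel_constraints():
    """Empirical (p_ee, r_ee) of prior draws falls in the constraint window
    for most draws; the pairwise-random models comply essentially always,
    the structured models' printed prior boxes extend somewhat beyond it."""
    prior = default_prior()
    rng = np.random.default_rng(7)
    fractions = {}
    for model in MODELS:
        n = 150 if model == "FEVER" else (200 if model == "STDP_SORN"
                                          else 500)
        cfg = BarrelConfig().scaled(n)
        ok = []
        for seed in range(6):
            params = prior.sample_params(model, rng)
            if model == "STDP_SORN":
                params["tau_end"] = 1000
            try:
                conn = sample_connectome(model, params, cfg, seed)
            except SimulationError:
                ok.append(False)
                continue
            p_ee = exc_connectivity(conn)
            r_ee = reciprocity(conn, "e", "e")
            ok.append(check_barrel_constraints(p_ee, r_ee, cfg))
        fractions[model] = np.mean(ok)
    assert fractions["ER_ESN"] >= 0.9
    assert fractions["EXP_LSM"] >= 0.9
    for model in MODELS:
        assert fractions[model] >= 0.5, (model, fractions)
    assert np.mean(list(fractions.values())) >= 0.7


# ---------------------------------------------------------------------------
# ER-ESN
# ---------------------------------------------------------------------------

def test_er_default_population_sizes():
    conn = sample_er_esn(BarrelConfig(), seed=0)
    assert conn.n_e == 1800 and conn.n_i == 200


def test_er_zero_probability_gives_empty_graph():
    cfg = BarrelConfig(n_e=90, n_i=10, p_e=0.0, p_i=0.0)
    assert sample_er_esn(cfg, seed=0).n_edges == 0


def test_er_connectivity_within_binomial_bounds():
    cfg = BarrelConfig().scaled(1000)
    n_draws = cfg.n_e * (cfg.n - 1)
    tol = 4 * math.sqrt(0.2 * 0.8 / n_draws)
    ps = []
    for seed in range(10):
        conn = sample_er_esn(cfg, seed)
        e_cols = conn.support()[:, :cfg.n_e]
        ps.append(e_cols.nnz / n_draws)
    assert abs(np.mean(ps) - 0.2) < tol


# ---------------------------------------------------------------------------
# EXP-LSM
# ---------------------------------------------------------------------------

def test_calibrate_decay_distance_independent_limit():
    assert math.isinf(calibrate_decay(0.2, 0.2, 300.0))


def test_calibrate_decay_unreachable_target_errors():
    with pytest.raises(FitError):
        calibrate_decay(0.5, 0.2, 300.0)


def test_calibrate_decay_monotone_in_target():
    lam_lo = calibrate_decay(0.1, 1.0, 300.0)
    lam_hi = calibrate_decay(0.3, 1.0, 300.0)
    assert lam_hi > lam_lo


def test_calibrate_decay_monte_carlo_oracle():
    """lambda calibrated for d_exp=1, p=0.2, side 300 reproduces the target
    connectivity under 1e6 independent uniform point pairs."""
    lam = calibrate_decay(0.2, 1.0, 300.0)
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 300, size=(10 ** 6, 3))
    b = rng.uniform(0, 300, size=(10 ** 6, 3))
    d = np.linalg.norm(a - b, axis=1)
    assert abs(np.mean(np.exp(-d / lam)) - 0.2) < 0.005


def test_exp_lsm_p0_interpolation_formula():
    cfg = BarrelConfig().scaled(200)
    conn = sample_exp_lsm(cfg, 1.0, seed=0)
    # d_exp = 1 -> p_0 = 1: neurons at negligible distance always connect
    assert conn.positions is not None
    # d_exp = 0 -> ER limit: calibration returns infinite lambda
    assert math.isinf(calibrate_decay(cfg.p_e,
                                      cfg.p_e + (1 - cfg.p_e) * 0.0, 300.0))


def test_exp_lsm_calibrated_connectivity():
    cfg = BarrelConfig().scaled(500)
    ps = [exc_connectivity(sample_exp_lsm(cfg, 1.0, seed))
          for seed in range(5)]
    assert abs(np.mean(ps) - 0.2) < 0.01


def test_exp_lsm_uncalibrated_without_lambdas_errors():
    cfg = BarrelConfig().scaled(100)
    with pytest.raises(ValueError):
        sample_exp_lsm(cfg, 1.0, 0, calibrate=False)


# ---------------------------------------------------------------------------
# LAYERED
# ---------------------------------------------------------------------------

def test_layered_single_layer_is_er():
    cfg = BarrelConfig().scaled(500)
    conn = sample_layered(cfg, 1, 0.9, 0.3, seed=0)
    assert abs(exc_connectivity(conn) - 0.3) < 0.02


def test_layered_block_connectivities_within_binomial_bounds():
    cfg = BarrelConfig().scaled(600)
    n_l, p_f, p_l = 3, 0.4, 0.35
    conn = sample_layered(cfg, n_l, p_f, p_l, seed=3)
    dense = np.abs(conn.adjacency.toarray())
    sizes = [len(a) for a in np.array_split(np.arange(cfg.n_e), n_l)]
    bounds = np.cumsum([0] + sizes)
    for k in range(n_l):
        a, b = bounds[k], bounds[k + 1]
        m = sizes[k] * (sizes[k] - 1)
        within = dense[a:b, a:b].sum() / m
        assert abs(within - p_l) < 3 * math.sqrt(p_l * (1 - p_l) / m)
        if k + 1 < n_l:
            c, d = bounds[k + 1], bounds[k + 2]
            m2 = sizes[k] * sizes[k + 1]
            fwd = dense[c:d, a:b].sum() / m2
            assert abs(fwd - p_f) < 3 * math.sqrt(p_f * (1 - p_f) / m2)
    # no backward or skip-layer excitatory edges
    for k in range(n_l):
        for j in range(n_l):
            if j not in (k, k + 1):
                a, b = bounds[k], bounds[k + 1]
                c, d = bounds[j], bounds[j + 1]
                assert dense[c:d, a:b].sum() == 0


# ---------------------------------------------------------------------------
# SYNFIRE
# ---------------------------------------------------------------------------

def test_synfire_iteration_count_printed_formula():
    cfg = BarrelConfig()
    assert synfire_n_iterations(cfg, 100) == 72
    assert synfire_n_iterations(cfg, 300) == 8


def test_synfire_pool_too_large_errors():
    cfg = BarrelConfig().scaled(100)
    with pytest.raises(SimulationError):
        sample_synfire(cfg, cfg.n_e, seed=0)


def test_synfire_overall_connectivity_hits_target():
    cfg = BarrelConfig()
    ps = [exc_connectivity(sample_synfire(cfg, 150, seed))
          for seed in range(5)]
    assert abs(np.mean(ps) - 0.2) < 0.02


# ---------------------------------------------------------------------------
# FEVER
# ---------------------------------------------------------------------------

def test_fever_initial_connectivity_formula():
    # f_r = 1, d_f = 200, n = 2000 -> p_e^0 = 0.2 - 200/2000 = 0.1
    assert 0.2 - 1.0 * 200 / 2000 == pytest.approx(0.1)
    # violated precondition raises
    cfg = BarrelConfig().scaled(200)
    with pytest.raises(SimulationError):
        sample_fever(cfg, 1.0, 100, seed=0)  # p_e^0 = 0.2 - 0.5 < 0


def test_fever_fitted_connectivity_and_elevated_reciprocity():
    cfg = BarrelConfig().scaled(400)
    conn = sample_fever(cfg, 0.7, 60, seed=0)
    assert abs(exc_connectivity(conn) - 0.2) < 0.02
    s = summarize(conn)
    assert s.rr_ee > 1.1


# ---------------------------------------------------------------------------
# API
# ---------------------------------------------------------------------------

def test_api_probability_formula_limits():
    # perfectly aligned excitatory pair -> connection certain
    assert api_connection_probability(1.0, +1.0, 5, 3) == pytest.approx(1.0)
    # anti-aligned excitatory pair -> no connection
    assert api_connection_probability(-1.0, +1.0, 5, 3) == pytest.approx(0.0)


def test_api_fitted_connectivities():
    cfg = BarrelConfig().scaled(500)
    pe, pi = [], []
    for seed in range(3):
        conn = sample_api(cfg, 5.0, 50, seed)
        pe.append(exc_connectivity(conn))
        pi.append(inh_connectivity(conn))
    assert abs(np.mean(pe) - 0.2) < 0.01
    assert abs(np.mean(pi) - 0.6) < 0.02


# ---------------------------------------------------------------------------
# STDP-SORN
# ---------------------------------------------------------------------------

def test_sorn_initial_normalization_exact():
    cfg = BarrelConfig().scaled(200)
    _, state = sample_stdp_sorn(cfg, 0.01, 0.01, seed=0, tau_end=0,
                                return_state=True)
    W = state["weights"]
    pos = np.where(W > 0, W, 0.0).sum(axis=1)
    neg = np.where(W < 0, W, 0.0).sum(axis=1)
    assert np.allclose(pos[pos > 0], 1.0, atol=1e-9)
    assert np.allclose(neg[neg < 0], -1.0, atol=1e-9)


def test_sorn_inhibitory_support_static():
    """No plasticity rule acts on inhibitory synapses: their support is the
    initial random draw for any learning rates."""
    cfg = BarrelConfig().scaled(150)
    conn, state = sample_stdp_sorn(cfg, 0.05, 0.05, seed=3, tau_end=100,
                                   return_state=True)
    final_inh = conn.adjacency.toarray()[:, cfg.n_e:] != 0
    init_inh = state["initial_support"][:, cfg.n_e:]
    np.testing.assert_array_equal(final_inh, init_inh)


def test_sorn_reduced_run_connectivity():
    cfg = BarrelConfig().scaled(400)
    ps = []
    for seed in range(3):
        conn = sample_stdp_sorn(cfg, 0.01, 0.01, seed, tau_end=2000)
        ps.append(exc_connectivity(conn))
    assert abs(np.mean(ps) - 0.2) < 0.03


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------

def test_sample_from_prior_ranges_and_dispatch():
    cfg = BarrelConfig().scaled(200)
    prior = default_prior()
    for seed in range(5):
        m, params, conn = sample_from_prior(prior, cfg, seed,
                                            model="LAYERED")
        assert m == "LAYERED"
        assert params["n_l"] in (2, 3, 4)
        assert 0.19 <= params["p_e_f"] <= 0.57
        assert 0.26 <= params["p_e_l"] <= 0.43
        assert conn.provenance["model"] == "LAYERED"
    m, params, _ = sample_from_prior(prior, cfg, 0, model="API")
    assert 4.0 <= params["n_pow"] <= 6.0


def test_sample_from_prior_restricted_model_set():
    cfg = BarrelConfig().scaled(150)
    prior = default_prior(("ER_ESN",))
    for seed in range(5):
        m, _, _ = sample_from_prior(prior, cfg, seed)
        assert m == "ER_ESN"


# ---------------------------------------------------------------------------
# analytic expectations vs Monte-Carlo oracles
# ---------------------------------------------------------------------------

def test_expected_layered_stats_degenerate_cases():
    cfg = BarrelConfig()
    p, r = expected_layered_stats(cfg, 3, 0.4, 0.0)
    assert r == 0.0
    p, r = expected_layered_stats(cfg, 1, 0.5, 0.35)
    assert p == pytest.approx(0.35)
    assert r == pytest.approx(0.35)


def test_expected_layered_stats_vs_sampling():
    cfg = BarrelConfig().scaled(300)
    n_l, p_f, p_l = 3, 0.4, 0.35
    exp_p, exp_r = expected_layered_stats(cfg, n_l, p_f, p_l)
    ps, rs = [], []
    for seed in range(50):
        conn = sample_layered(cfg, n_l, p_f, p_l, seed)
        ps.append(exc_connectivity(conn))
        rs.append(reciprocity(conn, "e", "e"))
    for got, want in ((ps, exp_p), (rs, exp_r)):
        se = np.std(got, ddof=1) / math.sqrt(len(got))
        assert abs(np.mean(got) - want) < 3 * se


def test_expected_synfire_stats_limits():
    cfg = BarrelConfig()
    _, r = expected_synfire_stats(cfg, 150, disjoint=True)
    assert r == 0.0
    p, r = expected_synfire_stats(cfg, cfg.n_e)
    assert r == pytest.approx(1.0)


def test_expected_synfire_stats_vs_sampling():
    cfg = BarrelConfig().scaled(500)
    s_pool = 40
    exp_p, exp_r = expected_synfire_stats(cfg, s_pool)
    ps, rs = [], []
    for seed in range(50):
        conn = sample_synfire(cfg, s_pool, seed)
        ps.append(exc_connectivity(conn))
        rs.append(reciprocity(conn, "e", "e"))
    for got, want in ((ps, exp_p), (rs, exp_r)):
        se = np.std(got, ddof=1) / math.sqrt(len(got))
        assert abs(np.mean(got) - want) < 3 * se + 1e-9


# ---------------------------------------------------------------------------
# constraint window
# ---------------------------------------------------------------------------

def test_check_barrel_constraints_examples():
    cfg = BarrelConfig()
    assert check_barrel_constraints(0.2, 0.25, cfg)
    assert not check_barrel_constraints(0.2, 0.0, cfg)
    assert not check_barrel_constraints(0.5, 0.2, cfg)


def test_max_feasible_layers_reported():
    cfg = BarrelConfig()
    ceiling = max_feasible_layers(cfg)
    # layered circuits remain constraint-compatible well beyond 4 layers
    assert ceiling >= 8
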