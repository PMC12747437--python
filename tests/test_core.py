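import itertools

import numpy as np
import pytest

from lear import (
    ErrorModel,
    OptimizerConfig,
    SimulationSpec,
    add_localization_error,
    compute_goal_variances,
    generate_polymer_traces,
    goal_variance_logdensity,
    locus_log_likelihood,
    optimize_locus,
    run_lear,
)

from conftest import make_traceset


# ---------------------------------------------------------------------------
# goal-variance table
# ---------------------------------------------------------------------------


def test_zero_error_goal_equals_empirical(chain_gt):
    ts = chain_gt.observed
    em = ErrorModel.uniform(ts.n_loci, [0.0, 0.0, 0.0])
    gvt = compute_goal_variances(ts, em, dim=0, min_n=10)
    u = gvt.usable
    assert np.allclose(gvt.mu[u], gvt.var[u])


def test_variance_decomposition_recovers_injected_sigma():
    """Var(O^a - O^b) - Var(T^a - O^b) converges to the injected error variance."""
    gt = generate_polymer_traces(SimulationSpec(n_loci=6, n_traces=2000, seed=31))
    for sigma in (25.0, 50.0, 100.0):
        noisy = add_localization_error(gt, sigma, seed=32)
        O = noisy.observed.positions[:, :, 0]
        T = noisy.truth.positions[:, :, 0]
        for a, b in [(0, 1), (2, 5)]:
            v_oo = np.var(O[:, a] - O[:, b], ddof=1)
            v_to = np.var(T[:, a] - O[:, b], ddof=1)
            # distribution-free SE of each sample variance, combined
            def se(x):
                c = x - x.mean()
                return np.sqrt((np.mean(c**4) - np.mean(c**2) ** 2) / len(x))
            tol = 4.0 * np.hypot(se(O[:, a] - O[:, b]), se(T[:, a] - O[:, b]))
            assert abs((v_oo - v_to) - sigma**2) < tol


def test_goal_table_matches_bruteforce():
    rng = np.random.default_rng(33)
    pos = rng.normal(0, 120, size=(80, 5, 3))
    pos[rng.random((80, 5)) < 0.15] = np.nan
    ts = make_traceset(pos)
    em = ErrorModel.uniform(5, [40.0, 40.0, 40.0])
    gvt = compute_goal_variances(ts, em, dim=1, min_n=20)
    X = pos[:, :, 1]
    for a in range(5):
        for b in range(5):
            if a == b:
                assert not gvt.usable[a, b]
                continue
            d = X[:, a] - X[:, b]
            d = d[np.isfinite(d)]
            assert gvt.n[a, b] == len(d)
            if len(d) < 20:
                assert not gvt.usable[a, b]
                continue
            v = np.var(d, ddof=1)
            assert gvt.var[a, b] == pytest.approx(v, rel=1e-12)
            assert gvt.mu[a, b] == pytest.approx(max(v - 40.0**2, 1.0), rel=1e-12)
            c = d - d.mean()
            se = np.sqrt((np.mean(c**4) - np.mean(c**2) ** 2) / len(d))
            assert gvt.sigma[a, b] == pytest.approx(max(se, 0.1), rel=1e-12)


def test_negative_goal_floored_with_warning():
    rng = np.random.default_rng(34)
    pos = rng.normal(0, 10, size=(100, 3, 1))  # tiny true spread
    ts = make_traceset(pos)
    em = ErrorModel.uniform(3, [500.0])
    with pytest.warns(UserWarning, match="floor"):
        gvt = compute_goal_variances(ts, em, dim=0, min_n=10)
    assert (gvt.mu[gvt.usable] == 1.0).all()


# ---------------------------------------------------------------------------
# density and likelihood
# ---------------------------------------------------------------------------


def test_logdensity_closed_forms():
    assert goal_variance_logdensity(5.0, 5.0, 2.0) == pytest.approx(
        np.log(1.0 / (2.0 * np.sqrt(2 * np.pi)))
    )
    assert goal_variance_logdensity(1.0, 0.0, 1.0) == pytest.approx(np.log(0.2419707), rel=1e-6)
    x = 0.7
    assert goal_variance_logdensity(3.0 + x, 3.0, 1.5) == pytest.approx(
        goal_variance_logdensity(3.0 - x, 3.0, 1.5)
    )
    with pytest.raises(ValueError):
        goal_variance_logdensity(1.0, 1.0, 0.0)


def test_likelihood_matches_bruteforce_small_instance():
    rng = np.random.default_rng(35)
    pos = rng.normal(0, 50, size=(5, 3, 1))
    ts = make_traceset(pos)
    em = ErrorModel.uniform(3, [10.0])
    gvt = compute_goal_variances(ts, em, dim=0, min_n=2)
    a_col = pos[:, 0, 0] + rng.normal(0, 5, size=5)
    got = locus_log_likelihood(0, a_col, ts, gvt)
    expected = 0.0
    for b in (1, 2):
        v = np.var(a_col - pos[:, b, 0], ddof=1)
        expected += float(goal_variance_logdensity(v, gvt.mu[0, b], gvt.sigma[0, b]))
    assert got == pytest.approx(expected, rel=1e-12)


def test_likelihood_translation_invariant(chain_gt):
    ts = chain_gt.observed
    em = ErrorModel.uniform(ts.n_loci, [30.0, 30.0, 30.0])
    gvt = compute_goal_variances(ts, em, dim=0, min_n=10)
    a_col = ts.positions[:, 2, 0]
    l0 = locus_log_likelihood(2, a_col, ts, gvt)
    l1 = locus_log_likelihood(2, a_col + 123.4, ts, gvt)
    assert l0 == pytest.approx(l1, rel=1e-12)


def test_unadjusted_data_is_global_max_at_zero_error(chain_gt):
    """With sigma_alpha = 0 every term sits at its mode for A = O."""
    ts = chain_gt.observed
    em = ErrorModel.uniform(ts.n_loci, [0.0, 0.0, 0.0])
    gvt = compute_goal_variances(ts, em, dim=0, min_n=10)
    a = ts.positions[:, 1, 0]
    l_at_o = locus_log_likelihood(1, a, ts, gvt)
    rng = np.random.default_rng(36)
    for _ in range(5):
        assert locus_log_likelihood(1, a + rng.normal(0, 10, a.shape), ts, gvt) < l_at_o


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


def test_optimizer_matches_grid_search_toy():
    """N=4, L=2: the descent reaches the exhaustive 1-nm-grid maximum."""
    pos = np.array([[0.0, 10.0], [40.0, 45.0], [90.0, 110.0], [150.0, 140.0]])[:, :, None]
    ts = make_traceset(pos)
    em = ErrorModel.uniform(2, [8.0])
    gvt = compute_goal_variances(ts, em, dim=0, min_n=2)
    cfg = OptimizerConfig(seed=7, sweeps=400, min_n=2, tol=1e-12)
    c, info = optimize_locus(0, ts, gvt, cfg, sigma_alpha=8.0)
    best_grid = -np.inf
    grid = np.arange(-8.0, 8.5, 1.0)
    for deltas in itertools.product(grid, repeat=4):
        val = locus_log_likelihood(0, pos[:, 0, 0] + np.array(deltas), ts, gvt)
        best_grid = max(best_grid, val)
    achieved = locus_log_likelihood(0, pos[:, 0, 0] + c, ts, gvt)
    assert achieved >= best_grid - 1e-6
    # non-decreasing likelihood trace
    assert (np.diff(info["loglik"]) >= -1e-9).all()


def test_zero_error_optimizer_leaves_data_alone(chain_gt):
    ts = chain_gt.observed
    em = ErrorModel.uniform(ts.n_loci, [0.0, 0.0, 0.0])
    gvt = compute_goal_variances(ts, em, dim=0, min_n=10)
    cfg = OptimizerConfig(seed=8, sweeps=50, min_n=10)
    c, _ = optimize_locus(3, ts, gvt, cfg, sigma_alpha=0.0)
    # proposal scale floor is sqrt(variance floor) = 1 nm
    assert np.abs(c).max() < 2.0


def test_monotone_likelihood_on_noisy_data(noisy_chain):
    ts = noisy_chain.observed
    em = ErrorModel.uniform(ts.n_loci, [50.0] * 3)
    gvt = compute_goal_variances(ts, em, dim=0, min_n=50)
    cfg = OptimizerConfig(seed=9, sweeps=80)
    c, info = optimize_locus(5, ts, gvt, cfg, sigma_alpha=50.0)
    assert (np.diff(info["loglik"]) >= -1e-9).all()
    assert info["final_loglik"] >= info["initial_loglik"]
    assert abs(np.mean(c)) < 1e-9  # zero-mean gauge


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


def test_run_lear_noise_free_identity(chain_gt):
    ts = chain_gt.observed
    em = ErrorModel.uniform(ts.n_loci, [0.0, 0.0, 0.0])
    adj, _ = run_lear(ts, em, OptimizerConfig(seed=10, sweeps=50, min_n=50))
    assert np.nanmax(np.abs(adj.positions - ts.positions)) < 2.0


def test_run_lear_deterministic(noisy_chain):
    ts = noisy_chain.observed
    em = ErrorModel.uniform(ts.n_loci, [50.0] * 3)
    cfg = OptimizerConfig(seed=12, sweeps=40)
    a1, _ = run_lear(ts, em, cfg)
    a2, _ = run_lear(ts, em, cfg)
    assert np.array_equal(a1.positions, a2.positions, equal_nan=True)


def test_run_lear_gauge_covariance(noisy_chain):
    """Adding a constant to one observed locus shifts its adjustment equally."""
    ts = noisy_chain.observed
    em = ErrorModel.uniform(ts.n_loci, [50.0] * 3)
    cfg = OptimizerConfig(seed=13, sweeps=40)
    a1, _ = run_lear(ts, em, cfg)
    shifted = ts.positions.copy()
    shifted[:, 4, 0] += 500.0
    a2, _ = run_lear(ts.with_positions(shifted), em, cfg)
    delta = a2.positions[:, 4, 0] - a1.positions[:, 4, 0]
    assert np.allclose(delta[np.isfinite(delta)], 500.0, atol=1e-9)
    other = np.delete(a2.positions - a1.positions, 4, axis=1)
    assert np.nanmax(np.abs(other)) < 1e-9


def test_corrections_anticorrelate_with_injected_noise(noisy_chain):
    """The corrections oppose the injected errors at the single-spot level."""
    ts = noisy_chain.observed
    em = ErrorModel.uniform(ts.n_loci, [50.0] * 3)
    adj, diag = run_lear(ts, em, OptimizerConfig(seed=14, sweeps=80))
    c = diag["corrections"][:, :, 0].ravel()
    e = noisy_chain.injected_noise[:, :, 0].ravel()
    ok = np.isfinite(c) & np.isfinite(e)
    r = np.corrcoef(c[ok], -e[ok])[0, 1]
    assert r > 0.1


def test_effectiveness_grows_with_error_size():
    """Holding the truth fixed, larger injected error yields larger relative
    improvement (the effectiveness-scaling property)."""
    from lear import relative_error_per_locus

    gt = generate_polymer_traces(SimulationSpec(n_loci=30, n_traces=300, seed=37))
    rel = {}
    for sigma in (25.0, 50.0, 100.0):
        noisy = add_localization_error(gt, sigma, seed=38)
        em = ErrorModel.uniform(30, [sigma] * 3)
        adj, _ = run_lear(noisy.observed, em, OptimizerConfig(seed=15, sweeps=80))
        rel[sigma] = float(np.nanmean(relative_error_per_locus(adj, noisy.observed, noisy.truth)))
    assert rel[100.0] < rel[50.0] < rel[25.0] < 1.0


def test_locus_without_partner_passes_through():
    rng = np.random.default_rng(39)
    pos = rng.normal(0, 50, size=(60, 3, 1))
    pos[5:, 2, 0] = np.nan  # locus 2 co-localized with others in only 5 traces
    ts = make_traceset(pos)
    em = ErrorModel.uniform(3, [20.0])
    with pytest.warns(UserWarning, match="passed through"):
        adj, diag = run_lear(ts, em, OptimizerConfig(seed=16, sweeps=30, min_n=50))
    assert (2, 0) in diag["skipped"]
    assert np.array_equal(adj.positions[:, 2, 0], pos[:, 2, 0], equal_nan=True)
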