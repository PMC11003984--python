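import numpy as np
import pytest
from scipy import stats

import coregrn as cg
from coregrn.data_model import (
    GeneNetwork,
    NetworkEdge,
    RacipeParams,
    SamplingRanges,
)
from coregrn.racipe_sim import (
    check_steady_states,
    estimate_median_threshold,
    sample_parameters,
    shifted_hill,
    simulate_ensemble,
    simulate_knockdown,
    simulate_model,
)


class TestShiftedHill:
    @pytest.mark.parametrize(
        "x,x0,n,lam,expected",
        [
            (0.0, 2.0, 3, 4.0, 1.0),  # absent regulator -> no modulation
            (2.0, 2.0, 3, 4.0, (1 + 4.0) / 2),  # at threshold -> halfway
            (2.0, 2.0, 5, 0.2, (1 + 0.2) / 2),
        ],
    )
    def test_identities(self, x, x0, n, lam, expected):
        assert shifted_hill(x, x0, n, lam) == pytest.approx(expected, abs=1e-12)

    def test_saturation(self):
        assert shifted_hill(100 * 2.0, 2.0, 6, 4.0) == pytest.approx(4.0, abs=1e-9)

    def test_range_bounds(self):
        x = np.linspace(0, 50, 200)
        act = shifted_hill(x, 5.0, 3, 10.0)
        inh = shifted_hill(x, 5.0, 3, 0.1)
        assert np.all(act >= 1.0) and np.all(act < 10.0)
        assert np.all(inh > 0.1) and np.all(inh <= 1.0)


class TestMedianThreshold:
    def test_degenerate_ranges_give_ratio(self):
        r = SamplingRanges(g=(1.0, 1.0 + 1e-12), k=(1.0, 1.0 + 1e-12))
        assert estimate_median_threshold(r) == pytest.approx(1.0, rel=1e-6)

    def test_matches_brute_force_median(self):
        """Default estimate agrees within 2% with a 10^6-draw brute force."""
        m = estimate_median_threshold()
        rng = np.random.default_rng(123456)
        brute = np.median(rng.uniform(1, 100, 1_000_000) / rng.uniform(0.1, 1, 1_000_000))
        assert m == pytest.approx(brute, rel=0.02)

    def test_scale_equivariance(self):
        base = estimate_median_threshold(seed=3)
        scaled = estimate_median_threshold(SamplingRanges(g=(3.0, 300.0)), seed=3)
        assert scaled == pytest.approx(3 * base, rel=1e-9)


class TestSampling:
    def test_hill_coefficients_uniform(self, toggle_net):
        params = sample_parameters(toggle_net, n_models=50_000, seed=1)
        ns = np.array([p.n for p in params]).ravel()
        for v in range(1, 7):
            assert np.mean(ns == v) == pytest.approx(1 / 6, abs=0.01)

    def test_inhibitory_fold_changes_are_reciprocals(self, toggle_net):
        params = sample_parameters(toggle_net, n_models=2000, seed=2)
        lams = np.array([p.lam for p in params]).ravel()
        assert np.all((lams > 0.01) & (lams < 1.0))

    def test_seed_reproducibility(self, toggle_net):
        a = sample_parameters(toggle_net, n_models=50, seed=9)
        b = sample_parameters(toggle_net, n_models=50, seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.g, pb.g) and np.array_equal(pa.x0, pb.x0)

    def test_ranges_respected(self, planted):
        params = sample_parameters(planted.network, n_models=500, seed=4)
        g = np.array([p.g for p in params])
        k = np.array([p.k for p in params])
        assert g.min() >= 1.0 and g.max() <= 100.0
        assert k.min() >= 0.1 and k.max() <= 1.0
        signs = np.array([e.sign for e in planted.network.edges])
        lam = np.array([p.lam for p in params])
        assert np.all(lam[:, signs > 0] > 1.0)
        assert np.all((lam[:, signs < 0] > 0) & (lam[:, signs < 0] < 1.0))


def _single_gene_params(g=10.0, k=0.5):
    return RacipeParams(
        g=np.array([g]),
        k=np.array([k]),
        n=np.array([], dtype=int),
        lam=np.array([]),
        x0=np.array([]),
    )


class TestSimulateModel:
    def test_isolated_gene_reaches_g_over_k(self):
        net = GeneNetwork(["A"])
        y, conv = simulate_model(net, _single_gene_params(), init=np.array([1.0]))
        assert conv
        # the convergence test allows a relative derivative of 1e-3, which
        # maps to a relative state error of the same order
        assert y[0] == pytest.approx(10.0 / 0.5, rel=5e-3)

    def test_saturated_activator_cancels_scaling(self):
        # A at its own steady state far above the threshold: Hs -> lam+, and the
        # 1/prod(lam+) normalization leaves B at exactly G_B/k_B
        net = GeneNetwork(
            ["A", "B"], [NetworkEdge("A", "B", 1, "curated", 0.9)]
        )
        params = RacipeParams(
            g=np.array([50.0, 20.0]),
            k=np.array([0.5, 0.4]),
            n=np.array([4]),
            lam=np.array([30.0]),
            x0=np.array([0.01]),  # threshold far below A's level
        )
        y, conv = simulate_model(net, params, init=np.array([1.0, 1.0]), t_max=200.0)
        assert conv
        assert y[1] == pytest.approx(20.0 / 0.4, rel=1e-2)

    def test_toggle_switch_bistability_matches_dense_init_oracle(self, toggle_net):
        """Strong symmetric mutual inhibition admits exactly two attractors.

        Oracle: fixed points found from a dense grid of initial conditions,
        deduplicated; the circuit must yield exactly two, each reachable."""
        params = RacipeParams(
            g=np.array([50.0, 50.0]),
            k=np.array([0.5, 0.5]),
            n=np.array([4, 4]),
            lam=np.array([0.02, 0.02]),
            x0=np.array([20.0, 20.0]),
        )
        fixed_points = []
        # offset grids so no initial condition sits exactly on the symmetric
        # manifold, where the (unstable) saddle would trap the dynamics
        for a0 in np.logspace(-1, 2.2, 8):
            for b0 in 1.37 * np.logspace(-1, 2.2, 8):
                y, conv = simulate_model(
                    toggle_net, params, init=np.array([a0, b0]), t_max=300.0
                )
                if conv and not any(np.allclose(y, fp, rtol=1e-2) for fp in fixed_points):
                    fixed_points.append(y)
        assert len(fixed_points) == 2
        # the two states are mirror images: one gene high, the other repressed
        hi = 50.0 / 0.5
        states = sorted(fixed_points, key=lambda y: y[0])
        assert states[1][0] == pytest.approx(hi, rel=0.05)
        assert states[0][1] == pytest.approx(hi, rel=0.05)

    def test_euler_and_rk45_agree(self, toggle_net):
        params = RacipeParams(
            g=np.array([50.0, 40.0]),
            k=np.array([0.5, 0.8]),
            n=np.array([3, 2]),
            lam=np.array([0.05, 0.1]),
            x0=np.array([20.0, 30.0]),
        )
        init = np.array([80.0, 1.0])
        y_e, conv_e = simulate_model(toggle_net, params, init=init, method="euler")
        y_r, conv_r = simulate_model(toggle_net, params, init=init, method="rk45")
        assert conv_e and conv_r
        assert np.allclose(y_e, y_r, rtol=1e-2)


class TestSimulateEnsemble:
    def test_one_gene_distribution_matches_g_over_k(self):
        """Without regulation the steady state is G/k, so the ensemble must be
        indistinguishable from direct G/k draws (two-sample KS)."""
        net = GeneNetwork(["A"])
        ens = simulate_ensemble(net, n_models=5000, seed=21)
        rng = np.random.default_rng(77)
        direct = rng.uniform(1, 100, 5000) / rng.uniform(0.1, 1, 5000)
        ks = stats.ks_2samp(ens.states[:, 0], direct)
        assert ks.pvalue > 0.01

    def test_bitwise_reproducible(self, toggle_net):
        a = simulate_ensemble(toggle_net, n_models=300, seed=5)
        b = simulate_ensemble(toggle_net, n_models=300, seed=5)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.converged, b.converged)

    def test_steady_states_positive_and_verified(self, planted_ensemble):
        ok = planted_ensemble.converged
        assert np.all(planted_ensemble.states[ok] > 0)
        # direct re-evaluation of the ODE right-hand side, independent of the
        # integrator path
        resid = check_steady_states(planted_ensemble)
        assert np.all(resid[ok] < 1e-3)

    def test_toggle_ensemble_forms_two_clusters(self, toggle_net):
        """Steady-state profiles of a toggle ensemble cluster into >= 2 groups
        under 1 - Spearman complete-linkage (silhouette sweep)."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform
        from sklearn.metrics import silhouette_score

        ens = simulate_ensemble(toggle_net, n_models=500, seed=8)
        x = ens.normalized()[ens.converged]
        rho = stats.spearmanr(x, axis=1).statistic
        dist = 1 - rho
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="complete")
        best_k, best_s = None, -2
        for k in range(2, 6):
            labels = fcluster(z, k, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            s = silhouette_score(dist, labels, metric="precomputed")
            if s > best_s:
                best_k, best_s = k, s
        assert best_k == 2
        assert best_s > 0.5


class TestKnockdown:
    def test_isolated_gene_scales_by_kd_factor(self):
        net = GeneNetwork(["A"])
        ens = simulate_ensemble(net, n_models=200, seed=3)
        kd = simulate_knockdown(net, ens, ["A"], kd_factor=0.95)
        ratio = kd.states[kd.converged & ens.converged, 0] / ens.states[
            kd.converged & ens.converged, 0
        ]
        assert np.allclose(ratio, 0.05, rtol=1e-2)

    def test_sink_gene_kd_leaves_upstream_unchanged(self):
        net = GeneNetwork(["A", "B"], [NetworkEdge("A", "B", 1, "curated", 0.9)])
        ens = simulate_ensemble(net, n_models=200, seed=6)
        kd = simulate_knockdown(net, ens, ["B"], kd_factor=0.95)
        both = ens.converged & kd.converged
        assert np.allclose(kd.states[both, 0], ens.states[both, 0], rtol=1e-9)

    def test_kd_factor_zero_is_identity(self, planted, planted_ensemble):
        kd = simulate_knockdown(planted.network, planted_ensemble, ["TFA01"], kd_factor=0.0)
        assert np.array_equal(kd.states, planted_ensemble.states)

    def test_unknown_gene_raises(self, planted, planted_ensemble):
        with pytest.raises(KeyError, match="NOPE"):
            simulate_knockdown(planted.network, planted_ensemble, ["NOPE"])

    def test_pairing_preserved(self, planted, planted_ensemble):
        kd = simulate_knockdown(planted.network, planted_ensemble, ["TFB01", "TFB02"])
        assert kd.n_models == planted_ensemble.n_models
        gi = planted_ensemble.genes.index("TFB01")
        for m in (0, 10, 500):
            assert kd.params[m].g[gi] == pytest.approx(
                0.05 * planted_ensemble.params[m].g[gi]
            )
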