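import numpy as np
import pytest
from scipy import stats

from paleoburden import abcdl


@pytest.fixture(scope="module")
def tree():
    return abcdl.default_tree()


@pytest.fixture(scope="module")
def priors():
    return abcdl.Priors()


class TestSampleTree:
    def test_default_has_eight_leaves(self, tree):
        assert sorted(tree.leaf_names) == sorted(abcdl.DEFAULT_LEAVES)

    def test_depths_increase_from_root(self, tree):
        depth = tree.depths()
        assert depth[0] == 0
        for i in range(1, tree.n_nodes):
            assert depth[i] > depth[tree.parent[i]]

    def test_config_round_trip(self, tree):
        back = abcdl.SampleTree.from_config(tree.to_config())
        assert back.names == tree.names
        np.testing.assert_array_equal(back.parent, tree.parent)
        np.testing.assert_array_equal(back.dt, tree.dt)

    def test_newick_contains_all_leaves(self, tree):
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for name in tree.leaf_names:
            assert name in nwk

    def test_rejects_bad_topology(self):
        with pytest.raises(ValueError):
            abcdl.SampleTree(
                names=["a", "b"], parent=np.array([1, -1]), dt=np.array([1.0, 0.0])
            )

    def test_shared_generations_diagonal_is_depth(self, tree):
        shared = tree.shared_generations()
        depth = tree.depths()[tree.leaf_indices]
        np.testing.assert_allclose(np.diag(shared), depth)


class TestSimulateBranch:
    def test_identity_when_no_drift_no_trend(self):
        rng = np.random.default_rng(0)
        f = np.linspace(0.1, 0.9, 50)
        out = abcdl.simulate_branch(f, 0.0, 0.0, 100.0, rng)
        np.testing.assert_array_equal(out, f)

    def test_deterministic_trend(self):
        rng = np.random.default_rng(0)
        out = abcdl.simulate_branch(np.array([0.5]), 1e-4, 0.0, 1000.0, rng)
        assert out[0] == pytest.approx(0.6)

    def test_clamped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        out = abcdl.simulate_branch(np.full(1000, 0.99), 1e-4, 1e-3, 500.0, rng)
        assert np.all(out <= 1.0) and np.all(out >= 0.0)

    def test_moments_match_closed_form(self):
        # mean gamma*dt, variance d*dt at interior frequencies (3 SE)
        rng = np.random.default_rng(2)
        n = 100000
        d, dt = 1e-6, 100.0
        f = np.full(n, 0.5)
        child = abcdl.simulate_branch(f, 0.0, d, dt, rng)
        inc = child - f
        var = d * dt
        se_mean = np.sqrt(var / n)
        se_var = var * np.sqrt(2.0 / (n - 1))
        assert abs(inc.mean()) < 3 * se_mean
        assert abs(inc.var(ddof=1) - var) < 3 * se_var

    def test_rejects_bad_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            abcdl.simulate_branch(np.array([0.5]), 0, 0, -1.0, rng)
        with pytest.raises(ValueError):
            abcdl.simulate_branch(np.array([1.5]), 0, 0, 1.0, rng)


class TestSimulateDataset:
    def test_star_tree_negative_trend_lowers_all_leaves(self):
        tr = abcdl.star_tree(["a", "b", "c"], [100.0, 200.0, 300.0])
        out = abcdl.simulate_dataset(
            tr, gamma=-1e-4, d=0.0, f0=np.full(100, 0.5), seed=3
        )
        assert np.all(out < 0.5)

    def test_sister_leaf_symmetry_at_zero_drift(self):
        tr = abcdl.star_tree(["a", "b"], [250.0, 250.0])
        out = abcdl.simulate_dataset(
            tr, gamma=5e-5, d=0.0, f0=np.full(60, 0.4), seed=4
        )
        assert out[0] == out[1]

    def test_leaf_covariance_matches_tree_paths(self, tree):
        # with fixed root frequencies, cov of leaf means across replicates is
        # d * shared_generations / n_loci (Brownian, no clamping)
        d, n_loci, reps = 1e-6, 300, 3000
        rng = np.random.default_rng(5)
        f0 = np.full((reps, n_loci), 0.5)
        out = abcdl.simulate_batch(
            tree, np.zeros(reps), np.full(reps, d), f0, rng
        )
        expected = d * tree.shared_generations() / n_loci
        observed = np.cov(out.T)
        se = np.sqrt(
            (np.outer(np.diag(expected), np.diag(expected)) + expected**2)
            / reps
        )
        assert np.all(np.abs(observed - expected) < 5 * se)

    def test_batch_deterministic(self, tree, priors):
        a = abcdl.simulate_dataset(tree, -5e-5, 1e-6, n_loci=50, seed=11)
        b = abcdl.simulate_dataset(tree, -5e-5, 1e-6, n_loci=50, seed=11)
        np.testing.assert_array_equal(a, b)


class TestPriorsAndReference:
    def test_gamma_bounds_must_be_symmetric(self):
        with pytest.raises(ValueError):
            abcdl.Priors(gamma_bounds=(-1e-4, 2e-4))

    def test_gamma_scaling_round_trip(self, priors):
        g = np.array([-1e-4, 0.0, 1e-4])
        np.testing.assert_allclose(
            priors.unscale_gamma(priors.scale_gamma(g)), g
        )

    def test_empty_table_error(self, tree, priors):
        with pytest.raises(ValueError):
            abcdl.generate_reference_table(priors, tree, n_sims=0)

    def test_fixed_seed_identical(self, tree, priors):
        a = abcdl.generate_reference_table(priors, tree, 50, n_loci=40, seed=6)
        b = abcdl.generate_reference_table(priors, tree, 50, n_loci=40, seed=6)
        np.testing.assert_array_equal(a.raw, b.raw)
        np.testing.assert_array_equal(a.gamma, b.gamma)

    def test_gamma_prior_uniform_by_ks(self, tree, priors):
        ref = abcdl.generate_reference_table(priors, tree, 10000, n_loci=10, seed=7)
        u = priors.scale_gamma(ref.gamma)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_standardisation(self, tree, priors):
        ref = abcdl.generate_reference_table(priors, tree, 500, n_loci=100, seed=8)
        z = ref.standardised()
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)


class TestElliottNet:
    def test_elliott01_midpoint(self):
        assert abcdl.elliott01(np.array([0.0]))[0] == pytest.approx(0.5)

    def test_elliott_range(self):
        x = np.linspace(-1000, 1000, 101)
        y = abcdl.elliott(x)
        assert np.all(y > -1) and np.all(y < 1)

    def test_gradient_matches_finite_differences(self):
        # backprop vs numeric differentiation of the full-batch MSE
        rng = np.random.default_rng(9)
        x = rng.standard_normal((20, 3))
        y = rng.random(20)
        net = abcdl.ElliottNet(3, hidden=(4, 3), seed=1)

        def loss():
            return float(np.mean((net.predict(x) - y) ** 2))

        yhat, acts, masks = net._forward_cached(x)
        err = (yhat - y)[:, None]
        n = len(y)
        last = len(net.weights) - 1
        deltas = None
        grads = [None] * len(net.weights)
        for li in range(last, -1, -1):
            z_in = np.column_stack([acts[li], np.ones(len(acts[li]))])
            if li == last:
                dz = 0.5 * abcdl._elliott_grad(net._pre_cache[li], net.slope)
                deltas = (2.0 / n) * err * dz
            else:
                back = deltas @ net.weights[li + 1][:-1, :].T
                deltas = back * abcdl._elliott_grad(net._pre_cache[li], net.slope)
            grads[li] = z_in.T @ deltas
        eps = 1e-6
        for li in (0, len(net.weights) - 1):
            w = net.weights[li]
            for idx in [(0, 0), (w.shape[0] - 1, w.shape[1] - 1)]:
                orig = w[idx]
                w[idx] = orig + eps
                up = loss()
                w[idx] = orig - eps
                dn = loss()
                w[idx] = orig
                fd = (up - dn) / (2 * eps)
                assert grads[li][idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_constant_target_learned(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((200, 4))
        y = np.full(200, 0.37)
        net = abcdl.ElliottNet(4, seed=2)
        mse = net.train_rprop(x, y, max_iter=2000, target_error=1e-4, dropout=0.0,
                              seed=3)
        assert mse <= 1e-4
        assert np.allclose(net.predict(x), 0.37, atol=0.05)


@pytest.fixture(scope="module")
def small_ensemble(tree, priors):
    ref = abcdl.generate_reference_table(priors, tree, 3000, n_loci=500, seed=20)
    ens = abcdl.train_summary_ensemble(
        ref, priors, n_nets=3, max_iter=3000, seed=21
    )
    return ref, ens


class TestEnsemble:
    def test_informative_on_fresh_validation(self, tree, priors, small_ensemble):
        _, ens = small_ensemble
        val = abcdl.generate_reference_table(priors, tree, 500, n_loci=500, seed=22)
        pred = ens.predict_scaled(val.raw)
        true = priors.scale_gamma(val.gamma)
        assert np.corrcoef(pred, true)[0, 1] > 0.7

    def test_component_predictions_shape(self, small_ensemble):
        ref, ens = small_ensemble
        comp = ens.predict_components(ref.raw[:10])
        assert comp.shape == (3, 10)
        np.testing.assert_allclose(
            comp.mean(axis=0), ens.predict_scaled(ref.raw[:10])
        )


class TestAbc:
    def test_retain_exceeds_pool_error(self, priors):
        with pytest.raises(ValueError):
            abcdl.abc_from_pool(0.5, np.zeros(10), np.zeros(10), priors, 11)

    def test_null_recovery_contains_zero(self, tree, priors, small_ensemble):
        _, ens = small_ensemble
        obs_raw = abcdl.simulate_dataset(
            tree, gamma=0.0, d=1e-8, n_loci=500, seed=30
        )
        pool_g, pool_s = abcdl.simulate_pool(
            priors, tree, ens, 5000, n_loci=500, seed=31
        )
        res = abcdl.abc_from_pool(
            float(ens.predict_scaled(obs_raw)[0]), pool_g, pool_s, priors, 200
        )
        lo, hi = res.credible_interval
        assert lo <= 0.0 <= hi

    def test_posterior_within_prior_support(self, tree, priors, small_ensemble):
        _, ens = small_ensemble
        obs_raw = abcdl.simulate_dataset(
            tree, gamma=9e-5, d=1e-5, n_loci=500, seed=32
        )
        pool_g, pool_s = abcdl.simulate_pool(
            priors, tree, ens, 3000, n_loci=500, seed=33
        )
        res = abcdl.abc_from_pool(
            float(ens.predict_scaled(obs_raw)[0]), pool_g, pool_s, priors, 300
        )
        lo, hi = priors.gamma_bounds
        assert np.all(res.posterior_draws >= lo)
        assert np.all(res.posterior_draws <= hi)
        assert lo <= res.credible_interval[0] <= res.credible_interval[1] <= hi


class TestFactor2:
    @pytest.mark.parametrize(
        "true,est,inside",
        [
            (1e-4, 1.5e-4, True),
            (1e-4, 2.5e-4, False),
            (1e-4, -1e-4, False),
            (-1e-4, -0.6e-4, True),
            (1e-4, 0.4e-4, False),
        ],
    )
    def test_cases(self, true, est, inside):
        out = abcdl.factor2([(true, est)])
        assert out["fraction"] == (1.0 if inside else 0.0)

    def test_floor_exclusion(self):
        out = abcdl.factor2([(1e-9, 5e-5), (1e-4, 1e-4)], floor=1e-6)
        assert out["n_excluded"] == 1
        assert out["n_used"] == 1


class TestArithmetic:
    def test_generations(self):
        assert round(abcdl.generations_from_years(45000)) == 1552

    def test_cumulative_shift(self):
        assert abcdl.cumulative_frequency_shift(-7.72e-5, 1552) == pytest.approx(
            -0.1198, abs=1e-4
        )

    def test_truncate(self):
        assert abcdl.truncate_decimals(0.1552, 2) == pytest.approx(0.15)
        assert abcdl.truncate_decimals(-0.159, 2) == pytest.approx(-0.15)
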