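import numpy as np
import pytest
from scipy import stats

from paleoburden import burden, synthdata, trend_tests
from paleoburden.io_formats import GwasTable
from tests.conftest import make_gwas_df, make_panel


def tau_b_oracle(x, y):
    """O(n^2) pair-counting Kendall tau-b with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                tie_x += 1
                tie_y += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tie_x) * (n0 - tie_y))
    return (conc - disc) / denom if denom > 0 else 0.0


class TestKendallTrend:
    def test_perfect_concordance_with_calendar_time(self):
        tau, _ = trend_tests.kendall_trend([3, 2, 1], [1000, 2000, 3000])
        assert tau == pytest.approx(1.0)

    def test_constant_burden_zero_tau(self):
        tau, _ = trend_tests.kendall_trend([1, 1, 1, 1], [1, 2, 3, 4])
        assert tau == 0.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=30).round(1)  # rounding makes ties
        age = rng.integers(1000, 40000, size=30).astype(float)
        tau, _ = trend_tests.kendall_trend(f, age)
        assert tau == pytest.approx(tau_b_oracle(-age, f))

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            trend_tests.kendall_trend([1, 2], [1, 2])

    def test_sign_flips_with_risk_flip(self):
        cfg = synthdata.SynthConfig(n_snps=50, samples_per_leaf=3, gamma=-5e-5)
        gwas, _ = synthdata.make_gwas(cfg, seed=4)
        panel = synthdata.make_ancient_panel(cfg, gwas, seed=5)
        risk = burden.orient_risk(gwas)
        flipped = gwas.df.copy()
        flipped["beta"] = -flipped["beta"]
        risk_f = burden.orient_risk(GwasTable(flipped))
        res = burden.f_adhd(panel, risk)
        res_f = burden.f_adhd(panel, risk_f)
        t1, _ = trend_tests.kendall_trend(res["f_adhd"], res["age_bp"])
        t2, _ = trend_tests.kendall_trend(res_f["f_adhd"], res_f["age_bp"])
        assert t1 == pytest.approx(-t2)


class TestFlipNull:
    def _setup(self, gamma=0.0, seed=30, n_snps=60):
        cfg = synthdata.SynthConfig(
            n_snps=n_snps, samples_per_leaf=3, missing_rate=0.2, gamma=gamma, d=0.0
        )
        gwas, _ = synthdata.make_gwas(cfg, seed=seed)
        panel = synthdata.make_ancient_panel(cfg, gwas, seed=seed + 1)
        return panel, burden.orient_risk(gwas)

    def test_deterministic_for_fixed_seed(self):
        panel, risk = self._setup()
        a = trend_tests.flip_null_trend(panel, risk, n=150, seed=7)
        b = trend_tests.flip_null_trend(panel, risk, n=150, seed=7)
        np.testing.assert_array_equal(a.null_draws, b.null_draws)
        assert a.p_empirical == b.p_empirical

    def test_warns_below_100_draws(self):
        panel, risk = self._setup()
        with pytest.warns(UserWarning, match="unstable"):
            trend_tests.flip_null_trend(panel, risk, n=50, seed=1)

    def test_null_symmetric_about_zero(self):
        panel, risk = self._setup()
        nd = trend_tests.flip_null_trend(panel, risk, n=400, seed=2)
        assert abs(np.mean(nd.null_draws)) < 4 * np.std(nd.null_draws) / 20

    def test_strong_decay_minimal_p(self):
        cfg = synthdata.SynthConfig(
            n_snps=200, samples_per_leaf=6, missing_rate=0.2, gamma=-7e-5, d=1e-8
        )
        gwas, _ = synthdata.make_gwas(cfg, seed=41)
        panel = synthdata.make_ancient_panel(cfg, gwas, seed=42)
        risk = burden.orient_risk(gwas)
        nd = trend_tests.flip_null_trend(panel, risk, n=999, seed=43)
        assert nd.observed < 0
        assert nd.p_empirical == pytest.approx(1 / 1000)

    def test_null_burden_algebra_matches_direct_recompute(self):
        # one explicit draw: flipping a known SNP subset equals recomputing
        # burdens from a re-oriented dosage matrix
        panel, risk = self._setup(n_snps=20)
        g, _ = burden.oriented_dosage(panel, risk)
        called = ~np.isnan(g)
        j = called.sum(axis=1)
        flip = np.zeros(g.shape[1], dtype=bool)
        flip[::3] = True
        g_flip = g.copy()
        ploidy = panel.ploidy[:, None]
        g_flip[:, flip] = ploidy - g[:, flip]
        f_direct = np.nansum(g_flip, axis=1) / j
        f_obs = np.nansum(g, axis=1) / j
        delta = np.where(called, ploidy - 2 * np.nan_to_num(g), 0.0)
        f_formula = f_obs + (delta @ flip.astype(float)) / j
        np.testing.assert_allclose(f_formula, f_direct)


class TestContinentRegression:
    def test_identical_distributions_zero_slope(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(1000, 9000, 400)
        f = 0.5 + 0.01 * rng.standard_normal(400)
        cont = np.array(["Africa", "Europe"] * 200)
        res = trend_tests.continent_regression(f, age, cont).set_index("term")
        assert abs(res.loc["continent[Europe]", "coef"]) < 0.005

    def test_offset_recovered(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(1000, 9000, 500)
        cont = np.array(["Africa"] * 250 + ["Europe"] * 250)
        f = 0.5 + 0.02 * (cont == "Europe") + 0.005 * rng.standard_normal(500)
        res = trend_tests.continent_regression(f, age, cont).set_index("term")
        assert res.loc["continent[Europe]", "coef"] == pytest.approx(0.02, abs=0.003)
        assert res.loc["continent[Europe]", "pvalue"] < 1e-6

    def test_collinear_design_warns(self):
        age = np.array([1000.0, 1000, 2000, 2000] * 10)
        cont = np.where(age == 1000, "Africa", "Europe")
        f = np.random.default_rng(2).random(40)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            trend_tests.continent_regression(f, age * 1e9, cont)


class TestPartialKendall:
    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(3)
        n = 300
        f = rng.random(n)
        hg = rng.random(n)
        age = rng.uniform(0, 10000, n)
        tau_p, p = trend_tests.partial_kendall(f, hg, age)
        assert abs(tau_p) < 0.1
        assert p > 0.01

    def test_confounder_largely_removed(self):
        # f and hg are (noisy) functions of age only; conditioning on age
        # should strip most of the raw association. (The standard partial-tau
        # formula does not vanish exactly under conditional independence, so
        # the assertion is a strong reduction, not zero.)
        rng = np.random.default_rng(4)
        n = 200
        age = rng.uniform(0, 10000, n)
        f = age / 10000 + 0.1 * rng.standard_normal(n)
        hg = age / 10000 + 0.1 * rng.standard_normal(n)
        raw = stats.kendalltau(f, hg).statistic
        tau_p, _ = trend_tests.partial_kendall(f, hg, age)
        assert raw > 0.6
        assert abs(tau_p) < raw / 2

    def test_matches_monte_carlo_oracle(self):
        # trivariate normal with known structure; oracle computes the same
        # partial formula from brute-force pair-counting taus
        rng = np.random.default_rng(5)
        n = 150
        z = rng.standard_normal(n)
        x = 0.6 * z + 0.8 * rng.standard_normal(n)
        y = -0.5 * z + 0.7 * rng.standard_normal(n) + 0.3 * x
        tau_p, _ = trend_tests.partial_kendall(x, y, -z)  # age = -z
        t_xy = tau_b_oracle(x, y)
        t_xz = tau_b_oracle(x, z)
        t_yz = tau_b_oracle(y, z)
        expected = (t_xy - t_xz * t_yz) / np.sqrt(
            (1 - t_xz**2) * (1 - t_yz**2)
        )
        assert tau_p == pytest.approx(expected, abs=1e-12)


class TestGroupCompare:
    def test_identical_groups(self):
        rng = np.random.default_rng(6)
        a = rng.random(80)
        w, p = trend_tests.group_compare(a, a.copy())
        assert 0.4 < p < 0.6

    def test_disjoint_supports_minimal_p(self):
        a = np.arange(10) + 100.0
        b = np.arange(8) * 1.0
        _, p = trend_tests.group_compare(a, b)
        from math import comb

        assert p == pytest.approx(1 / comb(18, 8))

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            a = rng.standard_normal(100) + 0.5
            b = rng.standard_normal(100)
            _, p = trend_tests.group_compare(a, b)
            hits += p < 0.05
        assert hits / 200 > 0.9


class TestWeightedKendall:
    def weighted_oracle(self, a, b, w):
        num = den = 0.0
        n = len(a)
        for i in range(n):
            for j in range(i + 1, n):
                pw = w[i] * w[j]
                num += pw * np.sign(a[i] - a[j]) * np.sign(b[i] - b[j])
                den += pw
        return num / den

    def test_equal_weights_reduce_to_tau_a(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(25), rng.standard_normal(25)
        tw = trend_tests.weighted_kendall(a, b, weights=np.full(25, 3.0))
        # tie-free data: tau-a == tau-b
        assert tw == pytest.approx(stats.kendalltau(a, b).statistic)

    def test_zero_weight_drops_snp(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        w = np.ones(12)
        w[5] = 0.0
        keep = np.ones(12, bool)
        keep[5] = False
        tw = trend_tests.weighted_kendall(a, b, weights=w)
        tr = trend_tests.weighted_kendall(
            a[keep], b[keep], weights=np.ones(11)
        )
        assert tw == pytest.approx(tr)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        w = rng.random(20)
        tw = trend_tests.weighted_kendall(a, b, weights=w)
        assert tw == pytest.approx(self.weighted_oracle(a, b, w))

    def test_default_weights_from_pvalues(self):
        rng = np.random.default_rng(11)
        a, b = rng.standard_normal(15), rng.standard_normal(15)
        p = rng.uniform(1e-6, 1, 15)
        tw = trend_tests.weighted_kendall(a, b, pvalues=p)
        assert tw == pytest.approx(
            trend_tests.weighted_kendall(a, b, weights=-np.log10(p))
        )


def test_empirical_p_never_zero():
    draws = np.linspace(-1, 1, 99)
    assert trend_tests.empirical_p(2.0, draws) == pytest.approx(1 / 100)
    assert trend_tests.empirical_p(-2.0, draws) == pytest.approx(1 / 100)


def test_null_distribution_invariants():
    with pytest.raises(ValueError):
        trend_tests.NullDistribution(0.0, np.zeros(10), 0.0, "flip_risk", 10, 0)
    with pytest.raises(ValueError):
        trend_tests.NullDistribution(0.0, np.zeros(9), 0.5, "flip_risk", 10, 0)
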