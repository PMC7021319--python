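"""ANOVA, effect size, power, allometry regression and the trajectory
permutation test."""

import numpy as np
import pytest
import scipy.stats

from talogm.dimorphism import (
    anova_two_group,
    cohens_d,
    fit_trajectory,
    pearson_r,
    permutation_trajectory_test,
    power_two_sample,
    sex_dimorphism_stats,
    trajectory_angle,
)
from talogm.errors import TalogmError


def _brute_force_anova(a, b):
    """Independent sums-of-squares computation."""
    all_ = np.concatenate([a, b])
    grand = all_.mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, len(all_) - 2
    return (ss_between / df1) / (ss_within / df2)


class TestAnova:
    def test_equal_means(self, rng):
        v = np.concatenate([rng.normal(size=20), rng.normal(size=20)])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        v[20:] += v[:20].mean() - v[20:].mean()
        s = anova_two_group(v, labels)
        assert s.F_statistic == pytest.approx(0.0, abs=1e-12)
        assert s.p_value == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups(self, rng):
        v = np.concatenate([rng.normal(0, 1e-3, 3), rng.normal(1, 1e-3, 3)])
        s = anova_two_group(v, np.array(["a"] * 3 + ["b"] * 3))
        assert s.p_value < 1e-6
        assert s.df == (1, 4)

    def test_matches_brute_force(self, rng):
        a, b = rng.normal(size=6), rng.normal(0.4, 1.2, size=6)
        s = anova_two_group(np.concatenate([a, b]), np.array(["a"] * 6 + ["b"] * 6))
        assert s.F_statistic == pytest.approx(_brute_force_anova(a, b), abs=1e-9)

    def test_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=10), rng.normal(0.5, size=12)
        s = anova_two_group(np.concatenate([a, b]), np.array(["a"] * 10 + ["b"] * 12))
        t, _ = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert s.F_statistic == pytest.approx(t**2, abs=1e-9)

    def test_singleton_group_rejected(self):
        with pytest.raises(TalogmError):
            anova_two_group(np.arange(4.0), np.array(["a", "b", "b", "b"]))


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)

    def test_definition(self):
        a = np.array([-1.0, 1.0])   # mean 0
        b = np.array([0.0, 2.0])    # mean 1, pooled SD 1... sd both sqrt(2)
        sp = np.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2))
        assert cohens_d(a, b) == pytest.approx(-1.0 / sp)

    def test_sign_flips_on_swap(self, rng):
        a, b = rng.normal(size=9), rng.normal(1, size=7)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(TalogmError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert power_two_sample(0.0, 20, 20, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_canonical_value(self):
        # d = 0.5, n = 64/64, alpha .05 -> ~0.80 (noncentral-t)
        assert power_two_sample(0.5, 64, 64) == pytest.approx(0.80, abs=0.01)

    def test_large_effect_saturates(self):
        assert power_two_sample(3.0, 10, 10) > 0.999

    def test_monotone_in_d_and_n(self):
        p = [power_two_sample(d, 30, 30) for d in (0.2, 0.5, 0.9)]
        assert p[0] < p[1] < p[2]
        q = [power_two_sample(0.5, n, n) for n in (10, 40, 160)]
        assert q[0] < q[1] < q[2]

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.power")
        expected = sm.TTestIndPower().power(0.7, nobs1=25, ratio=30 / 25, alpha=0.05)
        assert power_two_sample(0.7, 25, 30) == pytest.approx(expected, abs=1e-6)

    def test_invalid_alpha(self):
        with pytest.raises(TalogmError):
            power_two_sample(0.5, 10, 10, alpha=1.5)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = pearson_r(x, z)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(TalogmError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTrajectories:
    def test_exact_linear_recovery(self, rng):
        z = rng.normal(5.7, 0.1, 30)
        slope = rng.normal(size=12)
        x = np.outer(z, slope) + 3.0
        tr = fit_trajectory(x, z, np.array(["g"] * 30))
        np.testing.assert_allclose(tr["g"].coefficient_vector, slope, atol=1e-9)
        assert tr["g"].length == pytest.approx(
            np.linalg.norm(slope) * (z.max() - z.min())
        )

    def test_noise_slope_shrinks_with_n(self, rng):
        norms = []
        for n in (40, 4000):
            z = rng.normal(0, 0.1, n)
            x = rng.normal(size=(n, 10))
            tr = fit_trajectory(x, z, np.array(["g"] * n), length="norm")
            norms.append(tr["g"].length)
        assert norms[1] < norms[0]

    def test_angle_recovery_with_ten_percent_noise(self, rng):
        """Two generator slopes at 60 deg, noise SD 10% of the slope scale."""
        n, dims = 200, 20
        v1 = np.zeros(dims); v1[0] = 1.0
        v2 = np.zeros(dims); v2[0], v2[1] = np.cos(np.radians(60)), np.sin(np.radians(60))
        rows, zs, gs = [], [], []
        for g, v in (("a", v1), ("b", v2)):
            z = rng.normal(0, 1.0, n)
            rows.append(np.outer(z, v) + rng.normal(scale=0.1, size=(n, dims)))
            zs.append(z)
            gs += [g] * n
        tr = fit_trajectory(np.vstack(rows), np.concatenate(zs), np.array(gs))
        assert trajectory_angle(tr["a"], tr["b"]) == pytest.approx(60.0, abs=5.0)

    @pytest.mark.parametrize(
        "u,v,expected",
        [((1, 0), (1, 0), 0.0), ((1, 0), (0, 1), 90.0), ((1, 0), (-1, 0), 180.0)],
    )
    def test_angle_special_cases(self, u, v, expected):
        from talogm.dimorphism import AllometricTrajectory

        a = AllometricTrajectory("a", np.array(u, float), 1.0, (0, 1), 3)
        b = AllometricTrajectory("b", np.array(v, float), 1.0, (0, 1), 3)
        assert trajectory_angle(a, b) == pytest.approx(expected)
        assert trajectory_angle(b, a) == pytest.approx(expected)

    def test_constant_lncs_rejected(self):
        with pytest.raises(TalogmError, match="constant"):
            fit_trajectory(np.ones((6, 3)), np.ones(6), np.array(["g"] * 6))

    def test_angle_invariant_to_common_rotation(self, rng):
        n, dims = 50, 8
        z = rng.normal(0, 1, 2 * n)
        x = rng.normal(size=(2 * n, dims)) + np.outer(z, rng.normal(size=dims))
        g = np.array(["a"] * n + ["b"] * n)
        tr1 = fit_trajectory(x, z, g)
        q, _ = np.linalg.qr(rng.normal(size=(dims, dims)))
        tr2 = fit_trajectory(x @ q, z, g)
        assert trajectory_angle(tr1["a"], tr1["b"]) == pytest.approx(
            trajectory_angle(tr2["a"], tr2["b"]), abs=1e-8
        )


class TestPermutationTest:
    def _data(self, rng, n=40, dims=10):
        z = rng.normal(0, 0.5, 2 * n)
        x = np.outer(z, rng.normal(size=dims)) + rng.normal(size=(2 * n, dims))
        g = np.array(["a"] * n + ["b"] * n)
        return x, z, g

    def test_deterministic_under_seed(self, rng):
        x, z, g = self._data(rng)
        c1 = permutation_trajectory_test(x, z, g, n_perm=50, seed=7)
        c2 = permutation_trajectory_test(x, z, g, n_perm=50, seed=7)
        assert c1[0].angle_p == c2[0].angle_p
        assert c1[0].length_p == c2[0].length_p

    def test_p_values_in_unit_interval(self, rng):
        x, z, g = self._data(rng)
        c = permutation_trajectory_test(x, z, g, n_perm=99, seed=1)[0]
        assert 0 < c.angle_p <= 1
        assert 0 < c.length_p <= 1

    def test_single_permutation_floor(self, rng):
        """With n_perm = 1 the +1 correction pins p at 1 or 0.5."""
        x, z, g = self._data(rng)
        c = permutation_trajectory_test(x, z, g, n_perm=1, seed=1)[0]
        assert c.angle_p in (0.5, 1.0)

    def test_detects_orthogonal_trajectories(self, rng):
        n, dims = 100, 15
        v1 = np.zeros(dims); v1[0] = 1
        v2 = np.zeros(dims); v2[1] = 1
        z = rng.normal(0, 1, 2 * n)
        x = np.vstack(
            [
                np.outer(z[:n], v1) + rng.normal(scale=0.1, size=(n, dims)),
                np.outer(z[n:], v2) + rng.normal(scale=0.1, size=(n, dims)),
            ]
        )
        g = np.array(["a"] * n + ["b"] * n)
        c = permutation_trajectory_test(x, z, g, n_perm=200, seed=3)[0]
        assert c.angle_deg == pytest.approx(90.0, abs=5.0)
        assert c.angle_p < 0.05


def test_sex_dimorphism_stats_bundle(rng):
    values = np.concatenate([rng.normal(0, 1, 20), rng.normal(1.5, 1, 25)])
    sex = np.array(["F"] * 20 + ["M"] * 25)
    lncs = values * 0.1 + rng.normal(0, 0.05, 45)
    s = sex_dimorphism_stats(values, sex, lncs=lncs, variable="v")
    assert s.cohens_d < 0           # females smaller by construction
    assert 0 <= s.achieved_power <= 1
    assert s.pearson_r_vs_lncs > 0.5
    assert s.F_statistic == pytest.approx(
        _brute_force_anova(values[:20], values[20:]), abs=1e-9
    )
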