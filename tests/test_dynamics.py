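"""Change measures, PCA, downscaling regression, ANCOVA, CC and bootstrap."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as hst

from synmorph.data_model import Trajectory, ValidationError
from synmorph.dynamics import (
    DegeneracyError,
    InsufficientDataError,
    PairedChange,
    ancova_equal_slopes,
    bootstrap_sd,
    compute_changes,
    cross_correlation,
    pca_changes,
    size_pairs,
    size_regression,
)

area = hst.floats(min_value=1e-6, max_value=1e6)


def two_point_traj(a0_s, a1_s, a0_p=0.1, a1_p=0.1, spine_id="s"):
    return Trajectory(spine_id, "EE", ((0, a0_s, a0_p), (30, a1_s, a1_p)))


def make_change(x, y):
    return PairedChange("s", "EE", 30, 0, 0, 0, y, x, 0, 0)


class TestChangeMeasures:
    def test_no_change_gives_zeros(self):
        (c,) = compute_changes([two_point_traj(1.0, 1.0)], 30)
        assert c.d_abs_spine == c.d_norm_spine == c.d_pct_spine == 0.0

    def test_tripling_example(self):
        (c,) = compute_changes([two_point_traj(1.0, 3.0)], 30)
        assert c.d_abs_spine == pytest.approx(2.0)
        assert c.d_norm_spine == pytest.approx(0.5)  # (3-1)/(3+1)
        assert c.d_pct_spine == pytest.approx(200.0)

    def test_pooling_counts_both_windows(self):
        traj = Trajectory("s", "EE", ((0, 1.0, 0.1), (30, 1.1, 0.1), (60, 1.2, 0.1)))
        changes = compute_changes([traj], 30)
        assert len(changes) == 2
        assert sorted(c.t_start_min for c in changes) == [0, 30]

    def test_no_qualifying_pairs_warns_not_raises(self):
        traj = Trajectory("s", "EE", ((0, 1.0, 0.1),))
        with pytest.warns(UserWarning):
            assert compute_changes([traj], 30) == []

    @given(a=area, b=area)
    @settings(max_examples=200, deadline=None)
    def test_norm_change_bounded_and_antisymmetric(self, a, b):
        (fwd,) = compute_changes([two_point_traj(a, b)], 30)
        (rev,) = compute_changes([two_point_traj(b, a)], 30)
        assert abs(fwd.d_norm_spine) <= 1.0
        assert rev.d_norm_spine == pytest.approx(-fwd.d_norm_spine, abs=1e-12)


def rotation_scan_pca(pts, n_coarse=3600, refine_iters=80):
    """Brute-force PC1 by scanning/refining the projection angle."""
    centered = pts - pts.mean(axis=0)

    def var_along(theta):
        d = centered @ np.array([np.cos(theta), np.sin(theta)])
        return d.var(ddof=1)

    thetas = np.linspace(0, np.pi, n_coarse, endpoint=False)
    best = max(thetas, key=var_along)
    lo, hi = best - np.pi / n_coarse, best + np.pi / n_coarse
    gr = (np.sqrt(5) - 1) / 2
    for _ in range(refine_iters):  # golden-section maximization
        m1, m2 = hi - gr * (hi - lo), lo + gr * (hi - lo)
        if var_along(m1) < var_along(m2):
            lo = m1
        else:
            hi = m2
    theta = (lo + hi) / 2
    v1 = var_along(theta)
    v2 = var_along(theta + np.pi / 2)
    return np.array([np.cos(theta), np.sin(theta)]), v1, v2


class TestPCA:
    def test_collinear_points_degenerate_pc2(self):
        pts = [(1, 1), (-1, -1), (2, 2), (-2, -2)]
        res = pca_changes([make_change(x, y) for x, y in pts])
        assert res.pc1 == pytest.approx((2**-0.5, 2**-0.5))
        assert res.var_pc2 == pytest.approx(0.0, abs=1e-15)

    def test_isotropic_points_equal_variances(self):
        pts = [(1, 0), (-1, 0), (0, 1), (0, -1)]
        res = pca_changes([make_change(x, y) for x, y in pts])
        assert res.var_pc1 == pytest.approx(res.var_pc2)

    def test_matches_rotation_scan_oracle(self):
        rng = np.random.default_rng(7)
        cov = np.array([[1.0, 0.6], [0.6, 0.8]])
        pts = rng.multivariate_normal([0.2, -0.1], cov, size=200)
        res = pca_changes([make_change(x, y) for x, y in pts])
        v_oracle, var1, var2 = rotation_scan_pca(pts)
        assert res.var_pc1 == pytest.approx(var1, abs=1e-9)
        assert res.var_pc2 == pytest.approx(var2, abs=1e-9)
        assert abs(np.dot(res.pc1, v_oracle)) == pytest.approx(1.0, abs=1e-9)

    def test_trace_conservation(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((50, 2)) * [0.3, 0.1]
        res = pca_changes([make_change(x, y) for x, y in pts])
        marginals = pts.var(axis=0, ddof=1).sum()
        assert res.var_pc1 + res.var_pc2 == pytest.approx(marginals, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            pca_changes([make_change(0, 0), make_change(1, 1)])

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegeneracyError):
            pca_changes([make_change(1, 1)] * 5)


class TestSizeRegression:
    def test_identity_dynamics(self):
        res = size_regression([(1, 1), (2, 2), (3, 3)])
        assert (res.slope, res.intercept, res.r) == (1.0, 0.0, 1.0)
        assert res.regression_to_mean_slope == 0.0

    def test_exact_affine_map(self):
        pairs = [(x, 0.5 * x + 0.1) for x in (0.2, 0.5, 1.0, 2.0)]
        res = size_regression(pairs)
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.1)

    def test_zero_variance_in_x(self):
        with pytest.raises(DegeneracyError):
            size_regression([(1, 1), (1, 2), (1, 3)])


class TestAncova:
    def _noisy_group(self, slope, n, seed, sd=0.01):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.2, 2.0, n)
        return np.column_stack([x, slope * x + 0.1 + sd * rng.standard_normal(n)])

    def test_identical_groups_zero_statistic(self):
        g = self._noisy_group(0.8, 50, 0)
        res = ancova_equal_slopes(g, g)
        assert res.slope_diff == 0.0 and res.t == 0.0

    def test_clearly_different_slopes(self):
        a = self._noisy_group(0.5, 100, 1)
        b = self._noisy_group(1.0, 100, 2)
        assert ancova_equal_slopes(a, b).p < 1e-6

    def test_exchanging_groups_flips_sign(self):
        a = self._noisy_group(0.7, 60, 3, sd=0.05)
        b = self._noisy_group(0.9, 80, 4, sd=0.05)
        r_ab, r_ba = ancova_equal_slopes(a, b), ancova_equal_slopes(b, a)
        assert r_ba.t == pytest.approx(-r_ab.t)
        assert r_ba.p == pytest.approx(r_ab.p)

    def test_matches_statsmodels_interaction_fit(self):
        # independent route: OLS y ~ x * group, Wald t on the interaction
        a = self._noisy_group(0.6, 40, 5, sd=0.08)
        b = self._noisy_group(0.75, 55, 6, sd=0.08)
        ours = ancova_equal_slopes(a, b)
        x = np.concatenate([a[:, 0], b[:, 0]])
        y = np.concatenate([a[:, 1], b[:, 1]])
        g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
        X = sm.add_constant(np.column_stack([x, g, x * g]))
        fit = sm.OLS(y, X).fit()
        assert ours.t == pytest.approx(-fit.tvalues[3], rel=1e-10)
        assert ours.p == pytest.approx(fit.pvalues[3], rel=1e-10)
        assert ours.df == pytest.approx(fit.df_resid)


def three_spine_set():
    """Hand-sized fixture: 3 spines × 2 time points."""
    data = {
        "a": ((0, 1.0, 0.30), (30, 1.2, 0.35)),
        "b": ((0, 0.5, 0.10), (30, 0.4, 0.12)),
        "c": ((0, 0.8, 0.22), (30, 0.9, 0.18)),
    }
    return [Trajectory(k, "EE", v) for k, v in data.items()]


class TestCrossCorrelation:
    def test_identical_channels_unity_at_zero_lag(self):
        trajs = [
            Trajectory(k, "EE", ((0, a, a), (30, b, b)))
            for k, (a, b) in {"a": (1.0, 1.2), "b": (0.4, 0.3), "c": (0.7, 0.9)}.items()
        ]
        assert cross_correlation(trajs, 0).cc == pytest.approx(1.0)

    def test_exact_anti_relation_minus_one(self):
        trajs = [
            Trajectory(k, "EE", ((0, a, 2.0 - a),))
            for k, a in {"a": 0.3, "b": 0.9, "c": 1.4}.items()
        ]
        assert cross_correlation(trajs, 0).cc == pytest.approx(-1.0)

    def test_zero_lag_equals_pearson_on_pooled_pairs(self, default_cohort):
        spine = np.array([s[1] for t in default_cohort for s in t.samples])
        psd = np.array([s[2] for t in default_cohort for s in t.samples])
        pearson = np.corrcoef(spine, psd)[0, 1]
        cc = cross_correlation(default_cohort, 0).cc
        assert cc == pytest.approx(pearson, abs=1e-9)

    def test_matches_hand_evaluated_formula_at_lag_30(self):
        trajs = three_spine_set()
        # direct evaluation of the lagged sum formula over the 3 usable pairs
        a1_lag = np.array([1.2, 0.4, 0.9])  # spine at t+30
        a1_base = np.array([1.0, 0.5, 0.8])  # spine at t
        a2_base = np.array([0.30, 0.10, 0.22])  # PSD at t
        m1 = np.mean(np.concatenate([a1_lag, a1_base]))
        m2 = a2_base.mean()
        num = ((a1_lag - m1) * (a2_base - m2)).sum()
        den = np.sqrt(((a1_base - m1) ** 2).sum() * ((a2_base - m2) ** 2).sum())
        res = cross_correlation(trajs, 30)
        assert res.cc == pytest.approx(num / den, abs=1e-12)
        assert res.n_pairs == 3

    def test_negative_lag_lags_psd_channel(self):
        trajs = three_spine_set()
        fwd = cross_correlation(trajs, 30)
        bwd = cross_correlation(trajs, -30)
        assert fwd.n_pairs == bwd.n_pairs == 3
        assert fwd.cc != pytest.approx(bwd.cc)  # asymmetric fixture

    def test_symmetrized_variant_reported(self, default_cohort):
        res = cross_correlation(default_cohort, 30)
        assert -1.0 <= res.cc_symmetrized <= 1.0

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            cross_correlation(three_spine_set(), 60)


class TestBootstrap:
    @staticmethod
    def _mean_spine_t0(trajs):
        return float(np.mean([t.samples[0][1] for t in trajs]))

    def test_constant_data_zero_sd(self):
        trajs = [two_point_traj(1.0, 1.0, spine_id=f"s{i}") for i in range(20)]
        assert bootstrap_sd(self._mean_spine_t0, trajs, n_boot=50, seed=0) == 0.0

    def test_matches_analytic_se_of_mean(self):
        rng = np.random.default_rng(3)
        areas = np.exp(0.3 * rng.standard_normal(400))
        trajs = [
            Trajectory(f"s{i}", "EE", ((0, float(a), 0.1),))
            for i, a in enumerate(areas)
        ]
        sd = bootstrap_sd(self._mean_spine_t0, trajs, n_boot=2000, seed=1)
        analytic = areas.std(ddof=1) / np.sqrt(len(areas))
        assert sd == pytest.approx(analytic, rel=0.15)

    def test_deterministic_per_seed(self):
        trajs = three_spine_set()
        run = lambda: bootstrap_sd(self._mean_spine_t0, trajs, n_boot=100, seed=9)
        assert run() == run()

    def test_size_pairs_channels_differ(self):
        trajs = three_spine_set()
        assert size_pairs(trajs, 30, "spine") == [(1.0, 1.2), (0.5, 0.4), (0.8, 0.9)]
        assert size_pairs(trajs, 30, "psd") == [(0.30, 0.35), (0.10, 0.12), (0.22, 0.18)]
        with pytest.raises(ValidationError):
            size_pairs(trajs, 30, "brightness")
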