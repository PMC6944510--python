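"""Wald/IVW/Egger/weighted-median/PC-gIVW estimators against independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from cismr import (
    LDMatrix,
    egger,
    funnel_data,
    ivw,
    leave_one_out,
    pc_givw,
    wald_ratio,
    weighted_median,
)
from cismr.estimators import Z95, _weighted_median
from cismr.exceptions import CollinearInstrumentsError, InsufficientInstrumentsError
from conftest import make_hset, random_hset


def wls_origin_oracle(h):
    """Weighted least squares of Gamma on gamma through the origin (statsmodels)."""
    res = sm.WLS(h.Gamma, h.gamma[:, None], weights=h.se_y**-2.0).fit()
    se_fixed = float(res.bse[0] / np.sqrt(res.scale))  # unscaled (fixed-effect) SE
    return float(res.params[0]), se_fixed


def brute_force_weighted_median(ratios, weights):
    """Scan interpolation breakpoints of the cumulative-weight staircase."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    for j in range(len(r) - 1):
        if s[j] <= 0.5 <= s[j + 1]:
            frac = (0.5 - s[j]) / (s[j + 1] - s[j])
            return float(r[j] + frac * (r[j + 1] - r[j]))
    return float(r[-1])


class TestWald:
    def test_null_numerator(self):
        est = wald_ratio(0.1, 0.0, 0.1)
        assert est.theta == 0.0 and est.se == pytest.approx(1.0)

    def test_hand_example(self):
        est = wald_ratio(0.05, 0.02, 0.01)
        assert est.theta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.2)

    def test_orientation_invariance(self):
        assert wald_ratio(0.05, 0.02, 0.01).theta == wald_ratio(-0.05, -0.02, 0.01).theta

    def test_zero_gamma_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.1, 0.1)


class TestIVW:
    def test_single_variant_equals_wald(self):
        h = make_hset([0.05], [0.02], se_y=[0.01])
        est, wald = ivw(h), wald_ratio(0.05, 0.02, 0.01)
        assert est.theta == pytest.approx(wald.theta)
        assert est.se == pytest.approx(wald.se)

    def test_hand_example(self):
        h = make_hset([0.1, 0.1], [0.01, 0.03], se_y=[0.01, 0.01])
        est = ivw(h)
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(1.0 / np.sqrt(200.0))

    def test_equals_wls_through_origin(self, rng):
        h = random_hset(rng, J=20)
        theta, se = wls_origin_oracle(h)
        est = ivw(h)
        assert est.theta == pytest.approx(theta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_ci_width(self, rng):
        est = ivw(random_hset(rng))
        assert est.ci_high - est.ci_low == pytest.approx(2 * Z95 * est.se)
        assert est.ci_low <= est.theta <= est.ci_high

    def test_zero_variants_rejected(self):
        h = make_hset([0.1], [0.1]).subset([])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)


class TestEgger:
    def test_exact_interpolation(self):
        g = np.array([0.02, 0.05, 0.09])
        h = make_hset(g, 0.01 + 0.3 * g)
        est, diag = egger(h)
        assert est.theta == pytest.approx(0.3, abs=1e-12)
        assert diag.intercept == pytest.approx(0.01, abs=1e-12)

    def test_two_variants_refused(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.01, 0.02]))

    def test_collinear_refused(self):
        with pytest.raises(CollinearInstrumentsError):
            egger(make_hset([0.1, 0.1, -0.1], [0.01, 0.02, 0.03]))

    def test_single_variant_reorientation_invariance(self, rng):
        h = random_hset(rng, J=10)
        est1, diag1 = egger(h)
        df = h.df.copy()
        df.loc[3, ["gamma", "Gamma"]] = -df.loc[3, ["gamma", "Gamma"]].astype(float)
        h2 = type(h)(df=df, exposure_scale=h.exposure_scale, outcome_scale=h.outcome_scale)
        est2, diag2 = egger(h2)
        assert est2.theta == pytest.approx(est1.theta, abs=1e-12)
        assert diag2.intercept == pytest.approx(diag1.intercept, abs=1e-12)

    def test_matches_statsmodels_wls(self, rng):
        h = random_hset(rng, J=30)
        sign = np.where(h.gamma < 0, -1.0, 1.0)
        X = sm.add_constant(h.gamma * sign)
        res = sm.WLS(h.Gamma * sign, X, weights=h.se_y**-2.0).fit()
        est, diag = egger(h)
        assert est.theta == pytest.approx(float(res.params[1]), abs=1e-10)
        assert diag.intercept == pytest.approx(float(res.params[0]), abs=1e-10)
        scale = np.sqrt(res.scale)
        assert est.se == pytest.approx(float(res.bse[1]) / scale, abs=1e-10)
        assert diag.intercept_se == pytest.approx(float(res.bse[0]) / scale, abs=1e-10)

    def test_i2_gx_hand_value(self):
        # gamma (0.1, 0.2, 0.3), se_x 0.01 each: Q_GX = 200, I2 = (200-2)/200
        h = make_hset([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], se_x=[0.01] * 3)
        _, diag = egger(h)
        assert diag.i2_gx == pytest.approx(0.99)

    def test_i2_gx_floored_at_zero(self):
        h = make_hset([0.10, 0.11, 0.12], [0.01, 0.02, 0.03], se_x=[1.0] * 3)
        _, diag = egger(h)
        assert diag.i2_gx == 0.0

    def test_slope_equals_ivw_when_intercept_zero(self):
        # symmetric construction forcing a zero fitted intercept
        g = np.array([0.02, 0.05, 0.09])
        h = make_hset(g, 0.3 * g)
        est, diag = egger(h)
        assert diag.intercept == pytest.approx(0.0, abs=1e-15)
        assert est.theta == pytest.approx(ivw(h).theta, abs=1e-12)


class TestWeightedMedian:
    def test_plain_median_equal_weights(self):
        h = make_hset([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], se_y=[0.01] * 3)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.theta == pytest.approx(0.2)

    def test_matches_brute_force_oracle_unequal_weights(self):
        g = np.array([0.05, 0.1, 0.2, 0.08, 0.12])
        G = np.array([0.01, 0.05, 0.02, 0.03, 0.04])
        sy = np.array([0.01, 0.02, 0.01, 0.03, 0.015])
        h = make_hset(g, G, se_y=sy)
        expected = brute_force_weighted_median(G / g, g**2 / sy**2)
        assert weighted_median(h, n_boot=50, seed=1).theta == pytest.approx(expected)

    def test_bootstrap_se_reproducible(self, rng):
        h = random_hset(rng, J=10)
        a = weighted_median(h, n_boot=100, seed=7)
        b = weighted_median(h, n_boot=100, seed=7)
        assert a.se == b.se

    def test_fewer_than_three_refused(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_hset([0.1, 0.2], [0.01, 0.02]), n_boot=10, seed=0)


def random_ld(rng, J):
    x = rng.normal(size=(4 * J, J)) @ rng.normal(size=(J, J))
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


class TestPCgIVW:
    def test_identity_ld_equals_ivw(self, rng):
        h = random_hset(rng, J=10)
        ld = LDMatrix.identity(h.keys)
        est = pc_givw(h, ld, kappa=1.0)
        ref = ivw(h)
        assert est.theta == pytest.approx(ref.theta, abs=1e-10)
        assert est.se == pytest.approx(ref.se, abs=1e-10)
        assert est.n_components == 10

    def test_duplicated_variant_adds_no_information(self):
        h1 = make_hset([0.05], [0.02], se_y=[0.01])
        h2 = make_hset([0.05, 0.05], [0.02, 0.02], se_y=[0.01, 0.01])
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        est = pc_givw(h2, LDMatrix(h2.keys, r, 100), kappa=0.99)
        ref = ivw(h1)
        assert est.theta == pytest.approx(ref.theta, abs=1e-10)
        assert est.se == pytest.approx(ref.se, abs=1e-10)
        assert est.n_components == 1

    def test_full_rank_kappa_one_matches_direct_gls(self, rng):
        J = 10
        h = random_hset(rng, J=J)
        r = random_ld(rng, J)
        ld = LDMatrix(h.keys, r, 100)
        omega = np.outer(h.se_y, h.se_y) * r
        oinv = np.linalg.inv(omega)
        denom = float(h.gamma @ oinv @ h.gamma)
        theta = float(h.gamma @ oinv @ h.Gamma) / denom
        est = pc_givw(h, ld, kappa=1.0)
        assert est.theta == pytest.approx(theta, abs=1e-10)
        assert est.se == pytest.approx(denom**-0.5, abs=1e-10)

    def test_se_nonincreasing_in_kappa(self, rng):
        J = 12
        h = random_hset(rng, J=J)
        ld = LDMatrix(h.keys, random_ld(rng, J), 100)
        ses = [pc_givw(h, ld, kappa=k).se for k in (0.9, 0.99, 0.999, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(ses, ses[1:]))

    def test_kappa_recorded(self, rng):
        h = random_hset(rng, J=8)
        est = pc_givw(h, LDMatrix.identity(h.keys), kappa=0.9)
        assert est.kappa == 0.9
        assert 1 <= est.n_components <= 8


class TestDiagnostics:
    def test_leave_one_out_cardinality(self, rng):
        h = random_hset(rng, J=6)
        tbl = leave_one_out(h, "ivw")
        assert len(tbl) == 6
        assert set(tbl["omitted_key"]) == set(h.keys)

    def test_identical_variants_give_equal_rows(self):
        h = make_hset([0.1] * 4, [0.03] * 4, se_y=[0.01] * 4)
        tbl = leave_one_out(h, "ivw")
        assert tbl["theta"].nunique() == 1
        assert tbl["theta"].iloc[0] == pytest.approx(0.3)

    def test_outlier_omission_moves_estimate_most(self):
        g = np.array([0.1, 0.1, 0.1, 0.1, 0.1])
        G = np.array([0.03, 0.031, 0.029, 0.03, 0.25])  # last ratio is a gross outlier
        h = make_hset(g, G, se_y=[0.01] * 5)
        full = ivw(h).theta
        tbl = leave_one_out(h, "ivw")
        deltas = (tbl["theta"] - full).abs()
        assert tbl.loc[deltas.idxmax(), "omitted_key"] == h.keys[-1]

    def test_funnel_definition(self, rng):
        h = random_hset(rng, J=8)
        tbl = funnel_data(h)
        assert len(tbl) == 8
        np.testing.assert_allclose(tbl["precision"], np.abs(h.gamma) / h.se_y)
        np.testing.assert_allclose(tbl["theta_j"], h.Gamma / h.gamma)

    def test_funnel_weighted_mean_equals_ivw(self, rng):
        h = random_hset(rng, J=15)
        tbl = funnel_data(h)
        w = tbl["precision"] ** 2
        pooled = float((w * tbl["theta_j"]).sum() / w.sum())
        assert pooled == pytest.approx(ivw(h).theta, abs=1e-12)
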