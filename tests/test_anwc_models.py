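"""The four AnWC/AnC models and their algebraic identities."""

import numpy as np
import pytest

from anwc.anwc_models import (
    MODEL_CP,
    MODEL_GE_LAST,
    anaerobic_mr,
    anaerobic_po,
    critical_power_3ao,
    estimate_all_models,
    fit_po_mr_regression,
    instantaneous_ge,
    required_mr_ge_last,
    required_mr_regression,
    w_prime,
)
from anwc.core_data_io import ModelConfig
from anwc.energetics import BaselineResult


def make_tt_profile(peak=730.0, end=353.0, tau=35.0, n=180):
    t = np.arange(n, dtype=float)
    return end + (peak - end) * np.exp(-t / tau)


class TestRegression:
    def test_exact_line_recovered(self):
        po = np.array([100.0, 150, 200, 250, 300, 350, 400])
        mr = 4.0 * po + 2.0
        reg = fit_po_mr_regression(po, mr)
        assert reg.slope == pytest.approx(4.0, rel=1e-12)
        assert reg.intercept == pytest.approx(2.0, rel=1e-9)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.see == pytest.approx(0.0, abs=1e-9)

    def test_delta_efficiency_from_printed_slope(self):
        po = np.linspace(100, 300, 7)
        reg = fit_po_mr_regression(po, 4.14 * po + 150.0)
        assert 100 * reg.delta_efficiency == pytest.approx(24.2, abs=0.05)

    def test_on_line_baseline_leaves_fit_unchanged(self):
        po = np.array([120.0, 160, 200, 240, 280, 320, 360])
        mr = 4.1 * po + 155.0
        base = BaselineResult(mr_bl=155.0, vo2_bl=0.45, rer_bl=0.85)
        with_b = fit_po_mr_regression(po, mr, baseline=base)
        without = fit_po_mr_regression(po, mr)
        assert with_b.slope == pytest.approx(without.slope, rel=1e-12)
        assert with_b.intercept == pytest.approx(without.intercept, rel=1e-12)
        assert with_b.n_points == without.n_points + 1

    def test_see_uses_n_minus_2(self, rng):
        po = np.linspace(100, 400, 7)
        mr = 4.0 * po + 150 + rng.normal(0, 5, size=7)
        reg = fit_po_mr_regression(po, mr)
        resid = mr - reg.predict(po)
        assert reg.see == pytest.approx(np.sqrt(np.sum(resid**2) / 5), rel=1e-12)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_po_mr_regression([200.0, 200.0, 200.0], [800.0, 810.0, 805.0])


class TestRequiredMr:
    def test_regression_form(self):
        po = np.linspace(100, 300, 7)
        reg = fit_po_mr_regression(po, 4.14 * po + 1.94)
        assert required_mr_regression(reg, np.array([0.0]))[0] == pytest.approx(1.94)
        # per-kg group means: slope 4.14, intercept 1.94, mean TT PO 5.43
        assert reg.slope * 5.43 + reg.intercept == pytest.approx(24.42, abs=0.01)

    def test_ge_last_form(self):
        np.testing.assert_allclose(
            required_mr_ge_last(0.20, np.array([400.0])), [2000.0]
        )
        # printed GE_LAST 21.1% at printed mean TT PO 5.43 W/kg
        assert required_mr_ge_last(0.211, np.array([5.43]))[0] == pytest.approx(
            25.7, abs=0.05
        )
        np.testing.assert_allclose(required_mr_ge_last(0.2, np.array([0.0])), [0.0])

    def test_nonpositive_ge_rejected(self):
        with pytest.raises(ValueError):
            required_mr_ge_last(0.0, np.array([100.0]))


class TestInstantaneousGe:
    def test_zero_intercept_gives_constant_ge(self):
        po = make_tt_profile()
        ge = instantaneous_ge(po, po / 0.21)
        np.testing.assert_allclose(ge, 0.21, rtol=1e-12)

    def test_positive_intercept_means_ge_increases_with_po(self):
        po = np.linspace(100, 700, 50)
        ge = instantaneous_ge(po, 4.1 * po + 150.0)
        assert np.all(np.diff(ge) > 0)


class TestIntegrals:
    def test_anc_zero_when_no_deficit(self):
        m = np.full(180, 1500.0)
        _, anc = anaerobic_mr(m, m)
        assert anc == 0.0

    def test_anc_linear_in_deficit(self):
        req, ae = np.full(180, 25.8), np.full(180, 17.78)
        _, anc = anaerobic_mr(req, ae)
        assert anc / 1000 == pytest.approx(1.44, abs=0.005)  # kJ per kg
        _, anc2 = anaerobic_mr(2 * req - ae, ae)
        assert anc2 == pytest.approx(2 * anc, rel=1e-12)

    def test_anwc_pointwise(self):
        po_an, anwc = anaerobic_po(
            np.array([400.0]), np.array([1000.0]), np.array([0.22])
        )
        assert po_an[0] == pytest.approx(180.0)
        assert anwc == pytest.approx(180.0)

    def test_aerobic_only_power_gives_zero_anwc(self):
        ae = np.full(180, 1200.0)
        ge = np.full(180, 0.21)
        _, anwc = anaerobic_po(ae * ge, ae, ge)
        assert anwc == pytest.approx(0.0, abs=1e-9)

    def test_clamping_removes_negative_contributions(self):
        req = np.array([10.0, 30.0])
        ae = np.array([20.0, 20.0])
        signed, anc_s = anaerobic_mr(req, ae)
        clamped, anc_c = anaerobic_mr(req, ae, clamp_negative=True)
        assert signed[0] == -10.0 and clamped[0] == 0.0
        assert anc_c > anc_s

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            anaerobic_mr(np.zeros(5), np.zeros(6))


class TestCriticalPower:
    def test_constant_series(self):
        assert critical_power_3ao(np.full(180, 300.0)) == 300.0

    def test_step_profile(self):
        po = np.concatenate([np.full(150, 400.0), np.full(30, 300.0)])
        assert critical_power_3ao(po) == 300.0

    def test_equals_tail_slice_mean_on_decay_profile(self):
        po = make_tt_profile()
        assert critical_power_3ao(po) == pytest.approx(po[-30:].mean(), rel=1e-15)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            critical_power_3ao(np.full(179, 300.0))


class TestWPrime:
    def test_zero_when_po_equals_cp(self):
        assert w_prime(np.full(180, 300.0), 300.0) == 0.0

    def test_step_profile_analytic(self):
        po = np.concatenate([np.full(150, 400.0), np.full(30, 300.0)])
        assert w_prime(po, 300.0) == pytest.approx(15000.0)

    def test_signed_identity_mean_po_minus_cp(self):
        po = make_tt_profile()
        cp = critical_power_3ao(po)
        assert w_prime(po, cp) == pytest.approx((po.mean() - cp) * 180, rel=1e-12)

    def test_signed_vs_clamped_differ_only_below_cp(self):
        po = make_tt_profile()  # strictly decaying: po >= cp until the tail
        cp = critical_power_3ao(po)
        dips = np.sum(np.minimum(po - cp, 0.0))
        assert w_prime(po, cp, clamp_below_cp=True) == pytest.approx(
            w_prime(po, cp) - dips, rel=1e-12
        )


class TestEstimateAllModels:
    def setup_method(self):
        self.po = make_tt_profile()
        self.t = np.arange(180.0)
        self.mr_ae = np.minimum(4.1 * self.po + 150, 1750.0) * (
            1 - np.exp(-(self.t + 1) / 25.0)
        )
        self.reg = fit_po_mr_regression(
            np.linspace(120, 360, 7), 4.1 * np.linspace(120, 360, 7) + 150
        )

    def test_ge_last_identity_anwc_equals_ge_times_anc(self):
        decomps, errors = estimate_all_models(
            self.t, self.po, self.mr_ae, ModelConfig(), ge_last=0.2129
        )
        assert not any(m in errors for m in (MODEL_GE_LAST, MODEL_CP))
        d = decomps[MODEL_GE_LAST]
        assert d.anwc == pytest.approx(0.2129 * d.anc, rel=1e-9)

    def test_zero_intercept_regression_equals_ge_method(self):
        po7 = np.linspace(120, 360, 7)
        reg0 = fit_po_mr_regression(po7, po7 / 0.21)  # zero intercept line
        decomps, _ = estimate_all_models(
            self.t,
            self.po,
            self.mr_ae,
            ModelConfig(models=("7-Y_LIN", "GE_LAST")),
            reg_without_baseline=reg0,
            ge_last=1.0 / reg0.slope,
        )
        assert decomps["7-Y_LIN"].anwc == pytest.approx(
            decomps["GE_LAST"].anwc, rel=1e-9
        )
        np.testing.assert_allclose(
            decomps["7-Y_LIN"].ge_inst, 1.0 / reg0.slope, rtol=1e-9
        )

    def test_missing_inputs_skip_models_but_cp_runs(self):
        decomps, errors = estimate_all_models(
            self.t, self.po, self.mr_ae, ModelConfig()
        )
        assert list(decomps) == [MODEL_CP]
        assert set(errors) == {"7+Y_LIN", "7-Y_LIN", "GE_LAST"}

    def test_time_origin_invariance(self):
        kw = dict(
            config=ModelConfig(),
            reg_with_baseline=None,
            reg_without_baseline=self.reg,
            ge_last=0.21,
        )
        d1, _ = estimate_all_models(self.t, self.po, self.mr_ae, **kw)
        d2, _ = estimate_all_models(self.t + 2580.0, self.po, self.mr_ae, **kw)
        for m in d1:
            assert d1[m].anwc == pytest.approx(d2[m].anwc, rel=1e-14)
            if d1[m].anc is not None:
                assert d1[m].anc == pytest.approx(d2[m].anc, rel=1e-14)
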