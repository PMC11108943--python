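"""A/C_i curve recomputation, FvCB parameter fitting, and the CV
comparison statistic."""

import numpy as np
import pytest

from cutigas import (
    FvCBParams,
    NoiseSpec,
    delta_cv,
    delta_cv_from_summary,
    fit_aci,
    recompute_curve,
)
from cutigas.aci import FitError, FitResult
from cutigas.fvcb import rubisco_limited_rate, rubp_limited_rate
from cutigas.synthetic import ProtocolSpec, StomatalModel, generate_curve


class TestRecomputeCurve:
    def test_zero_gcw_corrected_equals_uncorrected(self, clean_ss_frame):
        cu = recompute_curve(clean_ss_frame, 0.0, "uncorrected")
        cc = recompute_curve(clean_ss_frame, 0.0, "corrected")
        np.testing.assert_allclose(cu.data["Ci"], cc.data["Ci"], rtol=1e-12)

    def test_corrected_uses_partitioned_gsw(self):
        import pandas as pd

        rec = pd.DataFrame({
            "A": [10.0], "E": [0.002], "Ca": [400.0], "gsw": [0.17],
        })
        cc = recompute_curve(rec, 0.0056, "corrected")
        assert cc.data["gsw_used"].iloc[0] == pytest.approx(0.1644)

    def test_corrected_ci_below_uncorrected_everywhere(self, rich_params):
        df = generate_curve(
            ProtocolSpec.steady_state(), params=rich_params,
            stomata=StomatalModel.static(0.05, 0.0056),
        )
        cu = recompute_curve(df, 0.0056, "uncorrected")
        cc = recompute_curve(df, 0.0056, "corrected")
        # ordering holds for assimilating rows; it flips (correctly)
        # where the leaf is a net CO2 source
        ok = (cc.data["flag"] == "") & (cc.data["A"] > 0)
        assert ok.sum() >= 10
        assert np.all(cc.data.loc[ok, "Ci"] < cu.data.loc[ok, "Ci"])

    def test_nonphysical_rows_flagged(self):
        import pandas as pd

        rec = pd.DataFrame({
            "A": [5.0, 5.0], "E": [0.001, 0.001], "Ca": [400.0, 400.0],
            "gsw": [0.004, 0.05],
        })
        cc = recompute_curve(rec, 0.0056, "corrected")
        assert list(cc.data["flag"]) == ["non_physical", ""]
        assert len(cc.fit_data) == 1


class TestFitAci:
    def test_noise_free_recovery_within_half_percent(self, rich_params, clean_ss_frame):
        fit = fit_aci(recompute_curve(clean_ss_frame, 0.0, "uncorrected"))
        assert fit.converged
        assert fit.vcmax == pytest.approx(rich_params.vcmax, rel=0.005)
        assert fit.j == pytest.approx(rich_params.j, rel=0.005)
        assert fit.tpu == pytest.approx(rich_params.tpu, rel=0.005)
        assert fit.rd == pytest.approx(rich_params.rd, rel=0.005)

    def test_transitions_are_internally_consistent(self, clean_ss_frame):
        """At the fitted C_itrans1 the two potential rates intersect."""
        fit = fit_aci(recompute_curve(clean_ss_frame, 0.0, "uncorrected"))
        p = fit.params()
        assert rubisco_limited_rate(fit.ci_trans1, p) == pytest.approx(
            rubp_limited_rate(fit.ci_trans1, p), abs=1e-6
        )

    def test_truncated_curve_reports_tpu_absent(self):
        """True RuBP->TPU transition near 716; a curve stopping at 600
        carries no TPU information."""
        params = FvCBParams(vcmax=50, j=100, tpu=7.0, rd=1.5)
        proto = ProtocolSpec.steady_state(
            setpoints=(380, 285, 190, 145, 100, 50, 420, 460, 500, 540, 580, 620, 660, 700)
        )
        df = generate_curve(proto, params=params, stomata=StomatalModel.static(0.3, 0.0))
        df = df[df["Ci"] <= 600]
        fit = fit_aci(recompute_curve(df, 0.0, "uncorrected"))
        assert fit.tpu is None
        assert fit.ci_trans2 is None

    def test_noisy_recovery_median_bias_under_3_percent(self, rich_params):
        """50 seeded noisy curves (conductance sd 0.00415, A sd 0.2):
        the median absolute bias of V_cmax and J stays below 3%."""
        stomata = StomatalModel.static(0.25, 0.0)
        vbias, jbias = [], []
        for seed in range(50):
            df = generate_curve(
                ProtocolSpec.steady_state(), params=rich_params, stomata=stomata,
                noise=NoiseSpec(sd_glw=0.00415, sd_a=0.2), seed=seed,
            )
            fit = fit_aci(recompute_curve(df, 0.0, "uncorrected"))
            vbias.append(abs(fit.vcmax - rich_params.vcmax) / rich_params.vcmax)
            jbias.append(abs(fit.j - rich_params.j) / rich_params.j)
        assert np.median(vbias) < 0.03
        assert np.median(jbias) < 0.03

    def test_correction_raises_vcmax_on_low_conductance_curve(self, rich_params):
        """Refitting with the cuticle-aware C_i increases V_cmax when
        the g_cw:g_sw ratio is high (the corrected C_i is lower, so the
        same A demands more carboxylation capacity)."""
        df = generate_curve(
            ProtocolSpec.steady_state(), params=rich_params,
            stomata=StomatalModel.static(0.045, 0.0056),
        )
        fu = fit_aci(recompute_curve(df, 0.0056, "uncorrected"))
        fc = fit_aci(recompute_curve(df, 0.0056, "corrected"))
        assert fc.vcmax > fu.vcmax

    def test_too_few_points_raises(self, clean_ss_frame):
        with pytest.raises(FitError):
            fit_aci(recompute_curve(clean_ss_frame.iloc[:4], 0.0, "uncorrected"))


def _fits(values):
    return [FitResult(vcmax=v, j=100.0, tpu=None, rd=1.0) for v in values]


class TestDeltaCV:
    def test_identical_arms_give_zero(self):
        fits = _fits([100.0, 110.0, 95.0])
        assert delta_cv(fits, fits, "vcmax") == pytest.approx(0.0)

    def test_summary_form_matches_table_values(self):
        # published mean +/- SE pairs, n = 5 in both arms
        assert delta_cv_from_summary(590.93, 13.20, 570.88, 57.83) == pytest.approx(0.78, abs=0.005)
        assert delta_cv_from_summary(115.11, 6.79, 111.67, 5.90) == pytest.approx(-0.12, abs=0.005)
        assert delta_cv_from_summary(145.64, 7.43, 220.00, 31.14) == pytest.approx(0.64, abs=0.005)

    def test_se_and_sd_summaries_agree_at_equal_n(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(100, 8, 5), rng.normal(90, 12, 5)
        sd_form = delta_cv_from_summary(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))
        se_form = delta_cv_from_summary(
            a.mean(), a.std(ddof=1) / np.sqrt(5), b.mean(), b.std(ddof=1) / np.sqrt(5)
        )
        assert sd_form == pytest.approx(se_form, rel=1e-12)

    def test_fit_list_form_matches_manual_cv(self):
        r = _fits([100.0, 105.0, 98.0])
        s = _fits([100.0, 120.0, 80.0])
        rv = np.array([100.0, 105.0, 98.0])
        sv = np.array([100.0, 120.0, 80.0])
        expected = 1 - (rv.std(ddof=1) / rv.mean()) / (sv.std(ddof=1) / sv.mean())
        assert delta_cv(r, s, "vcmax") == pytest.approx(expected)

    def test_single_fit_arm_rejected(self):
        with pytest.raises(ValueError):
            delta_cv(_fits([100.0]), _fits([90.0, 95.0]), "vcmax")
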