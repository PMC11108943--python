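"""FvCB rates, limitation transitions, and the coupled leaf solver.

The solver's independent oracle is an exhaustive grid search over C_i
implemented here from the raw formulas, not through the package's
solver path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cutigas import (
    ChamberState,
    CoupledSolverError,
    FvCBParams,
    NonPhysicalConductanceError,
    coupled_solve,
    net_assimilation,
    rubisco_limited_rate,
    rubp_limited_rate,
    tpu_limited_rate,
    transition_ci,
)
from cutigas.fvcb import limiting_process

P = FvCBParams()  # vcmax 50, j 100, rd 1.5, km 710.3


class TestPotentialRates:
    def test_zero_at_compensation_point(self):
        assert rubisco_limited_rate(P.gamma_star, P) == 0.0
        assert rubp_limited_rate(P.gamma_star, P) == 0.0

    def test_high_ci_asymptotes(self):
        assert rubisco_limited_rate(1e9, P) == pytest.approx(P.vcmax, rel=1e-6)
        assert rubp_limited_rate(1e9, P) == pytest.approx(P.j / 4.0, rel=1e-6)

    def test_hand_evaluated_rates_at_ci_300(self):
        assert rubisco_limited_rate(300.0, P) == pytest.approx(
            50.0 * 257.25 / (300.0 + P.km), rel=1e-9
        )
        assert rubp_limited_rate(300.0, P) == pytest.approx(
            100.0 * 257.25 / 1542.0, rel=1e-9
        )

    def test_tpu_rate(self):
        assert tpu_limited_rate(FvCBParams(tpu=8.0)) == 24.0
        assert tpu_limited_rate(FvCBParams(tpu=10.52)) == pytest.approx(31.56)
        assert tpu_limited_rate(P) == np.inf  # absent: never binding

    def test_net_assimilation_picks_binding_minimum(self):
        p0 = FvCBParams(rd=0.0)
        assert net_assimilation(p0.gamma_star, p0) == pytest.approx(0.0, abs=1e-12)
        assert net_assimilation(300.0, p0) == pytest.approx(
            rubisco_limited_rate(300.0, p0), rel=1e-12
        )
        assert limiting_process(300.0, p0) == "Rubisco"
        p = FvCBParams(vcmax=50, j=100, tpu=7.0, rd=1.0)
        assert net_assimilation(800.0, p) == pytest.approx(20.0)
        assert limiting_process(800.0, p) == "TPU"


class TestTransitions:
    def test_first_transition_closed_form(self):
        t1 = transition_ci(P, "first")
        assert t1 == pytest.approx((100.0 * P.km - 8 * 42.75 * 50.0) / 100.0, rel=1e-12)

    def test_first_transition_matches_rate_intersection(self):
        """Cross-check the closed form by root-finding A_c = A_j."""
        from scipy.optimize import brentq

        t1 = transition_ci(P, "first")
        root = brentq(
            lambda ci: rubisco_limited_rate(ci, P) - rubp_limited_rate(ci, P),
            P.gamma_star + 1.0,
            5000.0,
        )
        assert t1 == pytest.approx(root, abs=1e-6)

    def test_second_transition(self):
        p = FvCBParams(tpu=7.0)
        assert transition_ci(p, "second") == pytest.approx(42.75 * 268.0 / 16.0)
        assert transition_ci(FvCBParams(tpu=9.0), "second") is None  # j - 12 tpu < 0
        assert transition_ci(P, "second") is None  # no TPU

    def test_first_transition_absent_when_rubp_never_binds(self):
        assert transition_ci(FvCBParams(vcmax=20.0, j=100.0), "first") is None


def _oracle_ci(g_lw, g_cw, ca, params, mode, vpd=1.5, patm=101.325, step=0.001):
    """Exhaustive grid search over C_i from the raw formulas."""
    if mode == "corrected":
        gsw = g_lw - g_cw
        glc = gsw / 1.6 + g_cw / 20.0
        gtc = 1.0 / (1.6 / (1.6 * glc) + 1.37 / 2.23)
    else:
        gtc = 1.0 / (1.6 / g_lw + 1.37 / 2.23)
    e = g_lw * vpd / patm
    ci = np.arange(step, 1.5 * ca + 300.0, step)  # spans respiring solutions too
    ac = params.vcmax * (ci - params.gamma_star) / (ci + params.km)
    aj = params.j * (ci - params.gamma_star) / (4 * ci + 8 * params.gamma_star)
    a = np.minimum(ac, aj) - params.rd
    implied = ((gtc - e / 2) * ca - a) / (gtc + e / 2)
    return ci[np.argmin(np.abs(implied - ci))]


class TestCoupledSolver:
    def test_infinite_conductance_limit(self):
        # boundary layer lifted and VPD zeroed so the diffusion
        # drawdown is the only term left — and it vanishes
        sol = coupled_solve(
            1e3, 0.0, ChamberState(ca=400.0, vpd=0.0), P, "uncorrected", g_bw=1e9
        )
        assert sol.ci == pytest.approx(400.0, abs=0.5)
        assert sol.a > 0

    def test_residual_closure(self):
        sol = coupled_solve(0.056, 0.0056, ChamberState(), P, "corrected")
        assert abs(sol.residual) < 1e-8
        assert net_assimilation(sol.ci, P) == pytest.approx(sol.a, abs=1e-12)

    def test_reference_point_uncorrected_vs_corrected(self):
        """Frozen oracle values at the low-conductance reference point."""
        rd0 = FvCBParams(rd=0.0)
        cu = coupled_solve(0.056, 0.0056, ChamberState(), rd0, "uncorrected").ci
        cc = coupled_solve(0.056, 0.0056, ChamberState(), rd0, "corrected").ci
        assert cu == pytest.approx(_oracle_ci(0.056, 0.0056, 400.0, rd0, "uncorrected"), abs=0.002)
        assert cc == pytest.approx(_oracle_ci(0.056, 0.0056, 400.0, rd0, "corrected"), abs=0.002)
        assert (cu - cc) / cc == pytest.approx(0.052, abs=0.005)

    def test_corrected_requires_physical_partition(self):
        with pytest.raises(NonPhysicalConductanceError):
            coupled_solve(0.005, 0.0056, ChamberState(), P, "corrected")

    def test_sub_compensation_ca_gives_respiring_solution(self):
        """Below the operational compensation point the leaf is a net
        CO2 source, so the solved C_i sits above C_a."""
        sol = coupled_solve(0.1, 0.0, ChamberState(ca=20.0), P, "uncorrected")
        assert sol.a < 0
        assert sol.ci > 20.0
        assert abs(sol.residual) < 1e-8

    def test_grid_search_oracle_equivalence(self):
        """100 random parameter draws agree with the exhaustive grid
        search to within one 0.001 umol mol-1 grid step."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            params = FvCBParams(
                vcmax=rng.uniform(20, 150),
                j=rng.uniform(40, 250),
                rd=rng.uniform(0.0, 3.0),
            )
            g_cw = rng.uniform(0.001, 0.01)
            g_lw = rng.uniform(g_cw + 0.005, 0.5)
            ca = rng.choice([100.0, 400.0, 2000.0])
            mode = rng.choice(["uncorrected", "corrected"])
            sol = coupled_solve(g_lw, g_cw, ChamberState(ca=ca), params, mode)
            oracle = _oracle_ci(g_lw, g_cw, ca, params, mode)
            assert abs(sol.ci - oracle) <= 0.001 + 1e-9

    @given(
        g_lw=st.floats(min_value=0.02, max_value=0.8),
        scale=st.floats(min_value=1.05, max_value=3.0),
    )
    @settings(max_examples=25)
    def test_ci_nondecreasing_in_glw(self, g_lw, scale):
        lo = coupled_solve(g_lw, 0.0, ChamberState(), P, "uncorrected").ci
        hi = coupled_solve(g_lw * scale, 0.0, ChamberState(), P, "uncorrected").ci
        assert hi >= lo - 1e-9

    @given(g_lw=st.floats(min_value=0.012, max_value=0.8))
    @settings(max_examples=25)
    def test_corrected_ci_never_above_uncorrected(self, g_lw):
        cu = coupled_solve(g_lw, 0.0056, ChamberState(), P, "uncorrected").ci
        cc = coupled_solve(g_lw, 0.0056, ChamberState(), P, "corrected").ci
        assert cc <= cu + 1e-9
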