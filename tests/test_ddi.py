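"""Static and dynamic DDI prediction and regulatory classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cypddi import ddi
from cypddi.nca import auc_trapezoid
from cypddi.params import VICTIM_SUBSTRATES, VictimSubstrate


class TestR1:
    def test_weak_inhibitor_row(self):
        assert ddi.compute_r1(0.3515, 1.73054) == pytest.approx(1.20, abs=0.005)

    def test_no_inhibitor_identity(self):
        assert ddi.compute_r1(0.0, 1.0) == 1.0

    def test_strong_inhibitor_row(self):
        assert ddi.compute_r1(0.3515, 0.0036157) == pytest.approx(98.2, abs=0.1)

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            ddi.compute_r1(1.0, 0.0)

    @pytest.mark.parametrize("r1,flag", [(1.01, False), (1.02, True), (15.14, True)])
    def test_follow_up_flag_threshold(self, r1, flag):
        assert ddi.r1_flag(r1) is flag


class TestStaticAUCR:
    def test_no_inhibitor_and_no_pathway_identities(self):
        assert ddi.static_aucr(0.5, 0.0, 1.0) == 1.0
        assert ddi.static_aucr(0.0, 1e6, 1.0) == 1.0

    def test_hand_computed_midpoint(self):
        # fm=0.5 and [I]=Ki: 1/(0.25 + 0.5) = 4/3
        assert ddi.static_aucr(0.5, 2.0, 2.0) == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_cap_on_complete_inhibition(self):
        with pytest.warns(UserWarning, match="cap"):
            assert ddi.static_aucr(1.0, 1e12, 1e-6) == 1e6

    @given(
        fm=st.floats(min_value=0.0, max_value=0.99),
        i1=st.floats(min_value=0.0, max_value=1e3),
        i2=st.floats(min_value=0.0, max_value=1e3),
        ki=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_bounds_and_monotonicity_in_exposure(self, fm, i1, i2, ki):
        lo, hi = sorted([i1, i2])
        a_lo = ddi.static_aucr(fm, lo, ki)
        a_hi = ddi.static_aucr(fm, hi, ki)
        assert 1.0 <= a_lo <= a_hi < 1.0 / (1.0 - fm) + 1e-9

    @given(i=st.floats(min_value=1e-3, max_value=1e3),
           ki=st.floats(min_value=1e-3, max_value=1e3))
    def test_full_fm_limit_approaches_r1_form(self, i, ki):
        # as fm -> 1 the static model tends to 1 + [I]/Ki
        assert ddi.static_aucr(1.0, i, ki) == pytest.approx(1.0 + i / ki, rel=1e-9)


class TestDynamicAUCR:
    def test_infinite_ki_means_no_interaction(self, human_spec, q8h_regimen):
        aucr = ddi.dynamic_aucr(
            human_spec, q8h_regimen, VICTIM_SUBSTRATES["midazolam"], ki_u=1e12
        )
        assert aucr == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("name,ki_u", [("midazolam", 0.0036157),
                                           ("phenacetin", 1.73054)])
    def test_constant_exposure_limit_equals_static(self, name, ki_u):
        """With a flat perpetrator profile the co-simulation must collapse to
        the basic static model."""
        victim = VICTIM_SUBSTRATES[name]
        i_const = 0.3515
        profile = (np.array([-1e6, 1e6]), np.array([i_const, i_const]))
        *_, auc_inh = ddi.simulate_victim(victim, profile, ki_u, dose_time=0.0)
        *_, auc_ctl = ddi.simulate_victim(victim, None, None, dose_time=0.0)
        static = ddi.static_aucr(victim.fm, i_const, ki_u)
        assert auc_inh / auc_ctl == pytest.approx(static, rel=5e-3)

    def test_dynamic_never_exceeds_static_at_unbound_cmax(
        self, human_spec, q8h_regimen
    ):
        """Competitive inhibition at the profile's peak bounds the dynamic ratio."""
        grid = np.linspace(0.0, 120.0, 961)
        from cypddi import pbpk

        prof = pbpk.simulate(human_spec, q8h_regimen, grid, rtol=1e-8, atol=1e-9)
        fu = 0.037
        imax_u = float((prof.plasma_conc_um * fu).max())
        for name, ki_u in [("midazolam", 0.0036157), ("tolbutamide", 0.102742),
                           ("bufuralol", 0.407725)]:
            victim = VICTIM_SUBSTRATES[name]
            dyn = ddi.dynamic_aucr(
                human_spec, q8h_regimen, victim, ki_u=ki_u, fu_plasma=fu
            )
            stat = ddi.static_aucr(victim.fm, imax_u, ki_u)
            assert 1.0 <= dyn <= stat * (1 + 1e-9)

    def test_victim_before_perpetrator_rejected(self, human_spec, q8h_regimen):
        with pytest.raises(ValueError):
            ddi.dynamic_aucr(
                human_spec, q8h_regimen, VICTIM_SUBSTRATES["midazolam"],
                ki_u=1.0, victim_dose_time=-1.0,
            )

    def test_short_horizon_warns_extrapolated(self, human_spec, q8h_regimen):
        with pytest.warns(UserWarning, match="extrapolated"):
            ddi.dynamic_aucr(
                human_spec, q8h_regimen, VICTIM_SUBSTRATES["phenacetin"],
                ki_u=10.0, horizon_half_lives=4.0,
            )


class TestClassification:
    @pytest.mark.parametrize(
        "static,dynamic,expected",
        [
            (1.86, 1.17, "weak"),
            (3.86, 5.36, "strong"),
            (3.00, 1.46, "moderate"),
            (19.45, 5.14, "strong"),
            (1.10, 1.0, "none"),
            (2.0, 1.0, "moderate"),  # boundary into moderate
            (5.0, 1.0, "strong"),  # boundary into strong
            (1.25, 1.0, "none"),  # weak requires AUCR > 1.25
        ],
    )
    def test_worst_case_banding(self, static, dynamic, expected):
        fda_class, _ = ddi.classify_fda(static, dynamic)
        assert fda_class == expected

    def test_clinical_study_flag_at_1_25(self):
        assert ddi.classify_fda(1.25, 1.0)[1] is True
        assert ddi.classify_fda(1.24, 1.0)[1] is False

    @given(
        a=st.floats(min_value=0.0, max_value=30.0),
        b=st.floats(min_value=0.0, max_value=30.0),
        bump=st.floats(min_value=0.0, max_value=30.0),
    )
    def test_classification_monotone_in_aucr(self, a, b, bump):
        order = ["none", "weak", "moderate", "strong"]
        base = order.index(ddi.classify_fda(a, b)[0])
        higher = order.index(ddi.classify_fda(a + bump, b)[0])
        assert higher >= base


class TestVictimModel:
    def test_victim_parameter_validation(self):
        with pytest.raises(ValueError):
            VictimSubstrate("x", "CYP", fm=1.2, ka=1.0, v_over_f=10.0,
                            cl_over_f=1.0, dose_mg=1.0)
        with pytest.raises(ValueError):
            VictimSubstrate("x", "CYP", fm=0.5, ka=-1.0, v_over_f=10.0,
                            cl_over_f=1.0, dose_mg=1.0)

    def test_control_auc_matches_one_compartment_theory(self):
        victim = VICTIM_SUBSTRATES["midazolam"]
        t, c, auc = ddi.simulate_victim(victim, None, None, dose_time=0.0)
        # AUC(inf) = F*dose/CL with concentrations in ng/mL: dose mg -> *1e6 ng
        expected = victim.dose_mg / victim.cl_over_f * 1000.0
        assert auc == pytest.approx(expected, rel=2e-3)
        assert c[0] == 0.0 and c.max() > 0
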