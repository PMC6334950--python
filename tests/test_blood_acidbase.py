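"""Blood acid-base formulas: frozen hand/oracle values and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from strongion import (
    BloodPanel, DEFAULT_CONSTANTS, actual_bicarbonate, anion_gap, atot,
    base_excess_actual, base_excess_ecf, derive_blood, derive_blood_frame,
    magnesium_effective_charge, sid_measured, standard_bicarbonate,
    strong_ion_gap, temperature_correct, unmeasured_anions, weak_acid_charges,
)

C = DEFAULT_CONSTANTS

# strategies spanning the plausible venous panel space
ph_s = st.floats(6.9, 7.7)
pco2_s = st.floats(20.0, 90.0)
hb_s = st.floats(4.0, 16.0)
conc = st.floats(0.0, 200.0)


class TestHendersonHasselbalch:
    @pytest.mark.parametrize("ph, pco2, expected", [
        (6.12, 40.0, 1.228),      # exponent vanishes at pH = pK1'
        (7.40, 0.0, 0.0),
        (7.40, 45.0, 26.3239),
    ])
    def test_actual_bicarbonate_values(self, ph, pco2, expected):
        assert actual_bicarbonate(ph, pco2) == pytest.approx(expected, abs=1e-3)

    def test_negative_pco2_rejected(self):
        with pytest.raises(ValueError):
            actual_bicarbonate(7.40, -1.0)

    @given(ph=ph_s, pco2=st.floats(25.0, 80.0), d=st.floats(0.01, 0.3))
    @settings(deadline=None, derandomize=True)
    def test_strictly_monotone_in_both_arguments(self, ph, pco2, d):
        base = actual_bicarbonate(ph, pco2)
        assert actual_bicarbonate(ph + d, pco2) > base
        assert actual_bicarbonate(ph, pco2 * (1 + d)) > base


class TestTemperatureCorrection:
    def test_identity_at_analyzer_temperature(self):
        assert temperature_correct(7.40, 45.0, 37.0) == (7.40, 45.0)

    def test_febrile_sample_shifts_acidic_and_hypercapnic(self):
        ph, pco2 = temperature_correct(7.40, 45.0, 39.0)
        assert ph < 7.40 and pco2 > 45.0

    def test_published_coefficients(self):
        ph, pco2 = temperature_correct(7.40, 40.0, 38.5)
        assert ph == pytest.approx(7.37795, abs=1e-5)
        assert pco2 == pytest.approx(42.7130, abs=1e-3)

    @pytest.mark.parametrize("temp", [29.0, 43.5])
    def test_implausible_temperature_rejected(self, temp):
        with pytest.raises(ValueError):
            temperature_correct(7.40, 45.0, temp)


class TestVanSlyke:
    def test_zero_at_reference_point(self):
        # pCO2 chosen so actual bicarbonate is exactly the 24.4 mmol/L zero point
        pco2_ref = C.ref_hco3 / (C.S * 10 ** (7.40 - C.pK1))
        assert base_excess_actual(7.40, pco2_ref, 10.0) == pytest.approx(0.0, abs=1e-12)
        assert base_excess_ecf(7.40, pco2_ref, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_acidemia_gives_base_deficit(self):
        assert base_excess_actual(7.30, 45.0, 10.0) < 0

    def test_frozen_values(self):
        assert base_excess_actual(7.45, 40.0, 10.0) == pytest.approx(2.6946, abs=1e-3)
        assert base_excess_ecf(7.45, 40.0, 10.0) == pytest.approx(2.4767, abs=1e-3)

    @given(ph=ph_s, pco2=pco2_s)
    @settings(deadline=None, derandomize=True)
    def test_ecf_equals_actual_at_zero_hemoglobin(self, ph, pco2):
        assert base_excess_ecf(ph, pco2, 0.0) == pytest.approx(
            base_excess_actual(ph, pco2, 0.0), abs=1e-12)

    @given(ph=st.floats(7.0, 7.6), pco2=pco2_s, hb=hb_s, d=st.floats(0.01, 0.2))
    @settings(deadline=None, derandomize=True)
    def test_monotone_increasing_in_ph(self, ph, pco2, hb, d):
        assert base_excess_actual(ph + d, pco2, hb) > base_excess_actual(ph, pco2, hb)


class TestStandardBicarbonate:
    @given(ph=ph_s, hb=hb_s)
    @settings(deadline=None, derandomize=True)
    def test_fixed_point_at_40_mmhg(self, ph, hb):
        assert standard_bicarbonate(ph, 40.0, hb) == pytest.approx(
            actual_bicarbonate(ph, 40.0), abs=1e-9)

    def test_acidotic_sample_below_reference(self):
        assert standard_bicarbonate(7.20, 45.0, 10.0) < C.ref_hco3

    @given(ph=st.floats(7.1, 7.6), pco2=st.floats(25.0, 70.0), hb=hb_s)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_agrees_with_independent_root_finder(self, ph, pco2, hb):
        # oracle: solve the buffer-line equilibration with brentq
        beta = C.vs_buffer_slope * hb + C.vs_buffer_intercept
        target = actual_bicarbonate(ph, pco2) - C.ref_hco3 + beta * (ph - C.ref_ph)

        def f(x):
            return (C.S * 40.0 * 10 ** (x - C.pK1) - C.ref_hco3
                    + beta * (x - C.ref_ph) - target)

        ph40 = brentq(f, 6.0, 8.5, xtol=1e-12)
        expected = C.S * 40.0 * 10 ** (ph40 - C.pK1)
        assert standard_bicarbonate(ph, pco2, hb) == pytest.approx(expected, abs=1e-6)

    def test_frozen_value(self):
        assert standard_bicarbonate(7.35, 50.0, 10.0) == pytest.approx(24.3375, abs=5e-3)


class TestStrongIonArithmetic:
    @pytest.mark.parametrize("na, k, cl, hco3, expected", [
        (140.0, 4.0, 104.0, 26.0, 14.0),
        (100.0, 0.0, 50.0, 50.0, 0.0),
        (137.0, 4.5, 99.0, 28.5, 14.0),
    ])
    def test_anion_gap(self, na, k, cl, hco3, expected):
        assert anion_gap(na, k, cl, hco3) == pytest.approx(expected, abs=1e-12)

    def test_sid_variants(self):
        assert sid_measured(140, 4, 104, variant="m3") == pytest.approx(40.0)
        assert sid_measured(140, 4, 104, 0.0, 1.2, variant="m4") == pytest.approx(
            sid_measured(140, 4, 104, variant="m3"))
        assert sid_measured(140, 4, 104, 1.0, 1.2, variant="m5") == pytest.approx(41.4)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            sid_measured(140, 4, 104, variant="m6")

    @pytest.mark.parametrize("conc, basis, expected", [
        (0.0, "albumin", 0.0), (30.0, "albumin", 22.8), (70.0, "protein", 25.2),
    ])
    def test_atot(self, conc, basis, expected):
        assert atot(conc, basis) == pytest.approx(expected, abs=1e-12)

    def test_atot_negative_rejected(self):
        with pytest.raises(ValueError):
            atot(-1.0, "albumin")

    def test_sig_half_dissociation_at_pka(self):
        assert strong_ion_gap(22.0, C.pKa, 14.0) == pytest.approx(-3.0, abs=1e-12)

    def test_sig_zero_buffer(self):
        assert strong_ion_gap(0.0, 7.40, 14.0) == pytest.approx(-14.0)

    def test_sig_frozen_value(self):
        assert strong_ion_gap(22.8, 7.40, 14.0) == pytest.approx(1.6476, abs=1e-3)

    def test_magnesium_charge_is_exact_69_percent_dissociation(self):
        assert magnesium_effective_charge(1.0) == 2.0 * 0.69
        assert magnesium_effective_charge(0.0) == 0.0
        assert magnesium_effective_charge(0.9) == pytest.approx(1.242, abs=1e-12)

    def test_weak_acid_charges(self):
        assert weak_acid_charges(0, 0, 0, 7.40) == (0.0, 0.0, 0.0)
        alb, glob, phos = weak_acid_charges(35.0, 70.0, 2.0, 7.40)
        assert alb == pytest.approx(9.7713, abs=1e-4)
        assert glob == pytest.approx(2.548, abs=1e-4)
        assert phos == pytest.approx(3.6352, abs=1e-4)

    def test_albumin_above_total_protein_rejected(self):
        with pytest.raises(ValueError):
            weak_acid_charges(40.0, 35.0, 1.0, 7.40)

    def test_unmeasured_anions_frozen_value(self):
        xa = unmeasured_anions(140, 4, 1.2, 1.0, 104, 26, 9.77, 2.548, 3.635)
        assert xa == pytest.approx(1.827, abs=1e-9)
        assert unmeasured_anions(0, 0, 0, 0, 0, 0, 0, 0, 0) == 0.0


# joint strategy for a physiologically valid panel
panel_s = st.builds(
    BloodPanel,
    pH_v=st.floats(7.0, 7.7), pCO2_v=st.floats(25.0, 80.0),
    ctHb=hb_s, body_temp=st.floats(37.5, 39.9),
    cNa=st.floats(125.0, 160.0), cK=st.floats(2.5, 7.0),
    cCa_ion=st.floats(0.5, 1.8), cCl=st.floats(80.0, 125.0),
    cLactate=st.floats(0.0, 8.0), cPi=st.floats(0.3, 3.5),
    cMg_total=st.floats(0.4, 1.8),
    cAlbumin=st.floats(15.0, 45.0), cTotalProtein=st.floats(50.0, 95.0),
)


class TestDeriveBlood:
    @given(panel=panel_s)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_anion_gap_identity(self, panel):
        d = derive_blood(panel)
        assert d.AG == pytest.approx(d.SID_m3 - d.cHCO3_act, abs=1e-9)

    @given(panel=panel_s)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_sig_difference_identity(self, panel):
        d = derive_blood(panel)
        frac = 1.0 / (1.0 + 10 ** (C.pKa - panel.pH_v))
        assert d.SIG_alb - d.SIG_prt == pytest.approx(
            (d.Atot_alb - d.Atot_prt) * frac, abs=1e-9)

    @given(panel=panel_s)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_sig_approaches_atot_minus_ag_at_high_ph(self, panel):
        d = derive_blood(panel)
        sig_limit = strong_ion_gap(d.Atot_alb, 12.0, d.AG)
        assert sig_limit == pytest.approx(d.Atot_alb - d.AG, abs=1e-3)

    def test_degenerate_albumin(self):
        p = BloodPanel(pH_v=7.40, pCO2_v=45, ctHb=10, body_temp=38.5,
                       cNa=140, cK=4, cCa_ion=1.1, cCl=104,
                       cAlbumin=0.0, cTotalProtein=0.0)
        d = derive_blood(p)
        assert d.Atot_alb == 0.0
        assert d.SIG_alb == pytest.approx(-d.AG, abs=1e-12)

    def test_deterministic(self):
        p = BloodPanel(pH_v=7.39, pCO2_v=49, ctHb=10, body_temp=38.6,
                       cNa=143, cK=4.3, cCa_ion=1.1, cCl=105,
                       cAlbumin=31, cTotalProtein=72)
        assert derive_blood(p) == derive_blood(p)

    def test_healthy_reference_panel_lands_in_reference_column(self):
        # panel inverted from mid-reference targets; the strong-ion block
        # must come back inside the printed intervals
        p = BloodPanel(pH_v=7.39, pCO2_v=49.2, ctHb=10, body_temp=38.6,
                       cNa=143, cK=4.3, cCa_ion=1.1, cCl=104.75,
                       cLactate=0.7, cPi=1.8, cMg_total=0.95,
                       cAlbumin=23.45 / 0.76, cTotalProtein=25.85 / 0.36)
        d = derive_blood(p)
        assert 42.6 <= d.SID_m5 <= 45.5
        assert 21.4 <= d.Atot_alb <= 25.5
        assert 24.5 <= d.Atot_prt <= 27.2
        assert 13.5 <= d.AG <= 15.3

    def test_validation_errors_carry_field_name(self):
        with pytest.raises(Exception, match="pH_v"):
            BloodPanel(pH_v=8.5, pCO2_v=45, ctHb=10, cNa=140, cK=4,
                       cCa_ion=1.1, cCl=104)

    def test_frame_matches_scalar_path(self):
        import pandas as pd
        p = BloodPanel(pH_v=7.39, pCO2_v=49, ctHb=10, body_temp=38.6,
                       cNa=143, cK=4.3, cCa_ion=1.1, cCl=105,
                       cLactate=0.7, cPi=1.8, cMg_total=0.95,
                       cAlbumin=31, cTotalProtein=72)
        frame = pd.DataFrame([p.model_dump()])
        out = derive_blood_frame(frame)
        scalar = derive_blood(p)
        for col in out.columns:
            assert out.loc[0, col] == pytest.approx(getattr(scalar, col), abs=1e-9)


class TestXARecovery:
    @given(u=st.floats(0.0, 15.0), na=st.floats(130.0, 150.0),
           alb=st.floats(20.0, 40.0), pi=st.floats(0.5, 3.0),
           ph=st.floats(7.1, 7.6))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_injected_unmeasured_anion_load_recovered(self, u, na, alb, pi, ph):
        """Electroneutrality bookkeeping: constructing a panel whose charges
        balance except for a known unmeasured-anion load u must return XA = u."""
        k, ca, mg, cl, tp = 4.3, 1.1, 0.95, 100.0, alb + 40.0
        ch_alb, ch_glob, ch_pi = weak_acid_charges(alb, tp, pi, ph)
        cation = na + k + 2 * ca + 1.38 * mg
        hco3 = cation - cl - ch_alb - ch_glob - ch_pi - u
        assert hco3 > 0
        xa = unmeasured_anions(na, k, ca, mg, cl, hco3, ch_alb, ch_glob, ch_pi)
        assert xa == pytest.approx(u, abs=1e-6)
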