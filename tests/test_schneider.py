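"""Schneider secondary-cancer models: age modifier, LNT and full mechanistic EAR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radrisk.dose import DoseDistribution, DoseVolumeHistogram, FractionationScheme, dvh_from_distribution
from radrisk.params import load_default_parameters
from radrisk.schneider import (
    AgePair,
    SchneiderParams,
    age_modifier,
    alpha_prime,
    ear_full,
    ear_lnt,
    organ_equivalent_dose,
    red,
)

PARAMS = load_default_parameters()
LUNG = PARAMS.schneider_for("lung")
BREAST = PARAMS.schneider_for("breast")
WBI = FractionationScheme(25, 2.0)


class TestAgeModifier:
    def test_registry_matches_published_rows(self):
        assert (LUNG.delta, LUNG.gamma_e, LUNG.gamma_a, LUNG.alpha_lq, LUNG.repop) == (
            8.0, 0.002, 4.23, 0.042, 0.83
        )
        assert (BREAST.delta, BREAST.gamma_e, BREAST.gamma_a, BREAST.alpha_lq, BREAST.repop) == (
            8.2, -0.037, 1.70, 0.044, 0.15
        )

    def test_reference_ages_give_unity_for_every_organ(self):
        ref = AgePair(30, 70)
        for organ in ("lung", "breast"):
            assert age_modifier(ref, PARAMS.schneider_for(organ)) == pytest.approx(1.0, abs=1e-15)

    def test_lung_value(self):
        assert age_modifier(AgePair(55, 75), LUNG) == pytest.approx(1.40753485767, rel=1e-9)

    def test_breast_value(self):
        assert age_modifier(AgePair(55, 95), BREAST) == pytest.approx(0.66640932458, rel=1e-9)

    def test_invalid_ages_rejected(self):
        with pytest.raises(ValueError):
            AgePair(0, 70)
        with pytest.raises(ValueError):
            AgePair(70, 55)


class TestEarLnt:
    def test_zero_dose(self):
        assert ear_lnt(0.0, AgePair(55, 75), LUNG) == 0.0

    def test_half_gray_lung(self):
        assert ear_lnt(0.5, AgePair(55, 75), LUNG) == pytest.approx(5.63013943, rel=1e-8)

    @given(st.floats(0.001, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, d):
        ages = AgePair(55, 75)
        assert ear_lnt(2 * d, ages, LUNG) == pytest.approx(2 * ear_lnt(d, ages, LUNG), rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            ear_lnt(-0.1, AgePair(55, 75), LUNG)


class TestAlphaPrime:
    def test_intercept_at_zero_dose(self):
        assert alpha_prime(0.0, WBI, LUNG) == pytest.approx(LUNG.alpha_lq, abs=1e-15)

    def test_lung_value_at_10_gy(self):
        assert alpha_prime(10.0, WBI, LUNG) == pytest.approx(0.0476, rel=1e-12)

    def test_at_prescription_equals_alpha_plus_beta_d(self):
        assert alpha_prime(WBI.total_dose, WBI, LUNG) == pytest.approx(
            LUNG.alpha_lq + LUNG.beta_lq * WBI.dose_per_fraction, rel=1e-12
        )

    def test_beta_derived_from_alpha_beta_ratio(self):
        assert LUNG.beta_lq == pytest.approx(0.042 / 3.0, rel=1e-12)


class TestRed:
    def test_zero_dose(self):
        assert red(0.0, 0.0476, 0.83) == 0.0

    def test_low_dose_slope_is_unity(self):
        assert red(0.001, 0.0476, 0.83) / 0.001 == pytest.approx(1.0, abs=1e-3)

    def test_lung_value_at_10_gy(self):
        # independent high-precision evaluation of the general form
        assert red(10.0, 0.0476, 0.83) == pytest.approx(7.013989342, rel=1e-8)

    def test_limit_forms(self):
        for ap in (0.02, 0.0476, 0.09):
            for d in (0.5, 5.0, 20.0, 60.0):
                assert red(d, ap, 1e-7) == pytest.approx(d * np.exp(-ap * d), abs=1e-6)
                assert red(d, ap, 1.0 - 1e-7) == pytest.approx(
                    (1 - np.exp(-ap * d)) / ap, abs=1e-6
                )

    def test_general_form_converges_to_limits(self):
        # general bracket just inside the guard band vs analytic limit forms
        for d in (1.0, 10.0, 40.0):
            assert red(d, 0.05, 2e-6) == pytest.approx(red(d, 0.05, 0.0), abs=1e-4)
            assert red(d, 0.05, 1 - 2e-6) == pytest.approx(red(d, 0.05, 1.0), abs=1e-4)

    def test_never_exceeds_physical_dose(self):
        doses = np.linspace(0.0, 80.0, 161)
        for ap in (0.01, 0.03, 0.0476, 0.1):
            for r in (0.0, 0.15, 0.5, 0.83, 1.0):
                assert np.all(red(doses, ap, r) <= doses + 1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            red(1.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            red(1.0, 0.05, 1.5)
        with pytest.raises(ValueError):
            red(-1.0, 0.05, 0.5)


class TestEarFull:
    def uniform_dvh(self, dose, organ="lung"):
        d = DoseDistribution(organ, np.full(200, dose), 0.1, WBI)
        return dvh_from_distribution(d, min(0.001, dose / 2) if dose < 0.1 else 0.1)

    def test_zero_dose_dvh(self):
        # all volume in a vanishing-dose bin (midpoint ~1e-12 Gy)
        dvh = DoseVolumeHistogram("lung", [0.0, 2e-12, 0.1], [1.0, 0.0])
        assert ear_full(dvh, WBI, AgePair(55, 75), LUNG) == pytest.approx(0.0, abs=1e-9)

    def test_lnt_limit_at_low_dose(self):
        ages = AgePair(55, 75)
        dvh = self.uniform_dvh(0.01)
        full = ear_full(dvh, WBI, ages, LUNG)
        lnt = ear_lnt(dvh.mean_dose, ages, LUNG)
        assert full == pytest.approx(lnt, rel=5e-3)

    def test_lnt_and_full_agree_below_tenth_gray(self):
        ages = AgePair(55, 75)
        for dose in (0.02, 0.05, 0.1):
            dvh = self.uniform_dvh(dose)
            assert ear_full(dvh, WBI, ages, LUNG) == pytest.approx(
                ear_lnt(dvh.mean_dose, ages, LUNG), rel=0.01
            )

    def test_uniform_dvh_collapses_to_single_bin_formula(self):
        ages = AgePair(55, 75)
        dvh = self.uniform_dvh(10.0)
        mid = dvh.bin_midpoints[dvh.diff_volume > 0][0]
        expected = LUNG.delta * age_modifier(ages, LUNG) * red(
            mid, alpha_prime(mid, WBI, LUNG), LUNG.repop
        )
        assert ear_full(dvh, WBI, ages, LUNG) == pytest.approx(expected, rel=1e-12)

    def test_bin_sum_linearity(self):
        # two-bin DVH equals the volume-weighted mix of single-bin results
        ages = AgePair(55, 75)
        edges = [0.0, 9.95, 10.05, 29.95, 30.05]
        mixed = DoseVolumeHistogram("lung", edges, [0.0, 0.3, 0.0, 0.7])
        lo = DoseVolumeHistogram("lung", edges, [0.0, 1.0, 0.0, 0.0])
        hi = DoseVolumeHistogram("lung", edges, [0.0, 0.0, 0.0, 1.0])
        expected = 0.3 * ear_full(lo, WBI, ages, LUNG) + 0.7 * ear_full(hi, WBI, ages, LUNG)
        assert ear_full(mixed, WBI, ages, LUNG) == pytest.approx(expected, rel=1e-12)

    def test_eqd2_scale_uses_constant_effective_alpha_prime(self):
        # summed plan (scheme None): alpha'*D accumulates as alpha*BED, and a
        # uniform EQD2 dose D has BED = D*(1+2/3)
        dvh = self.uniform_dvh(12.0)
        oed = organ_equivalent_dose(dvh, None, LUNG)
        mid = dvh.bin_midpoints[dvh.diff_volume > 0][0]
        ap_eff = LUNG.alpha_lq * (1 + 2 / 3)
        assert oed == pytest.approx(red(mid, ap_eff, LUNG.repop), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SchneiderParams("x", delta=-1, gamma_e=0, gamma_a=0, alpha_lq=0.04, repop=0.5)
        with pytest.raises(ValueError):
            SchneiderParams("x", delta=8, gamma_e=0, gamma_a=0, alpha_lq=0.04, repop=1.5)
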