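"""Dose model: BED/EQD2 conversion, plan summation, DVH binning and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radrisk.dose import (
    AlphaBetaRatio,
    DoseDistribution,
    DoseVolumeHistogram,
    FractionationScheme,
    bed,
    dose_metrics,
    dvh_from_distribution,
    eqd2,
    sum_courses,
)

WBI = FractionationScheme(25, 2.0)
BRACHY = FractionationScheme(2, 6.0)


class TestBedEqd2:
    @pytest.mark.parametrize(
        "total,scheme,expected",
        [
            (50.0, WBI, 50 * (1 + 2 / 3)),  # 83.333
            (12.0, BRACHY, 36.0),
            (0.0, WBI, 0.0),
        ],
    )
    def test_bed_hand_values(self, total, scheme, expected):
        assert bed(total, scheme) == pytest.approx(expected, rel=1e-12)

    def test_bed_rederives_fraction_dose_off_prescription(self):
        # voxel at half prescription: d = 1 Gy locally
        assert bed(25.0, WBI) == pytest.approx(25 * (1 + 1 / 3), rel=1e-12)

    @pytest.mark.parametrize("b,expected", [(36.0, 21.6), (50 * (1 + 2 / 3), 50.0), (0.0, 0.0)])
    def test_eqd2_values(self, b, expected):
        assert eqd2(b) == pytest.approx(expected, rel=1e-12)

    def test_eqd2_bed_roundtrip_identity_for_2gy_course(self):
        assert eqd2(bed(WBI.total_dose, WBI)) == pytest.approx(WBI.total_dose, rel=1e-9)

    def test_invalid_alpha_beta_rejected(self):
        with pytest.raises(ValueError):
            AlphaBetaRatio(0.0)
        with pytest.raises(ValueError):
            bed(-1.0, WBI)

    @given(
        d=st.floats(0.5, 8.0),
        n=st.integers(1, 40),
        extra=st.floats(0.0, 30.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bed_monotone_in_total_dose(self, d, n, extra):
        scheme = FractionationScheme(n, d)
        assert bed(scheme.total_dose + extra, scheme) >= bed(scheme.total_dose, scheme)

    @given(total=st.floats(1.0, 80.0), n=st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_bed_approaches_physical_dose_for_large_alpha_beta(self, total, n):
        scheme = FractionationScheme(n, total / n)
        assert bed(total, scheme, ab=1e9) == pytest.approx(total, rel=1e-6)

    def test_bed_increases_with_fraction_size_at_fixed_total(self):
        few_large = bed(60.0, FractionationScheme(10, 6.0))
        many_small = bed(60.0, FractionationScheme(30, 2.0))
        assert few_large > many_small


class TestSumCourses:
    def test_prescription_voxel_sum(self):
        d1 = DoseDistribution("breast", [50.0], 0.1, WBI)
        d2 = DoseDistribution("breast", [12.0], 0.1, BRACHY)
        total = sum_courses([d1, d2])
        assert total.voxel_doses[0] == pytest.approx(71.6, rel=1e-12)
        assert total.scheme is None

    def test_single_2gy_course_is_identity(self):
        d = DoseDistribution("lung", [50.0, 25.0, 2.0, 0.0], 0.1, WBI)
        out = sum_courses([d])
        # only the voxel at exactly 2 Gy/fx locally maps to itself; the
        # prescription voxel does (proportional fractionation)
        assert out.voxel_doses[0] == pytest.approx(50.0, rel=1e-12)

    def test_zero_boost_is_additive_identity(self):
        rng = np.random.default_rng(0)
        doses = rng.uniform(0, 50, 100)
        d1 = DoseDistribution("lung", doses, 0.1, WBI)
        zero = DoseDistribution("lung", np.full(100, 1e-300), 0.1, BRACHY)
        out = sum_courses([d1, zero])
        ref = sum_courses([d1])
        np.testing.assert_allclose(out.voxel_doses, ref.voxel_doses, rtol=1e-9)

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(1)
        courses = [
            DoseDistribution("lung", rng.uniform(0, 50, 50), 0.1, WBI),
            DoseDistribution("lung", rng.uniform(0, 12, 50), 0.1, BRACHY),
            DoseDistribution("lung", rng.uniform(0, 10, 50), 0.1, FractionationScheme(5, 2.0)),
        ]
        a = sum_courses(courses)
        b = sum_courses(courses[::-1])
        nested = sum_courses([sum_courses(courses[:2]), courses[2]])
        np.testing.assert_allclose(a.voxel_doses, b.voxel_doses, rtol=1e-12)
        np.testing.assert_allclose(a.voxel_doses, nested.voxel_doses, rtol=1e-12)

    def test_physical_mode_sums_raw_doses(self):
        d1 = DoseDistribution("lung", [10.0, 20.0], 0.1, WBI)
        d2 = DoseDistribution("lung", [1.0, 2.0], 0.1, BRACHY)
        out = sum_courses([d1, d2], mode="physical")
        np.testing.assert_allclose(out.voxel_doses, [11.0, 22.0])

    def test_mismatched_grids_rejected(self):
        d1 = DoseDistribution("lung", [10.0, 20.0], 0.1, WBI)
        d2 = DoseDistribution("lung", [1.0], 0.1, BRACHY)
        with pytest.raises(ValueError):
            sum_courses([d1, d2])
        d3 = DoseDistribution("heart", [1.0, 2.0], 0.1, BRACHY)
        with pytest.raises(ValueError):
            sum_courses([d1, d3])


class TestDvh:
    def test_counting_example(self):
        d = DoseDistribution("lung", [1.0, 1.0, 3.0, 3.0], 0.1, WBI)
        dvh = dvh_from_distribution(d, 2.0)
        np.testing.assert_allclose(dvh.bin_edges, [0, 2, 4])
        np.testing.assert_allclose(dvh.diff_volume, [0.5, 0.5])

    def test_uniform_dose_single_occupied_bin(self):
        d = DoseDistribution("lung", np.full(10, 7.3), 0.1, WBI)
        dvh = dvh_from_distribution(d, 0.1)
        assert np.count_nonzero(dvh.diff_volume) == 1
        assert dvh.diff_volume.max() == 1.0

    @given(st.lists(st.floats(0, 80), min_size=1, max_size=200), st.floats(0.05, 3.0))
    @settings(max_examples=100, deadline=None)
    def test_volume_conserved_and_mean_within_one_bin(self, doses, width):
        d = DoseDistribution("lung", doses, 0.1, WBI)
        dvh = dvh_from_distribution(d, width)
        assert dvh.diff_volume.sum() == pytest.approx(1.0, abs=1e-12)
        assert abs(dvh.mean_dose - d.mean_dose) <= width

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DoseVolumeHistogram("x", [1.0, 2.0], [1.0])  # first edge not 0
        with pytest.raises(ValueError):
            DoseVolumeHistogram("x", [0.0, 1.0, 2.0], [0.6, 0.6])  # sum != 1
        with pytest.raises(ValueError):
            dvh_from_distribution(DoseDistribution("x", [1.0], 0.1, WBI), 0.0)


class TestDoseMetrics:
    def test_uniform_dvh(self):
        d = DoseDistribution("lung", np.full(100, 10.0), 0.1, WBI)
        m = dose_metrics(dvh_from_distribution(d, 0.1))
        assert m["Dmean"] == pytest.approx(10.0, abs=0.051)  # half-bin midpoint offset
        assert m["V20Gy"] == 0.0
        assert m["D1%"] == pytest.approx(10.0, abs=0.051)

    def test_two_level_dvh(self):
        dvh = DoseVolumeHistogram("lung", [0.0, 10.0, 10.1, 30.0, 30.1], [0.0, 0.5, 0.0, 0.5])
        m = dose_metrics(dvh)
        assert m["Dmean"] == pytest.approx(20.0, abs=0.1)
        assert m["V20Gy"] == pytest.approx(50.0)

    def test_v0_is_total_volume(self):
        dvh = DoseVolumeHistogram("lung", [0.0, 5.0, 9.0], [0.3, 0.7])
        assert dose_metrics(dvh, v_thresholds=[0.0])["V0Gy"] == pytest.approx(100.0)

    def test_d_percent_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        d = DoseDistribution("lung", rng.exponential(5.0, 2000), 0.1, WBI)
        dvh = dvh_from_distribution(d, 0.1)
        ys = [1, 5, 20, 50, 90, 100]
        doses = [dose_metrics(dvh, d_percents=[y])[f"D{y:g}%"] for y in ys]
        assert all(a >= b for a, b in zip(doses, doses[1:]))

    def test_v_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        d = DoseDistribution("lung", rng.uniform(0, 40, 2000), 0.1, WBI)
        dvh = dvh_from_distribution(d, 0.1)
        xs = [0, 5, 10, 20, 39, 45]
        vs = [dose_metrics(dvh, v_thresholds=[x])[f"V{x:g}Gy"] for x in xs]
        assert all(a >= b for a, b in zip(vs, vs[1:]))

    def test_invalid_percent_rejected(self):
        dvh = DoseVolumeHistogram("lung", [0.0, 5.0], [1.0])
        with pytest.raises(ValueError):
            dose_metrics(dvh, d_percents=[0.0])
        with pytest.raises(ValueError):
            dose_metrics(dvh, d_percents=[101.0])
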