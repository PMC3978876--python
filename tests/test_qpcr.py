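"""Standard-curve fitting, copy estimation and QFI computation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qfikit.qpcr import (
    UNDETECTED,
    CqMeasurement,
    DegenerateCurveError,
    InsufficientDataError,
    check_inhibition,
    compute_qfi,
    determine_loq,
    efficiency_from_slope,
    estimate_copies,
    fit_calibration,
    mass_to_copies,
    quantify_samples,
    relative_dye_quant,
)


def _line_points(slope, intercept, levels=(5, 25, 125, 625, 3125)):
    return [(c, intercept + slope * math.log10(c)) for c in levels]


class TestFitCalibration:
    @pytest.mark.parametrize(
        "slope,expected_eff",
        [
            (-1 / math.log10(2), 100.0),  # one doubling per cycle
            (-3.512, 92.6),               # typical real-world efficiency
        ],
    )
    def test_efficiency_from_exact_line(self, slope, expected_eff):
        curve = fit_calibration(_line_points(slope, 38.0))
        assert curve.efficiency_percent == pytest.approx(expected_eff, abs=0.1)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(slope, rel=1e-9)

    def test_recovers_slope_from_noisy_titration(self):
        rng = np.random.default_rng(11)
        slope, intercept = -3.45, 39.0
        pts = []
        for i in range(6):  # 5-fold steps from 15,150 down to ~5 copies
            copies = 15150.0 / 5**i
            for _ in range(3):
                pts.append(
                    (copies, intercept + slope * math.log10(copies)
                     + rng.normal(0, 0.15))
                )
        curve = fit_calibration(pts)
        assert curve.slope == pytest.approx(slope, rel=0.02)
        assert curve.copy_range[0] < 5 < curve.copy_range[1]

    def test_too_few_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([(10, 35.0), (100, 31.7), (10, 35.1)])

    def test_positive_slope_rejected(self):
        pts = [(c, 20 + 3.3 * math.log10(c)) for c in (10, 100, 1000)]
        with pytest.raises(DegenerateCurveError):
            fit_calibration(pts)

    def test_efficiency_limits(self):
        assert efficiency_from_slope(-1 / math.log10(2)) == pytest.approx(100.0)
        assert efficiency_from_slope(-1e9) == pytest.approx(0.0, abs=1e-6)


_DOUBLING_CURVE = fit_calibration(_line_points(-1 / math.log10(2), 40.0))


class TestEstimateCopies:
    @pytest.fixture()
    def curve(self):
        return _DOUBLING_CURVE

    def test_intercept_is_one_copy(self, curve):
        assert estimate_copies(curve, curve.intercept) == pytest.approx(1.0)

    def test_worked_inversion(self, curve):
        # cq = 40 - 3.3219 log10(n); ten cycles earlier = 2^10 copies
        assert estimate_copies(curve, 30.0) == pytest.approx(1024, abs=1)

    def test_undetected_gives_zero(self, curve):
        assert estimate_copies(curve, UNDETECTED) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        cq1=st.floats(10, 45),
        delta=st.floats(0.01, 5),
    )
    def test_strictly_decreasing_in_cq(self, cq1, delta):
        curve = _DOUBLING_CURVE
        assert estimate_copies(curve, cq1) > estimate_copies(curve, cq1 + delta)

    @settings(max_examples=50, deadline=None)
    @given(copies=st.floats(1, 1e6))
    def test_round_trip_on_exact_line(self, copies):
        curve = _DOUBLING_CURVE
        cq = curve.cq_at(copies)
        assert estimate_copies(curve, cq) == pytest.approx(copies, rel=1e-6)


class TestMassAndQfi:
    @pytest.mark.parametrize(
        "mass,copies", [(10, 3030), (5, 1515), (0, 0), (1, 303)]
    )
    def test_mass_to_copies(self, mass, copies):
        assert mass_to_copies(mass) == copies

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            mass_to_copies(-1)

    @pytest.mark.parametrize(
        "copies,mass,qfi",
        [(3030, 10, 100.0), (100, 10, 3.3), (1515, 5, 100.0)],
    )
    def test_qfi_worked_examples(self, copies, mass, qfi):
        assert compute_qfi(copies, mass).qfi_percent == pytest.approx(qfi, abs=0.05)

    def test_undetected_sample(self):
        r = compute_qfi(0, 5)
        assert r.qfi_percent == 0.0 and not r.detected and not r.below_loq

    def test_below_loq_flag(self):
        assert compute_qfi(8, 5).below_loq
        assert not compute_qfi(12, 5).below_loq

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_qfi(100, 0)

    @settings(max_examples=50, deadline=None)
    @given(
        copies=st.floats(1, 1e5),
        mass=st.floats(0.1, 100),
        k=st.floats(0.1, 10),
    )
    def test_scale_consistency(self, copies, mass, k):
        a = compute_qfi(copies, mass).qfi_percent
        b = compute_qfi(copies * k, mass * k).qfi_percent
        assert a == pytest.approx(b, rel=1e-9)


class TestLoq:
    def test_sd_criterion(self):
        levels = {10: [30.0, 30.3, 30.5], 5: [31.0, 32.2, 30.4]}
        assert determine_loq(levels) == 10

    def test_all_tight_gives_smallest(self):
        levels = {100: [28.0, 28.0], 10: [31.0, 31.0], 5: [32.0, 32.0]}
        assert determine_loq(levels) == 5

    def test_noise_inflated_below_boundary(self):
        rng = np.random.default_rng(3)
        levels = {}
        for copies in (5, 10, 20, 40, 80):
            sd = 1.0 if copies < 8 else 0.15
            levels[copies] = list(38 - 3.32 * math.log10(copies)
                                  + rng.normal(0, sd, size=10))
        assert determine_loq(levels) == 10

    def test_undetected_replicate_disqualifies(self):
        levels = {10: [30.0, 30.1], 5: [31.0, UNDETECTED]}
        assert determine_loq(levels) == 10

    def test_nothing_quantifiable(self):
        assert determine_loq({10: [30.0, 31.5], 5: [31.0, 33.0]}) is None

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            determine_loq({10: [30.0]})


class TestInhibition:
    def test_small_shift_passes(self):
        assert not check_inhibition(30.4, 30.0)

    def test_large_shift_flagged(self):
        chk = check_inhibition(32.0, 30.0)
        assert chk.inhibited and not chk.total_inhibition
        assert chk.delta_cq == pytest.approx(2.0)

    def test_undetected_is_total_inhibition(self):
        chk = check_inhibition(UNDETECTED, 30.0)
        assert chk.inhibited and chk.total_inhibition


class TestDyeQuant:
    def test_relative_values(self):
        assert relative_dye_quant(0.30, 5.0) == pytest.approx(6.0)
        assert relative_dye_quant(5.0, 5.0) == pytest.approx(100.0)

    def test_below_floor_is_undetected(self):
        assert relative_dye_quant(0.0, 5.0) is None
        assert relative_dye_quant(0.05, 5.0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_dye_quant(-0.1, 5.0)


class TestQuantifySamples:
    @pytest.fixture()
    def curve(self):
        return fit_calibration(_line_points(-1 / math.log10(2), 40.0))

    def test_replicates_averaged_and_priority(self, curve):
        cq_100 = curve.cq_at(100.0)
        meas = [
            CqMeasurement("s1", "TBP", 5.0, 1, cq_100),
            CqMeasurement("s1", "TBP", 5.0, 2, cq_100),
            CqMeasurement("s1", "FTH1", 5.0, 1, curve.cq_at(1000.0)),
        ]
        (res,) = quantify_samples(meas, curve)
        assert res.estimated_copies == pytest.approx(100.0, rel=1e-6)
        assert res.qfi_percent == pytest.approx(100 * 100 / 1515, rel=1e-6)

    def test_average_combination(self, curve):
        meas = [
            CqMeasurement("s1", "TBP", 5.0, 1, curve.cq_at(100.0)),
            CqMeasurement("s1", "FTH1", 5.0, 1, curve.cq_at(300.0)),
        ]
        (res,) = quantify_samples(meas, curve, combine="average")
        assert res.estimated_copies == pytest.approx(200.0, rel=1e-6)

    def test_spud_wells_drive_inhibition_not_quantification(self, curve):
        meas = [
            CqMeasurement("s1", "TBP", 5.0, 1, curve.cq_at(100.0)),
            CqMeasurement("s1", "SPUD", 5.0, 1, 32.0),
        ]
        (res,) = quantify_samples(meas, curve, spud_control_cq=30.0)
        assert res.inhibited is True
        assert res.estimated_copies == pytest.approx(100.0, rel=1e-6)

    def test_all_undetected_sample(self, curve):
        meas = [CqMeasurement("s1", "TBP", 5.0, 1, UNDETECTED)]
        (res,) = quantify_samples(meas, curve)
        assert not res.detected and res.qfi_percent == 0.0
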