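"""Calibration-curve parsing, single and mixed-curve calibration, OxCal."""

import numpy as np
import pytest

from paleodairy.reservoir_calibration import (
    CalibrationCurve,
    MixedCurveSpec,
    RadiocarbonDate,
    calbp_to_calendar,
    calibrate,
    emit_oxcal_code,
    format_calendar,
    interval_95,
    mix_curves_calibrate,
    read_curve,
    write_curve,
)
from paleodairy.synthetic_data import synthetic_curve


def identity_curve(lo=4000.0, hi=6000.0, step=1.0, sd=1.0):
    cal = np.arange(lo, hi + step, step)
    return CalibrationCurve(cal, cal.copy(), np.full_like(cal, sd))


class TestCurveIO:
    def test_three_row_file(self, tmp_path):
        path = tmp_path / "tiny.14c"
        path.write_text("# header\n5010,5020,12\n5005,5010,11\n5000,5000,10\n")
        curve = read_curve(path)
        assert len(curve.cal_bp) == 3
        assert curve.cal_bp[0] == 5000  # stored ascending

    def test_comments_only_is_an_error(self, tmp_path):
        path = tmp_path / "empty.14c"
        path.write_text("# only\n# headers\n")
        with pytest.raises(ValueError, match="no data rows"):
            read_curve(path)

    def test_non_numeric_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.14c"
        path.write_text("5010,5020,12\n5005,abc,11\n")
        with pytest.raises(ValueError, match="line 2"):
            read_curve(path)

    def test_non_monotone_rejected(self, tmp_path):
        path = tmp_path / "wiggle.14c"
        path.write_text("5010,5020,12\n5010,5010,11\n5000,5000,10\n")
        with pytest.raises(ValueError, match="monotone"):
            read_curve(path)

    def test_round_trip_identity(self, tmp_path):
        curve = synthetic_curve(0, 500, step=5)
        path = tmp_path / "rt.14c"
        write_curve(curve, path)
        back = read_curve(path)
        np.testing.assert_allclose(back.cal_bp, curve.cal_bp)
        np.testing.assert_allclose(back.c14_age, curve.c14_age)
        np.testing.assert_allclose(back.curve_sd, curve.curve_sd)


class TestCalibrate:
    def test_identity_curve_mode(self):
        res = calibrate(RadiocarbonDate("X", 5000, 20), identity_curve())
        assert res.mode == pytest.approx(5000, abs=1)
        assert res.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identity_curve_interval_matches_closed_form(self):
        res = calibrate(RadiocarbonDate("X", 5000, 20), identity_curve())
        sigma = np.sqrt(20.0**2 + 1.0**2)
        older, younger = res.interval_95
        assert older == pytest.approx(5000 + 1.96 * sigma, abs=2)
        assert younger == pytest.approx(5000 - 1.96 * sigma, abs=2)

    def test_shifted_curve_shifts_mode(self):
        cal = np.arange(4000.0, 6001.0)
        shifted = CalibrationCurve(cal, cal + 100.0, np.full_like(cal, 1.0))
        res = calibrate(RadiocarbonDate("X", 5000, 20), shifted)
        assert res.mode == pytest.approx(4900, abs=1)

    def test_out_of_span_date_rejected(self):
        with pytest.raises(ValueError, match="outside curve span"):
            calibrate(RadiocarbonDate("X", 9000, 20), identity_curve())


class TestMixedCurve:
    def test_zero_mixing_reduces_to_plain(self):
        curve = identity_curve()
        date = RadiocarbonDate("X", 5000, 20)
        plain = calibrate(date, curve)
        mixed = mix_curves_calibrate(date, curve, MixedCurveSpec(0.0, 0.0))
        tv = 0.5 * np.abs(plain.posterior - mixed.posterior).sum()
        assert tv <= 1e-9

    def test_tiny_sd_zero_mean_also_reduces(self):
        curve = identity_curve()
        date = RadiocarbonDate("X", 5000, 20)
        plain = calibrate(date, curve)
        mixed = mix_curves_calibrate(date, curve, MixedCurveSpec(0.0, 1e-9))
        tv = 0.5 * np.abs(plain.posterior - mixed.posterior).sum()
        assert tv <= 1e-9

    def test_degenerate_reservoir_equals_shifted_date(self):
        # all mixing mass at p=100 with Delta-R fixed at 500: identical to
        # plain calibration of the date made younger by 500 14C years
        curve = identity_curve()
        date = RadiocarbonDate("X", 5500, 20)
        mixed = mix_curves_calibrate(
            date, curve, MixedCurveSpec(100.0, 0.0, delta_r_low=500, delta_r_high=500)
        )
        plain = calibrate(RadiocarbonDate("X", 5000, 20), curve)
        np.testing.assert_allclose(mixed.posterior, plain.posterior, atol=1e-12)

    def test_reservoir_uncertainty_widens_interval(self):
        curve = synthetic_curve()
        date = RadiocarbonDate("OxA-35976", 5965, 20)
        plain = calibrate(date, curve, grid_step=5.0)
        mixed = mix_curves_calibrate(
            date, curve, MixedCurveSpec(63, 26), grid_step=5.0, delta_r_step=50.0, mix_step=5.0
        )
        width = lambda r: r.interval_95[0] - r.interval_95[1]
        assert width(mixed) > width(plain)
        assert mixed.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_coarse_lattice_rejected(self):
        curve = identity_curve()
        with pytest.raises(ValueError, match="lattice"):
            mix_curves_calibrate(
                RadiocarbonDate("X", 5000, 20),
                curve,
                MixedCurveSpec(50, 10),
                delta_r_step=1000.0,
            )


class TestInterval:
    def test_symmetric_posterior(self):
        grid = np.arange(0.0, 201.0)
        post = np.exp(-0.5 * ((grid - 100.0) / 10.0) ** 2)
        post /= post.sum()
        lo, hi = interval_95(post, grid)
        assert (100 - lo) == pytest.approx(hi - 100, abs=1)

    def test_three_point_posterior(self):
        grid = np.array([1.0, 2.0, 3.0])
        lo, hi = interval_95(np.array([0.02, 0.96, 0.02]), grid)
        assert (lo, hi) == (2.0, 2.0)

    def test_contains_at_least_95_percent(self, rng):
        for _ in range(50):
            post = rng.dirichlet(np.ones(40))
            grid = np.arange(40.0)
            lo, hi = interval_95(post, grid)
            inside = post[(grid >= lo) & (grid <= hi)].sum()
            assert inside >= 0.95


class TestOxcal:
    def test_printed_block(self):
        text = emit_oxcal_code(
            [
                (RadiocarbonDate("OxA-35976", 5965, 20), (63, 26)),
                (RadiocarbonDate("OxA-37350", 4390, 20), (36, 22)),
            ]
        )
        assert 'Mix_Curves("Date1", "IntCal20","LocalFRE", 63,26);' in text
        assert 'R_Date("OxA-35976", 5965, 20);' in text
        assert 'Mix_Curves("Date2", "IntCal20","LocalFRE", 36,22);' in text

    def test_empty_input_scaffolding(self):
        text = emit_oxcal_code([])
        assert text == (
            "Plot()\n{\n"
            'Curve("IntCal20","IntCal20.14c");\n'
            'Curve("FRE","IntCal20.14c");\n'
            'Delta_R("LocalFRE", U(0,1000));\n'
            "};\n"
        )


class TestCalendarConversion:
    @pytest.mark.parametrize(
        "cal_bp, expected",
        [(1950, (1, "BC")), (4950, (3001, "BC")), (950, (1000, "AD")), (0, (1950, "AD"))],
    )
    def test_no_year_zero_convention(self, cal_bp, expected):
        assert calbp_to_calendar(cal_bp) == expected

    def test_formatting(self):
        assert format_calendar(4950) == "3001 BC"
        assert format_calendar(950) == "AD 1000"
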