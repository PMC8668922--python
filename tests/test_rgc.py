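"""Estimated retinal ganglion cell count formulas."""
import math

import numpy as np
import pytest

from ergpred import (
    FieldLocation,
    OCTSummary,
    VisualField,
    axon_density,
    combine_ergc,
    ergc_from_inputs,
    gl_human,
    gl_primate,
    grid_24_2,
    md_correction,
    oct_rgc_count,
    sap_rgc_count,
)
from ergpred.exceptions import DomainError, EmptyFieldError
from ergpred.rgc import SCAN_LENGTH_UM


class TestGlMaps:
    def test_human_worked_example(self):
        # m = 0.07128*15 + 0.91 = 1.9792; b = -1.98*15 - 14.8 = -44.5
        # gl = (30 - 1 + 44.5)/1.9792 + 4.7
        assert gl_human(30.0, 15.0) == pytest.approx((30 - 1 + 44.5) / 1.9792 + 4.7)
        assert gl_human(30.0, 15.0) == pytest.approx(41.84, abs=0.01)

    def test_human_zero_numerator_gives_offset(self):
        # s = b + 1 makes the quotient vanish, leaving the +4.7 offset
        for ec in (0.0, 5.0, 20.0):
            b = -1.98 * ec - 14.8
            assert gl_human(b + 1.0, ec) == pytest.approx(4.7)
        assert gl_human(-13.8, 0.0) == pytest.approx(4.7)

    def test_primate_worked_examples(self):
        assert gl_primate(-14.8, 0.0) == pytest.approx(0.0)
        # m = 0.054*10 + 0.91 = 1.45; b = -1.5*10 - 14.8 = -29.8
        assert gl_primate(20.0, 10.0) == pytest.approx((20 + 29.8) / 1.45)
        assert gl_primate(20.0, 10.0) == pytest.approx(34.34, abs=0.01)

    def test_monotone_in_sensitivity(self):
        for ec in (0.0, 10.0, 25.0):
            assert gl_primate(21.0, ec) > gl_primate(20.0, ec)
            assert gl_human(21.0, ec) > gl_human(20.0, ec)


class TestSapCount:
    def test_single_location_worked_example(self):
        field = VisualField(locations=(FieldLocation(ec=15.0, s=30.0),), md=0.0)
        expected = 10 ** (0.1 * gl_human(30.0, 15.0))
        assert sap_rgc_count(field) == pytest.approx(expected)
        assert sap_rgc_count(field) == pytest.approx(1.53e4, rel=0.01)

    def test_count_matches_formula_at_perimeter_floor(self):
        # floor sensitivity passes through the maps unchanged (no substitution)
        field = VisualField(locations=(FieldLocation(ec=0.0, s=-2.0),), md=0.0)
        expected = 10 ** (0.1 * ((-2.0 - 1.0 + 14.8) / 0.91 + 4.7))
        assert sap_rgc_count(field) == pytest.approx(expected)

    def test_duplicating_locations_doubles_count(self):
        locs = tuple(FieldLocation(ec=e, s=28.0) for e in (3.0, 9.0, 21.0))
        one = sap_rgc_count(VisualField(locations=locs, md=0.0))
        two = sap_rgc_count(VisualField(locations=locs + locs, md=0.0))
        assert two == pytest.approx(2 * one)

    def test_increasing_in_any_sensitivity(self):
        locs = [FieldLocation(ec=e, s=25.0) for e in (3.0, 9.0, 15.0)]
        base = sap_rgc_count(VisualField(locations=tuple(locs), md=0.0))
        locs[1] = FieldLocation(ec=9.0, s=25.5)
        assert sap_rgc_count(VisualField(locations=tuple(locs), md=0.0)) > base

    def test_empty_field_raises(self):
        with pytest.raises(EmptyFieldError):
            sap_rgc_count(VisualField(locations=(), md=0.0))


class TestOctSide:
    def test_axon_density_examples(self):
        assert axon_density(75.0) == pytest.approx(0.875)
        assert axon_density(20.0) == pytest.approx(1.26)
        assert axon_density(60.0) - axon_density(70.0) == pytest.approx(0.07)

    def test_axon_density_domain(self):
        with pytest.raises(DomainError):
            axon_density(200.0)

    def test_md_correction_examples(self):
        assert md_correction(0.0) == pytest.approx(0.12)
        assert md_correction(-10.0) == pytest.approx(2.72)
        assert md_correction(-5.0) > md_correction(-4.0)  # decreasing in MD

    def test_oct_count_worked_example(self):
        # c = 0 requires MD = 0.12/0.26; correction factor is then exactly 1
        md0 = 0.12 / 0.26
        got = oct_rgc_count(OCTSummary(rnfl=73.0, age=75.0), md=md0)
        assert got == pytest.approx(SCAN_LENGTH_UM * 0.875 * 73.0, rel=1e-9)
        assert got == pytest.approx(6.943e5, rel=0.001)

    def test_log_form_equals_closed_form(self):
        # Eq. printed in log form; algebraic simplification must agree
        for rnfl, age, md in [(73, 75, -2.5), (95, 50, 0.0), (55, 82, -12.0)]:
            d = axon_density(age)
            c = md_correction(md)
            closed = SCAN_LENGTH_UM * d * rnfl * 10 ** (-0.1 * c)
            log_form = oct_rgc_count(OCTSummary(rnfl=rnfl, age=age), md=md)
            assert abs(log_form - closed) / closed < 1e-12

    def test_linear_in_rnfl(self):
        a = oct_rgc_count(OCTSummary(rnfl=50.0, age=60.0), md=-3.0)
        b = oct_rgc_count(OCTSummary(rnfl=100.0, age=60.0), md=-3.0)
        assert b == pytest.approx(2 * a)

    def test_deeper_md_decreases_count(self):
        a = oct_rgc_count(OCTSummary(rnfl=73.0, age=60.0), md=-2.0)
        b = oct_rgc_count(OCTSummary(rnfl=73.0, age=60.0), md=-10.0)
        assert b < a

    def test_bad_rnfl_rejected(self):
        with pytest.raises(DomainError):
            OCTSummary(rnfl=0.0, age=60.0)


class TestCombination:
    def test_md_zero_returns_oct(self):
        assert combine_ergc(0.0, 6e5, 4e5) == 6e5

    def test_md_minus30_returns_sap(self):
        assert combine_ergc(-30.0, 6e5, 4e5) == pytest.approx(4e5)

    def test_midpoint(self):
        assert combine_ergc(-15.0, 600000.0, 400000.0) == pytest.approx(500000.0)

    def test_weights_sum_to_one(self):
        # (1 + MD/30) + (-MD/30) == 1 identically; spot-check via affinity
        for md in (-30.0, -17.3, -0.01, 0.0):
            shift = 1234.5
            assert combine_ergc(md, 6e5 + shift, 4e5 + shift) == pytest.approx(
                combine_ergc(md, 6e5, 4e5) + shift
            )

    def test_out_of_range_md_clamped(self, caplog):
        assert combine_ergc(-45.0, 6e5, 4e5) == pytest.approx(4e5)
        assert combine_ergc(5.0, 6e5, 4e5) == pytest.approx(6e5)


class TestFullEstimate:
    def test_grid_has_52_points_excluding_blind_spot(self):
        assert len(grid_24_2()) == 52
        assert len(grid_24_2(exclude_blind_spot=False)) == 54
        assert (15.0, 3.0) not in grid_24_2()
        assert (27.0, 3.0) in grid_24_2()

    def test_md_zero_path_ignores_field(self):
        oct_summary = OCTSummary(rnfl=80.0, age=60.0)
        e1 = ergc_from_inputs(VisualField.from_grid([30.0] * 52, md=0.0), oct_summary)
        e2 = ergc_from_inputs(VisualField.from_grid([10.0] * 52, md=0.0), oct_summary)
        assert e1.ergc == pytest.approx(e1.oct_rgc)
        assert e1.ergc == pytest.approx(e2.ergc)

    def test_estimate_between_sap_and_oct(self, rng):
        for _ in range(10):
            md = rng.uniform(-30, 0)
            sens = np.clip(30 + md + rng.normal(0, 2, 52), -2, 50)
            est = ergc_from_inputs(
                VisualField.from_grid(sens, md=md),
                OCTSummary(rnfl=rng.uniform(45, 110), age=rng.uniform(40, 90)),
            )
            lo, hi = sorted((est.sap_rgc, est.oct_rgc))
            assert lo - 1e-9 <= est.ergc <= hi + 1e-9

    def test_full_example_matches_independent_recomputation(self):
        # spreadsheet-style oracle: raw arithmetic over all 52 locations
        md = -4.0
        coords = grid_24_2()
        sens = [28.0 - 0.1 * math.hypot(x, y) for x, y in coords]
        field = VisualField.from_grid(sens, md=md, coords=coords)
        est = ergc_from_inputs(field, OCTSummary(rnfl=70.0, age=68.0))

        sap = 0.0
        for (x, y), s in zip(coords, sens):
            ec = math.sqrt(x * x + y * y)
            m = 0.07128 * ec + 0.91
            b = -1.98 * ec - 14.8
            gl = (s - 1 - b) / m + 4.7
            sap += 10 ** (0.1 * gl)
        d = -0.007 * 68.0 + 1.4
        c = -0.26 * md + 0.12
        oct_c = 10 ** (0.1 * (10 * math.log10(10870 * d * 70.0) - c))
        expected = (1 + md / 30) * oct_c - (md / 30) * sap
        assert est.sap_rgc == pytest.approx(sap, rel=1e-12)
        assert est.oct_rgc == pytest.approx(oct_c, rel=1e-12)
        assert est.ergc == pytest.approx(expected, rel=1e-12)

    def test_healthy_eye_is_physiologic_order_of_magnitude(self):
        est = ergc_from_inputs(
            VisualField.from_grid([30.0] * 52, md=0.0),
            OCTSummary(rnfl=95.0, age=50.0),
        )
        assert 0.5e6 <= est.ergc <= 1.5e6
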