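"""Static vessel mechanics: tube law, compliance, resistance, wave speed."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from cuffsim import (
    A_MIN_CM2,
    R_MAX,
    ArmGeometry,
    BloodProperties,
    TubeLawParams,
    area_compliance,
    elastic_compliance,
    is_transmitting,
    luminal_area,
    poiseuille_resistance,
    pulse_wave_velocity,
    segment_transit_time,
)

REF = TubeLawParams()
BLOOD = BloodProperties()
GEO = ArmGeometry()


class TestLuminalArea:
    @pytest.mark.parametrize(
        "ptm, expected",
        [
            (0.0, 0.08 * np.log(3.3) ** 2),  # 0.1140 cm^2
            (100.0, 0.147248),
            (-80.0, A_MIN_CM2),  # deep collapse clamps to the floor
        ],
    )
    def test_reference_values(self, ptm, expected):
        assert luminal_area(ptm, REF) == pytest.approx(expected, rel=1e-4)

    def test_never_below_floor_and_finite(self):
        grid = np.arange(-500.0, 500.0, 0.25)
        area = luminal_area(grid, REF)
        assert np.all(np.isfinite(area))
        assert np.all(area >= A_MIN_CM2)

    def test_monotone_up_to_local_dip(self):
        """The tube law is globally non-decreasing except for a known ~2e-3
        cm^2 dip near zero transmural pressure (a property of the law
        itself, not of the implementation)."""
        grid = np.arange(-150.0, 250.0, 1.0)
        area = luminal_area(grid, REF)
        assert np.min(np.diff(area)) > -2.5e-3
        outside = (grid < -6.0) | (grid > 16.0)
        assert np.all(np.diff(area)[outside[:-1]] >= -1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.017, 0.035),
        c=st.floats(0.08, 0.14),
        d=st.floats(0.05, 0.12),
        ptm=st.floats(-300, 300),
    )
    def test_always_finite_positive(self, a, c, d, ptm):
        area = luminal_area(ptm, a=a, c=c, d=d)
        assert np.isfinite(area) and area >= A_MIN_CM2


class TestAreaCompliance:
    def test_matches_symbolic_derivative_where_positive(self):
        p, a, c, d = sympy.symbols("p a c d", real=True)
        u = a * p + sympy.Rational(33, 10)
        expr = d * sympy.log(u) ** (1 + sympy.exp(-c * p))
        deriv = sympy.lambdify(p, sympy.diff(expr, p).subs({a: 0.03, c: 0.1, d: 0.08}))
        grid = np.concatenate([np.arange(-30, -8.0, 1.0), np.arange(18.0, 200.0, 2.0)])
        sym = np.array([float(deriv(x)) for x in grid])
        num = np.asarray(area_compliance(grid, REF))
        # compare only where the derivative is meaningfully positive and the
        # area clamp is inactive (num > 0)
        keep = (sym > 1e-6) & (num > 0)
        assert keep.sum() > 50
        assert np.allclose(num[keep], sym[keep], rtol=1e-3)

    def test_non_negative_and_zero_on_clamped_floor(self):
        grid = np.arange(-300.0, 300.0, 0.5)
        comp = area_compliance(grid, REF)
        assert np.all(comp >= 0.0)
        assert area_compliance(-200.0, REF) == 0.0

    def test_reference_value_at_100(self):
        assert area_compliance(100.0, REF) == pytest.approx(3.81e-4, rel=0.01)


class TestElasticCompliance:
    def test_positive_on_open_range(self):
        # below ~ -55 mmHg the compliance underflows to zero along with the
        # area (deep collapse); the tube is treated as non-transmitting there
        grid = np.arange(-50.0, 300.0, 0.5)
        comp = elastic_compliance(grid, REF)
        assert np.all(comp > 0.0)

    def test_stiffening_with_pressure(self):
        # the relaxed vessel is far more compliant than the distended one
        assert elastic_compliance(0.0, REF) > elastic_compliance(150.0, REF)

    def test_agrees_with_full_derivative_at_high_pressure(self):
        # the collapse exponent is ~1 at 100 mmHg, so both derivatives agree
        assert elastic_compliance(100.0, REF) == pytest.approx(
            area_compliance(100.0, REF), rel=2e-3
        )


class TestPoiseuilleResistance:
    def test_reference_value(self):
        assert poiseuille_resistance(100.0, GEO, BLOOD, REF) == pytest.approx(
            0.427, rel=0.01
        )

    def test_quartic_radius_law(self):
        # doubling the radius quadruples the area and divides R by 16
        r1 = poiseuille_resistance(100.0, GEO, BLOOD, REF)
        area = luminal_area(100.0, REF)
        big = TubeLawParams(d=REF.d * 4.0)  # area scales linearly with d
        assert luminal_area(100.0, big) == pytest.approx(4.0 * area)
        assert poiseuille_resistance(100.0, GEO, BLOOD, big) == pytest.approx(
            r1 / 16.0, rel=1e-9
        )

    def test_proportional_to_length(self):
        short = ArmGeometry(arm_length_m=1.0, cuff_length_m=1e-6)
        assert poiseuille_resistance(100.0, short, BLOOD, REF) < 1e-4
        double = ArmGeometry(arm_length_m=1.0, cuff_length_m=0.28)
        assert poiseuille_resistance(100.0, double, BLOOD, REF) == pytest.approx(
            2.0 * poiseuille_resistance(100.0, GEO, BLOOD, REF)
        )

    def test_capped_when_collapsed(self):
        assert poiseuille_resistance(-200.0, GEO, BLOOD, REF) == R_MAX

    def test_monotone_non_increasing_where_area_increases(self):
        grid = np.arange(20.0, 250.0, 1.0)
        r = poiseuille_resistance(grid, GEO, BLOOD, REF)
        assert np.all(np.diff(r) <= 1e-12)


class TestPulseWaveVelocity:
    def test_reference_value(self):
        assert pulse_wave_velocity(100.0, REF, BLOOD) == pytest.approx(7.0, abs=0.1)

    def test_stiffening_increases_speed(self):
        assert pulse_wave_velocity(120.0, REF, BLOOD) > pulse_wave_velocity(
            60.0, REF, BLOOD
        )

    def test_monotone_over_transmitting_range(self):
        grid = np.arange(-30.0, 250.0, 1.0)
        pwv = np.asarray(pulse_wave_velocity(grid, REF, BLOOD))
        assert np.all(np.isfinite(pwv))
        assert np.all(np.diff(pwv) > 0)

    def test_collapsed_is_non_transmitting(self):
        assert np.isnan(pulse_wave_velocity(-200.0, REF, BLOOD))
        assert not is_transmitting(-200.0, REF)
        assert is_transmitting(50.0, REF)


class TestSegmentTransitTime:
    def test_reference_value(self):
        assert segment_transit_time(100.0, 0.86, REF, BLOOD) == pytest.approx(
            123.0, abs=1.5
        )

    def test_zero_length(self):
        assert segment_transit_time(100.0, 0.0, REF, BLOOD) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ptm=st.floats(-25, 200),
        l1=st.floats(0.01, 1.0),
        l2=st.floats(0.01, 1.0),
    )
    def test_additive_and_linear_in_length(self, ptm, l1, l2):
        t1 = segment_transit_time(ptm, l1, REF, BLOOD)
        t2 = segment_transit_time(ptm, l2, REF, BLOOD)
        both = segment_transit_time(ptm, l1 + l2, REF, BLOOD)
        assert both == pytest.approx(t1 + t2, rel=1e-12)
        assert segment_transit_time(ptm, l1 / 2, REF, BLOOD) == pytest.approx(
            t1 / 2, rel=1e-12
        )

    def test_non_transmitting_propagates(self):
        assert np.isnan(segment_transit_time(-200.0, 0.5, REF, BLOOD))


class TestParameterValidation:
    @pytest.mark.parametrize("bad", [{"a": -1.0}, {"c": 0.0}, {"d": -0.08}])
    def test_tube_law_rejects_non_positive(self, bad):
        with pytest.raises(ValueError):
            TubeLawParams(**bad)

    def test_geometry_rejects_cuff_longer_than_arm(self):
        with pytest.raises(ValueError):
            ArmGeometry(arm_length_m=0.1, cuff_length_m=0.2)
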