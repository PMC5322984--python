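"""Lineshapes, saturation rate, chemical shift, and micro-field terms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from mrpool.constants import GAMMA, GAMMA_HZ
from mrpool.lineshape import (FieldContext, MicroFieldModel,
                              chemical_shift_field, effective_field,
                              gaussian_lineshape, sample_micro_field,
                              saturation_rate, super_lorentzian_lineshape)


class TestGaussian:
    def test_on_resonance_value(self):
        assert gaussian_lineshape(0.0, 1e-5) == pytest.approx(
            1e-5 / math.sqrt(2 * math.pi))

    @given(offset=st.floats(-1e5, 1e5, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_even_in_offset(self, offset):
        assert gaussian_lineshape(-offset, 1e-5) == \
            gaussian_lineshape(offset, 1e-5)

    def test_unit_area_over_angular_offset(self):
        val, _ = quad(lambda o: gaussian_lineshape(o, 1e-5), -5e5, 5e5,
                      limit=200)
        assert 2 * math.pi * val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_t2(self):
        with pytest.raises(ValueError):
            gaussian_lineshape(0.0, -1.0)


class TestSuperLorentzian:
    @pytest.mark.parametrize("offset", [1.5e3, 1e4, 5e4])
    def test_even_in_offset(self, offset):
        assert super_lorentzian_lineshape(-offset, 1e-5) == \
            pytest.approx(super_lorentzian_lineshape(offset, 1e-5))

    def test_unit_area_over_angular_offset(self):
        val, _ = quad(lambda o: super_lorentzian_lineshape(
            o, 1e-5, extrapolate=False), 1e-3, 2e6,
            points=[1e3, 1e4, 1e5], limit=400)
        assert 2 * (2 * math.pi) * val == pytest.approx(1.0, abs=1e-4)

    def test_against_riemann_sum(self):
        """Adaptive quadrature vs a brute-force fine-grid Riemann sum
        of the orientation integral at 10 kHz."""
        t2, off = 1e-5, 1e4
        u = (np.arange(2_000_000) + 0.5) / 2_000_000
        s = np.abs(3 * u * u - 1)
        integrand = math.sqrt(2 / math.pi) * t2 / s \
            * np.exp(-2 * (2 * math.pi * off * t2 / s) ** 2)
        riemann = integrand.mean()
        assert super_lorentzian_lineshape(off, t2) == \
            pytest.approx(riemann, rel=1e-6)

    def test_monotone_decreasing_beyond_near_resonance(self):
        vals = super_lorentzian_lineshape(
            np.array([2e3, 5e3, 1e4, 3e4, 1e5]), 1e-5)
        assert np.all(np.diff(vals) < 0)

    def test_extrapolated_region_is_linear_and_finite(self):
        g0 = super_lorentzian_lineshape(0.0, 1e-5)
        g500 = super_lorentzian_lineshape(500.0, 1e-5)
        g1000 = super_lorentzian_lineshape(1000.0, 1e-5)
        assert np.isfinite(g0)
        assert g500 == pytest.approx((g0 + g1000) / 2, rel=1e-9)


class TestSaturationRate:
    def test_zero_b1(self):
        assert saturation_rate(0.0, 1e4, 1e-5) == 0.0

    def test_quadratic_in_b1(self):
        w1 = saturation_rate(1e-6, 5e3, 1e-5, "gaussian")
        w2 = saturation_rate(2e-6, 5e3, 1e-5, "gaussian")
        assert w2 == pytest.approx(4 * w1)

    def test_matches_scalar_composition(self):
        """W = pi * (gamma B1 / 2pi)^2 * g for a 100 Hz field."""
        b1 = 100.0 / GAMMA_HZ
        expect = math.pi * 100.0 ** 2 * gaussian_lineshape(5e3, 1e-5)
        assert saturation_rate(b1, 5e3, 1e-5, "gaussian") == \
            pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("kind", ["gaussian", "super_lorentzian"])
    def test_even_in_offset(self, kind):
        a = saturation_rate(2e-6, 3e3, 1e-5, kind)
        b = saturation_rate(2e-6, -3e3, 1e-5, kind)
        assert a == pytest.approx(b)

    def test_unknown_lineshape(self):
        with pytest.raises(ValueError):
            saturation_rate(1e-6, 0.0, 1e-5, "lorentzian")


class TestChemicalShift:
    def test_zero_ppm(self):
        assert chemical_shift_field([(0.0, 1.0)], 7.0) == [(0.0, 1.0)]

    def test_one_ppm_at_7t(self):
        [(db, amp)] = chemical_shift_field([(1.0, 1.0)], 7.0)
        assert db == pytest.approx(7e-6)
        assert GAMMA_HZ * db == pytest.approx(298.04, abs=0.05)
        assert amp == 1.0

    def test_two_peak_fat(self):
        spec = [(-3.4, 0.9), (-3.8, 0.1)]
        out = chemical_shift_field(spec, 3.0)
        for (ppm, a), (db, amp) in zip(spec, out):
            assert db == pytest.approx(ppm * 1e-6 * 3.0)
            assert amp == a

    def test_bad_amplitudes(self):
        with pytest.raises(ValueError):
            chemical_shift_field([(0.0, 0.9)], 3.0)


class TestMicroField:
    def test_median_point_is_zero(self):
        m = MicroFieldModel(0.02, 0.08)
        assert sample_micro_field(m, 0.5) == 0.0

    def test_quartile_closed_form(self):
        m = MicroFieldModel(0.02, 0.08)
        assert sample_micro_field(m, 0.75) == \
            pytest.approx(1.0 / (GAMMA * m.t2_prime))

    def test_t2_prime_decomposition(self):
        m = MicroFieldModel(0.02, 0.08)
        assert 1.0 / m.t2_prime == pytest.approx(1 / 0.02 - 1 / 0.08)

    def test_invalid_t2_star(self):
        with pytest.raises(ValueError):
            MicroFieldModel(0.09, 0.08)  # T2' would be negative

    def test_u_bounds(self):
        m = MicroFieldModel(0.02, 0.08)
        with pytest.raises(ValueError):
            sample_micro_field(m, 0.0)
        with pytest.raises(ValueError):
            sample_micro_field(m, 1.0)

    def test_empirical_quartiles_match_cauchy(self):
        m = MicroFieldModel(0.02, 0.08, seed=7)
        rng = np.random.default_rng(7)
        samples = sample_micro_field(m, rng.uniform(1e-9, 1 - 1e-9, 100_000))
        scale = 1.0 / (GAMMA * m.t2_prime)
        q1, q3 = np.quantile(samples, [0.25, 0.75])
        assert q1 == pytest.approx(-scale, rel=0.02)
        assert q3 == pytest.approx(scale, rel=0.02)

    def test_characteristic_function_gives_t2_prime_decay(self):
        """Mean of exp(i gamma dB t) over stratified realizations
        reproduces the exp(-t/T2') envelope."""
        m = MicroFieldModel(0.02, 0.08)
        us = (np.arange(10_000) + 0.5) / 10_000
        db = sample_micro_field(m, us)
        for t in np.linspace(0.005, 3 * m.t2_prime, 8):
            emp = abs(np.mean(np.exp(1j * GAMMA * db * t)))
            assert emp == pytest.approx(math.exp(-t / m.t2_prime), rel=0.03)


class TestEffectiveField:
    def test_all_zero(self):
        bt, bz = effective_field(FieldContext())
        assert bt == 0 and bz == 0

    def test_gradient_term(self):
        ctx = FieldContext(gradient=(10e-3, 0, 0), position=(0.01, 0, 0))
        _, bz = effective_field(ctx)
        assert bz == pytest.approx(1e-4)

    def test_rf_offset_term(self):
        ctx = FieldContext(rf_offset_hz=1000.0)
        _, bz = effective_field(ctx)
        assert bz == pytest.approx(-1000.0 * 2 * math.pi / GAMMA)

    def test_sum_of_terms(self):
        ctx = FieldContext(b1_effective=1e-6 * 1j, delta_b_macro=2e-6,
                           micro_field=-1e-6)
        bt, bz = effective_field(ctx, pool_offset_tesla=3e-6)
        assert bt == 1e-6 * 1j
        assert bz == pytest.approx(4e-6)
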