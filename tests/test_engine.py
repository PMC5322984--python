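"""Spin-engine correctness: generator structure, closed-form Bloch
behaviour, full-generator matrix-exponential oracles, events, and
micro-field averaging."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from helpers import STRONG_B1, full_generator_oracle, hard_pulse_segment

from mrpool.constants import GAMMA, GAMMA_HZ
from mrpool.engine import (SpinState, build_generator, compile_model, evolve,
                           evolve_with_microfield, ideal_cpmg_echoes, step)
from mrpool.lineshape import FieldContext, MicroFieldModel, saturation_rate
from mrpool.sequence import (ExternalEvent, SequenceSegment, Timeline,
                             build_multi_spin_echo)
from mrpool.tissue import preset_model


class TestGenerator:
    def test_single_pool_is_classic_bloch(self, water):
        A, c = build_generator(water, longitudinal_field_offsets=[1e-6])
        wz = -GAMMA * 1e-6
        expect = np.array([[-1 / 0.08, -wz, 0.0],
                           [wz, -1 / 0.08, 0.0],
                           [0.0, 0.0, -1.0]])
        assert np.allclose(A, expect)
        assert np.allclose(c, [0, 0, 1.0])

    def test_exchange_columns_conserve_magnetization(self):
        m = preset_model("mwf_two_pool", {"k": 25.0})
        A0, _ = build_generator(preset_model("mwf_two_pool", {"k": 0.0}))
        A, _ = build_generator(m)
        X = A - A0  # pure exchange part
        for comp in range(3):
            for j in range(2):
                assert X[:, 3 * j + comp].sum() == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_equilibrium_is_fixed_point(self, preset):
        c_mod = compile_model(preset)
        A, c = build_generator(c_mod)
        x0 = SpinState.equilibrium(preset).to_vector()
        assert np.allclose(A @ x0 + c, 0.0, atol=1e-12)

    def test_dimension_mismatch(self, water):
        with pytest.raises(ValueError):
            build_generator(water, w_bound=[1.0])


class TestStep:
    def test_90_degree_nutation(self, slow_water):
        dt = 90.0 / 360.0 / (GAMMA_HZ * STRONG_B1)
        out = step(SpinState.equilibrium(slow_water),
                   FieldContext(b1_effective=STRONG_B1), slow_water, dt)
        assert np.allclose(out.m_free[0], [0.0, 1.0, 0.0], atol=1e-6)

    def test_t2_decay_over_one_time_constant(self, water):
        st = SpinState(np.array([[0.0, 1.0, 0.0]]), np.zeros(0))
        out = step(st, FieldContext(), water, 0.08)
        assert abs(out.m_free[0, 1]) == pytest.approx(math.exp(-1.0),
                                                      rel=1e-6)

    def test_invalid_dt(self, water):
        with pytest.raises(ValueError):
            step(SpinState.equilibrium(water), FieldContext(), water, 0.0)

    def test_composition_matches_full_exponential(self):
        """100 small steps of the split propagator against one dense
        matrix exponential of the complete generator."""
        model = preset_model("gagcest_three_pool")
        c_mod = compile_model(model)
        b1 = 2e-6
        off_hz = 500.0
        ctx = FieldContext(b1_effective=b1, rf_offset_hz=off_hz)
        dt, nstep = 1e-7, 100
        st = SpinState.equilibrium(model)
        for _ in range(nstep):
            st = step(st, ctx, model, dt, b0=7.0)
        bz = -2 * math.pi * off_hz / GAMMA + c_mod.ppm_f * 1e-6 * 7.0
        w = [saturation_rate(b1, off_hz, c_mod.t2_b[0],
                             c_mod.lineshape_b[0])]
        A, c = build_generator(c_mod, w_bound=w,
                               longitudinal_field_offsets=bz, b1=complex(b1))
        n = A.shape[0]
        G = np.zeros((n + 1, n + 1))
        G[:n, :n] = A
        G[:n, n] = c
        ref = (expm(G * dt * nstep)
               @ np.append(SpinState.equilibrium(model).to_vector(), 1.0))
        assert np.allclose(st.to_vector(), ref[:-1],
                           rtol=1e-6, atol=1e-8)


class TestEvolve:
    def test_inversion_recovery_closed_form(self, water):
        for delay in (0.1, 0.5, 1.5):
            seg, dur = hard_pulse_segment(0.0, 180.0, b1=1e-2)
            tl = Timeline([seg, SequenceSegment(dur + delay - 1e-6, 1e-6)])
            final, _ = evolve(SpinState.equilibrium(water), tl, water,
                              dt_max=1e-4)
            expect = 1.0 - 2.0 * math.exp(-delay / 1.0)
            assert final.m_free[0, 2] == pytest.approx(expect, abs=1e-5)

    def test_perfect_spoil_zeroes_transverse(self, water):
        seg, dur = hard_pulse_segment(0.0, 90.0)
        tl = Timeline([seg, SequenceSegment(dur + 1e-3, 1e-3)],
                      [ExternalEvent(dur + 1e-3, "perfect_spoil")])
        final, _ = evolve(SpinState.equilibrium(water), tl, water)
        assert final.m_free[0, 0] == 0.0 and final.m_free[0, 1] == 0.0

    def test_reset_event_restores_equilibrium(self, water):
        seg, dur = hard_pulse_segment(0.0, 90.0)
        tl = Timeline([seg, SequenceSegment(dur + 1e-3, 1e-3)],
                      [ExternalEvent(dur + 2e-3, "reset")])
        final, _ = evolve(SpinState.equilibrium(water), tl, water)
        assert np.allclose(final.to_vector(), [0.0, 0.0, 1.0])

    def test_event_outside_span_rejected(self, water):
        tl = Timeline([SequenceSegment(0.0, 1e-3)])
        with pytest.raises(ValueError):
            evolve(SpinState.equilibrium(water), tl, water,
                   events=[ExternalEvent(1.0, "perfect_spoil")])

    @pytest.mark.parametrize("name", ["mwf_two_pool", "qmt_two_pool",
                                      "gagcest_three_pool",
                                      "mt_fat_three_pool"])
    def test_full_generator_oracle_equivalence(self, name):
        """Engine stepping vs piecewise dense matrix exponentials on a
        saturation + excitation + sampling timeline, per preset."""
        model = preset_model(name)
        segs = [SequenceSegment(0.0, 0.005, (2e-6, 0.3, 1500.0))]
        pulse, dur = hard_pulse_segment(0.006, 30.0)
        segs.append(pulse)
        ta = 0.006 + dur + 0.002
        segs.append(SequenceSegment(ta - 1e-6, 2e-6, adc=(ta,)))
        tl = Timeline(segs)
        _, rec = evolve(SpinState.equilibrium(model), tl, model,
                        dt_max=1e-5, b0=3.0)
        ref = full_generator_oracle(model, tl, b0=3.0)
        got = rec.as_arrays()[1]
        assert np.allclose(got, ref, rtol=1e-5, atol=1e-9)

    def test_cpmg_exchange_train_vs_oracle(self):
        model = preset_model("mwf_two_pool", {"k": 25.0})
        tl = build_multi_spin_echo(0.010, 6)
        _, rec = evolve(SpinState.equilibrium(model), tl, model)
        ref = full_generator_oracle(model, tl)
        got = rec.as_arrays()[1]
        assert np.allclose(np.abs(got), np.abs(ref), rtol=1e-5)

    def test_cpmg_ideal_oracle_close(self):
        """Finite-pulse engine train vs the instantaneous-pulse CPMG
        closed form (agreement limited by pulse width, not stepping)."""
        model = preset_model("mwf_two_pool", {"k": 25.0})
        tl = build_multi_spin_echo(0.010, 8)
        _, rec = evolve(SpinState.equilibrium(model), tl, model)
        ref = ideal_cpmg_echoes(model, 0.010, 8)
        assert np.allclose(np.abs(rec.as_arrays()[1]), ref, rtol=5e-4)

    def test_halving_dt_converged(self, preset):
        segs = [SequenceSegment(0.0, 0.004, (2e-6, 0.0, 1200.0))]
        pulse, dur = hard_pulse_segment(0.005, 45.0)
        ta = 0.005 + dur + 1e-3
        segs += [pulse, SequenceSegment(ta - 1e-6, 2e-6, adc=(ta,))]
        tl = Timeline(segs)
        vals = []
        for scale in (1.0, 0.5):
            _, rec = evolve(SpinState.equilibrium(preset), tl, preset,
                            dt_max=1e-5 * scale, dt_max_rf=1e-6 * scale)
            vals.append(rec.as_arrays()[1][0])
        assert abs(vals[0] - vals[1]) / abs(vals[1]) < 1e-4

    def test_total_mz_relaxes_monotonically(self):
        """W=0, no RF, balanced exchange: total longitudinal
        magnetization approaches total M0 without overshoot."""
        model = preset_model("mwf_two_pool", {"k": 25.0})
        st = SpinState(np.array([[0.0, 0.0, 0.05], [0.0, 0.0, 0.2]]),
                       np.zeros(0))
        totals = []
        for _ in range(60):
            st = step(st, FieldContext(), model, 0.02)
            totals.append(st.m_free[:, 2].sum())
        totals = np.asarray(totals)
        assert np.all(np.diff(totals) > -1e-8)
        assert np.all(totals <= 1.0 + 1e-8)

    def test_transverse_norm_nonincreasing_without_rf(self, preset):
        c_mod = compile_model(preset)
        rng = np.random.default_rng(0)
        m_free = rng.normal(size=(c_mod.nf, 3)) * 0.2
        st = SpinState(m_free, c_mod.f[c_mod.nf:].copy())
        prev = np.linalg.norm(st.m_free[:, :2])
        for _ in range(20):
            st = step(st, FieldContext(delta_b_macro=1e-6), preset, 0.005)
            cur = np.linalg.norm(st.m_free[:, :2])
            assert cur <= prev + 1e-12
            prev = cur


class TestMicroField:
    def test_single_realization_is_plain_evolve(self, water):
        seg, dur = hard_pulse_segment(0.0, 90.0)
        ta = dur + 0.01
        tl = Timeline([seg, SequenceSegment(ta - 1e-6, 2e-6, adc=(ta,))])
        micro = MicroFieldModel(0.02, 0.08, n_realizations=1)
        # stratified n=1 puts the single draw at the median: dB = 0
        _, rec_m = evolve_with_microfield(SpinState.equilibrium(water), tl,
                                          water, micro)
        _, rec = evolve(SpinState.equilibrium(water), tl, water)
        assert rec_m.as_arrays()[1] == pytest.approx(rec.as_arrays()[1])

    def test_fid_envelope_t2_star(self, water):
        """FID of T2*=20 ms / T2=80 ms water, 100 realizations: the
        averaged envelope follows exp(-t/T2*) within 5% of the initial
        amplitude (the realization-average error dominates the tail)."""
        seg, dur = hard_pulse_segment(0.0, 90.0)
        ts = np.arange(0.002, 0.0401, 0.002)
        segs = [seg] + [SequenceSegment(dur / 2 + t - 1e-6, 2e-6,
                                        adc=(dur / 2 + t,)) for t in ts]
        micro = MicroFieldModel(0.02, 0.08, n_realizations=100)
        _, rec = evolve_with_microfield(SpinState.equilibrium(water),
                                        Timeline(segs), water, micro,
                                        dt_max=1e-4)
        env = np.abs(rec.as_arrays()[1])
        assert np.max(np.abs(env - np.exp(-ts / 0.02))) < 0.05

    def test_spin_echo_refocuses_static_dephasing(self, water):
        """A 180-degree refocusing pulse recovers exp(-TE/T2), not
        exp(-TE/T2*)."""
        te = 0.030
        p90, d90 = hard_pulse_segment(0.0, 90.0)
        p180, _ = hard_pulse_segment(d90 / 2 + te / 2, 180.0, phase=np.pi / 2)
        ta = d90 / 2 + te
        segs = [p90, p180, SequenceSegment(ta - 1e-6, 2e-6, adc=(ta,))]
        micro = MicroFieldModel(0.02, 0.08, n_realizations=100)
        _, rec = evolve_with_microfield(SpinState.equilibrium(water),
                                        Timeline(segs), water, micro,
                                        dt_max=1e-4)
        echo = abs(rec.as_arrays()[1][0])
        assert echo == pytest.approx(math.exp(-te / 0.08), rel=0.03)
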