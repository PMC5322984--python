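"""Shared test utilities: independent full-generator oracle and
hard-pulse construction."""

import math

import numpy as np
from scipy.linalg import expm

from mrpool.constants import GAMMA, GAMMA_HZ
from mrpool.engine import SpinState, build_generator, compile_model
from mrpool.lineshape import saturation_rate
from mrpool.sequence import SequenceSegment

STRONG_B1 = 1e-3  # tesla; makes hard pulses effectively instantaneous


def hard_pulse_segment(t, flip_deg, phase=0.0, b1=STRONG_B1):
    dur = abs(flip_deg) / 360.0 / (GAMMA_HZ * b1)
    return SequenceSegment(t, dur, (b1, phase, 0.0)), dur


def full_generator_oracle(model, timeline, b0=3.0, gamma=GAMMA):
    """Independent reference: piecewise matrix exponential of the
    complete Bloch-McConnell generator (rotation terms included) over
    each constant interval of the timeline."""
    c_mod = compile_model(model)
    n = 3 * c_mod.nf + c_mod.nb
    x = SpinState.equilibrium(model).to_vector()
    marks = sorted({0.0} | {s.start for s in timeline.segments}
                   | {s.end for s in timeline.segments}
                   | set(timeline.adc_times))
    samples = []
    for t0, t1 in zip(marks[:-1], marks[1:]):
        seg = next((s for s in timeline.segments
                    if s.start <= t0 + 1e-15 and t1 <= s.end + 1e-15), None)
        b1 = 0.0
        off_hz = 0.0
        if seg is not None and seg.rf is not None:
            amp, phase, off_hz = seg.rf
            b1 = amp * complex(math.cos(phase), math.sin(phase))
        bz = -2 * math.pi * off_hz / gamma + c_mod.ppm_f * 1e-6 * b0
        w = np.array([saturation_rate(abs(b1), off_hz, c_mod.t2_b[l],
                                      c_mod.lineshape_b[l], gamma)
                      for l in range(c_mod.nb)])
        A, c = build_generator(c_mod, w_bound=w,
                               longitudinal_field_offsets=bz, b1=b1)
        G = np.zeros((n + 1, n + 1))
        G[:n, :n] = A
        G[:n, n] = c
        x = (expm(G * (t1 - t0)) @ np.append(x, 1.0))[:-1]
        if any(abs(t1 - ta) < 1e-12 for ta in timeline.adc_times):
            samples.append(x[0:3 * c_mod.nf:3].sum()
                           + 1j * x[1:3 * c_mod.nf:3].sum())
    return np.asarray(samples) * c_mod.model.proton_density
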