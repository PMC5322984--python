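"""Pulse-sequence timelines and builders.

A sequence is a piecewise-constant list of :class:`SequenceSegment`
(RF amplitude/phase/carrier offset, gradient vector, optional ADC
sample times), plus :class:`ExternalEvent` markers applied atomically
at their timestamps (perfect spoiling, model/field updates, reset).
Gaps between segments are free precession.

Shaped pulses are hard-pulse decompositions: lists of adjacent
segments.  Timelines are deterministic functions of the builder
arguments and can be validated against virtual-scanner limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import GAMMA_HZ

__all__ = [
    "SequenceSegment",
    "ExternalEvent",
    "ScannerLimits",
    "Timeline",
    "validate_sequence",
    "build_multi_spin_echo",
    "build_mt_spgr",
    "build_afi",
    "build_cest_saturation",
    "build_bssfp",
]

#: Default hard-pulse amplitude, tesla (well under the 20 uT limit).
DEFAULT_RF_B1 = 10e-6

#: Nominal ramp interval used to estimate slew at contiguous segment
#: boundaries (instantaneous amplitude steps are assumed ramped over
#: this much time, a typical clinical ramp allowance).
GRADIENT_RASTER = 100e-6


@dataclass(frozen=True)
class SequenceSegment:
    """One piecewise-constant interval of the sequence."""

    start: float
    duration: float
    rf: tuple | None = None      # (amplitude T, phase rad, carrier offset Hz)
    gradient: tuple = (0.0, 0.0, 0.0)
    adc: tuple = ()              # absolute sample times within the segment

    def __post_init__(self):
        object.__setattr__(self, "gradient", tuple(self.gradient))
        object.__setattr__(self, "adc", tuple(self.adc))

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class ExternalEvent:
    """Programmable action applied at a prescribed time point."""

    time: float
    action: str                  # perfect_spoil | update_model | update_field | reset
    payload: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScannerLimits:
    """Virtual-scanner hardware limits."""

    max_b1: float = 20e-6        # tesla
    max_gradient: float = 40e-3  # T/m
    max_slew: float = 150.0      # T/m/s
    b0: float = 3.0              # tesla


@dataclass
class Timeline:
    """Ordered segments + events + free-form metadata."""

    segments: list = field(default_factory=list)
    events: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def span(self) -> float:
        return max((s.end for s in self.segments), default=0.0)

    @property
    def adc_times(self) -> list:
        out = []
        for s in self.segments:
            out.extend(s.adc)
        return out

    def shifted(self, dt: float) -> "Timeline":
        segs = [SequenceSegment(s.start + dt, s.duration, s.rf, s.gradient,
                                tuple(t + dt for t in s.adc))
                for s in self.segments]
        evs = [ExternalEvent(e.time + dt, e.action, e.payload)
               for e in self.events]
        return Timeline(segs, evs, dict(self.metadata))


def validate_sequence(timeline: Timeline, limits: ScannerLimits | None = None):
    """Check ordering, overlap, ADC placement, and hardware limits.

    Returns a list of diagnostic strings; empty means valid.
    """
    limits = limits or ScannerLimits()
    diags = []
    segs = timeline.segments
    for k, s in enumerate(segs):
        if s.duration <= 0:
            diags.append(f"segment {k}: duration {s.duration} <= 0")
        if s.rf is not None and abs(s.rf[0]) > limits.max_b1 * (1 + 1e-12):
            diags.append(
                f"segment {k}: RF amplitude {s.rf[0]:.3g} T exceeds "
                f"max_b1 {limits.max_b1:.3g} T")
        if max(abs(g) for g in s.gradient) > limits.max_gradient * (1 + 1e-12):
            diags.append(f"segment {k}: gradient exceeds "
                         f"max_gradient {limits.max_gradient:.3g} T/m")
        for t in s.adc:
            if not (s.start - 1e-12 <= t <= s.end + 1e-12):
                diags.append(f"segment {k}: ADC time {t} outside segment")
    for k in range(1, len(segs)):
        if segs[k].start < segs[k - 1].end - 1e-12:
            diags.append(f"segments {k - 1} and {k} overlap")
        gap = max(segs[k].start - segs[k - 1].end, GRADIENT_RASTER)
        step = max(abs(a - b) for a, b in
                   zip(segs[k].gradient, segs[k - 1].gradient))
        if step / gap > limits.max_slew * (1 + 1e-12):
            diags.append(
                f"segments {k - 1}->{k}: gradient step {step:.3g} T/m over "
                f"{gap:.3g} s implies slew > max_slew {limits.max_slew} T/m/s")
    span = timeline.span
    for e in timeline.events:
        if not (0.0 <= e.time <= span + 1e-12):
            diags.append(f"event '{e.action}' at {e.time} outside sequence span")
    return diags


def _hard_pulse(center: float, flip_deg: float, phase: float = 0.0,
                offset_hz: float = 0.0, b1: float = DEFAULT_RF_B1,
                adc: tuple = ()) -> SequenceSegment:
    dur = abs(flip_deg) / 360.0 / (GAMMA_HZ * b1)
    amp = b1 if flip_deg >= 0 else -b1
    return SequenceSegment(center - dur / 2.0, dur, (amp, phase, offset_hz),
                           adc=adc)


def build_multi_spin_echo(te_spacing: float, n_echoes: int,
                          refocus_deg: float = 180.0,
                          spoil: str = "none",
                          b1: float = DEFAULT_RF_B1) -> Timeline:
    """CPMG multiple spin echo: 90x excitation, refocusing pulses along y
    at TE/2 + k*TE, ADC at the echo centers k*TE (k = 1..n).

    Time origin is the center of the excitation pulse, shifted so the
    first segment starts at t = 0.
    """
    if te_spacing <= 0 or n_echoes < 1:
        raise ValueError("te_spacing must be > 0 and n_echoes >= 1")
    dur90 = 90.0 / 360.0 / (GAMMA_HZ * b1)
    t0 = dur90 / 2.0  # center of excitation
    segs = [_hard_pulse(t0, 90.0, phase=0.0, b1=b1)]
    for k in range(n_echoes):
        t_ref = t0 + te_spacing / 2.0 + k * te_spacing
        t_echo = t0 + (k + 1) * te_spacing
        segs.append(_hard_pulse(t_ref, refocus_deg, phase=math.pi / 2.0, b1=b1))
        # short ADC window centered on the echo
        segs.append(SequenceSegment(t_echo - 1e-6, 2e-6, adc=(t_echo,)))
    tl = Timeline(segs, [], {"te_spacing": te_spacing, "n_echoes": n_echoes,
                             "refocus_deg": refocus_deg, "kind": "mse"})
    if spoil == "end":
        tl.events.append(ExternalEvent(segs[-1].end, "perfect_spoil"))
    return tl


def build_mt_spgr(tr: float, te: float, flip_deg: float,
                  mt_pulse: tuple | None = None, n_reps: int = 1,
                  adc_times_in_tr: tuple | None = None,
                  b1: float = DEFAULT_RF_B1) -> Timeline:
    """MT-weighted spoiled gradient echo.

    Each TR: [MT saturation pulse at its carrier offset] -> perfect
    spoil -> on-resonance excitation -> ADC at TE (or a sweep of sample
    times) -> end-of-TR perfect spoil.  ``mt_pulse`` is
    (offset_hz, equivalent_flip_deg, duration_s, shape); shape "block"
    only.  With ``mt_pulse=None`` this is a plain SPGR.
    """
    if te >= tr:
        raise ValueError("te must be < tr")
    segs, events = [], []
    adc_rel = tuple(adc_times_in_tr) if adc_times_in_tr is not None else (te,)
    for rep in range(n_reps):
        t = rep * tr
        if mt_pulse is not None:
            offset_hz, eq_flip, dur, shape = mt_pulse
            if shape != "block":
                raise ValueError("only block MT pulses are supported")
            amp = (eq_flip / 360.0) / (GAMMA_HZ * dur)
            segs.append(SequenceSegment(t, dur, (amp, 0.0, offset_hz)))
            t += dur
            events.append(ExternalEvent(t, "perfect_spoil"))
        exc_dur = abs(flip_deg) / 360.0 / (GAMMA_HZ * b1)
        segs.append(SequenceSegment(t, exc_dur, (b1, 0.0, 0.0)))
        t_center = t + exc_dur / 2.0
        for dt_adc in adc_rel:
            ta = t_center + dt_adc
            segs.append(SequenceSegment(ta - 1e-6, 2e-6, adc=(ta,)))
        events.append(ExternalEvent((rep + 1) * tr, "perfect_spoil"))
    # free precession to the end of the last TR, so the final spoil
    # event lies within the sequence span
    tail = n_reps * tr - segs[-1].end
    if tail > 0:
        segs.append(SequenceSegment(segs[-1].end, tail))
    return Timeline(segs, events,
                    {"tr": tr, "te": te, "flip_deg": flip_deg,
                     "mt_pulse": mt_pulse, "n_reps": n_reps, "kind": "mt_spgr"})


def build_afi(tr1: float, tr2: float, flip_deg: float, n_reps: int = 50,
              b1: float = DEFAULT_RF_B1) -> Timeline:
    """Actual flip-angle imaging: interleaved two-TR SPGR.

    Produces two ADC streams (S1 sampled after the TR1 excitation, S2
    after the TR2 excitation), with perfect spoiling at each TR end.
    The TR ratio n = TR2/TR1 is stored in the metadata.
    """
    if tr2 <= tr1:
        raise ValueError("tr2 must exceed tr1")
    segs, events, labels = [], [], []
    exc_dur = abs(flip_deg) / 360.0 / (GAMMA_HZ * b1) if flip_deg else 1e-6
    rf = (b1, 0.0, 0.0) if flip_deg else None
    t = 0.0
    te = exc_dur / 2.0 + 1e-4  # sample shortly after the pulse
    for _ in range(n_reps):
        for trk, label in ((tr1, "s1"), (tr2, "s2")):
            segs.append(SequenceSegment(t, exc_dur, rf))
            ta = t + exc_dur / 2.0 + te
            segs.append(SequenceSegment(ta - 1e-6, 2e-6, adc=(ta,)))
            labels.append(label)
            events.append(ExternalEvent(t + trk, "perfect_spoil"))
            t += trk
    if t > segs[-1].end:
        segs.append(SequenceSegment(segs[-1].end, t - segs[-1].end))
    return Timeline(segs, events,
                    {"tr1": tr1, "tr2": tr2, "n": tr2 / tr1,
                     "flip_deg": flip_deg, "n_reps": n_reps,
                     "adc_labels": labels, "kind": "afi"})


def default_cest_readout(b1: float = DEFAULT_RF_B1) -> Timeline:
    """90-degree excitation followed by one immediate ADC sample."""
    dur = 90.0 / 360.0 / (GAMMA_HZ * b1)
    ta = dur + 1e-5
    return Timeline([SequenceSegment(0.0, dur, (b1, 0.0, 0.0)),
                     SequenceSegment(ta - 1e-6, 2e-6, adc=(ta,))],
                    [], {"kind": "cest_readout"})


def build_cest_saturation(offsets_hz, sat_flip_deg: float,
                          sat_duration: float = 0.1,
                          readout: Timeline | None = None,
                          n_pulses: int = 10) -> list:
    """Z-spectrum acquisition: one timeline per saturation offset.

    The saturation block is a contiguous train of ``n_pulses`` block
    pulses of ``sat_duration`` seconds each, every pulse delivering the
    equivalent flip ``sat_flip_deg`` at the carrier offset, followed by
    a perfect spoil and the readout (default: hard 90 + ADC).
    """
    if readout is None:
        readout = default_cest_readout()
    amp = (sat_flip_deg / 360.0) / (GAMMA_HZ * sat_duration)
    out = []
    for off in offsets_hz:
        segs = [SequenceSegment(k * sat_duration, sat_duration,
                                (amp, 0.0, float(off)))
                for k in range(n_pulses)] if sat_flip_deg else []
        t_sat = n_pulses * sat_duration if sat_flip_deg else 0.0
        events = [ExternalEvent(t_sat, "perfect_spoil")]
        ro = readout.shifted(t_sat)
        tl = Timeline(segs + ro.segments, events + ro.events,
                      {"offset_hz": float(off), "sat_flip_deg": sat_flip_deg,
                       "sat_duration": sat_duration, "n_pulses": n_pulses,
                       "kind": "cest"})
        out.append(tl)
    return out


def build_bssfp(tr: float, te: float, flip_deg: float,
                matrix: tuple = (8, 8), fov: float = 0.04,
                b1: float = DEFAULT_RF_B1, n_prep: int = 30) -> Timeline:
    """Balanced SSFP with alternating RF phase and a Cartesian
    phase-encode loop; net gradient area per TR is zero on all axes.

    ``matrix`` = (n_read, n_phase); ``fov`` in meters (isotropic).
    ``n_prep`` alpha/2-prepared dummy TRs precede the acquisition.
    Read gradient along x with prephaser/rewinder; phase-encode blips
    along y paired with opposite rewinders.
    """
    nx, ny = matrix
    exc_dur = abs(flip_deg) / 360.0 / (GAMMA_HZ * b1)
    dk = 1.0 / fov
    t_blip = 0.2e-3
    # phase-encode blip gradient for ky step m: area = m*dk/gamma_hz
    segs = []
    phase = 0.0
    t = 0.0
    readout_bw = nx * dk / GAMMA_HZ  # T/m * s total read area
    t_read = max(tr / 3.0, 1e-3)
    g_read = nx * dk / (GAMMA_HZ * t_read)
    pe_lines = list(range(-(ny // 2), ny - ny // 2))
    total_trs = n_prep + ny
    for rep in range(total_trs):
        phase = math.pi * (rep % 2)
        segs.append(SequenceSegment(t, exc_dur, (b1, phase, 0.0)))
        t_c = t + exc_dur / 2.0
        acquiring = rep >= n_prep
        m = pe_lines[rep - n_prep] if acquiring else 0
        g_pe = m * dk / (GAMMA_HZ * t_blip) if m else 0.0
        # prephase read (-half area) + phase-encode blip
        segs.append(SequenceSegment(t + exc_dur, t_blip,
                                    gradient=(-g_read * t_read / (2 * t_blip),
                                              g_pe, 0.0)))
        # readout centered at TE
        t_ro = t_c + te - t_read / 2.0
        adc = tuple(t_ro + (k + 0.5) * t_read / nx
                    for k in range(nx)) if acquiring else ()
        segs.append(SequenceSegment(t_ro, t_read, gradient=(g_read, 0.0, 0.0),
                                    adc=adc))
        # rewind read (-half) and phase encode (-blip)
        segs.append(SequenceSegment(t_ro + t_read, t_blip,
                                    gradient=(-g_read * t_read / (2 * t_blip),
                                              -g_pe, 0.0)))
        t += tr
    return Timeline(segs, [],
                    {"tr": tr, "te": te, "flip_deg": flip_deg,
                     "matrix": matrix, "fov": fov, "n_prep": n_prep,
                     "pe_lines": pe_lines, "kind": "bssfp"})


def export_waveforms(timeline: Timeline, path) -> None:
    """Write (time, channel, value) tab-separated waveform samples."""
    with open(path, "w") as fh:
        fh.write("# time_s\tchannel\tvalue\n")
        for s in timeline.segments:
            if s.rf is not None:
                fh.write(f"{s.start:.9g}\trf_amp_T\t{s.rf[0]:.9g}\n")
                fh.write(f"{s.start:.9g}\trf_phase_rad\t{s.rf[1]:.9g}\n")
                fh.write(f"{s.start:.9g}\trf_offset_hz\t{s.rf[2]:.9g}\n")
            for ax, g in zip("xyz", s.gradient):
                if g:
                    fh.write(f"{s.start:.9g}\tg{ax}_T_per_m\t{g:.9g}\n")
            for tadc in s.adc:
                fh.write(f"{tadc:.9g}\tadc\t1\n")
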