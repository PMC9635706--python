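"""Frequency- and energy-domain pulse wave analysis.

Aortic input impedance (harmonic pressure/flow ratio), wave intensity
dI = dP·dU with forward/backward peak labelling, and foot-to-foot pulse
wave velocity by the intersecting-tangent rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import units as U
from .beat_features import BeatIndex, detect_beats, lowpass
from .record import WaveformRecord

__all__ = [
    "ImpedanceSpectrum", "WaveIntensityResult", "WIPeak", "PWVEstimate",
    "ensemble_average_beat", "input_impedance", "wave_intensity",
    "detect_wi_peaks", "foot_to_foot_pwv", "velocity_from_flow",
]


# ---------------------------------------------------------------------------
# ensemble averaging
# ---------------------------------------------------------------------------

def ensemble_average_beat(record: WaveformRecord,
                          beats: BeatIndex | None = None) -> WaveformRecord:
    """Average the accepted beats into one representative beat.

    Beats are resampled to the median beat length and averaged pointwise;
    flow/velocity channels are averaged with the same windows. A single
    available beat is passed through with a warning.
    """
    if beats is None:
        beats = detect_beats(record.pressure, record.fs,
                             record.meta.get("hr_bpm"))
    wins = [(int(a), int(b)) for a, b in
            zip(beats.onsets[:-1], beats.onsets[1:])]
    if beats.accepted.size == len(wins):
        wins = [w for w, ok in zip(wins, beats.accepted) if ok] or wins
    if len(wins) < 2:
        warnings.warn("fewer than 2 accepted beats; returning the record "
                      "unchanged", RuntimeWarning, stacklevel=2)
        if len(wins) == 1:
            a, b = wins[0]
            return _slice_record(record, a, b)
        return record

    n = int(np.median([b - a for a, b in wins]))
    xi = np.arange(n)

    def avg(arr):
        if arr is None:
            return None
        acc = np.zeros(n)
        for a, b in wins:
            seg = arr[a:b]
            acc += np.interp(xi * (seg.size - 1) / (n - 1),
                             np.arange(seg.size), seg)
        return acc / len(wins)

    return WaveformRecord(
        site=record.site, fs=record.fs, t=np.arange(n) / record.fs,
        pressure=avg(record.pressure), flow=avg(record.flow),
        velocity=avg(record.velocity),
        meta={**record.meta, "ensemble_n_beats": len(wins)},
    )


def _slice_record(record: WaveformRecord, a: int, b: int) -> WaveformRecord:
    sl = slice(a, b)
    return WaveformRecord(
        site=record.site, fs=record.fs,
        t=np.arange(b - a) / record.fs,
        pressure=record.pressure[sl],
        flow=None if record.flow is None else record.flow[sl],
        velocity=None if record.velocity is None else record.velocity[sl],
        meta=dict(record.meta))


# ---------------------------------------------------------------------------
# input impedance
# ---------------------------------------------------------------------------

@dataclass
class ImpedanceSpectrum:
    """Harmonic input impedance z(ω) = p(ω)/q(ω) of one beat.

    modulus in mmHg·s/mL, phase wrapped to (-pi, pi]; harmonic 0 is the
    mean-pressure/mean-flow ratio (phase 0), also exposed in mmHg·min/L.
    Harmonics whose flow power is negligible are flagged unreliable rather
    than dropped.
    """

    harmonic: np.ndarray       # 0..k_max
    frequency: np.ndarray      # Hz
    modulus: np.ndarray        # mmHg·s/mL
    phase: np.ndarray          # rad, (-pi, pi]
    reliable: np.ndarray       # bool per harmonic
    z0_mmhg_min_per_l: float

    def __post_init__(self):
        assert self.frequency[0] == 0.0


def input_impedance(pressure_mmhg, flow_mls, fs: float,
                    k_max: int = 15) -> ImpedanceSpectrum:
    """Discrete Fourier impedance over one beat-periodic window.

    pressure in mmHg, flow in mL/s. modulus_k = |p_k|/|q_k|,
    phase_k = arg(p_k) - arg(q_k) wrapped to (-pi, pi]; harmonic 0 is
    mean(P)/mean(Q). Harmonics with |q_k| below 1e-9·|q_1| are flagged.
    """
    p = np.asarray(pressure_mmhg, dtype=float)
    q = np.asarray(flow_mls, dtype=float)
    if p.size != q.size:
        raise ValueError("pressure and flow must have equal length")
    if p.size < 4:
        raise ValueError("beat too short")
    if q.mean() <= 0:
        raise ValueError("mean flow must be > 0")
    n = p.size
    pk = np.fft.rfft(p) / n
    qk = np.fft.rfft(q) / n
    k_max = min(k_max, pk.size - 1)
    k = np.arange(k_max + 1)
    f0 = fs / n
    q1 = np.abs(qk[1]) if qk.size > 1 else np.abs(qk[0])
    reliable = np.abs(qk[k]) > 1e-9 * max(q1, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        modulus = np.abs(pk[k]) / np.abs(qk[k])
        phase = np.angle(pk[k]) - np.angle(qk[k])
    modulus = np.where(np.isfinite(modulus), modulus, np.inf)
    phase = np.mod(phase + math.pi, 2.0 * math.pi) - math.pi
    phase = np.where(phase == -math.pi, math.pi, phase)
    modulus[0] = p.mean() / q.mean()
    phase[0] = 0.0
    # mmHg/(mL/s) -> mmHg/(L/min): 1 mL/s = 0.06 L/min
    z0_lmin = modulus[0] / 0.06
    return ImpedanceSpectrum(harmonic=k, frequency=k * f0, modulus=modulus,
                             phase=phase, reliable=reliable,
                             z0_mmhg_min_per_l=float(z0_lmin))


# ---------------------------------------------------------------------------
# wave intensity
# ---------------------------------------------------------------------------

@dataclass
class WIPeak:
    label: str        # Wf1 | Wb | Wf2
    amplitude: float
    time: float       # s


@dataclass
class WaveIntensityResult:
    """dI(t) and its labelled peaks.

    convention "time-normalized" (default): dI = (dP/dt)(dU/dt) from
    smoothed central differences, units mmHg·m/s^3; "per-sample": the
    literal dI = ΔP·ΔU per sampling interval, units mmHg·m/s (sampling
    dependent). Both share the same zero-crossing structure.
    """

    t: np.ndarray
    di: np.ndarray
    convention: str
    peaks: list = field(default_factory=list)

    def peak(self, label: str) -> WIPeak | None:
        for p in self.peaks:
            if p.label == label:
                return p
        return None


def wave_intensity(pressure_mmhg, velocity_ms, fs: float,
                   convention: str = "time-normalized",
                   detect_peaks: bool = True,
                   min_prominence: float = 0.005) -> WaveIntensityResult:
    """Wave intensity dI = dP·dU of time-aligned pressure and velocity."""
    p = np.asarray(pressure_mmhg, dtype=float)
    u = np.asarray(velocity_ms, dtype=float)
    if p.size != u.size:
        raise ValueError("pressure and velocity must have equal length")
    if convention == "per-sample":
        di = np.diff(p) * np.diff(u)
        t = (np.arange(di.size) + 0.5) / fs
    elif convention == "time-normalized":
        dp = np.gradient(lowpass(p, fs)) * fs
        du = np.gradient(lowpass(u, fs)) * fs
        di = dp * du
        t = np.arange(di.size) / fs
    else:
        raise ValueError("convention must be 'time-normalized' or 'per-sample'")
    res = WaveIntensityResult(t=t, di=di, convention=convention)
    if detect_peaks:
        res.peaks = detect_wi_peaks(res, min_prominence)
    return res


def detect_wi_peaks(wi: WaveIntensityResult,
                    min_prominence: float = 0.005) -> list[WIPeak]:
    """Label the classic three-peak pattern.

    Wf1: the dominant forward-compression peak (largest positive peak);
    Wb: the most negative excursion after Wf1 (the reflected backward
    compression); Wf2: the largest positive peak after Wb (the forward
    decompression at valve closure). Absent peaks are reported absent,
    never fabricated. ``min_prominence`` is a fraction of max |dI|.
    """
    di, t = wi.di, wi.t
    if di.size == 0:
        raise ValueError("empty dI")
    scale = float(np.max(np.abs(di)))
    if scale <= 0:
        return []
    thr = min_prominence * scale
    pos_idx, _ = sps.find_peaks(di, prominence=thr)
    peaks: list[WIPeak] = []
    if pos_idx.size == 0:
        return peaks
    i_f1 = int(pos_idx[np.argmax(di[pos_idx])])
    peaks.append(WIPeak("Wf1", float(di[i_f1]), float(t[i_f1])))
    tail = di[i_f1 + 1:]
    if tail.size == 0:
        return peaks
    i_b = i_f1 + 1 + int(np.argmin(tail))
    if di[i_b] < -thr:
        peaks.append(WIPeak("Wb", float(di[i_b]), float(t[i_b])))
        tail2_idx = pos_idx[pos_idx > i_b]
        if tail2_idx.size:
            i_f2 = int(tail2_idx[np.argmax(di[tail2_idx])])
            peaks.append(WIPeak("Wf2", float(di[i_f2]), float(t[i_f2])))
    return peaks


# ---------------------------------------------------------------------------
# foot-to-foot PWV
# ---------------------------------------------------------------------------

@dataclass
class PWVEstimate:
    transit_time: float       # s
    path_distance: float      # m
    pwv: float                # m/s
    foot_times: tuple         # (proximal s, distal s) of the first used pair

    def __post_init__(self):
        assert self.transit_time > 0
        assert abs(self.pwv - self.path_distance / self.transit_time) < 1e-9


def foot_to_foot_pwv(p_prox, p_dist, fs: float,
                     path_distance: float,
                     hr_hint: float | None = None) -> PWVEstimate:
    """Foot-to-foot pulse wave velocity between two pressure taps.

    Feet are located per beat by the intersecting-tangent rule on each
    trace (sub-sample precision); the transit time is the median of the
    per-beat proximal-to-distal foot delays and PWV = distance/transit.
    """
    if path_distance <= 0:
        raise ValueError("path_distance must be > 0")
    b_prox = detect_beats(p_prox, fs, hr_hint)
    b_dist = detect_beats(p_dist, fs, hr_hint)
    period = 60.0 / b_prox.hr_estimate
    delays, pairs = [], []
    for tp in b_prox.foot_times_s:
        later = b_dist.foot_times_s[(b_dist.foot_times_s > tp)
                                    & (b_dist.foot_times_s < tp + 0.9 * period)]
        if later.size:
            delays.append(float(later[0] - tp))
            pairs.append((float(tp), float(later[0])))
    if not delays:
        raise ValueError("transit time unresolvable: no distal foot follows "
                         "a proximal foot within one beat")
    tt = float(np.median(delays))
    if tt <= 0 or tt < 1.0 / fs:
        raise ValueError(
            f"transit time {tt * 1e3:.3f} ms unresolvable at fs = {fs} Hz")
    return PWVEstimate(transit_time=tt, path_distance=path_distance,
                       pwv=path_distance / tt, foot_times=pairs[0])


def velocity_from_flow(flow_lmin, diameter_mm: float):
    """Cross-sectionally averaged velocity U = Q/(pi d^2/4), m/s."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be > 0")
    area = math.pi * (diameter_mm * 1e-3) ** 2 / 4.0
    q = np.asarray(flow_lmin, dtype=float) * U.LMIN_M3S
    u = q / area
    return u if u.ndim else float(u)
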