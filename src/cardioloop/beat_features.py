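"""Per-beat and ensemble scalar indices from pressure/flow traces.

Implements the standard pulse-wave-analysis toolbox: intersecting-tangent
beat-foot detection, systolic/diastolic extrema, time-averaged and
one-third-rule mean pressures, form factor, augmentation index, dp/dt_max,
LVEDP, stroke volume, total peripheral resistance, and static-inflation
compliance, plus a `summarize` aggregator that never crashes on a single
failed index (missing quantities carry a reason code).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .record import WaveformRecord

__all__ = [
    "BeatIndex", "FeatureSummary", "AugmentationResult",
    "detect_beats", "extract_extrema", "mean_pressure", "map_onethird",
    "form_factor", "augmentation_index", "dpdt_max", "lvedp_extract",
    "tpr", "stroke_volume", "compliance_from_inflation",
    "detect_dicrotic_notch", "summarize", "tile_periodic",
]

_LP_CUTOFF_HZ = 25.0
_LP_ORDER = 4


class DetectionError(ValueError):
    """No usable beats in the signal."""


def lowpass(x: np.ndarray, fs: float, cutoff: float = _LP_CUTOFF_HZ,
            order: int = _LP_ORDER) -> np.ndarray:
    """Zero-phase Butterworth low-pass; identity when fs is too low."""
    x = np.asarray(x, dtype=float)
    if fs <= 2.0 * cutoff * 1.05 or x.size < 12:
        return x
    sos = sps.butter(order, cutoff, fs=fs, output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1), x.size - 1)
    return sps.sosfiltfilt(sos, x, padlen=padlen)


# ---------------------------------------------------------------------------
# beat detection
# ---------------------------------------------------------------------------

@dataclass
class BeatIndex:
    """Beat feet located by the intersecting-tangent rule.

    onsets are sample indices (strictly increasing); foot_times_s the
    sub-sample foot instants; accepted marks beats whose spacing lies
    within +/-20 % of the median spacing.
    """

    onsets: np.ndarray
    foot_times_s: np.ndarray
    hr_estimate: float
    accepted: np.ndarray = field(default=None)

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=int)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.foot_times_s is None:
            self.foot_times_s = self.onsets.astype(float)
        self.foot_times_s = np.asarray(self.foot_times_s, dtype=float)
        if self.accepted is None:
            self.accepted = _accept_spacing(self.onsets)
        self.accepted = np.asarray(self.accepted, dtype=bool)

    @property
    def n_beats(self) -> int:
        return max(0, self.onsets.size - 1)


def _accept_spacing(onsets: np.ndarray, tol: float = 0.2) -> np.ndarray:
    """Beat-length gate: intervals deviating >20 % from the median spacing
    are excluded from ensemble statistics."""
    if onsets.size < 2:
        return np.zeros(0, dtype=bool)
    gaps = np.diff(onsets).astype(float)
    med = np.median(gaps)
    return np.abs(gaps - med) <= tol * med


def detect_beats(pressure, fs: float, hr_hint: float | None = None) -> BeatIndex:
    """Locate beat feet with the intersecting-tangent rule.

    The tangent at the point of maximum upstroke slope is intersected with
    the horizontal line through the preceding pressure minimum; the
    intersection is the wave foot.
    """
    p = np.asarray(pressure, dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if p.size / fs < 2.0:
        raise ValueError("need at least 2 s of signal")
    pf = lowpass(p, fs)
    rng = float(pf.max() - pf.min())
    if rng < 1e-9:
        raise DetectionError("no detectable upstrokes (flat signal)")

    d = np.gradient(pf) * fs
    if hr_hint is not None and hr_hint > 0:
        min_dist = int(0.5 * 60.0 / hr_hint * fs)
    else:
        min_dist = int(0.3 * fs)
    peaks, _ = sps.find_peaks(d, height=0.35 * d.max(),
                              distance=max(1, min_dist))
    if peaks.size == 0 or d.max() <= 0:
        raise DetectionError("no detectable upstrokes")

    onsets, feet = [], []
    prev = 0
    for m in peaks:
        lo = prev
        seg = pf[lo:m + 1]
        if seg.size == 0:
            prev = m
            continue
        i_min = lo + int(np.argmin(seg))
        # robust horizontal level: median over a short window around the
        # minimum, not the single (noise-prone) lowest sample
        w = max(1, int(0.015 * fs))
        p_min = float(np.median(pf[max(0, i_min - w):i_min + w + 1]))
        # tangent point: the mid-amplitude crossing of the upstroke (far
        # more noise-stable than the argmax of the derivative); slope by
        # least squares over +/-10 ms around it
        hi = min(pf.size, m + int(0.25 * fs))
        p_max = float(pf[m:hi].max()) if hi > m else float(pf[m])
        half = 0.5 * (p_min + p_max)
        above = np.nonzero(pf[i_min:hi] >= half)[0]
        c = i_min + int(above[0]) if above.size else m
        w2 = max(1, int(0.010 * fs))
        a, bnd = max(0, c - w2), min(pf.size, c + w2 + 1)
        xs = np.arange(a, bnd)
        slope, intercept = np.polyfit(xs / fs, pf[a:bnd], 1)
        if slope <= 0:
            prev = m
            continue
        t_foot = (p_min - intercept) / slope
        t_foot = max(t_foot, i_min / fs)
        idx = int(round(t_foot * fs))
        if 0 <= idx < p.size and (not onsets or idx > onsets[-1]):
            onsets.append(idx)
            feet.append(t_foot)
        prev = m
    if len(onsets) == 0:
        raise DetectionError("no beat feet found")

    onsets = np.asarray(onsets, dtype=int)
    feet = np.asarray(feet)
    if onsets.size >= 2:
        hr = 60.0 * fs / float(np.median(np.diff(onsets)))
    elif hr_hint:
        hr = float(hr_hint)
    else:
        hr = 60.0 * fs / p.size
    return BeatIndex(onsets=onsets, foot_times_s=feet, hr_estimate=hr)


# ---------------------------------------------------------------------------
# scalar indices
# ---------------------------------------------------------------------------

class Extrema(NamedTuple):
    sbp: float
    dbp: float
    pp: float
    sbp_per_beat: np.ndarray
    dbp_per_beat: np.ndarray


def _beat_windows(beats: BeatIndex):
    if beats.n_beats < 1:
        raise ValueError("need at least one complete beat")
    return [(int(a), int(b)) for a, b in zip(beats.onsets[:-1], beats.onsets[1:])]


def extract_extrema(pressure, beats: BeatIndex) -> Extrema:
    """Per-beat max/min between consecutive feet; summary = median."""
    p = np.asarray(pressure, dtype=float)
    sbp, dbp = [], []
    for a, b in _beat_windows(beats):
        seg = p[a:b + 1]
        sbp.append(float(seg.max()))
        dbp.append(float(seg.min()))
    sbp, dbp = np.asarray(sbp), np.asarray(dbp)
    return Extrema(float(np.median(sbp)), float(np.median(dbp)),
                   float(np.median(sbp) - np.median(dbp)), sbp, dbp)


def mean_pressure(pressure, beats: BeatIndex, fs: float | None = None) -> float:
    """Trapezoidal time average over an integer number of beats (mmHg)."""
    p = np.asarray(pressure, dtype=float)
    a, b = int(beats.onsets[0]), int(beats.onsets[-1])
    if b <= a:
        raise ValueError("need at least one complete beat")
    return float(np.trapezoid(p[a:b + 1]) / (b - a))


def map_onethird(sbp: float, dbp: float) -> float:
    """Classic one-third rule: MAP = DBP + (SBP - DBP)/3."""
    if sbp < dbp:
        raise ValueError("sbp must be >= dbp")
    return dbp + (sbp - dbp) / 3.0


def form_factor(map_mmhg: float, sbp: float, dbp: float) -> float:
    """FF = MPP/PP = (MAP - DBP)/(SBP - DBP), a pulse-shape index in [0, 1]."""
    if sbp == dbp:
        raise ValueError("form factor undefined for zero pulse pressure")
    if not (dbp <= map_mmhg <= sbp) or sbp < dbp:
        raise ValueError("require dbp <= map <= sbp")
    return (map_mmhg - dbp) / (sbp - dbp)


@dataclass
class AugmentationResult:
    defined: bool
    aix: float | None = None     # %
    ap: float | None = None      # mmHg
    pi: float | None = None      # mmHg
    sbp: float | None = None
    pp: float | None = None
    waveform_type: str = "undefined"


def augmentation_index(pressure, fs: float) -> AugmentationResult:
    """AIx = 100*(SBP - Pi)/PP on a single representative beat.

    The inflection Pi is the first (- to +) zero crossing of the smoothed
    second derivative after the point of maximum upstroke slope and before
    the systolic peak (type A, positive AP). If none exists there, the
    window just after the peak is searched (type C, negative-AP
    convention); with no inflection at all the result is flagged undefined.
    """
    p = np.asarray(pressure, dtype=float)
    if p.size / fs < 0.2:
        raise ValueError("beat shorter than 0.2 s")
    pf = lowpass(p, fs)
    sbp = float(pf.max())
    dbp = float(pf.min())
    pp = sbp - dbp
    if pp <= 0:
        return AugmentationResult(defined=False)
    i_peak = int(np.argmax(pf))
    d1 = np.gradient(pf) * fs
    d2 = np.gradient(d1) * fs
    i_slope = int(np.argmax(d1[:max(i_peak, 1)])) if i_peak > 0 else 0

    def _first_up_crossing(lo, hi):
        for i in range(lo, min(hi, d2.size - 1)):
            if d2[i] < 0.0 <= d2[i + 1]:
                frac = -d2[i] / (d2[i + 1] - d2[i])
                return i + frac
        return None

    x = _first_up_crossing(i_slope + 1, i_peak)
    if x is not None:
        pi = float(np.interp(x, np.arange(pf.size), pf))
        ap = sbp - pi
        return AugmentationResult(True, 100.0 * ap / pp, ap, pi, sbp, pp, "A")
    # late shoulder (type C): a complete inflection pair after the peak —
    # d2 must cross up AND come back down (a bare monotone decay, e.g. a
    # Gaussian tail, has only the up-crossing and stays undefined)
    x = _first_up_crossing(i_peak + 1, i_peak + 1 + int(0.15 * fs))
    if x is not None:
        i_x = int(math.ceil(x))
        hi = min(i_peak + 1 + int(0.15 * fs), d2.size - 1)
        has_down = any(d2[i] > 0.0 >= d2[i + 1] for i in range(i_x, hi))
        if has_down:
            pi = float(np.interp(x, np.arange(pf.size), pf))
            ap = pi - sbp  # negative-AP convention: shoulder after the peak
            return AugmentationResult(True, 100.0 * ap / pp, ap, pi, sbp, pp,
                                      "C")
    return AugmentationResult(defined=False, sbp=sbp, pp=pp)


def dpdt_max(pressure, fs: float, beats: BeatIndex) -> float:
    """Median over beats of the maximum smoothed pressure derivative
    (central difference after a 25 Hz zero-phase low-pass), mmHg/s."""
    p = np.asarray(pressure, dtype=float)
    d = np.gradient(lowpass(p, fs)) * fs
    vals = [float(d[a:b + 1].max()) for a, b in _beat_windows(beats)]
    return float(np.median(vals))


def lvedp_extract(lv_pressure, fs: float, beats: BeatIndex,
                  slope_fraction: float = 0.02) -> float:
    """LV end-diastolic pressure, median across beats (mmHg).

    For each detected upstroke the onset of systole is the last
    pre-upstroke sample where the smoothed dP/dt is below
    ``slope_fraction`` of that beat's peak upstroke slope (walking back
    from the point of maximum slope). This reads the end-diastolic
    plateau rather than a point on the (initially gentle) upstroke.
    """
    p = np.asarray(lv_pressure, dtype=float)
    idx = beats.onsets[beats.onsets < p.size]
    if idx.size == 0:
        raise ValueError("no beat feet inside the trace")
    pf = lowpass(p, fs)
    d = np.gradient(pf) * fs
    vals = []
    for o in idx:
        hi = min(p.size, o + int(0.25 * fs))
        if hi <= o + 1:
            vals.append(float(p[o]))
            continue
        m = o + int(np.argmax(d[o:hi]))
        thr = slope_fraction * max(d[m], 1e-12)
        i = m
        lo = max(0, o - int(0.15 * fs))
        while i > lo and d[i] > thr:
            i -= 1
        vals.append(float(p[i]))
    return float(np.median(vals))


def tpr(map_mmhg: float, co_lmin: float) -> float:
    """Total peripheral resistance MAP/CO in mmHg·min/L (venous pressure
    neglected, the convention used for bench reporting)."""
    if co_lmin <= 0:
        raise ValueError("co must be > 0")
    return map_mmhg / co_lmin


class StrokeVolume(NamedTuple):
    ml: float
    ml_rounded: int


def stroke_volume(co_lmin: float, hr_bpm: float) -> StrokeVolume:
    """SV = 1000*CO/HR, mL/beat (full precision and nearest-mL)."""
    if hr_bpm <= 0:
        raise ValueError("hr must be > 0")
    sv = 1000.0 * co_lmin / hr_bpm
    return StrokeVolume(sv, int(round(sv)))


def compliance_from_inflation(volumes_ml, pressures_mmhg) -> float:
    """Least-squares slope of volume vs pressure (mL/mmHg) from a static
    incremental-inflation experiment."""
    v = np.asarray(volumes_ml, dtype=float)
    p = np.asarray(pressures_mmhg, dtype=float)
    if v.size != p.size or v.size < 2:
        raise ValueError("need >= 2 matched (volume, pressure) points")
    if np.ptp(p) <= 0:
        raise ValueError("degenerate inflation data (constant pressure)")
    return float(np.polyfit(p, v, 1)[0])


def detect_dicrotic_notch(pressure, fs: float, beats: BeatIndex) -> float | None:
    """Time from the beat foot to the dicrotic notch (the incisure after
    the systolic peak), median across beats; None when absent."""
    p = lowpass(np.asarray(pressure, dtype=float), fs)
    times = []
    for a, b in _beat_windows(beats):
        seg = p[a:b + 1]
        i_peak = int(np.argmax(seg))
        tail = seg[i_peak:]
        if tail.size < 5:
            continue
        dips, props = sps.find_peaks(-tail, prominence=0.01 * np.ptp(seg))
        # the notch must be followed by a secondary (dicrotic) rise
        for i_dip in dips:
            if i_dip + 1 < tail.size and tail[i_dip:].max() > tail[i_dip]:
                times.append((i_peak + i_dip) / fs)
                break
    return float(np.median(times)) if times else None


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class FeatureSummary:
    """Per-recording scalar indices; every absent field has a reason code."""

    site: str
    sbp: float | None = None
    dbp: float | None = None
    pp: float | None = None
    map_timeavg: float | None = None
    map_onethird: float | None = None
    ff: float | None = None
    aix: float | None = None          # %
    ap: float | None = None           # mmHg
    pi: float | None = None           # mmHg
    dpdt_max: float | None = None     # mmHg/s
    lvedp: float | None = None        # mmHg, LV site only
    sv: float | None = None           # mL/beat
    co: float | None = None           # L/min
    tpr: float | None = None          # mmHg·min/L
    ac: float | None = None           # mL/mmHg
    notch_time: float | None = None   # s from beat foot
    hr_estimate: float | None = None  # bpm
    reasons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return d


def summarize(record: WaveformRecord,
              co_lmin: float | None = None,
              inflation: tuple | None = None,
              hr_hint: float | None = None) -> FeatureSummary:
    """Fill every derivable index for one recording.

    ``co_lmin`` overrides the flow-derived cardiac output (e.g. the
    simulator's measured CO); ``inflation`` is an optional
    (volumes_ml, pressures_mmhg) pair from a static compliance run.
    Constituent failures become absent fields with a reason code.
    """
    out = FeatureSummary(site=record.site)
    try:
        beats = detect_beats(record.pressure, record.fs,
                             hr_hint or record.meta.get("hr_bpm"))
    except (ValueError, DetectionError) as e:
        if record.t.size >= 2 and record.meta.get("periodic", True):
            # single simulated steady-state cycle: wrap it so the windowed
            # estimators see complete beats
            try:
                rec3, beats = tile_periodic(record)
                return _summarize_with(rec3, beats, out, co_lmin, inflation)
            except (ValueError, DetectionError) as e2:
                out.reasons["all"] = f"beat detection failed: {e2}"
                return out
        out.reasons["all"] = f"beat detection failed: {e}"
        return out
    return _summarize_with(record, beats, out, co_lmin, inflation)


def tile_periodic(record: WaveformRecord, reps: int | None = None):
    """Tile a single steady-state cycle into enough copies for the
    windowed estimators (>= 2.5 s and >= 3 beats). Returns
    (tiled_record, beats)."""
    n = record.t.size
    if reps is None:
        reps = max(3, int(np.ceil(2.5 * record.fs / n)) + 1)
    t = np.arange(reps * n) / record.fs
    rec = WaveformRecord(
        site=record.site, fs=record.fs, t=t,
        pressure=np.tile(record.pressure, reps),
        flow=None if record.flow is None else np.tile(record.flow, reps),
        velocity=(None if record.velocity is None
                  else np.tile(record.velocity, reps)),
        meta=dict(record.meta),
    )
    beats = detect_beats(rec.pressure, rec.fs, rec.meta.get("hr_bpm"))
    return rec, beats


def _summarize_with(record, beats, out, co_lmin, inflation):
    p = record.pressure
    fs = record.fs
    out.hr_estimate = beats.hr_estimate
    try:
        ex = extract_extrema(p, beats)
        out.sbp, out.dbp, out.pp = ex.sbp, ex.dbp, ex.pp
        out.map_onethird = map_onethird(ex.sbp, ex.dbp)
    except ValueError as e:
        out.reasons["sbp"] = str(e)
    try:
        out.map_timeavg = mean_pressure(p, beats, fs)
        if out.sbp is not None:
            m = min(max(out.map_timeavg, out.dbp), out.sbp)
            out.ff = form_factor(m, out.sbp, out.dbp)
    except ValueError as e:
        out.reasons["map_timeavg"] = str(e)
    try:
        out.dpdt_max = dpdt_max(p, fs, beats)
    except ValueError as e:
        out.reasons["dpdt_max"] = str(e)
    try:
        a, b = _representative_beat(beats)
        aug = augmentation_index(p[a:b + 1], fs)
        if aug.defined:
            out.aix, out.ap, out.pi = aug.aix, aug.ap, aug.pi
        else:
            out.reasons["aix"] = "no inflection"
    except ValueError as e:
        out.reasons["aix"] = str(e)
    out.notch_time = detect_dicrotic_notch(p, fs, beats)
    if out.notch_time is None:
        out.reasons["notch_time"] = "no notch"
    if record.site == "LV":
        out.lvedp = lvedp_extract(p, fs, beats)
    else:
        out.reasons["lvedp"] = "site"

    co = co_lmin
    if co is None and record.flow is not None:
        a, b = int(beats.onsets[0]), int(beats.onsets[-1])
        co = float(np.mean(record.flow[a:b + 1]))
    if co is not None and co > 0:
        out.co = co
        hr = out.hr_estimate or record.meta.get("hr_bpm")
        if hr:
            out.sv = stroke_volume(co, hr).ml
        if out.map_timeavg is not None:
            out.tpr = tpr(out.map_timeavg, co)
    else:
        out.reasons["co"] = "no flow"
        out.reasons["tpr"] = "no flow"
        out.reasons["sv"] = "no flow"
    if inflation is not None:
        try:
            out.ac = compliance_from_inflation(*inflation)
        except ValueError as e:
            out.reasons["ac"] = str(e)
    else:
        out.reasons["ac"] = "no inflation data"
    return out


def _representative_beat(beats: BeatIndex) -> tuple[int, int]:
    """The accepted beat whose length is closest to the median length."""
    wins = _beat_windows(beats)
    lens = np.array([b - a for a, b in wins])
    ok = beats.accepted if beats.accepted.size == lens.size else np.ones(
        lens.size, dtype=bool)
    cand = np.where(ok)[0]
    if cand.size == 0:
        cand = np.arange(lens.size)
    med = np.median(lens[cand])
    pick = cand[int(np.argmin(np.abs(lens[cand] - med)))]
    return wins[pick]
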