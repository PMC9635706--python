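import math

import numpy as np
import pytest

from cardioloop import circuit_sim as cs
from cardioloop import beat_features as bf
from cardioloop.record import WaveformRecord

_SIM_CACHE: dict = {}


@pytest.fixture(scope="session")
def sim():
    """Memoized preset simulations (the heavy fixture of the suite)."""
    def get(name: str) -> cs.SimResult:
        if name not in _SIM_CACHE:
            _SIM_CACHE[name] = cs.simulate(cs.make_preset(name))
        return _SIM_CACHE[name]
    return get


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def synthetic_pulse(fs=1000.0, hr=75.0, n_beats=5, dbp=80.0, sbp=120.0,
                    sys_frac=0.35):
    """Smooth periodic arterial-like pulse with feet at the beat starts."""
    period = 60.0 / hr
    n = int(round(n_beats * period * fs))
    t = np.arange(n) / fs
    phase = np.mod(t, period) / period
    shape = np.where(phase < sys_frac,
                     np.sin(np.pi * phase / sys_frac) ** 2,
                     0.0)
    return t, dbp + (sbp - dbp) * shape


def tiled_record(rec: WaveformRecord, min_duration=2.5) -> WaveformRecord:
    """Tile a single simulated cycle so windowed estimators see full beats."""
    reps = max(3, math.ceil(min_duration * rec.fs / rec.t.size) + 1)
    n = rec.t.size * reps
    return WaveformRecord(
        site=rec.site, fs=rec.fs, t=np.arange(n) / rec.fs,
        pressure=np.tile(rec.pressure, reps),
        flow=None if rec.flow is None else np.tile(rec.flow, reps),
        velocity=None if rec.velocity is None else np.tile(rec.velocity, reps),
        meta=dict(rec.meta))


def lvedp_of(res: cs.SimResult) -> float:
    rec = tiled_record(res.records["LV"])
    beats = bf.detect_beats(rec.pressure, rec.fs, res.config.hr)
    return bf.lvedp_extract(rec.pressure, rec.fs, beats)


def map_of(res: cs.SimResult, site="ascending_aorta") -> float:
    rec = tiled_record(res.records[site])
    beats = bf.detect_beats(rec.pressure, rec.fs, res.config.hr)
    return bf.mean_pressure(rec.pressure, beats)


def dpdt_of(res: cs.SimResult, site="ascending_aorta") -> float:
    rec = tiled_record(res.records[site])
    beats = bf.detect_beats(rec.pressure, rec.fs, res.config.hr)
    return bf.dpdt_max(rec.pressure, rec.fs, beats)


def pp_of(res: cs.SimResult, site="ascending_aorta") -> float:
    return float(np.ptp(res.records[site].pressure))
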