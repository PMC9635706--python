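"""The waveform container shared by the simulator and the analysis layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SITES = ("LA", "LV", "ascending_aorta", "abdominal_aorta", "other")

_T_UNIFORM_TOL = 1e-6  # s


@dataclass
class WaveformRecord:
    """One site's uniformly sampled trace.

    pressure in mmHg, optional flow in L/min and velocity in m/s; ``t`` in
    seconds, uniformly spaced at 1/fs.
    """

    site: str
    fs: float
    t: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray | None = None
    velocity: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self.t = np.asarray(self.t, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.t.size != self.pressure.size:
            raise ValueError("t and pressure must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.fs)) > _T_UNIFORM_TOL:
                bad = int(np.argmax(np.abs(dt - 1.0 / self.fs))) + 1
                raise ValueError(
                    f"t must be uniformly spaced at 1/fs; first offending "
                    f"sample index {bad}")
        for name in ("flow", "velocity"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != self.t.size:
                    raise ValueError(f"{name} length must match t")
                setattr(self, name, arr)

    @property
    def duration(self) -> float:
        return self.t.size / self.fs

    def __len__(self) -> int:
        return self.t.size
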