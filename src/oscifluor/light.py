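"""Harmonic light-forcing waveforms and experimental schedules.

A protocol consists of a constant pre-illumination phase followed by an
ordered sequence of sinusoidal oscillation segments.  Each segment
oscillates between u_min and u_max with period T for a whole number of
cycles, starting at the minimum and ascending:

    u(t_seg) = u0 - u1*cos(2*pi*t_seg/T),   u0 = (u_min+u_max)/2,
                                            u1 = (u_max-u_min)/2.

An optional quantizer emulates the instrument's digital-to-analog light
control by rounding the ideal sine to a fixed number of equally spaced
intensity levels within [u_min, u_max].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["LightProtocol", "standard_schedule", "STANDARD_QUANTIZATION"]

#: DAC step counts reported for the three standard oscillation ranges
STANDARD_QUANTIZATION = {(100.0, 200.0): 8, (100.0, 400.0): 22, (100.0, 800.0): 49}

#: period (s), cycle count for the standard descending-period schedule
STANDARD_SEGMENTS = [
    (480.0, 3), (240.0, 5), (120.0, 5), (60.0, 5),
    (30.0, 5), (10.0, 5), (5.0, 10), (1.0, 10),
]


@dataclass
class LightProtocol:
    """Forcing-waveform definition.

    Parameters
    ----------
    u_min, u_max : oscillation extremes, umol photons m^-2 s^-1.
    segments : ordered list of ``(period_s, cycle_count)`` pairs.
    pre_illum : ``(duration_s, intensity)``; intensity defaults to the
        oscillation mean (u_min + u_max)/2.
    quantization : number of equally spaced light levels spanning
        [u_min, u_max], or None for the ideal sine.
    sample_interval : output grid spacing, s.
    """

    u_min: float
    u_max: float
    segments: list = field(default_factory=list)
    pre_illum: tuple = None
    quantization: int | None = None
    sample_interval: float = 0.1

    def __post_init__(self):
        if not 0 < self.u_min < self.u_max:
            raise ValueError("need 0 < u_min < u_max")
        for T, n in self.segments:
            if T <= 0 or n < 1:
                raise ValueError("periods must be > 0 and cycle counts >= 1")
        if self.pre_illum is None:
            self.pre_illum = (0.0, 0.5 * (self.u_min + self.u_max))
        else:
            self.pre_illum = (float(self.pre_illum[0]), float(self.pre_illum[1]))
        if self.quantization is not None and self.quantization < 2:
            raise ValueError("quantization needs at least 2 levels")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")

    # -- schedule geometry --------------------------------------------------
    @property
    def u0(self) -> float:
        return 0.5 * (self.u_min + self.u_max)

    @property
    def u1(self) -> float:
        return 0.5 * (self.u_max - self.u_min)

    @property
    def duration(self) -> float:
        return self.pre_illum[0] + sum(T * n for T, n in self.segments)

    def segment_bounds(self):
        """``(t_start, t_end)`` of each oscillation segment, after pre-illumination."""
        bounds = []
        t = self.pre_illum[0]
        for T, n in self.segments:
            bounds.append((t, t + T * n))
            t += T * n
        return bounds

    def levels(self) -> np.ndarray | None:
        """The quantizer's emitted intensity levels, or None."""
        if self.quantization is None:
            return None
        return np.linspace(self.u_min, self.u_max, self.quantization)

    # -- evaluation ----------------------------------------------------------
    def ideal(self, t: float) -> float:
        """Unquantized waveform at time t (s from protocol start)."""
        if t < -1e-9 or t > self.duration + 1e-9:
            raise ValueError(f"t = {t} outside the protocol duration {self.duration}")
        if t < self.pre_illum[0]:  # the boundary sample belongs to the segment
            return self.pre_illum[1]
        for (t0, t1), (T, _n) in zip(self.segment_bounds(), self.segments):
            if t <= t1 + 1e-12:
                t_seg = (t - t0) % T
                return self.u0 - self.u1 * math.cos(2.0 * math.pi * t_seg / T)
        return self.pre_illum[1]  # unreachable

    def waveform(self, t: float) -> float:
        """Emitted light intensity at time t, quantized if configured."""
        u = self.ideal(t)
        if self.quantization is None or t < self.pre_illum[0]:
            return u
        lv = self.levels()
        step = lv[1] - lv[0]
        idx = int(round((u - self.u_min) / step))
        return float(lv[min(max(idx, 0), self.quantization - 1)])

    def sample_times(self) -> np.ndarray:
        """The uniform output grid (includes t = 0, excludes the endpoint)."""
        n = int(round(self.duration / self.sample_interval))
        return np.arange(n) * self.sample_interval

    def plateau_times(self, t0: float, t1: float, T: float, seg_start: float):
        """Quantizer switching times within [t0, t1] of a segment.

        Returns the sorted times at which the ideal sine crosses a midpoint
        between adjacent quantizer levels, i.e. where the emitted intensity
        steps to the next level.  Empty for unquantized protocols.
        """
        if self.quantization is None:
            return []
        lv = self.levels()
        mids = 0.5 * (lv[1:] + lv[:-1])
        w = 2.0 * math.pi / T
        crossings = []
        for m in mids:
            c = (self.u0 - m) / self.u1
            if not -1.0 < c < 1.0:
                continue
            tau = math.acos(c) / w           # ascending crossing within a cycle
            for base in (tau, T - tau):      # descending mirror
                k0 = math.floor((t0 - seg_start - base) / T)
                k1 = math.ceil((t1 - seg_start - base) / T)
                for k in range(k0, k1 + 1):
                    t = seg_start + base + k * T
                    if t0 < t < t1:
                        crossings.append(t)
        return sorted(set(crossings))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segments"] = [[float(T), int(n)] for T, n in self.segments]
        d["pre_illum"] = [float(x) for x in self.pre_illum]
        return d

    def export_csv(self, path) -> None:
        """Write the sampled waveform as a two-column time/intensity CSV."""
        import pandas as pd

        t = self.sample_times()
        u = np.array([self.waveform(ti) for ti in t])
        pd.DataFrame({"time_s": t, "light": u}).to_csv(path, index=False)


def standard_schedule(u_min: float, u_max: float, quantized: bool = True) -> LightProtocol:
    """The full descending-period measurement schedule.

    10 min of constant pre-illumination at the oscillation mean, then
    3 cycles of T = 8 min followed by 5 cycles each of 4 min, 2 min,
    1 min, 30 s and 10 s and 10 cycles each of 5 s and 1 s.  For the
    three canonical ranges the reported DAC granularity (8, 22 or 49
    levels) is applied; other ranges default to the unquantized sine.
    """
    q = STANDARD_QUANTIZATION.get((float(u_min), float(u_max))) if quantized else None
    return LightProtocol(
        u_min=u_min,
        u_max=u_max,
        segments=list(STANDARD_SEGMENTS),
        pre_illum=(600.0, 0.5 * (u_min + u_max)),
        quantization=q,
    )
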