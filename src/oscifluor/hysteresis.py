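"""Stimulus-response loop construction, orientation and classification.

A hysteresis loop is the closed (light, ChlF) trajectory over one
steady-state oscillation cycle.  Its signed area (shoelace formula)
distinguishes a response that lags the light (counter-clockwise,
"constitutive" hysteresis of the primary photosynthetic reactions)
from one shaped by delayed quenching regulation (clockwise,
"regulatory" hysteresis).  The area is normalized by the bounding-box
area of the loop, giving a dimensionless index in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HysteresisLoop",
    "extract_loop",
    "orientation_and_area",
    "classify",
    "split_phases",
    "signed_area",
]

#: |normalized area| below which a loop is considered degenerate
ORIENTATION_TOL = 0.02


@dataclass
class HysteresisLoop:
    """Phase-averaged (light, ChlF) pairs over one oscillation cycle."""

    light: np.ndarray
    chlf: np.ndarray
    T: float
    phase: np.ndarray          # cycle phase in [0, 1)
    n_cycles_averaged: int = 1

    def __post_init__(self):
        if self.light.size != self.chlf.size:
            raise ValueError("light and chlf must have equal length")


def extract_loop(trace, segment: str, discard: int | None = None) -> HysteresisLoop:
    """Build the steady-state loop of one oscillation segment.

    Initial transient cycles are discarded (1 for the 8-min period,
    2 otherwise, overridable) and the retained cycles are phase-averaged
    on the common within-cycle sample grid.
    """
    idx = trace.segment_slice(segment)
    cycles = trace.cycle[idx]
    ncyc = int(cycles.max())
    # period from the protocol labels: samples per cycle * dt
    nsamp = int(np.sum(cycles == 1))
    dt = float(np.median(np.diff(trace.time[idx][:max(nsamp, 2)])))
    T = nsamp * dt
    if discard is None:
        discard = 1 if T >= 480.0 - 1e-9 else 2
    keep = [c for c in range(discard + 1, ncyc + 1)]
    if not keep:
        raise ValueError(
            f"segment {segment!r}: {ncyc} cycles leave none after discarding {discard}"
        )
    light = np.zeros(nsamp)
    chlf = np.zeros(nsamp)
    for c in keep:
        sel = cycles == c
        light += trace.light[idx][sel][:nsamp]
        chlf += trace.ChlF[idx][sel][:nsamp]
    light /= len(keep)
    chlf /= len(keep)
    return HysteresisLoop(
        light=light,
        chlf=chlf,
        T=T,
        phase=np.arange(nsamp) / nsamp,
        n_cycles_averaged=len(keep),
    )


def signed_area(x: np.ndarray, y: np.ndarray) -> float:
    """Shoelace signed area of the closed polygon (positive = CCW)."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def orientation_and_area(loop: HysteresisLoop, tol: float = ORIENTATION_TOL):
    """Loop orientation and normalized signed-area index.

    Returns ``(orientation, index)`` with orientation in
    {"CCW", "CW", "none"}; the index is the shoelace area divided by the
    product of the light and ChlF ranges, so |index| <= 1 and the sign is
    invariant to positive rescaling of either axis.
    """
    if loop.light.size < 8:
        raise ValueError("need at least 8 samples per loop")
    dx = float(loop.light.max() - loop.light.min())
    dy = float(loop.chlf.max() - loop.chlf.min())
    if dx <= 0:
        raise ValueError("degenerate loop: zero light range")
    area = signed_area(loop.light, loop.chlf)
    index = 0.0 if dy == 0 else area / (dx * dy)
    if abs(index) < tol:
        orientation = "none"
    elif index > 0:
        orientation = "CCW"
    else:
        orientation = "CW"
    return orientation, index


def classify(loop: HysteresisLoop, tol: float = ORIENTATION_TOL) -> str:
    """Categorize a loop as constitutive (CCW), regulatory (CW) or negligible."""
    orientation, _ = orientation_and_area(loop, tol)
    return {"CCW": "constitutive", "CW": "regulatory", "none": "negligible"}[
        orientation
    ]


def split_phases(loop: HysteresisLoop):
    """Masks of the ascending- and descending-light branches.

    Branch membership follows the sign of the light derivative along the
    cycle phase; extrema terminate the branch that reaches them (the
    ascending branch ends at the light maximum).
    """
    u = loop.light
    i_max = int(np.argmax(u))
    i_min = int(np.argmin(u))
    n = u.size
    asc = np.zeros(n, dtype=bool)
    # walk forward from just after the minimum up to (and including) the
    # maximum; the minimum itself terminates the descending branch
    i = (i_min + 1) % n
    while True:
        asc[i] = True
        if i == i_max:
            break
        i = (i + 1) % n
    return asc, ~asc
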