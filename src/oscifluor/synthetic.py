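"""Noisy periodic fluorescence-like traces with known ground truth.

The generator emulates the statistical structure of PAM measurements
under oscillating light — a periodic signal with up to four harmonic
components sampled every 0.1 s, additive Gaussian noise, and a small
number of biological replicates — so the harmonic-fitting and
loop-analysis code can be validated against exact truth without running
the kinetic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .harmonics import HarmonicFit, reconstruct

__all__ = ["SyntheticSpec", "generate", "truth_fit"]


@dataclass
class SyntheticSpec:
    """Ground-truth signal definition for the fixture generator."""

    T: float                              # period, s
    A0: float = 0.4
    amplitudes: tuple = (0.08, 0.02, 0.01, 0.005)   # A_1..A_4
    phases: tuple = (0.25, 0.1, 0.0, 0.5)           # tau_k/T in [0, 1)
    noise_sd: float = 0.005               # additive Gaussian SD, ChlF units
    n_replicates: int = 3
    n_cycles: int = 3
    sample_interval: float = 0.1          # s
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_replicates < 1 or self.n_cycles < 1:
            raise ValueError("need >= 1 replicate and >= 1 cycle")


def truth_fit(spec: SyntheticSpec) -> HarmonicFit:
    """The ground truth expressed as a (zero-residual) harmonic fit."""
    return HarmonicFit(
        T=spec.T,
        A0=spec.A0,
        amplitudes=np.asarray(spec.amplitudes, dtype=float),
        phases=np.asarray(spec.phases, dtype=float) % 1.0,
        residual_rms=0.0,
        n_samples=0,
    )


def generate(spec: SyntheticSpec):
    """Draw the replicate traces; fully reproducible from ``spec.seed``.

    Returns a list of ``(times, values)`` pairs, one per replicate.  All
    replicates share the same time grid and underlying signal and differ
    only in their independent Gaussian noise draws.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.T * spec.n_cycles / spec.sample_interval))
    times = np.arange(n) * spec.sample_interval
    clean = reconstruct(truth_fit(spec), times)
    out = []
    for _ in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        out.append((times, clean + noise))
    return out
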