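"""Offset + four-harmonic decomposition of periodic fluorescence signals.

A steady-state periodic segment is fitted with

    Fit(t) = A0 + sum_k A_k * sin(k * 2*pi * (t - tau_k) / T),  k = 1..4,

estimated by exact linear least squares in the reparameterization
A_k sin(k*omega*(t - tau_k)) = a_k sin(k*omega*t) + b_k cos(k*omega*t),
which makes the fit deterministic and global (no initialization).
Amplitudes are reported non-negative with the sign absorbed into the
phase fraction tau_k/T in [0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HarmonicFit",
    "AggregatedFit",
    "fit_harmonics",
    "reconstruct",
    "aggregate",
    "aggregate_frame",
]


@dataclass
class HarmonicFit:
    """Fitted offset, amplitudes, phase fractions and residual."""

    T: float                   # period, s
    A0: float                  # offset
    amplitudes: np.ndarray     # A_1..A_n, >= 0
    phases: np.ndarray         # tau_k / T, canonicalized into [0, 1/k)
    residual_rms: float
    n_samples: int

    @property
    def n_harmonics(self) -> int:
        return len(self.amplitudes)


@dataclass
class AggregatedFit:
    """Per-parameter replicate mean and standard error (SD / sqrt(n))."""

    T: float
    n: int
    A0_mean: float
    A0_se: float
    amplitude_mean: np.ndarray
    amplitude_se: np.ndarray
    phase_mean: np.ndarray     # circular mean of tau_k/T, in [0, 1)
    phase_se: np.ndarray


def _design(times: np.ndarray, T: float, n_harmonics: int) -> np.ndarray:
    w = 2.0 * math.pi / T
    cols = [np.ones_like(times)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(k * w * times))
        cols.append(np.cos(k * w * times))
    return np.column_stack(cols)


def fit_harmonics(times, values, T: float, n_harmonics: int = 4) -> HarmonicFit:
    """Least-squares harmonic decomposition of one periodic segment.

    ``times``/``values`` must cover at least one full period; the number
    of samples must be at least the 2*n_harmonics + 1 free parameters.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if t.size < 2 * n_harmonics + 1:
        raise ValueError(
            f"{t.size} samples cannot constrain {2 * n_harmonics + 1} parameters"
        )
    # a full period sampled at n points spans T - dt, so allow one step
    dt_med = float(np.median(np.diff(np.sort(t)))) if t.size > 1 else 0.0
    if t.max() - t.min() + dt_med < T * (1.0 - 1e-9):
        raise ValueError("segment must cover at least one full period")

    X = _design(t, T, n_harmonics)
    coef, _res, rank, _sv = np.linalg.lstsq(X, v, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design; more samples needed")

    A0 = float(coef[0])
    amps = np.empty(n_harmonics)
    phases = np.empty(n_harmonics)
    w = 2.0 * math.pi / T
    for k in range(1, n_harmonics + 1):
        a, b = coef[2 * k - 1], coef[2 * k]
        A = math.hypot(a, b)
        amps[k - 1] = A
        if A == 0.0:
            phases[k - 1] = 0.0
        else:
            # a = A cos(k w tau), b = -A sin(k w tau); tau_k is only
            # identifiable modulo T/k, canonicalized into [0, T/k)
            tau = math.atan2(-b, a) / (k * w)
            phases[k - 1] = (tau / T) % (1.0 / k)
    resid = v - X @ coef
    return HarmonicFit(
        T=float(T),
        A0=A0,
        amplitudes=amps,
        phases=phases,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_samples=int(t.size),
    )


def reconstruct(fit: HarmonicFit, times) -> np.ndarray:
    """Evaluate the fitted harmonic model at the given times."""
    t = np.asarray(times, dtype=float)
    w = 2.0 * math.pi / fit.T
    out = np.full_like(t, fit.A0, dtype=float)
    for k in range(1, fit.n_harmonics + 1):
        A = fit.amplitudes[k - 1]
        tau = fit.phases[k - 1] * fit.T
        out += A * np.sin(k * w * (t - tau))
    return out


def _circular_mean_se(fracs: np.ndarray, k: int = 1):
    """Mean direction and SE of phase fractions of harmonic k.

    The phase of harmonic k lives on a circle of circumference 1/k
    (in fractions of the fundamental period), so the resultant-vector
    mean is taken at angle 2*pi*k*frac and mapped back to [0, 1/k).
    """
    period = 1.0 / k
    ang = 2.0 * math.pi * k * fracs
    z = np.exp(1j * ang)
    mean_ang = math.atan2(float(np.mean(z.imag)), float(np.mean(z.real)))
    mean_frac = (mean_ang / (2.0 * math.pi * k)) % period
    if period - mean_frac < 1e-12:  # snap the wrap-around representation
        mean_frac = 0.0
    dev = (fracs - mean_frac + period / 2) % period - period / 2
    se = float(np.std(dev, ddof=1) / math.sqrt(len(fracs)))
    return mean_frac, se


def aggregate(fits) -> AggregatedFit:
    """Average replicate fits; SE = sample SD / sqrt(n), phases circular."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 replicate fits for a standard error")
    T = fits[0].T
    if any(abs(f.T - T) > 1e-9 * T for f in fits):
        raise ValueError("replicate fits have mixed periods")
    nh = fits[0].n_harmonics
    n = len(fits)
    A0s = np.array([f.A0 for f in fits])
    amps = np.array([f.amplitudes for f in fits])    # (n, nh)
    phases = np.array([f.phases for f in fits])
    ph_mean = np.empty(nh)
    ph_se = np.empty(nh)
    for k in range(nh):
        ph_mean[k], ph_se[k] = _circular_mean_se(phases[:, k], k=k + 1)
    sqrt_n = math.sqrt(n)
    return AggregatedFit(
        T=T,
        n=n,
        A0_mean=float(A0s.mean()),
        A0_se=float(A0s.std(ddof=1) / sqrt_n),
        amplitude_mean=amps.mean(axis=0),
        amplitude_se=amps.std(axis=0, ddof=1) / sqrt_n,
        phase_mean=ph_mean,
        phase_se=ph_se,
    )


def aggregate_frame(agg: AggregatedFit, genotype: str = "", light_range: str = ""):
    """Tidy export of an aggregated fit: one row per fitted parameter.

    Columns: genotype, range, T, parameter, mean, SE, n.
    """
    import pandas as pd

    rows = [{"parameter": "A0", "mean": agg.A0_mean, "SE": agg.A0_se}]
    for k in range(len(agg.amplitude_mean)):
        rows.append({"parameter": f"A{k+1}", "mean": float(agg.amplitude_mean[k]),
                     "SE": float(agg.amplitude_se[k])})
        rows.append({"parameter": f"tau{k+1}_over_T", "mean": float(agg.phase_mean[k]),
                     "SE": float(agg.phase_se[k])})
    for row in rows:
        row.update(genotype=genotype, range=light_range, T=agg.T, n=agg.n)
    return pd.DataFrame(rows, columns=["genotype", "range", "T", "parameter",
                                       "mean", "SE", "n"])
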