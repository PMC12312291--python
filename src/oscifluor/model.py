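"""State variables, rate laws and the ODE right-hand side.

Six dynamic variables describe the electron-transport chain and its qE
regulation: the oxidized plastoquinone pool PQ_ox (molecules per PSII),
the oxidized fraction of PSI donors PI_ox, the lumen free-H+
concentration H_L (uM), the ATP pool (molecules per PSII), the
zeaxanthin fraction Zea and the active-PsbS fraction PsbS_act.  The
closed fraction of PSII reaction centers is a dependent (quasi-steady)
variable.

Flux conventions.  k1+/k1- are lumped rate constants for the
PSII <-> PQ exchange expressed per PQ molecule; since each plastoquinone
carries nu_e = 2 electrons, the electron flux is

    J2 = nu_e * (k1+ * p * B - k1- * r * (1 - B))   [e- PSII^-1 s^-1]

with p = PQ_ox/PQ_tot, r = 1 - p, and the quasi-steady closure

    B = (kL + nu_e*k1-*r) / (kL + nu_e*k1-*r + nu_e*k1+*p),

kL = sigma_II * q * light being the quenching-modulated PSII excitation
rate.  These two expressions are mutually consistent: J2 = kL * (1 - B),
i.e. every excitation of an open center translocates one electron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters
from .fluorescence import quench_factor

__all__ = [
    "ModelState",
    "rate_v3",
    "rate_v9",
    "rate_v5",
    "rcii_closed",
    "electron_flux_psii",
    "pq_reoxidation_flux",
    "ode_rhs",
    "STATE_FIELDS",
]

STATE_FIELDS = ("PQ_ox", "PI_ox", "H_L", "ATP", "Zea", "PsbS_act")


@dataclass
class ModelState:
    """The six dynamic variables at one instant."""

    PQ_ox: float    # oxidized PQ, molecules per PSII, in [0, PQ_tot]
    PI_ox: float    # oxidized PSI-donor fraction, in [0, 1]
    H_L: float      # lumen free H+, uM, > 0
    ATP: float      # ATP, molecules per PSII, in [0, A_tot]
    Zea: float      # zeaxanthin fraction, in [0, 1]
    PsbS_act: float  # active PsbS fraction, in [0, 1]

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.PQ_ox, self.PI_ox, self.H_L, self.ATP, self.Zea, self.PsbS_act]
        )

    @classmethod
    def from_array(cls, y) -> "ModelState":
        return cls(*(float(v) for v in y))

    def validate(self, params: ModelParameters, tol: float = 1e-9) -> None:
        if not -tol <= self.PQ_ox <= params.PQ_tot + tol:
            raise ValueError(f"PQ_ox = {self.PQ_ox} outside [0, {params.PQ_tot}]")
        for name, hi in (("PI_ox", 1.0), ("Zea", 1.0), ("PsbS_act", 1.0)):
            v = getattr(self, name)
            if not -tol <= v <= hi + tol:
                raise ValueError(f"{name} = {v} outside [0, {hi}]")
        if not -tol <= self.ATP <= params.A_tot + tol:
            raise ValueError(f"ATP = {self.ATP} outside [0, {params.A_tot}]")
        if self.H_L <= 0:
            raise ValueError(f"H_L = {self.H_L} must be > 0")


def _hill(H: float, K: float, n: float) -> float:
    """Sigmoidal activation by lumen H+: 1 / (1 + (K/H)^n)."""
    if H <= 0:
        raise ValueError(f"lumen H+ must be > 0, got {H}")
    return 1.0 / (1.0 + (K / H) ** n)


def rate_v3(state: ModelState, params: ModelParameters) -> float:
    """Violaxanthin -> zeaxanthin de-epoxidation rate, s^-1.

    v3 = k3 * (1 - Zea) / (1 + (KQ_VDE / H_L)^n_VDE).
    """
    return params.k3 * (1.0 - state.Zea) * _hill(state.H_L, params.KQ_VDE, params.n_VDE)


def rate_v9(state: ModelState, params: ModelParameters) -> float:
    """PsbS protonation/activation rate, s^-1.

    v9 = k9 * (1 - PsbS_act) / (1 + (KQ_PsbS / H_L)^n_PsbS).
    """
    return params.k9 * (1.0 - state.PsbS_act) * _hill(
        state.H_L, params.KQ_PsbS, params.n_PsbS
    )


def rate_v5(state: ModelState, params: ModelParameters) -> float:
    """Net ATP formation per PSII, molecules s^-1 (may be negative).

    v5 = k5 * [(A_tot - ATP) - a * ATP / H_L^(14/3)]; the 14/3 exponent is
    the H+/ATP stoichiometry of a c14-ring ATP synthase.
    """
    if state.H_L <= 0:
        raise ValueError(f"lumen H+ must be > 0, got {state.H_L}")
    back = params.a * state.ATP / state.H_L ** (14.0 / 3.0)
    return params.k5 * ((params.A_tot - state.ATP) - back)


def rcii_closed(state: ModelState, light: float, params: ModelParameters) -> float:
    """Quasi-steady closed fraction of PSII reaction centers, in [0, 1].

    B = (kL + nu_e*k1-*r) / (kL + nu_e*k1-*r + nu_e*k1+*p) with
    p = PQ_ox/PQ_tot, r = 1 - p and kL = sigma_II * q * light.  Monotone
    increasing in light and in PQ-pool reduction; 0 in darkness with a
    fully oxidized pool; -> 1 as light -> infinity.
    """
    if light < 0:
        raise ValueError("light must be >= 0")
    p = state.PQ_ox / params.PQ_tot
    r = 1.0 - p
    q = quench_factor(state.Zea, state.PsbS_act, params)
    kL = params.sigma_II * q * light
    num = kL + params.nu_e * params.k1_minus * r
    den = num + params.nu_e * params.k1_plus * p
    if den == 0.0:  # dark with fully reduced pool: recombination equilibrium
        return 1.0
    return num / den


def electron_flux_psii(
    state: ModelState, light: float, params: ModelParameters
) -> float:
    """Net electron flux PSII -> PQ, e- PSII^-1 s^-1 (J2 = kL*(1-B))."""
    p = state.PQ_ox / params.PQ_tot
    r = 1.0 - p
    B = rcii_closed(state, light, params)
    return params.nu_e * (
        params.k1_plus * p * B - params.k1_minus * r * (1.0 - B)
    )


def pq_reoxidation_flux(state: ModelState, params: ModelParameters) -> float:
    """Electron flux PQH2 -> PSI donors, e- PSII^-1 s^-1.

    J_bf = k2 * PI_ox * r / (K_PQ + r) with r the reduced-PQ fraction:
    the plastoquinol re-oxidation step (cytochrome b6f) is carried out by
    a finite enzyme complement, so the flux saturates once the reduced
    pool exceeds the half-saturation fraction K_PQ.  This saturation is
    what lets the pool integrate (and hence lag) a rising light flank on
    the sub-second scale.
    """
    r = min(max(1.0 - state.PQ_ox / params.PQ_tot, 0.0), 1.0)
    return params.k2 * state.PI_ox * r / (params.K_PQ + r)


def ode_rhs(t: float, y, light_fn, params: ModelParameters) -> np.ndarray:
    """Time derivatives of the six state variables.

    ``light_fn`` maps time (s) to PAR (umol photons m^-2 s^-1).  The
    proton balance books n_H lumen H+ per transported electron against
    the 14/3 H+ consumed per ATP synthesized (synthesis only; reverse
    proton pumping by the synthase is excluded) plus a passive leak.
    """
    PQ_ox, PI_ox, H_L, ATP, Zea, PsbS_act = (float(v) for v in y)
    light = float(light_fn(t)) if callable(light_fn) else float(light_fn)
    if light < 0:
        raise ValueError(f"light must be >= 0 at t={t}")
    # clamp H_L for stiff-solver trial evaluations that probe H <= 0; the
    # exact dynamics cannot cross zero (dH_L/dt > 0 there) so this only
    # regularizes off-trajectory points
    H_L = max(H_L, 1e-12)
    state = ModelState(PQ_ox, PI_ox, H_L, ATP, Zea, PsbS_act)

    J2 = electron_flux_psii(state, light, params)
    J_bf = pq_reoxidation_flux(state, params)

    v5 = rate_v5(state, params)
    v3 = rate_v3(state, params)
    v9 = rate_v9(state, params)

    dPQ_ox = (J_bf - J2) / params.nu_e
    dPI_ox = params.sigma_I * light * (1.0 - PI_ox) - J_bf
    dH_L = (
        params.beta_H * (params.n_H * J2 - (14.0 / 3.0) * max(v5, 0.0))
        - params.k_leak * (H_L - params.H_0)
    )
    dATP = v5 - params.k6 * ATP
    dZea = v3 - params.k4 * Zea
    dPsbS = v9 - params.k10 * PsbS_act

    out = np.array([dPQ_ox, dPI_ox, dH_L, dATP, dZea, dPsbS])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite derivative at t={t}: {out}")
    return out
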