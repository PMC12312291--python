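"""Normalized chlorophyll fluorescence observable and the NPQ parameter.

The instantaneous PAM fluorescence F'(t) is normalized to the
dark-adapted maximum F_M.  Two multiplicative quenchers (zeaxanthin and
active PsbS) scale the excitation fate; the minimal fluorescence of the
light-adapted state, F0', follows the Oxborough-Baker approximation
F0' = F0 / (Fv/Fm + F0/Fm').  Substituting F_M' = q*F_M yields the
closed form

    ChlF = q*(1-B)*(1-phi) / ((1-phi) + q*phi) + q*B

with B the closed-RCII fraction and phi = Fv/Fm the dark-adapted
maximum PSII quantum yield.
"""

from __future__ import annotations

__all__ = ["quench_factor", "chlf", "chlf_stepwise", "npq_parameter"]


def quench_factor(Zea: float, PsbS_act: float, params) -> float:
    """Multiplicative quenching factor q = F_M'/F_M in (0, 1].

    q = (1 - Zea_max*Zea) * (1 - PsbS_max*PsbS_act).
    """
    return (1.0 - params.Zea_max * Zea) * (1.0 - params.PsbS_max * PsbS_act)


def chlf(rcii_closed: float, q: float, params) -> float:
    """Normalized fluorescence yield F'(t)/F_M, in (0, 1].

    Strictly increasing in both the closed fraction B and the quench
    factor q; equals F0/F_M = 1 - phi_II_max for q = 1, B = 0 and reaches
    1 only at q = 1, B = 1 (the dark-adapted saturating pulse).
    """
    phi = params.phi_II_max
    B = rcii_closed
    f0p = q * (1.0 - phi) / ((1.0 - phi) + q * phi)  # F0'/F_M
    return f0p * (1.0 - B) + q * B


def chlf_stepwise(rcii_closed: float, q: float, params) -> float:
    """Reference two-step computation of F'(t)/F_M.

    F_M' = q*F_M; F0' by the Oxborough-Baker correction
    F0' = F0 / (Fv/Fm + F0/F_M'); F' = F0' + B*(F_M' - F0').  Used as an
    internal cross-check of the closed form in :func:`chlf`.
    """
    phi = params.phi_II_max
    F_M = 1.0
    F_0 = (1.0 - phi) * F_M
    F_Mp = q * F_M
    F_0p = F_0 / (phi + F_0 / F_Mp)
    Fp = F_0p + rcii_closed * (F_Mp - F_0p)
    return Fp / F_M


def npq_parameter(q: float) -> float:
    """Stern-Volmer NPQ parameter, (F_M - F_M')/F_M' = 1/q - 1."""
    if q <= 0:
        raise ValueError(f"quench factor must be > 0, got {q}")
    return 1.0 / q - 1.0
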