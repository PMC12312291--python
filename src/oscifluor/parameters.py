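"""Model parameters, genotype presets, and flat-file serialization.

The parameter set describes a six-variable kinetic model of linear
photosynthetic electron transport with two independently regulated
energy-dependent quenching (qE) mechanisms: zeaxanthin formed by
violaxanthin de-epoxidase (VDE) and protonation-activated PsbS.  A
subset of the constants is fixed by the published model description
(lumped PSII<->PQ exchange, quencher kinetics, Hill activation, ATP
turnover); the remaining transport/proton constants are effective
reconstruction parameters whose shipped defaults are calibrated against
two steady-state anchors (see :func:`oscifluor.simulate.calibrate`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ModelParameters",
    "genotype_preset",
    "load_parameters",
    "save_parameters",
    "GENOTYPES",
    "PRESET_DIR",
]

GENOTYPES = ("WT", "npq1", "npq4")

#: directory with the bundled, calibrated genotype preset files
PRESET_DIR = Path(__file__).parent / "presets"

# Fields fixed by the published model description.  They are not free for
# calibration; everything else is an effective reconstruction constant.
PRINTED_FIELDS = frozenset(
    {
        "k1_plus", "k1_minus", "k3", "k4", "k6", "k9", "k10",
        "KQ_VDE", "KQ_PsbS", "n_VDE", "n_PsbS", "Zea_max", "PsbS_max", "a",
    }
)


@dataclass
class ModelParameters:
    """Rate constants, pool sizes and quencher parameters.

    Units: rate constants in s^-1; lumen H+ concentrations in uM; light
    cross-sections sigma_II / sigma_I in (umol photons m^-2 s^-1)^-1 s^-1;
    PQ_tot in plastoquinone molecules per PSII; ATP / A_tot in ATP
    molecules per PSII; beta_H in uM lumen H+ per (H+ PSII^-1).
    """

    # --- printed constants -------------------------------------------------
    k1_plus: float = 250.0    # lumped PSII -> PQ forward rate, per PQ molecule
    k1_minus: float = 100.0   # lumped PQ -> PSII backward rate
    k3: float = 0.01          # violaxanthin de-epoxidation (VDE), effective
    k4: float = 0.001         # zeaxanthin epoxidation, effective
    k6: float = 8.0           # ATP consumption
    k9: float = 0.05          # PsbS protonation/activation
    k10: float = 0.004        # PsbS deactivation
    KQ_VDE: float = 1.0       # half-activation lumen [H+] for VDE, uM
    KQ_PsbS: float = 1.0      # half-activation lumen [H+] for PsbS, uM
    n_VDE: float = 6.0        # Hill coefficient, VDE activation
    n_PsbS: float = 4.0       # Hill coefficient, PsbS activation
    Zea_max: float = 0.3      # maximal zeaxanthin quenching depth
    PsbS_max: float = 0.3     # maximal PsbS quenching depth
    a: float = 9.202e-2       # empirical ATP back-pressure constant

    # --- reconstructed / calibrated constants ------------------------------
    k2: float = 281.25         # PQH2 re-oxidation Vmax toward PSI donors [calibrated]
    K_PQ: float = 0.05        # reduced-PQ fraction at half-maximal re-oxidation
    k5: float = 11.1606045627          # ATP-synthase rate constant [calibrated]
    sigma_II: float = 2.8871903751     # PSII excitation per unit PAR [calibrated]
    sigma_I: float = 6.0      # PSI oxidation per unit PAR [reconstructed]
    beta_H: float = 0.0826086956522     # lumen uM per (H+ PSII^-1) [calibrated]
    n_H: float = 1.0          # lumen H+ deposited per transported electron
    k_leak: float = 1.0       # passive proton leak rate constant
    H_0: float = 0.1          # resting lumen free H+, uM (~pH 7)
    A_tot: float = 10.0       # total adenylate pool, ATP molecules per PSII
    PQ_tot: float = 21.0       # PQ pool size per PSII, molecules
    nu_e: float = 2.0         # electrons per PQ molecule
    phi_II_max: float = 0.83  # dark-adapted Fv/Fm

    genotype: str = "WT"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rate_fields = (
            "k1_plus", "k1_minus", "k2", "k3", "k4", "k5", "k6", "k9",
            "k10", "sigma_II", "sigma_I", "beta_H", "n_H", "k_leak",
        )
        for name in rate_fields:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_VDE < 1 or self.n_PsbS < 1:
            raise ValueError("Hill coefficients must be >= 1")
        for name in ("Zea_max", "PsbS_max"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.phi_II_max < 1:
            raise ValueError("phi_II_max must be in (0, 1)")
        if self.KQ_VDE <= 0 or self.KQ_PsbS <= 0:
            raise ValueError("KQ values must be > 0")
        if self.K_PQ <= 0:
            raise ValueError("K_PQ must be > 0")
        if self.PQ_tot < 1:
            raise ValueError("PQ_tot must be >= 1")
        if self.A_tot <= 0 or self.H_0 <= 0:
            raise ValueError("A_tot and H_0 must be > 0")
        if self.nu_e <= 0:
            raise ValueError("nu_e must be > 0")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (float(v) if k != "genotype" else v) for k, v in d.items()}


def genotype_preset(name: str) -> ModelParameters:
    """Return the calibrated parameter set for a genotype.

    ``WT`` carries the full quenching machinery.  ``npq1`` (no functional
    VDE, hence no zeaxanthin) is emulated by dividing k3 by 1000; ``npq4``
    (no PsbS protein) by dividing k9 by 1000.  All other parameters are
    identical to WT.
    """
    if name not in GENOTYPES:
        raise ValueError(
            f"unknown genotype {name!r}; valid presets are {', '.join(GENOTYPES)}"
        )
    path = PRESET_DIR / f"{name}.yaml"
    if path.exists():
        return load_parameters(path)
    # fall back to the in-code defaults if the bundled file is absent
    base = ModelParameters()
    if name == "npq1":
        return base.replace(k3=base.k3 / 1000.0, genotype="npq1")
    if name == "npq4":
        return base.replace(k9=base.k9 / 1000.0, genotype="npq4")
    return base


def save_parameters(params: ModelParameters, path) -> None:
    """Write a parameter set as a flat key-value YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_parameters(path) -> ModelParameters:
    """Read a parameter set from a flat key-value YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameter values")
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return ModelParameters(**data)
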