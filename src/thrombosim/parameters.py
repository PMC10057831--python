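"""Parameter registry: drug, protein, clot and patient constants.

Single source of truth for every symbol in the coupled systemic/local model.
Printed kinetic and PK constants for the four plasminogen activators ship in
``data/drugs.yaml``; every constant the source tables do not print (protein
baselines and turnover, auxiliary plasmin-inhibition kinetics, clot geometry
and porous-medium properties, molecular weights) lives in
``data/calibration.yaml``, which is explicitly marked as the calibration
surface.

Internal unit system: concentrations in uM, time in seconds, SI for space and
pressure. Table values given in nM are converted at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "DRUG_NAMES",
    "PROTEIN_SPECIES",
    "DrugParameters",
    "ProteinParameters",
    "PlasmaKinetics",
    "ClotConfig",
    "Patient",
    "builtin_drug",
    "builtin_proteins",
    "builtin_plasma_kinetics",
    "builtin_clot_config",
    "mg_to_concentration",
    "load_calibration",
]

DRUG_NAMES = ("alteplase", "tenecteplase", "reteplase", "urokinase")

#: The six fibrinolytic proteins tracked systemically, in canonical order.
PROTEIN_SPECIES = ("PLG", "PLS", "AP", "MG", "FBG", "PAI")


def _read_packaged_yaml(name: str) -> dict:
    text = resources.files("thrombosim.data").joinpath(name).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class DrugParameters:
    """All plasma-phase and clot-phase constants for one plasminogen activator.

    Attributes
    ----------
    C0 : float
        Endogenous baseline plasma concentration, uM (0 for the engineered
        tPA variants).
    KM_plasma, kcat_plasma : float
        Michaelis constant (uM) and catalytic constant (1/s) for plasma-phase
        plasminogen activation.
    kPAI : float
        Second-order PAI-1 inhibition rate constant, 1/(uM s).
    kel, kcp, kpc : float
        Elimination and inter-compartment distribution rate constants, 1/s.
    Vc_per_kg : float
        Central-compartment distribution volume per body weight, L/kg.
    Mw : float
        Molecular weight, g/mol (for the mg -> uM dose conversion).
    ka, kd_off : float
        Fibrin adsorption (1/(uM s)) and desorption (1/s) rate constants;
        both zero for urokinase, which has no fibrin affinity.
    KM_clot, kcat_clot : float
        Michaelis-Menten constants for bound-phase plasmin generation.
    fibrin_binding : bool
        False only for urokinase.
    endogenous_secretion : bool
        True for alteplase and urokinase (nonzero C0 maintained by secretion);
        false for the engineered variants, whose secretion is zero.
    """

    name: str
    C0: float
    KM_plasma: float
    kcat_plasma: float
    kPAI: float
    kel: float
    kcp: float
    kpc: float
    Vc_per_kg: float
    Mw: float
    ka: float
    kd_off: float
    KM_clot: float
    kcat_clot: float
    fibrin_binding: bool
    endogenous_secretion: bool

    @property
    def Kd(self) -> Optional[float]:
        """Fibrin dissociation constant kd_off/ka (uM); None for non-binders.

        Represented as absent, not 0 or infinity: the urokinase kinetics
        bypass binding entirely and no expression may ever divide by Kd.
        """
        if not self.fibrin_binding:
            return None
        return self.kd_off / self.ka

    def __post_init__(self) -> None:
        if self.name not in DRUG_NAMES:
            raise ValueError(
                f"unknown drug {self.name!r}; valid names: {', '.join(DRUG_NAMES)}"
            )
        for attr in ("C0", "kPAI", "kel", "kcp", "kpc", "ka", "kd_off",
                     "kcat_plasma", "kcat_clot"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}.{attr} must be >= 0")
        for attr in ("KM_plasma", "KM_clot", "Vc_per_kg", "Mw"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}.{attr} must be > 0")
        if not self.fibrin_binding and (self.ka != 0 or self.kd_off != 0):
            raise ValueError(f"{self.name}: non-binding drug must have ka = kd_off = 0")
        if self.fibrin_binding and self.ka == 0:
            raise ValueError(f"{self.name}: binding drug must have ka > 0")
        if not self.endogenous_secretion and self.C0 != 0:
            raise ValueError(f"{self.name}: engineered variant must have C0 = 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DrugParameters":
        return cls(**d)


@dataclass(frozen=True)
class ProteinParameters:
    """Baseline level and first-order turnover of one fibrinolytic protein.

    The secretion rate ``S`` is derived from homeostasis (S = kel * C_init)
    rather than stored independently, so the drug-free pre-dose state is a
    steady state by construction.
    """

    species: str
    C_init: float   # uM
    kel: float      # 1/s

    def __post_init__(self) -> None:
        if self.species not in PROTEIN_SPECIES:
            raise ValueError(
                f"unknown protein {self.species!r}; valid: {', '.join(PROTEIN_SPECIES)}"
            )
        if self.C_init < 0 or self.kel < 0:
            raise ValueError(f"{self.species}: C_init and kel must be >= 0")

    @property
    def S(self) -> float:
        """Homeostatic secretion rate, uM/s."""
        return self.kel * self.C_init

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProteinParameters":
        return cls(**d)


@dataclass(frozen=True)
class PlasmaKinetics:
    """Second-order rate constants for the auxiliary plasma-phase reactions.

    Plasmin inhibition by alpha2-antiplasmin (1:1, consuming both) and by
    alpha2-macroglobulin, plus fibrinogen degradation by plasmin (catalytic in
    plasmin). All in 1/(uM s). These are part of the calibration surface.
    """

    k_pls_ap: float
    k_pls_mg: float
    k_pls_fbg: float

    def __post_init__(self) -> None:
        for attr in ("k_pls_ap", "k_pls_mg", "k_pls_fbg"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlasmaKinetics":
        return cls(**d)


@dataclass(frozen=True)
class ClotConfig:
    """Clot geometry, porous-medium flow, and binding-site model constants."""

    L_clot: float = 0.01          # m, clot length along flow
    n_cells: int = 50
    entry_length: float = 0.0     # m, clot-free region upstream of the clot face
    epsilon_clot: float = 0.75    # initial clot porosity
    fiber_radius: float = 2.0e-7  # m, fibrin fiber radius (Davis permeability)
    n_total_init: float = 1.0     # uM, accessible fibrin binding sites
    dp_per_length: float = 4.6e5  # Pa/m, pressure gradient across the clot
    mu: float = 1.3e-3            # Pa s, plasma dynamic viscosity
    D: float = 5.0e-11            # m^2/s, diffusivity of free species in clot
    kdeg: float = 6.25e-2         # 1/s, lysis coefficient
    gamma: float = 10.0           # plasmin cuts per fibrin unit
    x_monitor: float = 0.005      # m from the clot face, activation monitor
    ka_plg: float = 0.005         # 1/(uM s), plasminogen fibrin adsorption
    kd_plg: float = 0.1           # 1/s (Kd = 20 uM on intact fibrin)
    ka_pls: float = 0.04          # 1/(uM s), plasmin fibrin adsorption
    kd_pls: float = 0.02          # 1/s (Kd = 0.5 uM)
    bound_plasmin_protected: bool = True
    pressure_mode: str = "per_length"  # "per_length" or "total"
    spin_up: float = 0.0          # s, drug-free pre-dose equilibration
    u_max: float = 0.02           # m/s, numerical velocity cap once recanalized

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon_clot < 1.0):
            raise ValueError("epsilon_clot must lie in (0, 1)")
        if self.L_clot <= 0:
            raise ValueError("L_clot must be > 0")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.entry_length < 0:
            raise ValueError("entry_length must be >= 0")
        for attr in ("fiber_radius", "n_total_init", "mu", "D", "kdeg",
                     "gamma", "dp_per_length"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if not (0.0 <= self.x_monitor <= self.L_clot):
            raise ValueError("x_monitor must lie within [0, L_clot]")
        for attr in ("ka_plg", "kd_plg", "ka_pls", "kd_pls", "spin_up"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.u_max <= 0:
            raise ValueError("u_max must be > 0")
        if self.pressure_mode not in ("per_length", "total"):
            raise ValueError("pressure_mode must be 'per_length' or 'total'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClotConfig":
        return cls(**d)


@dataclass(frozen=True)
class Patient:
    """Simulated patient; the default 80 kg matches the standard assumption."""

    body_weight: float = 80.0  # kg

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Patient":
        return cls(**d)


# ---------------------------------------------------------------------------
# Built-in presets
# ---------------------------------------------------------------------------

def load_calibration() -> dict:
    """Return the packaged calibration-surface dictionary."""
    return _read_packaged_yaml("calibration.yaml")


def builtin_drug(name: str) -> DrugParameters:
    """Return the full parameter set for one of the four shipped drugs.

    Table constants come from ``drugs.yaml`` (literal transcription, internal
    uM/s units); the molecular weight comes from the calibration surface.
    """
    tables = _read_packaged_yaml("drugs.yaml")["drugs"]
    if name not in tables:
        raise ValueError(
            f"unknown drug {name!r}; valid names: {', '.join(DRUG_NAMES)}"
        )
    mw = load_calibration()["molecular_weights"][name]
    return DrugParameters(name=name, Mw=float(mw), **tables[name])


def builtin_proteins(calibration: Optional[dict] = None) -> list[ProteinParameters]:
    """The six-protein systemic set with homeostatic secretion."""
    cal = calibration if calibration is not None else load_calibration()
    out = []
    for sp in PROTEIN_SPECIES:
        row = cal["proteins"][sp]
        out.append(ProteinParameters(species=sp, C_init=float(row["C_init"]),
                                     kel=float(row["kel"])))
    return out


def builtin_plasma_kinetics(calibration: Optional[dict] = None) -> PlasmaKinetics:
    cal = calibration if calibration is not None else load_calibration()
    pk = cal["plasma_kinetics"]
    return PlasmaKinetics(k_pls_ap=float(pk["k_pls_ap"]),
                          k_pls_mg=float(pk["k_pls_mg"]),
                          k_pls_fbg=float(pk["k_pls_fbg"]))


def builtin_clot_config(calibration: Optional[dict] = None) -> ClotConfig:
    cal = calibration if calibration is not None else load_calibration()
    c = cal["clot"]
    return ClotConfig(
        L_clot=float(c["L_clot"]),
        n_cells=int(c["n_cells"]),
        entry_length=float(c.get("entry_length", 0.0)),
        epsilon_clot=float(c["epsilon_clot"]),
        fiber_radius=float(c["fiber_radius"]),
        n_total_init=float(c["n_total_init"]),
        dp_per_length=float(c["dp_per_length"]),
        mu=float(c["mu"]),
        D=float(c["D"]),
        kdeg=float(c["kdeg"]),
        gamma=float(c["gamma"]),
        x_monitor=float(c["x_monitor"]),
        pressure_mode=str(c.get("pressure_mode", "per_length")),
        u_max=float(c.get("u_max", 0.02)),
        spin_up=float(c.get("spin_up", 0.0)),
        ka_plg=float(c["plg_binding"]["ka"]),
        kd_plg=float(c["plg_binding"]["kd"]),
        ka_pls=float(c["pls_binding"]["ka"]),
        kd_pls=float(c["pls_binding"]["kd"]),
        bound_plasmin_protected=bool(c["bound_plasmin_protected"]),
    )


def mg_to_concentration(mass_mg: float, drug: DrugParameters,
                        patient: Patient) -> float:
    """Convert a drug mass in mg to a central-compartment concentration in uM.

    mass [mg] / (Mw [g/mol] * Vc [L]) with Vc = Vc_per_kg * body_weight;
    the factor 1000 carries mg -> g and mol/L -> uM net bookkeeping:
    (mg * 1e-3 g/mg) / (g/mol) / L = mol/L * 1e-3 -> uM requires * 1e6,
    hence * 1e3 overall.
    """
    if mass_mg < 0:
        raise ValueError("mass_mg must be >= 0")
    Vc = drug.Vc_per_kg * patient.body_weight
    return mass_mg * 1.0e3 / (drug.Mw * Vc)
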