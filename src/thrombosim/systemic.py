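"""Systemic two-compartment PK coupled to plasma-phase fibrinolysis kinetics.

State vector (all uM): drug central (Cc) and peripheral (Cp) concentrations
plus the six fibrinolytic proteins PLG, PLS, AP, MG, FBG, PAI.

Reactions in plasma:

* plasminogen activation (Michaelis-Menten, catalytic in the activator):
  rate = kcat * Cc * C_PLG / (KM + C_PLG); PLG -> PLS.
* PAI-1 inhibition: rate = kPAI * Cc * C_PAI; consumes drug and PAI-1 1:1.
* plasmin neutralisation by AP and by MG (second-order, consuming both).
* fibrinogen degradation by plasmin (second-order, catalytic in plasmin).

The drug is eliminated, distributed to a peripheral compartment, infused per
the regimen, and (for alteplase/urokinase) secreted at kel*C0 to hold the
endogenous baseline. Protein secretion is homeostatic, S_i = kel_i * C_init.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import Regimen, iv_rate
from .parameters import (
    PROTEIN_SPECIES,
    DrugParameters,
    Patient,
    PlasmaKinetics,
    ProteinParameters,
)

__all__ = [
    "SystemicTrajectory",
    "IntegrationError",
    "plasma_activation_rate",
    "pai_inhibition_rate",
    "systemic_rhs",
    "simulate_systemic",
]

# state indices
_ICC, _ICP = 0, 1
_IPROT = {sp: 2 + i for i, sp in enumerate(PROTEIN_SPECIES)}
_NSTATE = 2 + len(PROTEIN_SPECIES)


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries time and state."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(f"{message} (t={t:.6g} s, state={np.array2string(state, precision=6)})")
        self.t = t
        self.state = state


@dataclass
class SystemicTrajectory:
    """Sampled solution of the systemic model.

    ``proteins`` has one column per species in :data:`PROTEIN_SPECIES` order.
    """

    drug: str
    times: np.ndarray           # (nt,), s, strictly increasing, t[0] = 0
    Cc: np.ndarray              # (nt,), uM
    Cp: np.ndarray              # (nt,), uM
    proteins: np.ndarray        # (nt, 6), uM

    def protein(self, species: str) -> np.ndarray:
        return self.proteins[:, _IPROT[species] - 2]

    def interpolator(self):
        """Return f(t) -> (Cc, proteins[6]) by linear interpolation.

        Used as the inlet boundary condition of the local clot model.
        """
        times = self.times
        Cc = self.Cc
        prot = self.proteins

        def f(t: float) -> np.ndarray:
            out = np.empty(1 + prot.shape[1])
            out[0] = np.interp(t, times, Cc)
            for j in range(prot.shape[1]):
                out[1 + j] = np.interp(t, times, prot[:, j])
            return out

        return f

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: time, compartment, species, concentration."""
        rows = [
            pd.DataFrame({"time": self.times, "compartment": "central",
                          "species": self.drug, "concentration": self.Cc}),
            pd.DataFrame({"time": self.times, "compartment": "peripheral",
                          "species": self.drug, "concentration": self.Cp}),
        ]
        for i, sp in enumerate(PROTEIN_SPECIES):
            rows.append(pd.DataFrame({"time": self.times, "compartment": "central",
                                      "species": sp,
                                      "concentration": self.proteins[:, i]}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, drug: str) -> "SystemicTrajectory":
        cc = df[(df.compartment == "central") & (df.species == drug)]
        cp = df[(df.compartment == "peripheral") & (df.species == drug)]
        times = cc["time"].to_numpy()
        prot = np.column_stack([
            df[(df.compartment == "central") & (df.species == sp)]
            ["concentration"].to_numpy()
            for sp in PROTEIN_SPECIES
        ])
        return cls(drug=drug, times=times, Cc=cc["concentration"].to_numpy(),
                   Cp=cp["concentration"].to_numpy(), proteins=prot)


def plasma_activation_rate(C_PA: float, C_PLG: float,
                           drug: DrugParameters) -> float:
    """Michaelis-Menten plasma-phase plasminogen activation rate, uM/s.

    Saturates at kcat*C_PA as C_PLG grows; the activator is catalytic and is
    not consumed.
    """
    return drug.kcat_plasma * C_PA * C_PLG / (drug.KM_plasma + C_PLG)


def pai_inhibition_rate(C_PA: float, C_PAI: float,
                        drug: DrugParameters) -> float:
    """Bilinear PAI-1 inhibition rate, uM/s; consumes drug and PAI-1 1:1."""
    return drug.kPAI * C_PA * C_PAI


def _protein_arrays(proteins: list[ProteinParameters]):
    by_sp = {p.species: p for p in proteins}
    missing = [sp for sp in PROTEIN_SPECIES if sp not in by_sp]
    if missing:
        raise ValueError(f"missing protein parameters for {missing}")
    kel = np.array([by_sp[sp].kel for sp in PROTEIN_SPECIES])
    c0 = np.array([by_sp[sp].C_init for sp in PROTEIN_SPECIES])
    return kel, c0, kel * c0  # kel_i, C_init, S_i


def systemic_rhs(t: float, y: np.ndarray, drug: DrugParameters,
                 regimen: Regimen | None, proteins: list[ProteinParameters],
                 patient: Patient, kinetics: PlasmaKinetics) -> np.ndarray:
    """Time derivatives of the 8-dimensional systemic state, uM/s."""
    kel_i, _, S_i = _protein_arrays(proteins)
    rate_mg_s = iv_rate(regimen, t) if regimen is not None else 0.0
    return _rhs_core(t, y, drug, rate_mg_s, kel_i, S_i, patient, kinetics)


def _rhs_core(t, y, drug, rate_mg_s, kel_i, S_i, patient, kin) -> np.ndarray:
    Cc, Cp = y[_ICC], y[_ICP]
    C = y[2:]
    PLG, PLS, AP, MG, FBG, PAI = C

    r_act = plasma_activation_rate(Cc, PLG, drug)
    r_pai = pai_inhibition_rate(Cc, PAI, drug)
    r_ap = kin.k_pls_ap * PLS * AP
    r_mg = kin.k_pls_mg * PLS * MG
    r_fbg = kin.k_pls_fbg * PLS * FBG

    Vc = drug.Vc_per_kg * patient.body_weight
    source = rate_mg_s * 1.0e3 / (drug.Mw * Vc)  # uM/s
    S_PA = drug.kel * drug.C0 if drug.endogenous_secretion else 0.0

    dy = np.empty(_NSTATE)
    dy[_ICC] = source - drug.kel * Cc - drug.kcp * Cc + drug.kpc * Cp + S_PA - r_pai
    dy[_ICP] = drug.kcp * Cc - drug.kpc * Cp
    dprot = -kel_i * C + S_i
    dprot[0] += -r_act            # PLG
    dprot[1] += r_act - r_ap - r_mg  # PLS
    dprot[2] += -r_ap             # AP
    dprot[3] += -r_mg             # MG
    dprot[4] += -r_fbg            # FBG
    dprot[5] += -r_pai            # PAI
    dy[2:] = dprot
    return dy


def initial_state(drug: DrugParameters,
                  proteins: list[ProteinParameters]) -> np.ndarray:
    """Pre-dose state: endogenous drug at C0 (peripheral at distribution
    equilibrium) and proteins at their baselines."""
    _, c0, _ = _protein_arrays(proteins)
    y0 = np.empty(_NSTATE)
    y0[_ICC] = drug.C0
    y0[_ICP] = drug.C0 * drug.kcp / drug.kpc if drug.kpc > 0 else 0.0
    y0[2:] = c0
    return y0


def simulate_systemic(drug: DrugParameters, regimen: Regimen | None,
                      proteins: list[ProteinParameters], patient: Patient,
                      kinetics: PlasmaKinetics, t_end: float,
                      dt_out: float = 5.0, rtol: float = 1.0e-8,
                      atol: float = 1.0e-15) -> SystemicTrajectory:
    """Integrate the systemic model over [0, t_end] with a stiff solver.

    The integration is restarted at every infusion-segment boundary so the
    discontinuous source term never degrades the adaptive error control.
    Output is sampled on a uniform grid of spacing ``dt_out`` (segment
    boundaries are included). PAI-1 falls many orders of magnitude during
    therapy, hence the very small absolute floor.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    kel_i, _, S_i = _protein_arrays(proteins)

    brk = [b for b in (regimen.breakpoints() if regimen is not None else [0.0])
           if b < t_end]
    brk = sorted(set(brk + [0.0, t_end]))

    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_grid = np.unique(np.clip(np.concatenate([t_grid, brk]), 0.0, t_end))

    y0 = initial_state(drug, proteins)
    times, states = [np.array([0.0])], [y0[None, :]]

    for a, b in zip(brk, brk[1:]):
        # the source rate is constant on (a, b)
        rate = iv_rate(regimen, 0.5 * (a + b)) if regimen is not None else 0.0

        def rhs(t, y, _rate=rate):
            return _rhs_core(t, y, drug, _rate, kel_i, S_i, patient, kinetics)

        t_eval = t_grid[(t_grid > a) & (t_grid <= b)]
        sol = solve_ivp(rhs, (a, b), y0, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval if len(t_eval) else None, dense_output=False)
        if not sol.success:
            raise IntegrationError(f"systemic integration failed: {sol.message}",
                                   sol.t[-1] if len(sol.t) else a, y0)
        # advance the initial condition with an exact endpoint solve
        if len(sol.t) == 0 or sol.t[-1] < b - 1e-9:
            tail = solve_ivp(rhs, (sol.t[-1] if len(sol.t) else a, b),
                             sol.y[:, -1] if len(sol.t) else y0,
                             method="LSODA", rtol=rtol, atol=atol)
            if not tail.success:
                raise IntegrationError(f"systemic integration failed: {tail.message}",
                                       tail.t[-1], tail.y[:, -1])
            y0 = tail.y[:, -1]
        else:
            y0 = sol.y[:, -1]
        if len(sol.t):
            times.append(sol.t)
            states.append(sol.y.T)

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    # deduplicate breakpoints that coincide with grid points
    keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
    t_all, y_all = t_all[keep], y_all[keep]

    # non-negativity contract: tiny integrator undershoots (below the
    # absolute-tolerance scale) are floored; anything larger is an error.
    floor = -1.0e3 * atol
    if np.any(y_all < floor):
        i, j = np.unravel_index(np.argmin(y_all), y_all.shape)
        raise IntegrationError("negative concentration beyond solver tolerance",
                               t_all[i], y_all[i])
    y_all = np.maximum(y_all, 0.0)

    return SystemicTrajectory(drug=drug.name, times=t_all, Cc=y_all[:, _ICC],
                              Cp=y_all[:, _ICP], proteins=y_all[:, 2:])
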