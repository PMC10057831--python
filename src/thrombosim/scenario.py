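"""Scenario configuration and reproducible end-to-end runs.

A :class:`Scenario` bundles everything one coupled simulation needs: drug,
regimen, patient, clot configuration, protein set, auxiliary kinetics,
horizon and solver/grid settings. Scenarios serialize to a schema-versioned
YAML dialect; every run directory receives the fully resolved scenario, its
content hash, tidy CSV outputs, a JSON report and a log of all resolved
parameter values (so calibration-surface defaults are always visible in the
record). The pipeline is deterministic: identical scenarios give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import metrics as _metrics
from .clot import LysisResult, simulate_lysis
from .dosing import Regimen, builtin_regimen
from .metrics import TherapyReport, build_report
from .parameters import (
    ClotConfig,
    DrugParameters,
    Patient,
    PlasmaKinetics,
    ProteinParameters,
    builtin_clot_config,
    builtin_drug,
    builtin_plasma_kinetics,
    builtin_proteins,
)
from .systemic import SystemicTrajectory, simulate_systemic

__all__ = ["Scenario", "preset_scenario", "run_scenario", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

#: Default simulation horizon, s. The local march stops at clot dissolution;
#: the systemic window extends to 4 h so the slow-clearing agents' systemic
#: lytic state (fibrinogen depletion) is fully captured for every drug.
DEFAULT_T_END = {name: 14400.0 for name in
                 ("alteplase", "tenecteplase", "urokinase", "reteplase")}


@dataclass
class Scenario:
    """Fully resolved configuration of one coupled run."""

    drug: DrugParameters
    regimen: Regimen
    patient: Patient
    clot: ClotConfig
    proteins: list[ProteinParameters]
    kinetics: PlasmaKinetics
    t_end: float
    dt_out_systemic: float = 5.0
    dt_out_clot: float = 15.0
    dt_max_clot: float = 2.0
    rtol: float = 1.0e-8
    atol: float = 1.0e-15
    lysis_threshold: float = _metrics.DEFAULT_LYSIS_THRESHOLD
    activation_drop: float = _metrics.DEFAULT_ACTIVATION_DROP

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.regimen.drug != self.drug.name:
            raise ValueError("regimen.drug must match drug.name")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "drug": self.drug.to_dict(),
            "regimen": self.regimen.to_dict(),
            "patient": self.patient.to_dict(),
            "clot": self.clot.to_dict(),
            "proteins": [p.to_dict() for p in self.proteins],
            "kinetics": self.kinetics.to_dict(),
            "solver": {
                "t_end": self.t_end,
                "dt_out_systemic": self.dt_out_systemic,
                "dt_out_clot": self.dt_out_clot,
                "dt_max_clot": self.dt_max_clot,
                "rtol": self.rtol,
                "atol": self.atol,
                "lysis_threshold": self.lysis_threshold,
                "activation_drop": self.activation_drop,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        try:
            version = d["schema_version"]
            if version != SCHEMA_VERSION:
                raise ValueError(f"schema_version: unsupported value {version}")
            solver = d["solver"]
            return cls(
                drug=DrugParameters.from_dict(d["drug"]),
                regimen=Regimen.from_dict(d["regimen"]),
                patient=Patient.from_dict(d["patient"]),
                clot=ClotConfig.from_dict(d["clot"]),
                proteins=[ProteinParameters.from_dict(p) for p in d["proteins"]],
                kinetics=PlasmaKinetics.from_dict(d["kinetics"]),
                t_end=float(solver["t_end"]),
                dt_out_systemic=float(solver.get("dt_out_systemic", 5.0)),
                dt_out_clot=float(solver.get("dt_out_clot", 15.0)),
                dt_max_clot=float(solver.get("dt_max_clot", 2.0)),
                rtol=float(solver.get("rtol", 1.0e-8)),
                atol=float(solver.get("atol", 1.0e-15)),
                lysis_threshold=float(solver.get("lysis_threshold",
                                                 _metrics.DEFAULT_LYSIS_THRESHOLD)),
                activation_drop=float(solver.get("activation_drop",
                                                 _metrics.DEFAULT_ACTIVATION_DROP)),
            )
        except KeyError as e:
            raise ValueError(f"scenario config missing field: {e.args[0]}") from e
        except TypeError as e:
            raise ValueError(f"scenario config field error: {e}") from e

    def to_yaml(self, path: Optional[Path] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "Scenario":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def content_hash(self) -> str:
        """sha256 over the canonical YAML serialization."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def preset_scenario(drug_name: str, body_weight: float = 80.0,
                    t_end: Optional[float] = None, **overrides) -> Scenario:
    """Built-in scenario for one of the four shipped drugs.

    ``overrides`` are forwarded to the Scenario constructor (solver and
    metric settings); drug/regimen/clot/protein parameters come from the
    packaged preset and calibration files.
    """
    drug = builtin_drug(drug_name)
    patient = Patient(body_weight=body_weight)
    return Scenario(
        drug=drug,
        regimen=builtin_regimen(drug_name, patient),
        patient=patient,
        clot=builtin_clot_config(),
        proteins=builtin_proteins(),
        kinetics=builtin_plasma_kinetics(),
        t_end=t_end if t_end is not None else DEFAULT_T_END[drug_name],
        **overrides,
    )


def run_scenario(scenario: Scenario, outdir: Optional[Path] = None
                 ) -> tuple[SystemicTrajectory, LysisResult, TherapyReport]:
    """Execute systemic then local simulation then metrics.

    If ``outdir`` is given, writes the standard run-directory layout:
    scenario.yaml (resolved), systemic.csv, clot.csv, report.json, log.txt.
    """
    log_lines = [f"scenario hash: {scenario.content_hash()}",
                 "resolved scenario:", scenario.to_yaml()]
    traj = simulate_systemic(scenario.drug, scenario.regimen,
                             scenario.proteins, scenario.patient,
                             scenario.kinetics, scenario.t_end,
                             dt_out=scenario.dt_out_systemic,
                             rtol=scenario.rtol, atol=scenario.atol)
    result = simulate_lysis(scenario.drug, traj, scenario.clot,
                            scenario.kinetics, scenario.t_end,
                            dt_max=scenario.dt_max_clot,
                            dt_out=scenario.dt_out_clot)
    report = build_report(traj, result,
                          threshold_fraction=scenario.lysis_threshold,
                          drop_fraction=scenario.activation_drop)
    log_lines.append(f"report: {json.dumps(report.to_dict(), indent=2)}")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scenario.to_yaml(outdir / "scenario.yaml")
        traj.to_frame().to_csv(outdir / "systemic.csv", index=False)
        result.to_frame().to_csv(outdir / "clot.csv", index=False)
        meta = report.to_dict()
        meta["scenario_hash"] = scenario.content_hash()
        (outdir / "report.json").write_text(json.dumps(meta, indent=2))
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return traj, result, report
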