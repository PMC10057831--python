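"""Efficacy and safety read-outs from simulation records.

All metrics are pure functions of the recorded trajectories: lysis time
(first time every clot position falls below a threshold fraction of its
initial binding sites), activation time (first measurable site degradation
at the monitoring position, default 5 mm into the clot), front lysis
duration, systemic drug exposure (AUC), fibrinogen depletion (the proxy for
intracranial-hemorrhage risk) and PAI-1 resistance summaries. Crossing
times are linearly interpolated between stored frames.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .clot import LysisResult, _IPAI, _IFBG
from .systemic import SystemicTrajectory

__all__ = [
    "TherapyReport",
    "lysis_time",
    "activation_time",
    "front_lysis_duration",
    "exposure_auc",
    "safety_profile",
    "build_report",
    "compare_drugs",
]

#: Default completion threshold: a cell counts as lysed once its binding
#: sites fall below this fraction of their initial value.
DEFAULT_LYSIS_THRESHOLD = 0.05
#: Default activation criterion: sites at the monitor fall 10% below initial.
DEFAULT_ACTIVATION_DROP = 0.10


def _crossing_time(times: np.ndarray, series: np.ndarray,
                   level: float) -> Optional[float]:
    """First time ``series`` (non-increasing) reaches ``level``, interpolated."""
    below = series <= level
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = series[i - 1], series[i]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - level) / (y0 - y1) * (t1 - t0))


def _cell_crossing(result: LysisResult, cell: int,
                   fraction: float) -> Optional[float]:
    n0 = result.ntot_init[cell]
    return _crossing_time(result.times, result.ntot[:, cell], fraction * n0)


def lysis_time(result: LysisResult,
               threshold_fraction: float = DEFAULT_LYSIS_THRESHOLD
               ) -> Optional[float]:
    """First time all clot cells are below ``threshold_fraction`` of their
    initial binding sites; None if the clot never fully lyses."""
    cells = np.flatnonzero(result.clot_mask)
    crossings = [_cell_crossing(result, c, threshold_fraction) for c in cells]
    if any(c is None for c in crossings):
        return None
    return max(crossings)


def _monitor_cell(result: LysisResult, x_monitor: Optional[float]) -> int:
    xm = result.config.x_monitor if x_monitor is None else x_monitor
    cells = np.flatnonzero(result.clot_mask)
    return int(cells[np.argmin(np.abs(result.x_clot - xm))])


def activation_time(result: LysisResult, x_monitor: Optional[float] = None,
                    drop_fraction: float = DEFAULT_ACTIVATION_DROP
                    ) -> Optional[float]:
    """First time binding sites at the monitoring position (measured from the
    clot face) fall below (1 - drop_fraction) of their initial value."""
    cell = _monitor_cell(result, x_monitor)
    return _cell_crossing(result, cell, 1.0 - drop_fraction)


def front_lysis_duration(result: LysisResult,
                         threshold_fraction: float = DEFAULT_LYSIS_THRESHOLD,
                         drop_fraction: float = DEFAULT_ACTIVATION_DROP
                         ) -> Optional[float]:
    """Time for the inlet-face cell to go from activation (10% site loss) to
    completion (below the lysis threshold)."""
    face = int(np.flatnonzero(result.clot_mask)[0])
    t_act = _cell_crossing(result, face, 1.0 - drop_fraction)
    t_lys = _cell_crossing(result, face, threshold_fraction)
    if t_act is None or t_lys is None:
        return None
    return t_lys - t_act


def exposure_auc(traj: SystemicTrajectory) -> float:
    """Trapezoidal area under the central-compartment drug curve, uM*s."""
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    return float(np.trapezoid(traj.Cc, traj.times))


def safety_profile(traj: SystemicTrajectory,
                   result: Optional[LysisResult] = None,
                   lysis_t: Optional[float] = None) -> dict:
    """Fibrinogen and PAI-1 summaries.

    Systemic FBG nadir (absolute and as a fraction of baseline; low values
    proxy hemorrhage risk), minimum systemic PAI-1, and the mean free-phase
    PAI-1 inside the clot at lysis completion (if a local record and a lysis
    time are available).
    """
    fbg = traj.protein("FBG")
    pai = traj.protein("PAI")
    out = {
        "fbg_nadir_systemic": float(fbg.min()),
        "fbg_nadir_fraction": float(fbg.min() / fbg[0]) if fbg[0] > 0 else 1.0,
        "pai_min_systemic": float(pai.min()),
        "pai_at_lysis_clot": None,
    }
    if result is not None and lysis_t is not None:
        i = int(np.argmin(np.abs(result.times - lysis_t)))
        out["pai_at_lysis_clot"] = float(
            result.C[i, _IPAI, result.clot_mask].mean())
    return out


@dataclass
class TherapyReport:
    """Per-drug summary of one coupled simulation."""

    drug: str
    lysis_time: Optional[float]          # s; None if incomplete by t_end
    activation_time: Optional[float]     # s, at the monitoring position
    front_lysis_duration: Optional[float]  # s, at the inlet-face cell
    auc_drug_exposure: float             # uM*s
    peak_systemic: float                 # uM
    fbg_nadir_systemic: float            # uM
    fbg_nadir_fraction: float
    pai_min_systemic: float              # uM
    pai_at_lysis_clot: Optional[float]   # uM
    complete: bool

    def to_dict(self) -> dict:
        return asdict(self)


def build_report(traj: SystemicTrajectory, result: LysisResult,
                 threshold_fraction: float = DEFAULT_LYSIS_THRESHOLD,
                 drop_fraction: float = DEFAULT_ACTIVATION_DROP
                 ) -> TherapyReport:
    t_lys = lysis_time(result, threshold_fraction)
    t_act = activation_time(result, drop_fraction=drop_fraction)
    safety = safety_profile(traj, result, t_lys)
    return TherapyReport(
        drug=traj.drug,
        lysis_time=t_lys,
        activation_time=t_act,
        front_lysis_duration=front_lysis_duration(result, threshold_fraction,
                                                  drop_fraction),
        auc_drug_exposure=exposure_auc(traj),
        peak_systemic=float(traj.Cc.max()),
        complete=t_lys is not None,
        **safety,
    )


_RANK_METRICS = {
    # metric -> (column, ascending_is_first)
    "lysis_time": ("lysis_time", True),
    "activation_time": ("activation_time", True),
    "fbg_nadir": ("fbg_nadir_systemic", True),
    "pai_resistance": ("pai_min_systemic", True),
}


def compare_drugs(reports: list[TherapyReport]):
    """Assemble the multi-drug comparison.

    Returns ``(table, rankings)``: a DataFrame with one row per drug (sorted
    by drug name, so the result does not depend on input order) and, when at
    least two drugs are present, a dict of drug orderings per metric
    (ascending metric value; for PAI-1 the lowest minimum means the weakest
    inhibition resistance, so ascending order ranks resistance worst-first).
    """
    if len(reports) == 0:
        raise ValueError("at least one report required")
    rows = sorted((r.to_dict() for r in reports), key=lambda d: d["drug"])
    table = pd.DataFrame(rows).set_index("drug")
    rankings: dict[str, list[str]] = {}
    if len(rows) >= 2:
        for metric, (col, _) in _RANK_METRICS.items():
            sub = table[table[col].notna()]
            rankings[metric] = list(sub.sort_values(col).index)
    return table, rankings
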