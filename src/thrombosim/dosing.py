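"""Intravenous dose regimens as piecewise-constant infusion rate functions.

Boluses are modelled as short finite infusions at their clinically stated
durations (5 s, 1 min, 2 min), never as impulses. The reteplase 30-minute
"interval" is interpreted as end-of-bolus-1 to start-of-bolus-2 (standard
clinical phrasing), so its second segment starts at t = 1920 s; the timing is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .parameters import DRUG_NAMES, Patient

__all__ = ["InfusionSegment", "Regimen", "builtin_regimen", "iv_rate"]


@dataclass(frozen=True)
class InfusionSegment:
    """One constant-rate infusion: ``mass`` mg delivered over ``duration`` s."""

    t_start: float  # s
    duration: float  # s
    mass: float  # mg

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.mass < 0:
            raise ValueError("mass must be >= 0")
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    @property
    def rate(self) -> float:
        """mg/s while the segment is active."""
        return self.mass / self.duration

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Regimen:
    """An ordered, non-overlapping list of infusion segments for one drug."""

    drug: str
    segments: tuple[InfusionSegment, ...]

    def __post_init__(self) -> None:
        if self.drug not in DRUG_NAMES:
            raise ValueError(
                f"unknown drug {self.drug!r}; valid names: {', '.join(DRUG_NAMES)}"
            )
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ValueError("segments must be time-ordered and non-overlapping")
        if self.total_mass <= 0:
            raise ValueError("total regimen mass must be > 0")

    @property
    def total_mass(self) -> float:
        """Total delivered mass, mg."""
        return float(sum(s.mass for s in self.segments))

    @property
    def t_end(self) -> float:
        """End of the last segment, s."""
        return max(s.t_end for s in self.segments)

    def breakpoints(self) -> list[float]:
        """Sorted unique segment start/end times (integrator restart points)."""
        pts = {0.0}
        for s in self.segments:
            pts.add(s.t_start)
            pts.add(s.t_end)
        return sorted(pts)

    def to_dict(self) -> dict:
        return {"drug": self.drug,
                "segments": [s.to_dict() for s in self.segments]}

    @classmethod
    def from_dict(cls, d: dict) -> "Regimen":
        return cls(drug=d["drug"],
                   segments=tuple(InfusionSegment(**s) for s in d["segments"]))


def builtin_regimen(drug: str, patient: Patient) -> Regimen:
    """Resolve the standard clinical regimen of ``drug`` for ``patient``.

    * alteplase: 0.9 mg/kg; 10% as a 1-min loading bolus, the remaining 90%
      infused over 60 min.
    * tenecteplase: single 0.25 mg/kg bolus over 5 s.
    * reteplase: double bolus of 17.4 mg (10 U) over 2 min each, 30 min apart.
    * urokinase: 1,500,000 U (~11.3 mg) infused over 30 min.
    """
    w = patient.body_weight
    if drug == "alteplase":
        total = 0.9 * w
        segs = (InfusionSegment(0.0, 60.0, 0.1 * total),
                InfusionSegment(60.0, 3600.0, 0.9 * total))
    elif drug == "tenecteplase":
        segs = (InfusionSegment(0.0, 5.0, 0.25 * w),)
    elif drug == "reteplase":
        segs = (InfusionSegment(0.0, 120.0, 17.4),
                InfusionSegment(120.0 + 1800.0, 120.0, 17.4))
    elif drug == "urokinase":
        segs = (InfusionSegment(0.0, 1800.0, 11.3),)
    else:
        raise ValueError(
            f"unknown drug {drug!r}; valid names: {', '.join(DRUG_NAMES)}"
        )
    return Regimen(drug=drug, segments=segs)


def iv_rate(regimen: Regimen, t) -> float | np.ndarray:
    """Infusion rate IV(t) in mg/s; vectorized over ``t``.

    Segment boundaries are half-open [t_start, t_end) so rates never double
    up where one segment abuts the next.
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros_like(t_arr)
    for s in regimen.segments:
        out = np.where((t_arr >= s.t_start) & (t_arr < s.t_end), out + s.rate, out)
    if np.ndim(t) == 0:
        return float(out)
    return out
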