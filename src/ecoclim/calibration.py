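"""Stress-parameter calibration against labeled presence/absence records.

The original fitting of the cold/heat stress parameters was a manual
map-matching loop: adjust TTCS/THCS/TTHS/THHS until modeled persistence
agrees with the recorded distribution. Here that loop is formalised as
minimisation of the misclassification count of the persistence predicate
``EI > 0`` over labeled stations, by coordinate descent over user-supplied
per-parameter value grids. False presences (model persists where the
species is absent) and false absences are weighted equally by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import SoilParams, run_station
from .params import SpeciesParams
from .stations import StationClimate

__all__ = [
    "LabeledStation",
    "CalibrationResult",
    "objective",
    "fit_stress_params",
    "FREE_PARAMS",
]

FREE_PARAMS = ("TTCS", "THCS", "TTHS", "THHS")


@dataclass(frozen=True)
class LabeledStation:
    """A station plus a persistence label: 'present' means the species is
    recorded to persist/overwinter there, 'absent' that it is not."""

    station: StationClimate
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("present", "absent"):
            raise ValueError(f"label must be 'present' or 'absent', got {self.label!r}")


@dataclass(frozen=True)
class CalibrationResult:
    fitted: SpeciesParams
    misclassified: int
    false_presence: int   # EI > 0 where labeled absent
    false_absence: int    # EI = 0 where labeled present
    trace: tuple          # accepted (params, objective) pairs, in order


def objective(params: SpeciesParams, labeled: list[LabeledStation],
              soil: SoilParams | None = None,
              w_presence: float = 1.0, w_absence: float = 1.0,
              ) -> tuple[float, int, int]:
    """(weighted misclassification, false presences, false absences).

    With unit weights the first element is the plain misclassification count.
    """
    if not labeled:
        raise ValueError("need at least one labeled station")
    fp = fn = 0
    for ls in labeled:
        predicted_present = run_station(ls.station, params, soil).EI > 0.0
        if predicted_present and ls.label == "absent":
            fp += 1
        elif not predicted_present and ls.label == "present":
            fn += 1
    return w_presence * fp + w_absence * fn, fp, fn


def fit_stress_params(labeled: list[LabeledStation], init: SpeciesParams,
                      free: tuple[str, ...] | list[str],
                      grid: dict[str, list[float]],
                      soil: SoilParams | None = None,
                      max_cycles: int = 10,
                      w_presence: float = 1.0, w_absence: float = 1.0,
                      ) -> CalibrationResult:
    """Coordinate descent over per-parameter grids.

    Cycles through the free parameters in the order given; for each, takes
    the grid value minimising the objective with the others held fixed.
    Ties break deterministically: prefer the value closest to the initial
    parameter, then the smaller value. Stops at a fixed point or after
    ``max_cycles`` full cycles. The accepted objective is non-increasing
    along the trace, so the result is never worse than the start.
    """
    free = tuple(free)
    if not free:
        raise ValueError("free must name at least one parameter")
    for name in free:
        if name not in FREE_PARAMS:
            raise ValueError(f"unknown free parameter {name!r}; choose from {FREE_PARAMS}")
        if name not in grid or not grid[name]:
            raise ValueError(f"grid must supply a non-empty value list for {name!r}")
        for v in grid[name]:
            init.replace(**{name: v})  # raises early if a grid value breaks an invariant

    def score(p: SpeciesParams) -> float:
        return objective(p, labeled, soil, w_presence, w_absence)[0]

    current = init
    best_obj = score(current)
    trace = [(current, best_obj)]
    for _ in range(max_cycles):
        changed = False
        for name in free:
            init_val = getattr(init, name)
            candidates = []
            for v in grid[name]:
                cand = current.replace(**{name: v})
                candidates.append((score(cand), abs(v - init_val), v, cand))
            candidates.sort(key=lambda t: (t[0], t[1], t[2]))
            obj, _, v, cand = candidates[0]
            if obj <= best_obj and v != getattr(current, name):
                current, best_obj, changed = cand, obj, True
                trace.append((current, best_obj))
        if not changed:
            break
    _, fp, fn = objective(current, labeled, soil)
    return CalibrationResult(
        fitted=current, misclassified=fp + fn,
        false_presence=fp, false_absence=fn, trace=tuple(trace),
    )
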