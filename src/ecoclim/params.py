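"""Species parameter sets for the ecoclimatic suitability model.

A :class:`SpeciesParams` bundles the seventeen values that govern how a
poikilotherm responds to weekly temperature and soil moisture: the four
development thresholds (DV0..DV3, degC), the four soil-moisture thresholds
(SM0..SM3, fraction of bucket capacity), the four stress threshold/rate
pairs (cold, heat, dry, wet), and the degree-day total per generation (PDD,
degC-days above DV0).

Stress accumulation rates are stored as nonnegative magnitudes; the
direction of accumulation (stress grows while the driving series is past
its threshold) is fixed by the model, not by the sign of the rate.

Parameter files are flat UTF-8 ``KEY = value`` text, one key per line,
``#`` comments allowed, keys named exactly after the model symbols.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "SpeciesParams",
    "ParamFileError",
    "ParamValidationError",
    "load_params",
    "store_params",
    "load_fixture",
    "PARAM_KEYS",
]

PARAM_KEYS = (
    "DV0", "DV1", "DV2", "DV3",
    "SM0", "SM1", "SM2", "SM3",
    "TTCS", "THCS", "TTHS", "THHS",
    "SMDS", "HDS", "SMWS", "HWS",
    "PDD",
)


class ParamFileError(ValueError):
    """A parameter file is missing a key, has an unknown key, or is malformed."""


class ParamValidationError(ValueError):
    """A parameter set violates an ordering or sign invariant."""


@dataclass(frozen=True)
class SpeciesParams:
    """Validated species response parameters.

    Raises :class:`ParamValidationError` on construction if the threshold
    orderings or rate signs are inconsistent.
    """

    DV0: float   # lower development threshold, degC
    DV1: float   # lower optimum, degC
    DV2: float   # upper optimum, degC
    DV3: float   # upper development limit, degC
    SM0: float   # lower moisture threshold, fraction of capacity
    SM1: float   # lower moisture optimum
    SM2: float   # upper moisture optimum
    SM3: float   # upper moisture limit
    TTCS: float  # cold-stress temperature threshold, degC
    THCS: float  # cold-stress accumulation rate magnitude, week^-1
    TTHS: float  # heat-stress temperature threshold, degC
    THHS: float  # heat-stress accumulation rate magnitude, week^-1
    SMDS: float  # dry-stress moisture threshold, fraction
    HDS: float   # dry-stress rate magnitude, week^-1
    SMWS: float  # wet-stress moisture threshold, fraction
    HWS: float   # wet-stress rate magnitude, week^-1
    PDD: float   # degree-days per generation above DV0, degC-days

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self
        if not (p.DV0 < p.DV1):
            raise ParamValidationError("DV0 must be < DV1 (got DV0=%g, DV1=%g)" % (p.DV0, p.DV1))
        if not (p.DV1 <= p.DV2):
            raise ParamValidationError("DV1 must be <= DV2 (got DV1=%g, DV2=%g)" % (p.DV1, p.DV2))
        if not (p.DV2 < p.DV3):
            raise ParamValidationError("DV2 must be < DV3 (got DV2=%g, DV3=%g)" % (p.DV2, p.DV3))
        if not (p.SM0 < p.SM1):
            raise ParamValidationError("SM0 must be < SM1 (got SM0=%g, SM1=%g)" % (p.SM0, p.SM1))
        if not (p.SM1 <= p.SM2):
            raise ParamValidationError("SM1 must be <= SM2 (got SM1=%g, SM2=%g)" % (p.SM1, p.SM2))
        if not (p.SM2 < p.SM3):
            raise ParamValidationError("SM2 must be < SM3 (got SM2=%g, SM3=%g)" % (p.SM2, p.SM3))
        if not (p.SMDS <= p.SM0):
            raise ParamValidationError(
                "dry-stress threshold SMDS must be <= SM0 (got SMDS=%g, SM0=%g)" % (p.SMDS, p.SM0))
        if not (p.SMWS >= p.SM3):
            raise ParamValidationError(
                "wet-stress threshold SMWS must be >= SM3 (got SMWS=%g, SM3=%g)" % (p.SMWS, p.SM3))
        if not (p.TTCS < p.DV0):
            raise ParamValidationError(
                "cold-stress threshold TTCS must be < DV0 (got TTCS=%g, DV0=%g)" % (p.TTCS, p.DV0))
        if not (p.TTHS >= p.DV3):
            raise ParamValidationError(
                "heat-stress threshold TTHS must be >= DV3 (got TTHS=%g, DV3=%g)" % (p.TTHS, p.DV3))
        for key in ("THCS", "THHS", "HDS", "HWS"):
            if getattr(p, key) < 0:
                raise ParamValidationError(
                    "%s is a rate magnitude and must be >= 0 (got %g)" % (key, getattr(p, key)))
        if not (p.PDD > 0):
            raise ParamValidationError("PDD must be > 0 (got %g)" % p.PDD)

    def replace(self, **changes: float) -> "SpeciesParams":
        """Return a copy with some fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAM_KEYS}


def load_params(path: str | Path) -> SpeciesParams:
    """Read a ``KEY = value`` parameter file and return a validated set.

    All seventeen keys are required; unknown keys are rejected.
    """
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParamFileError(f"{path}:{lineno}: expected 'KEY = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in PARAM_KEYS:
            raise ParamFileError(f"{path}:{lineno}: unknown parameter key {key!r}")
        if key in values:
            raise ParamFileError(f"{path}:{lineno}: duplicate parameter key {key!r}")
        try:
            values[key] = float(val.strip())
        except ValueError as exc:
            raise ParamFileError(f"{path}:{lineno}: non-numeric value for {key}: {val.strip()!r}") from exc
    missing = [k for k in PARAM_KEYS if k not in values]
    if missing:
        raise ParamFileError(f"{path}: missing required parameter key(s): {', '.join(missing)}")
    return SpeciesParams(**values)


def store_params(params: SpeciesParams, path: str | Path) -> None:
    """Write a parameter file that round-trips through :func:`load_params` exactly.

    Values are written with ``repr`` so every float is preserved bit-for-bit.
    """
    path = Path(path)
    lines = ["# species parameter file (KEY = value)"]
    lines += [f"{k} = {getattr(params, k)!r}" for k in PARAM_KEYS]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_fixture(name: str) -> SpeciesParams:
    """Load a packaged parameter set by name.

    Shipped fixtures:

    - ``s_exigua_initial`` — the literature-derived set before iterative
      adjustment (TTCS 0.73 degC, THCS 0.1699, TTHS 40 degC, THHS 0.0177).
    - ``s_exigua_final`` — the set after iteration against the known world
      distribution (TTCS 3.2 degC, THCS 0.20, TTHS 36 degC, THHS 0.0163),
      used for the China projection.
    """
    ref = importlib.resources.files("ecoclim.data").joinpath(f"{name}.cfg")
    if not ref.is_file():
        raise FileNotFoundError(f"no packaged parameter fixture named {name!r}")
    with importlib.resources.as_file(ref) as p:
        return load_params(p)
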