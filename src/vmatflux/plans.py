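"""Arc-plan data model and I/O.

A VMAT arc is stored as an ordered sequence of control points (CPs); each CP
is a snapshot of gantry angle, MLC aperture, jaw settings, and cumulative
monitor units during the dynamic delivery.

Conventions
-----------
* Leaf travel axis ``x`` is positive toward bank B; positions are leaf-tip
  coordinates at isocenter in cm. Bank A is the "left" bank, so a valid pair
  has ``bank_a[j] <= bank_b[j]`` (equal when closed).
* Gantry and collimator angles in degrees; gantry in [0, 360) with wrap-around
  (e.g. 357° -> 3° crossing 0°) handled by unwrapping for spacing/interpolation.
* ``cumulative_mu`` is monotone non-decreasing; it may be absolute MU or a
  fraction of the plan total — all downstream weights are relative.

The on-disk format is the JSON schema ``vmatflux-plan/1`` (see README).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mlc import MLCModel, get_model

__all__ = [
    "Jaws",
    "Aperture",
    "ControlPoint",
    "ArcPlan",
    "PlanValidationError",
    "validate_plan",
    "read_plan",
    "write_plan",
    "import_dicom_rtplan",
    "unwrap_gantry",
]

PLAN_FORMAT = "vmatflux-plan/1"


class PlanValidationError(ValueError):
    """An arc plan violated a structural invariant; names the offending CP."""

    def __init__(self, message: str, cp_index: Optional[int] = None):
        self.cp_index = cp_index
        if cp_index is not None:
            message = f"control point {cp_index}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Jaws:
    """Jaw positions at isocenter (cm): x along leaf travel, y along leaf width."""

    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self):
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError("jaw intervals must be non-degenerate (x1 < x2, y1 < y2)")


@dataclass(frozen=True)
class Aperture:
    """One MLC + jaw machine-state snapshot (no gantry/MU attached)."""

    bank_a: np.ndarray  # leaf-tip x positions, cm, one per pair
    bank_b: np.ndarray
    jaws: Jaws

    def __post_init__(self):
        a = np.asarray(self.bank_a, dtype=float)
        b = np.asarray(self.bank_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("bank_a and bank_b must be 1-D and the same length")
        object.__setattr__(self, "bank_a", a)
        object.__setattr__(self, "bank_b", b)

    @property
    def n_pairs(self) -> int:
        return self.bank_a.size


@dataclass(frozen=True)
class ControlPoint:
    gantry_angle: float  # degrees, [0, 360)
    collimator_angle: float  # degrees
    bank_a: np.ndarray  # cm at isocenter
    bank_b: np.ndarray
    jaws: Jaws
    cumulative_mu: float

    def __post_init__(self):
        a = np.asarray(self.bank_a, dtype=float)
        b = np.asarray(self.bank_b, dtype=float)
        object.__setattr__(self, "bank_a", a)
        object.__setattr__(self, "bank_b", b)

    @property
    def aperture(self) -> Aperture:
        return Aperture(self.bank_a, self.bank_b, self.jaws)


@dataclass(frozen=True)
class ArcPlan:
    machine: MLCModel
    control_points: tuple
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "control_points", tuple(self.control_points))
        validate_plan(self)

    @property
    def n_cp(self) -> int:
        return len(self.control_points)

    @property
    def mu(self) -> np.ndarray:
        return np.array([cp.cumulative_mu for cp in self.control_points])

    @property
    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])


def unwrap_gantry(angles_deg: Sequence[float]) -> np.ndarray:
    """Unwrap a gantry-angle sequence so consecutive steps lie in (-180, 180].

    A 357° -> 3° crossing becomes 357 -> 363 so spacing and interpolation are
    well defined; re-wrap with ``% 360`` when needed.
    """
    a = np.asarray(angles_deg, dtype=float)
    out = a.copy()
    for i in range(1, a.size):
        d = (a[i] - a[i - 1] + 180.0) % 360.0 - 180.0
        if d == -180.0:
            d = 180.0
        out[i] = out[i - 1] + d
    return out


def validate_plan(plan: ArcPlan) -> None:
    """Check every ArcPlan invariant; raise a located PlanValidationError.

    Validation is total: a plan either passes everything or the first broken
    invariant is reported with its CP index. Nothing is silently repaired.
    """
    cps = plan.control_points
    if len(cps) < 2:
        raise PlanValidationError("an arc needs at least 2 control points")
    n_leaves = plan.machine.n_pairs
    coll = cps[0].collimator_angle
    for i, cp in enumerate(cps):
        if cp.bank_a.size != n_leaves:
            raise PlanValidationError(
                f"{cp.bank_a.size} leaf pairs but machine model has {n_leaves}", i
            )
        if np.any(cp.bank_a > cp.bank_b):
            j = int(np.argmax(cp.bank_a > cp.bank_b))
            raise PlanValidationError(f"bank crossing at leaf pair {j + 1}", i)
        if cp.collimator_angle != coll:
            raise PlanValidationError("collimator angle differs from first CP", i)
        if cp.cumulative_mu < 0:
            raise PlanValidationError("cumulative MU is negative", i)
        if i and cp.cumulative_mu < cps[i - 1].cumulative_mu:
            raise PlanValidationError("cumulative MU decreases", i)
    unwrapped = unwrap_gantry([cp.gantry_angle for cp in cps])
    steps = np.diff(unwrapped)
    if np.any(steps == 0):
        i = int(np.argmax(steps == 0)) + 1
        raise PlanValidationError("zero angular spacing from previous CP", i)
    if not (np.all(steps > 0) or np.all(steps < 0)):
        i = int(np.argmax(np.sign(steps) != np.sign(steps[0]))) + 1
        raise PlanValidationError("gantry direction reverses", i)


# -- JSON I/O ---------------------------------------------------------------


def write_plan(plan: ArcPlan, path) -> None:
    doc = {
        "format": PLAN_FORMAT,
        "machine": plan.machine.name,
        "metadata": dict(plan.metadata),
        "control_points": [
            {
                "gantry_angle": cp.gantry_angle,
                "collimator_angle": cp.collimator_angle,
                "bank_a": cp.bank_a.tolist(),
                "bank_b": cp.bank_b.tolist(),
                "jaws": {"x1": cp.jaws.x1, "x2": cp.jaws.x2, "y1": cp.jaws.y1, "y2": cp.jaws.y2},
                "cumulative_mu": cp.cumulative_mu,
            }
            for cp in plan.control_points
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_plan(path, machine: Optional[MLCModel] = None) -> ArcPlan:
    """Read a ``vmatflux-plan/1`` JSON document.

    The machine model is resolved from the built-in registry by name unless an
    explicit ``machine`` override is given.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != PLAN_FORMAT:
        raise PlanValidationError(f"not a {PLAN_FORMAT} document (format={doc.get('format')!r})")
    model = machine if machine is not None else get_model(doc["machine"])
    cps = []
    for i, c in enumerate(doc.get("control_points", [])):
        try:
            cps.append(
                ControlPoint(
                    gantry_angle=float(c["gantry_angle"]),
                    collimator_angle=float(c["collimator_angle"]),
                    bank_a=c["bank_a"],
                    bank_b=c["bank_b"],
                    jaws=Jaws(**c["jaws"]),
                    cumulative_mu=float(c["cumulative_mu"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise PlanValidationError(f"malformed control point ({exc})", i) from exc
    return ArcPlan(machine=model, control_points=cps, metadata=doc.get("metadata", {}))


# -- DICOM RTPLAN import ----------------------------------------------------


class UnsupportedPlanError(ValueError):
    """The DICOM plan is not a single-arc VMAT plan on a supported MLC."""


def _match_machine(boundaries_mm: np.ndarray) -> MLCModel:
    for name in ("millennium", "hdmlc"):
        model = get_model(name)
        if boundaries_mm.size == model.n_pairs + 1 and np.allclose(
            boundaries_mm, model.boundaries, atol=1e-6
        ):
            return model
    raise UnsupportedPlanError(
        f"MLC leaf boundary table ({boundaries_mm.size - 1} pairs) matches no built-in model"
    )


def import_dicom_rtplan(path) -> ArcPlan:
    """Import the first (only) VMAT beam of a DICOM RT Plan as an ArcPlan.

    Leaf/jaw positions are converted mm -> cm; cumulative meterset weight is
    used as ``cumulative_mu``. Static (non-arc) plans and unknown MLC
    geometries raise :class:`UnsupportedPlanError`.
    """
    import pydicom

    ds = pydicom.dcmread(path, force=True)
    beams = list(getattr(ds, "BeamSequence", []))
    if not beams:
        raise UnsupportedPlanError("RT Plan contains no beams")
    beam = beams[0]
    n_cp = int(getattr(beam, "NumberOfControlPoints", 0))
    cps_raw = list(getattr(beam, "ControlPointSequence", []))
    first = cps_raw[0]
    rotation = str(getattr(first, "GantryRotationDirection", "NONE"))
    if n_cp < 2 or rotation in ("NONE", ""):
        raise UnsupportedPlanError("not an arc plan (static gantry)")

    model = None
    for bld in getattr(beam, "BeamLimitingDeviceSequence", []):
        if str(bld.RTBeamLimitingDeviceType).startswith("MLC"):
            model = _match_machine(np.asarray(bld.LeafPositionBoundaries, dtype=float))
    if model is None:
        raise UnsupportedPlanError("no MLC in beam limiting device sequence")

    gantry = coll = None
    jaws_mm = {}
    mlc_mm = None
    cps = []
    for raw in cps_raw:
        gantry = float(getattr(raw, "GantryAngle", gantry))
        coll = float(getattr(raw, "BeamLimitingDeviceAngle", 0.0 if coll is None else coll))
        for pos in getattr(raw, "BeamLimitingDevicePositionSequence", []):
            kind = str(pos.RTBeamLimitingDeviceType)
            vals = np.asarray(pos.LeafJawPositions, dtype=float)
            if kind in ("X", "ASYMX"):
                jaws_mm["x"] = vals
            elif kind in ("Y", "ASYMY"):
                jaws_mm["y"] = vals
            elif kind.startswith("MLC"):
                mlc_mm = vals
        if mlc_mm is None or "x" not in jaws_mm or "y" not in jaws_mm:
            raise UnsupportedPlanError("control point missing MLC or jaw positions")
        n = model.n_pairs
        cps.append(
            ControlPoint(
                gantry_angle=gantry % 360.0,
                collimator_angle=coll,
                bank_a=mlc_mm[:n] / 10.0,
                bank_b=mlc_mm[n:] / 10.0,
                jaws=Jaws(
                    x1=jaws_mm["x"][0] / 10.0,
                    x2=jaws_mm["x"][1] / 10.0,
                    y1=jaws_mm["y"][0] / 10.0,
                    y2=jaws_mm["y"][1] / 10.0,
                ),
                cumulative_mu=float(raw.CumulativeMetersetWeight),
            )
        )
    meta = {"plan_id": str(getattr(ds, "RTPlanLabel", "")), "source": "dicom-rtplan"}
    return ArcPlan(machine=model, control_points=cps, metadata=meta)
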