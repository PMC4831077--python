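"""Arc-discretization schemes for VMAT dose calculation.

The continuous delivery arc is approximated by static beams. Three schemes
are provided:

``1aper``
    One beam per control point, carrying that CP's own aperture.
``3apers``
    One beam per control point carrying three apertures: the CP's own plus
    two interpolated at two-thirds of a CP interval before and after it
    (leaf positions 2/3*x_i + 1/3*x_{i-1} and 2/3*x_i + 1/3*x_{i+1}). The
    beam fluence is the unweighted mean of the three aperture fluences, so
    the number of beam-level dose evaluations is unchanged.
``3xbeams``
    A plain denser discretization: two beams inserted between each adjacent
    CP pair at 1/3 and 2/3 of the interval (leaf positions, jaws, gantry and
    cumulative MU all linearly interpolated), then treated as ``1aper``.

Per-beam relative weights assign half of the monitor units delivered in each
adjacent interval to the CPs at its ends:

    w_i = (MU_i - MU_{i-1})/2 + (MU_{i+1} - MU_i)/2

with the first and last CP carrying zero weight (kick-off / ending beams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plans import Aperture, ArcPlan, ControlPoint, Jaws, unwrap_gantry

__all__ = [
    "WeightedBeam",
    "cp_weight",
    "cp_weights",
    "interpolate_aperture",
    "three_aperture_beam",
    "one_aperture_beam",
    "triple_beams",
    "discretize",
    "MODES",
]

MODES = ("1aper", "3apers", "3xbeams")


@dataclass(frozen=True)
class WeightedBeam:
    """A static beam: gantry angle, 1-3 aperture snapshots, relative MU weight."""

    gantry_angle: float
    collimator_angle: float
    apertures: tuple  # of Aperture, all sharing the beam's jaws
    weight: float

    def __post_init__(self):
        object.__setattr__(self, "apertures", tuple(self.apertures))
        if self.weight < 0:
            raise ValueError("beam weight must be non-negative")
        if not self.apertures:
            raise ValueError("beam needs at least one aperture")


def cp_weight(plan: ArcPlan, i: int) -> float:
    """Relative MU weight of control point ``i`` (0-based).

    Interior CPs get half of each adjacent MU interval; the first and last CP
    (kick-off and ending beams) get zero. Plans with fewer than 3 CPs have no
    interior beams and are rejected.
    """
    n = plan.n_cp
    if n < 3:
        raise ValueError("plan has < 3 control points: no weighted interior beams exist")
    if not 0 <= i < n:
        raise IndexError(f"control point index {i} outside 0..{n - 1}")
    if i == 0 or i == n - 1:
        return 0.0
    mu = plan.mu
    return 0.5 * (mu[i] - mu[i - 1]) + 0.5 * (mu[i + 1] - mu[i])


def cp_weights(plan: ArcPlan) -> np.ndarray:
    """Vector of per-CP weights (endpoints zero)."""
    return np.array([cp_weight(plan, i) for i in range(plan.n_cp)])


def interpolate_aperture(cp_a: ControlPoint, cp_b: ControlPoint, f: float) -> Aperture:
    """Linear interpolation of two machine states: x = (1-f)*x_a + f*x_b.

    Every leaf of both banks and every jaw is interpolated (apertures are
    full machine states). Interpolating two valid apertures preserves the
    bank ordering invariant because the inequality a <= b survives convex
    combination.
    """
    if cp_a.bank_a.size != cp_b.bank_a.size:
        raise ValueError("mismatched leaf counts")
    g = 1.0 - f
    ja, jb = cp_a.jaws, cp_b.jaws
    return Aperture(
        bank_a=g * cp_a.bank_a + f * cp_b.bank_a,
        bank_b=g * cp_a.bank_b + f * cp_b.bank_b,
        jaws=Jaws(
            x1=g * ja.x1 + f * jb.x1,
            x2=g * ja.x2 + f * jb.x2,
            y1=g * ja.y1 + f * jb.y1,
            y2=g * ja.y2 + f * jb.y2,
        ),
    )


def one_aperture_beam(plan: ArcPlan, i: int) -> WeightedBeam:
    cp = plan.control_points[i]
    return WeightedBeam(
        gantry_angle=cp.gantry_angle,
        collimator_angle=cp.collimator_angle,
        apertures=(cp.aperture,),
        weight=cp_weight(plan, i),
    )


def three_aperture_beam(plan: ArcPlan, i: int) -> WeightedBeam:
    """Beam at CP ``i``'s gantry angle carrying [before, own, after] apertures.

    The flanking apertures sit two-thirds of a CP interval before and after
    the beam: leaf positions 2/3*x_i + 1/3*x_{i-1} and 2/3*x_i + 1/3*x_{i+1}.
    Downstream, the beam fluence is the unweighted mean of the three aperture
    fluences. Only interior CPs (1 <= i <= N-2) have both neighbors.
    """
    n = plan.n_cp
    if not 1 <= i <= n - 2:
        raise IndexError(f"three-aperture beams exist only for interior CPs 1..{n - 2}")
    cps = plan.control_points
    before = interpolate_aperture(cps[i], cps[i - 1], 1.0 / 3.0)
    after = interpolate_aperture(cps[i], cps[i + 1], 1.0 / 3.0)
    return WeightedBeam(
        gantry_angle=cps[i].gantry_angle,
        collimator_angle=cps[i].collimator_angle,
        apertures=(before, cps[i].aperture, after),
        weight=cp_weight(plan, i),
    )


def triple_beams(plan: ArcPlan) -> ArcPlan:
    """Insert two interpolated CPs in each interval: N CPs -> 3N - 2.

    Leaf positions, jaws, cumulative MU and (unwrapped) gantry angle are
    linearly interpolated at 1/3 and 2/3 of each interval; with the standard
    2° CP spacing this is the two-thirds-degree resolution. Endpoints are
    preserved exactly, so total MU is unchanged, and the result passes all
    ArcPlan invariants.
    """
    cps = plan.control_points
    unwrapped = unwrap_gantry([cp.gantry_angle for cp in cps])
    out = []
    for i in range(len(cps) - 1):
        a, b = cps[i], cps[i + 1]
        out.append(a)
        for f in (1.0 / 3.0, 2.0 / 3.0):
            ap = interpolate_aperture(a, b, f)
            out.append(
                ControlPoint(
                    gantry_angle=((1 - f) * unwrapped[i] + f * unwrapped[i + 1]) % 360.0,
                    collimator_angle=a.collimator_angle,
                    bank_a=ap.bank_a,
                    bank_b=ap.bank_b,
                    jaws=ap.jaws,
                    cumulative_mu=(1 - f) * a.cumulative_mu + f * b.cumulative_mu,
                )
            )
    out.append(cps[-1])
    meta = dict(plan.metadata)
    meta["derived"] = "3xbeams"
    return ArcPlan(machine=plan.machine, control_points=out, metadata=meta)


def discretize(plan: ArcPlan, mode: str) -> list:
    """Expand an arc plan into a list of :class:`WeightedBeam`.

    All three modes return one beam per (possibly inserted) control point,
    endpoints included with zero weight; ``3apers`` endpoints fall back to a
    single aperture since they have no flanking neighbor on one side (their
    weight is zero regardless).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if mode == "3xbeams":
        return discretize(triple_beams(plan), "1aper")
    beams = []
    for i in range(plan.n_cp):
        if mode == "3apers" and 1 <= i <= plan.n_cp - 2:
            beams.append(three_aperture_beam(plan, i))
        else:
            beams.append(one_aperture_beam(plan, i))
    return beams
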