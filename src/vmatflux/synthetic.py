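"""Synthetic study data: validation arc, toy commissioning data, random arcs.

Everything here is generated programmatically and deterministically (given a
seed where randomness is involved); these objects define the study
conditions for the test suite and the acceptance analyses.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np

from .dose import BeamData, Phantom, Plane
from .mlc import MLCModel, get_model
from .plans import Aperture, ArcPlan, ControlPoint, Jaws

__all__ = [
    "five_cp_arc",
    "FIVE_CP_GANTRY",
    "FIVE_CP_MU",
    "toy_beam_data",
    "film_slab_phantom",
    "film_plane",
    "random_arc",
    "random_aperture",
    "tg_misalignment_apertures",
    "MisalignmentApertures",
]

FIVE_CP_GANTRY = (357.0, 358.0, 0.0, 2.0, 3.0)
FIVE_CP_MU = (0.0, 0.1, 0.5, 0.9, 1.0)

# 5-CP validation-arc aperture choice for the moving pairs 30 and 31 (cm).
# The published description fixes the constraints, not the coordinates: a
# collimator-90° arc in which only the two central pairs move, sweeping left
# to right with total travel 4 cm for the trailing (bank A) and 8 cm for the
# leading (bank B) leaves over the middle three CPs, the middle aperture
# being a 4 cm wide centered opening; kick-off and ending CPs repeat their
# inner neighbors. The coordinates below are the symmetric realization.
_FIVE_CP_MOVING = ((-4.0, -2.0), (-4.0, -2.0), (-2.0, 2.0), (0.0, 6.0), (0.0, 6.0))
_FIVE_CP_JAWS = Jaws(x1=-4.5, x2=6.5, y1=-2.05, y2=2.05)
_FIVE_CP_STATIC_OPEN = (-3.0, 3.0)  # pairs 21..40 except the moving two
_PARKED = -10.0  # closed park position for unused pairs, outside the jaws


def five_cp_arc(machine: str | MLCModel = "hdmlc") -> ArcPlan:
    """The 5-control-point validation arc.

    Gantry 357°, 358°, 0°, 2°, 3°; cumulative MU 0, 0.1, 0.5, 0.9, 1;
    collimator 90°. Only leaf pairs 30 and 31 move; pairs 21-40 are
    statically open so the region around the isocenter (including the
    reference point 1 cm to its left) sees a constant aperture; everything
    else is parked closed outside the jaws.
    """
    model = machine if isinstance(machine, MLCModel) else get_model(machine)
    n = model.n_pairs
    moving = {29, 30}  # 0-based pairs 30 and 31
    static_open = {p for p in range(20, 40)} - moving
    cps = []
    for g, mu, (xa, xb) in zip(FIVE_CP_GANTRY, FIVE_CP_MU, _FIVE_CP_MOVING):
        bank_a = np.full(n, _PARKED)
        bank_b = np.full(n, _PARKED)
        for p in static_open:
            bank_a[p], bank_b[p] = _FIVE_CP_STATIC_OPEN
        for p in moving:
            bank_a[p], bank_b[p] = xa, xb
        cps.append(
            ControlPoint(
                gantry_angle=g,
                collimator_angle=90.0,
                bank_a=bank_a,
                bank_b=bank_b,
                jaws=_FIVE_CP_JAWS,
                cumulative_mu=mu,
            )
        )
    return ArcPlan(machine=model, control_points=cps, metadata={"plan_id": "five-cp-arc"})


def toy_beam_data(
    d_max_cm: float = 1.5,
    mu0_per_cm: float = 0.038,
    mu_size_slope: float = 0.003,
    kernel_core_sigma0_mm: float = 1.0,
    kernel_core_growth_mm_per_cm: float = 0.1,
    kernel_scatter_frac: float = 0.10,
    kernel_scatter_sigma0_mm: float = 8.0,
    kernel_scatter_growth_mm_per_cm: float = 0.4,
    kernel_halfsize_mm: int = 80,
    dose_per_mu: float = 1.0,
) -> BeamData:
    """Analytic toy commissioning data (deterministic, parameterized).

    TMR(d, s) = exp(-mu(s) * (d - d_max)), normalized to 1 at d_max, with a
    mild field-size dependence mu(s) = mu0 * (1 - slope * (s - 10)); unit
    output and off-axis factors; pencil-beam kernel = narrow core Gaussian
    plus a broad scatter Gaussian, both widening with depth, tabulated on the
    1 mm fluence grid and normalized to unit sum.
    """
    depths = np.concatenate([[0.0, 0.5, 1.0, d_max_cm], np.arange(2.0, 41.0)])
    depths = np.unique(depths)
    sizes = np.array([3.0, 5.0, 10.0, 15.0, 20.0, 30.0])
    mu = mu0_per_cm * (1.0 - mu_size_slope * (sizes - 10.0))
    tmr = np.exp(-np.outer(depths - d_max_cm, np.ones_like(sizes)) * mu)

    kernel_depths = np.array([d_max_cm, 5.0, 10.0, 20.0, 30.0, 40.0])
    ax = np.arange(-kernel_halfsize_mm, kernel_halfsize_mm + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    rr2 = xx**2 + yy**2
    kernels = []
    for d in kernel_depths:
        sc = kernel_core_sigma0_mm + kernel_core_growth_mm_per_cm * d
        ss = kernel_scatter_sigma0_mm + kernel_scatter_growth_mm_per_cm * d
        k = (1 - kernel_scatter_frac) * np.exp(-rr2 / (2 * sc**2)) / (2 * np.pi * sc**2) + (
            kernel_scatter_frac
        ) * np.exp(-rr2 / (2 * ss**2)) / (2 * np.pi * ss**2)
        kernels.append(k / k.sum())
    return BeamData(
        tmr_depths=depths,
        tmr_sizes=sizes,
        tmr=tmr,
        of_sizes=sizes,
        of_values=np.ones_like(sizes),
        oar_radii=np.array([0.0, 50.0]),
        oar_values=np.array([1.0, 1.0]),
        kernel_depths=kernel_depths,
        kernels=kernels,
        dose_per_mu=dose_per_mu,
    )


def film_slab_phantom() -> Phantom:
    """Film-between-slabs geometry: 5 cm buildup + 5 cm backscatter of water-
    equivalent plastic, film plane through the isocenter."""
    return Phantom.water(10.0, surface_z=5.0)


def film_plane() -> Plane:
    return Plane(z_cm=0.0)


def random_arc(
    seed: int,
    n_cp: int,
    motion_scale: float,
    machine: str | MLCModel = "hdmlc",
    n_active_pairs: int = 10,
    gantry_start: float = 200.0,
    gantry_step: float = -2.0,
) -> ArcPlan:
    """Reproducible random arc with controllable leaf-motion statistics.

    The active central leaf pairs keep a fixed random opening width and
    random-walk their centers with normal steps scaled so the expected
    absolute per-transition movement equals ``motion_scale`` (cm). A step
    that would leave the travel range is applied with flipped sign (so its
    magnitude is preserved); in the rare case neither direction fits it is
    clipped with a warning. ``motion_scale = 0`` gives a static plan.
    """
    if n_cp < 3:
        raise ValueError("need at least 3 control points")
    model = machine if isinstance(machine, MLCModel) else get_model(machine)
    rng = np.random.default_rng(seed)
    n = model.n_pairs
    jaws = Jaws(x1=-7.0, x2=7.0, y1=-3.05, y2=3.05)
    travel_limit = 6.0  # cm, leaf-tip range used by the generator

    first = n // 2 - n_active_pairs // 2
    active = list(range(first, first + n_active_pairs))
    widths = rng.uniform(2.0, 4.0, size=n_active_pairs)
    if np.any(widths / 2 > travel_limit):
        warnings.warn("requested opening infeasible for the travel range; clipping")
        widths = np.minimum(widths, 2 * travel_limit)
    centers = rng.uniform(-1.0, 1.0, size=n_active_pairs)

    sigma = motion_scale * np.sqrt(np.pi / 2.0)  # E|N(0, sigma)| = motion_scale
    mu_increments = rng.uniform(0.5, 1.5, size=n_cp - 1)
    mu = np.concatenate([[0.0], np.cumsum(mu_increments)])
    mu /= mu[-1]

    cps = []
    for i in range(n_cp):
        if i:
            steps = rng.normal(0.0, sigma, size=n_active_pairs) if sigma else np.zeros(n_active_pairs)
            for j, st in enumerate(steps):
                lo = -travel_limit + widths[j] / 2
                hi = travel_limit - widths[j] / 2
                c = centers[j] + st
                if not lo <= c <= hi:
                    c = centers[j] - st
                if not lo <= c <= hi:
                    warnings.warn("leaf step clipped to the travel range")
                    c = np.clip(c, lo, hi)
                centers[j] = c
        bank_a = np.full(n, _PARKED)
        bank_b = np.full(n, _PARKED)
        for j, p in enumerate(active):
            bank_a[p] = centers[j] - widths[j] / 2
            bank_b[p] = centers[j] + widths[j] / 2
        cps.append(
            ControlPoint(
                gantry_angle=(gantry_start + i * gantry_step) % 360.0,
                collimator_angle=0.0,
                bank_a=bank_a,
                bank_b=bank_b,
                jaws=jaws,
                cumulative_mu=float(mu[i]),
            )
        )
    return ArcPlan(
        machine=model,
        control_points=cps,
        metadata={"plan_id": f"random-arc-{seed}", "motion_scale_cm": motion_scale},
    )


def random_aperture(rng: np.random.Generator, model: MLCModel) -> Aperture:
    """One random machine state: mixed open/closed pairs, random jaws."""
    n = model.n_pairs
    bank_a = np.full(n, _PARKED)
    bank_b = np.full(n, _PARKED)
    for p in range(n):
        if rng.random() < 0.5:
            c = rng.uniform(-4.0, 4.0)
            w = rng.uniform(0.0, 5.0)
            bank_a[p], bank_b[p] = c - w / 2, c + w / 2
    jaws = Jaws(
        x1=rng.uniform(-8.0, -1.0),
        x2=rng.uniform(1.0, 8.0),
        y1=rng.uniform(-8.0, -1.0),
        y2=rng.uniform(1.0, 8.0),
    )
    return Aperture(bank_a, bank_b, jaws)


class MisalignmentApertures(NamedTuple):
    aligned: Aperture  # adjacent pairs share one position: no exposed strip
    offset: Aperture  # neighbor closed: a tongue strip protrudes into the field


def tg_misalignment_apertures(machine: str | MLCModel = "hdmlc") -> MisalignmentApertures:
    """Aperture pair demonstrating the grid-misalignment sampling problem.

    In the ``offset`` aperture only leaf pair 31 is open, so the
    tongue-and-groove strip on its +y boundary protrudes over the closed
    neighbor's opening. For the HDMLC that boundary sits at 2.5 mm off-axis,
    halfway between two 1 mm element centers, and center-point sampling
    misses the strip; for the Millennium the matching boundary is at 5 mm,
    on an element center, and 1 mm sampling already captures it. In the
    ``aligned`` aperture pairs 31 and 32 are both open so no strip is
    exposed. Jaw edges sit on half-integer mm so they introduce no
    volume-averaging differences of their own.
    """
    model = machine if isinstance(machine, MLCModel) else get_model(machine)
    n = model.n_pairs
    jaws = Jaws(x1=-5.0, x2=5.0, y1=-2.05, y2=2.05)

    def build(open_pairs):
        bank_a = np.full(n, _PARKED)
        bank_b = np.full(n, _PARKED)
        for p in open_pairs:
            bank_a[p], bank_b[p] = -6.0, 6.0
        return Aperture(bank_a, bank_b, jaws)

    return MisalignmentApertures(aligned=build({30, 31}), offset=build({30}))
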