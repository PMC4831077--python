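"""QA-style comparison metrics for planar doses and plans.

* ROI average dose difference (reference - test, as % of the ROI mean
  reference dose) with high-local-difference area flagging;
* gamma index (default local 3%/3 mm) with exhaustive search;
* MLC leaf-motion statistics (mean / SD / % of movements > 2 cm of the
  absolute leaf displacement between successive control points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .dose import DosePlane
from .plans import ArcPlan

__all__ = [
    "DoseDifference",
    "GammaResult",
    "MotionStats",
    "roi_mask_from_polygon",
    "dose_difference",
    "gamma",
    "leaf_motion_stats",
    "leaf_travel",
]


def _values(plane) -> np.ndarray:
    return plane.values if isinstance(plane, DosePlane) else np.asarray(plane, dtype=float)


def roi_mask_from_polygon(shape, polygon_mm, spacing: float = 1.0) -> np.ndarray:
    """Boolean mask of grid elements whose centers fall inside a polygon.

    ``polygon_mm`` is a sequence of (x, y) vertices in plane coordinates (mm,
    origin at the central-axis element center).
    """
    from matplotlib.path import Path

    ny, nx = shape
    cy, cx = ny // 2, nx // 2
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    pts = np.column_stack([(jj.ravel() - cx) * spacing, (ii.ravel() - cy) * spacing])
    return Path(np.asarray(polygon_mm, dtype=float)).contains_points(pts).reshape(shape)


def _resolve_roi(values: np.ndarray, roi) -> np.ndarray:
    if roi is None:
        return np.ones(values.shape, dtype=bool)
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if roi.shape != values.shape:
            raise ValueError("ROI mask shape does not match the dose grid")
        return roi
    return roi_mask_from_polygon(values.shape, roi)


@dataclass(frozen=True)
class DoseDifference:
    diff_map: np.ndarray  # reference - test
    mean_diff_pct: float  # mean(diff over ROI) / mean(reference over ROI) * 100
    area_gt_threshold_roi_norm: float  # fraction of ROI with |diff|/ROI-mean > threshold
    area_gt_threshold_local_norm: float  # fraction with |diff|/local reference > threshold
    threshold_pct: float
    roi_mask: np.ndarray


def dose_difference(reference, test, roi=None, threshold_pct: float = 4.0) -> DoseDifference:
    """Element-wise (reference - test) and its ROI summary.

    The average difference is normalized to the ROI mean reference dose. The
    fraction of ROI area whose local difference exceeds ``threshold_pct`` is
    reported under both normalizations (ROI-mean and local reference dose)
    since either convention is in clinical use.
    """
    r, t = _values(reference), _values(test)
    if r.shape != t.shape:
        raise ValueError("dose planes are not co-registered (shape mismatch)")
    mask = _resolve_roi(r, roi)
    if not mask.any():
        raise ValueError("empty ROI")
    diff = r - t
    roi_mean = r[mask].mean()
    if roi_mean == 0:
        raise ValueError("ROI mean reference dose is zero; percent difference undefined")
    pct_roi = np.abs(diff[mask]) / roi_mean * 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_local = np.abs(diff[mask]) / np.abs(r[mask]) * 100.0
    pct_local = np.where(r[mask] == 0, np.inf, pct_local)
    return DoseDifference(
        diff_map=diff,
        mean_diff_pct=float(diff[mask].mean() / roi_mean * 100.0),
        area_gt_threshold_roi_norm=float((pct_roi > threshold_pct).mean()),
        area_gt_threshold_local_norm=float((pct_local > threshold_pct).mean()),
        threshold_pct=threshold_pct,
        roi_mask=mask,
    )


@dataclass(frozen=True)
class GammaResult:
    gamma_map: np.ndarray  # NaN where not evaluated
    pass_rate: float  # % of evaluated elements with gamma <= 1
    criteria: dict
    roi_mask: np.ndarray
    n_evaluated: int


def gamma(
    reference,
    test,
    dose_pct: float = 3.0,
    dta_mm: float = 3.0,
    local: bool = True,
    threshold: float = 0.1,
    roi=None,
    spacing_mm: float = 1.0,
    search_radius_factor: float = 3.0,
    step_factor: float = 0.1,
) -> GammaResult:
    """Gamma index by exhaustive search over a disk of shifts.

        gamma(r) = min over r' of sqrt[ ((D_t(r') - D_r(r)) / crit)^2
                                        + (|r - r'|^2 / dta^2) ]

    ``crit`` is ``dose_pct`` % of the local reference dose (``local=True``,
    the clinically stricter convention) or of the global reference maximum.
    The search covers shifts up to ``search_radius_factor * dta`` on a grid
    of ``step_factor * dta`` (test dose bilinearly interpolated), visited in
    order of increasing shift so the scan stops as soon as the distance term
    alone exceeds every remaining candidate. Elements below ``threshold``
    (fraction of the ROI reference maximum) are excluded from the pass rate.
    """
    r, t = _values(reference), _values(test)
    if r.shape != t.shape:
        raise ValueError("dose planes are not co-registered (shape mismatch)")
    mask = _resolve_roi(r, roi)
    ref_max = r[mask].max() if mask.any() else 0.0
    if ref_max <= 0:
        raise ValueError("reference dose is zero over the ROI; gamma normalization undefined")
    evaluate = mask & (r >= threshold * ref_max)
    ii, jj = np.nonzero(evaluate)
    ref_vals = r[ii, jj]
    if local:
        crit = dose_pct / 100.0 * ref_vals
    else:
        crit = np.full_like(ref_vals, dose_pct / 100.0 * ref_max)

    # shift grid, integer subdivision of the element spacing
    sub = max(1, int(np.ceil(spacing_mm / (step_factor * dta_mm))))
    h = spacing_mm / sub
    radius = search_radius_factor * dta_mm
    m = int(np.floor(radius / h))
    dy, dx = np.meshgrid(np.arange(-m, m + 1) * h, np.arange(-m, m + 1) * h, indexing="ij")
    rr = np.sqrt(dy**2 + dx**2).ravel()
    keep = rr <= radius
    order = np.argsort(rr[keep])
    dy, dx, rr = dy.ravel()[keep][order], dx.ravel()[keep][order], rr[keep][order]

    best = np.full(ref_vals.shape, np.inf)
    for k in range(rr.size):
        dist_term = (rr[k] / dta_mm) ** 2
        if dist_term >= best.max():
            break  # no shift this far out can improve any point
        live = best > dist_term
        coords = [ii[live] + dy[k] / spacing_mm, jj[live] + dx[k] / spacing_mm]
        tv = map_coordinates(t, coords, order=1, mode="nearest")
        cand = ((tv - ref_vals[live]) / crit[live]) ** 2 + dist_term
        b = best[live]
        best[live] = np.minimum(b, cand)
    g = np.sqrt(best)
    gmap = np.full(r.shape, np.nan)
    gmap[ii, jj] = g
    return GammaResult(
        gamma_map=gmap,
        pass_rate=float((g <= 1.0).mean() * 100.0) if g.size else float("nan"),
        criteria={
            "dose_pct": dose_pct,
            "dta_mm": dta_mm,
            "local": local,
            "threshold": threshold,
        },
        roi_mask=mask,
        n_evaluated=int(g.size),
    )


@dataclass(frozen=True)
class MotionStats:
    mean_cm: float
    sd_cm: float  # population SD (divide by n)
    pct_gt_threshold: float  # % of movements strictly greater than the threshold
    threshold_cm: float
    n_movements: int
    movements: np.ndarray = field(repr=False, default=None)


def _pair_indices(plan: ArcPlan, leaf_pairs) -> np.ndarray:
    idx = np.atleast_1d(np.asarray(leaf_pairs, dtype=int))
    n = plan.machine.n_pairs
    bad = (idx < 1) | (idx > n)
    if bad.any():
        raise IndexError(f"unknown leaf pair index {idx[bad][0]} (valid 1..{n})")
    return idx - 1


def leaf_motion_stats(
    plan: ArcPlan, leaf_pairs, banks=("a", "b"), threshold_cm: float = 2.0
) -> MotionStats:
    """Leaf-movement statistics over successive control-point transitions.

    Movement is the absolute leaf-tip displacement between two successive
    CPs; movements are pooled over the selected banks of the selected
    (1-based) leaf pairs. The percentage counts movements strictly greater
    than ``threshold_cm`` over the total number of movements.
    """
    idx = _pair_indices(plan, leaf_pairs)
    if isinstance(banks, str):
        banks = (banks,)
    moves = []
    for bank in banks:
        pos = np.array(
            [getattr(cp, f"bank_{bank}")[idx] for cp in plan.control_points]
        )  # (n_cp, n_sel)
        moves.append(np.abs(np.diff(pos, axis=0)).ravel())
    m = np.concatenate(moves)
    return MotionStats(
        mean_cm=float(m.mean()),
        sd_cm=float(m.std()),  # population estimator
        pct_gt_threshold=float((m > threshold_cm).mean() * 100.0),
        threshold_cm=threshold_cm,
        n_movements=int(m.size),
        movements=m,
    )


def leaf_travel(plan: ArcPlan, pair: int, bank: str) -> float:
    """Total absolute travel (cm) of one leaf across the whole arc."""
    (j,) = _pair_indices(plan, [pair])
    pos = np.array([getattr(cp, f"bank_{bank}")[j] for cp in plan.control_points])
    return float(np.abs(np.diff(pos)).sum())
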