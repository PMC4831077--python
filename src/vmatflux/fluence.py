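"""In-air primary fluence rasterization at the isocenter plane.

An aperture (MLC leaf positions + jaws) is rasterized into a 512x512 map
with 1 mm resolution. Element centers lie on integer mm with the beam
central axis on the center of element (256, 256); columns run along leaf
travel (x), rows along leaf width (y), in the collimator frame. Rays are
parallel (fluence is defined at the isocenter level only).

Per sample point the fluence is 1 in the open field and otherwise the
transmission of the governing structure:

* outside the jaw rectangle: the (configurable) jaw transmission;
* under the full-thickness mid part of a leaf: ``t_leaf``, with the rounded
  leaf-end sigmoid applied along the travel direction near the tips;
* inside the 0.8 mm tongue-and-groove strip centered on an interleaf
  boundary: ``t_tg`` when exactly one of the two adjoining pairs covers the
  point (a single tongue or groove protruding over the neighbor's opening),
  ``t_interleaf`` when both cover it (full interlocked tongue+groove stack),
  1 when both are open.

The strip transmission is bilinear in the two pairs' covered fractions, so
the categories blend smoothly across the leaf-end penumbra.

Volume averaging (for MLCs whose leaf boundaries do not align with the 1 mm
grid, e.g. the 2.5 mm HDMLC leaves) splits each element into ``subelements``
equal sub-rows in the leaf-width direction, samples the fluence at each
sub-row center, and assigns the mean to the element.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .mlc import GeometryError, MLCModel
from .plans import Aperture, Jaws

__all__ = [
    "GRID_N",
    "GRID_SPACING_MM",
    "FluenceMap",
    "rasterize",
    "rasterize_fine",
    "rasterize_averaged",
    "jaw_fluence",
    "rotate_to_fixed_frame",
    "save_fluence",
]

GRID_N = 512
GRID_SPACING_MM = 1.0
GRID_CENTER = 256  # element whose center is the central axis

#: element-center coordinates (mm), identical for rows and columns
GRID_COORDS = np.arange(GRID_N, dtype=float) - GRID_CENTER


@dataclass(frozen=True)
class FluenceMap:
    """2-D in-air primary fluence fractions on the isocenter grid.

    ``collimator_angle`` is the angle of the (collimator) frame the map is
    expressed in relative to the fixed frame; 0 after
    :func:`rotate_to_fixed_frame`.
    """

    values: np.ndarray
    collimator_angle: float = 0.0
    spacing: float = GRID_SPACING_MM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (GRID_N, GRID_N):
            raise ValueError(f"fluence grid must be {GRID_N}x{GRID_N}, got {v.shape}")
        object.__setattr__(self, "values", v)


def _pair_open_fractions(aperture: Aperture, model: MLCModel, x_mm: np.ndarray) -> np.ndarray:
    """Covered-opening factor o_p(x) in [0, 1] for every leaf pair.

    o = 1 fully open between the tips, o = 0 under a leaf body, with the
    rounded-leaf-end sigmoid giving the transition at each tip. The product
    of the two tip sigmoids also yields the small residual transmission of an
    abutted (closed) pair — the dosimetric-gap leak.
    """
    curve = model.leaf_end
    xa = aperture.bank_a[:, None] * 10.0  # cm -> mm
    xb = aperture.bank_b[:, None] * 10.0
    return curve.sigmoid(x_mm[None, :] - xa) * curve.sigmoid(xb - x_mm[None, :])


def _mlc_rows(aperture: Aperture, model: MLCModel, y_samples: np.ndarray) -> np.ndarray:
    """Fluence of the MLC alone (no jaws) at each (y_sample, x-column)."""
    o = _pair_open_fractions(aperture, model, GRID_COORDS)  # (n_pairs, nx)
    u = 1.0 - o  # covered fraction
    g = model.t_leaf + (1.0 - model.t_leaf) * o  # mid-leaf transmission rows

    b = model.boundaries
    half = model.max_field_extent / 2.0
    hw = model.tg_width / 2.0

    y = np.asarray(y_samples, dtype=float)
    out = np.ones((y.size, GRID_COORDS.size))

    inside = (y >= -half) & (y <= half)
    # owning pair (0-based): boundaries b[p] < y <= b[p+1]
    pair = np.clip(np.searchsorted(b, y, side="left") - 1, 0, model.n_pairs - 1)
    out[inside] = g[pair[inside]]

    # tongue-and-groove strips: total width tg_width centered on each interior
    # boundary; transmission bilinear in the two adjoining covered fractions
    interior = b[1:-1]
    k = np.clip(np.searchsorted(interior, y), 0, interior.size - 1)
    near = np.where(np.abs(y - interior[k]) <= hw, k, np.where(
        (k > 0) & (np.abs(y - interior[k - 1]) <= hw), k - 1, -1))
    strip = inside & (near >= 0)
    if np.any(strip):
        kk = near[strip]
        uj, uq = u[kk], u[kk + 1]  # pairs kk+1 and kk+2 (1-based)
        c_tg = 1.0 - model.t_tg
        c_il = 1.0 - model.t_interleaf
        out[strip] = 1.0 - (uj + uq) * c_tg + uj * uq * (2.0 * c_tg - c_il)
    return out


def _jaw_mask(jaws: Jaws, y_samples: np.ndarray) -> np.ndarray:
    """Boolean (ny, nx): sample strictly inside the jaw rectangle."""
    x_in = (GRID_COORDS > jaws.x1 * 10.0) & (GRID_COORDS < jaws.x2 * 10.0)
    y = np.asarray(y_samples, dtype=float)
    y_in = (y > jaws.y1 * 10.0) & (y < jaws.y2 * 10.0)
    return y_in[:, None] & x_in[None, :]


def _check_jaws_on_grid(jaws: Jaws) -> None:
    lim = (GRID_N / 2.0) * GRID_SPACING_MM
    if min(jaws.x1, jaws.y1) * 10.0 < -lim or max(jaws.x2, jaws.y2) * 10.0 > lim:
        raise GeometryError(f"jaw field {jaws} extends beyond the ±{lim / 10} cm fluence grid")


def _sub_offsets(subelements: int) -> np.ndarray:
    """Sub-row center offsets (mm) inside one 1 mm element."""
    if subelements < 1:
        raise ValueError("subelements must be >= 1")
    return (np.arange(subelements) + 0.5) / subelements - 0.5


def rasterize(
    aperture: Aperture,
    model: MLCModel,
    volume_averaging: bool = False,
    subelements: int = 2,
    jaw_transmission: float = 0.0,
) -> FluenceMap:
    """Rasterize one aperture into the 512x512, 1 mm fluence map.

    With ``volume_averaging`` each element row is the mean of ``subelements``
    sub-row center samples (0.5 mm sub-rows by default); otherwise a single
    sample at the element center is used.
    """
    _check_jaws_on_grid(aperture.jaws)
    offsets = _sub_offsets(subelements) if volume_averaging else np.array([0.0])
    acc = np.zeros((GRID_N, GRID_N))
    for dy in offsets:
        ys = GRID_COORDS + dy
        vals = _mlc_rows(aperture, model, ys)
        vals = np.where(_jaw_mask(aperture.jaws, ys), vals, jaw_transmission)
        acc += vals
    acc /= offsets.size
    return FluenceMap(acc, meta={"volume_averaging": bool(volume_averaging)})


def rasterize_fine(
    aperture: Aperture,
    model: MLCModel,
    oversample: int = 2,
    jaw_transmission: float = 0.0,
) -> np.ndarray:
    """Reference rasterization on a finer row grid (rows at 1/oversample mm).

    Returns a ``(512 * oversample, 512)`` array whose row centers tile each
    1 mm element; box-averaging consecutive ``oversample`` rows reproduces the
    volume-averaged map exactly (the sample points coincide).
    """
    _check_jaws_on_grid(aperture.jaws)
    k = np.arange(GRID_N * oversample)
    ys = -GRID_CENTER - 0.5 + (k + 0.5) / oversample
    vals = _mlc_rows(aperture, model, ys)
    return np.where(_jaw_mask(aperture.jaws, ys), vals, jaw_transmission)


def box_downsample_rows(fine: np.ndarray, oversample: int) -> np.ndarray:
    """Average consecutive ``oversample`` rows of a fine rasterization."""
    return fine.reshape(-1, oversample, fine.shape[1]).mean(axis=1)


def rasterize_averaged(
    apertures,
    model: MLCModel,
    volume_averaging: bool = False,
    subelements: int = 2,
    jaw_transmission: float = 0.0,
) -> FluenceMap:
    """Per-element arithmetic mean of the individual aperture rasterizations.

    This is the three-aperture averaged fluence when given a
    :class:`~vmatflux.arcs.WeightedBeam`'s aperture list.
    """
    apertures = list(apertures)
    if not apertures:
        raise ValueError("need at least one aperture")
    acc = np.zeros((GRID_N, GRID_N))
    for ap in apertures:
        acc += rasterize(ap, model, volume_averaging, subelements, jaw_transmission).values
    return FluenceMap(acc / len(apertures), meta={"n_apertures": len(apertures)})


def jaw_fluence(jaws: Jaws, jaw_transmission: float = 0.0) -> FluenceMap:
    """The jaw-defined step-function fluence U (no MLC)."""
    _check_jaws_on_grid(jaws)
    vals = np.where(_jaw_mask(jaws, GRID_COORDS), 1.0, jaw_transmission)
    return FluenceMap(vals)


# -- collimator rotation ----------------------------------------------------


def _rotate_values(v: np.ndarray, angle: float, cval: float) -> np.ndarray:
    """Rotate a grid by ``angle`` degrees about the element (256, 256) center.

    Integer multiples of 90° are exact index permutations (rows/columns that
    rotate off the grid are filled with ``cval``); other angles use bilinear
    resampling.
    """
    a = angle % 360.0
    if a == 0.0:
        return v.copy()
    if a in (90.0, 180.0, 270.0):
        out = np.full_like(v, cval)
        if a == 90.0:
            out[:, 1:] = v[GRID_N - 1:0:-1, :].T
        elif a == 180.0:
            out[1:, 1:] = v[GRID_N - 1:0:-1, GRID_N - 1:0:-1]
        else:
            out[1:, :] = v[:, GRID_N - 1:0:-1].T
        return out
    t = np.deg2rad(a)
    c, s = np.cos(t), np.sin(t)
    X, Y = np.meshgrid(GRID_COORDS, GRID_COORDS)  # X: cols, Y: rows
    x = c * X + s * Y  # source coords in the unrotated frame
    y = -s * X + c * Y
    return map_coordinates(
        v, [y + GRID_CENTER, x + GRID_CENTER], order=1, mode="constant", cval=cval
    )


def rotate_to_fixed_frame(fl: FluenceMap, collimator_angle=None, cval: float = 0.0) -> FluenceMap:
    """Express a collimator-frame fluence map in the fixed (room) frame.

    A feature at collimator-frame position p appears at R(theta) p in the
    fixed frame, theta being the collimator angle (counterclockwise in the
    beam's-eye view).
    """
    theta = fl.collimator_angle if collimator_angle is None else collimator_angle
    return FluenceMap(
        _rotate_values(fl.values, theta, cval),
        collimator_angle=0.0,
        meta={**fl.meta, "rotated_by": theta},
    )


# -- export -----------------------------------------------------------------


def save_fluence(fl: FluenceMap, path, fmt: str = "npy") -> None:
    """Write the 2-D array (NPY or CSV) plus a JSON sidecar with the grid spec."""
    path = str(path)
    if fmt == "npy":
        np.save(path if path.endswith(".npy") else path + ".npy", fl.values)
        base = path[:-4] if path.endswith(".npy") else path
    elif fmt == "csv":
        np.savetxt(path if path.endswith(".csv") else path + ".csv", fl.values, delimiter=",")
        base = path[:-4] if path.endswith(".csv") else path
    else:
        raise ValueError("fmt must be 'npy' or 'csv'")
    sidecar = {
        "spacing_mm": fl.spacing,
        "origin": "element (256, 256) center on the central axis",
        "collimator_angle_deg": fl.collimator_angle,
        "axes": "rows: leaf width (y); columns: leaf travel (x)",
        **fl.meta,
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
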