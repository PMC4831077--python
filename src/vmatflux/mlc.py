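"""Multileaf-collimator machine models.

Leaf-bank geometry (per-pair leaf widths, tongue-and-groove strips, interleaf
boundaries) and transmission factors, all projected to the isocenter plane.
Two Varian geometries are built in: the Millennium 120 (5 mm central leaves)
and the HDMLC (2.5 mm central leaves).

Conventions
-----------
* ``y`` is the leaf-width direction (perpendicular to leaf travel), in mm at
  isocenter, zero on the beam central axis.
* Leaf pairs are numbered 1..60 from -y to +y; for both built-in models the
  central axis lies on the boundary between pairs 30 and 31.
* Each interior boundary between two leaf pairs carries a tongue-and-groove
  strip of total width ``tg_width`` centered on the boundary: the tongue of
  the -y leaf (tongue on the +y side of every leaf) interlocks with the
  groove of the +y leaf over that same strip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "LeafEndCurve",
    "MLCModel",
    "Zone",
    "build_millennium",
    "build_hdmlc",
    "get_model",
    "zone_profile",
    "save_model",
    "load_model",
    "GeometryError",
]

#: default transmission fractions (typical published Varian values; the
#: vendor does not publish a single number and every clinic commissions its
#: own — all are overridable).
DEFAULT_T_LEAF = 0.015
DEFAULT_T_INTERLEAF = 0.020
DEFAULT_T_TG = 0.08
DEFAULT_TG_WIDTH_MM = 0.8


class GeometryError(ValueError):
    """A query fell outside the modeled MLC geometry."""


@dataclass(frozen=True)
class LeafEndCurve:
    """Rounded-leaf-end transmission vs signed distance from the nominal tip.

    The curve is a logistic sigmoid in the signed tip distance ``s`` (mm,
    positive toward the open field), scaled to run from ``t_leaf`` deep under
    the leaf to 1 in the open field:

        T(s) = t_leaf + (1 - t_leaf) * sigmoid(s / tau),   tau = width / 4

    ``width`` is the effective dosimetric-gap half-width (mm): the distance
    over which most of the penumbral transmission change happens.
    """

    width: float = 1.0  # mm

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("leaf-end width must be positive")

    def sigmoid(self, s):
        """Open-fraction factor in [0, 1] for signed tip distance ``s`` mm."""
        from scipy.special import expit

        return expit(np.asarray(s, dtype=float) * (4.0 / self.width))


@dataclass(frozen=True)
class MLCModel:
    """Leaf-bank geometry and transmission factors at the isocenter plane."""

    name: str
    leaf_widths: tuple  # per-pair widths, mm, ordered -y to +y
    tg_width: float = DEFAULT_TG_WIDTH_MM
    t_leaf: float = DEFAULT_T_LEAF
    t_interleaf: float = DEFAULT_T_INTERLEAF
    t_tg: float = DEFAULT_T_TG
    leaf_end: LeafEndCurve = field(default_factory=LeafEndCurve)

    def __post_init__(self):
        w = np.asarray(self.leaf_widths, dtype=float)
        if w.ndim != 1 or w.size == 0 or np.any(w <= 0):
            raise ValueError("leaf_widths must be a non-empty list of positive widths")
        if not np.allclose(w, w[::-1]):
            raise ValueError("leaf widths must be symmetric about the central axis")
        if not (0 < self.tg_width < w.min()):
            raise ValueError("tg_width must be positive and smaller than the narrowest leaf")
        if not (0 < self.t_leaf <= self.t_interleaf):
            raise ValueError("require 0 < t_leaf <= t_interleaf")
        if not (self.t_leaf < self.t_tg < 1):
            raise ValueError("require t_leaf < t_tg < 1")
        object.__setattr__(self, "leaf_widths", tuple(float(x) for x in w))

    # -- derived geometry ---------------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_widths)

    @property
    def max_field_extent(self) -> float:
        """Total stacked leaf-bank width (mm)."""
        return float(sum(self.leaf_widths))

    @property
    def boundaries(self) -> np.ndarray:
        """The ``n_pairs + 1`` projected leaf-edge positions (mm), -y to +y."""
        w = np.asarray(self.leaf_widths)
        b = np.concatenate([[0.0], np.cumsum(w)]) - self.max_field_extent / 2.0
        return b

    def pair_interval(self, pair: int) -> tuple:
        """(low, high) y-interval of 1-based leaf pair ``pair`` (mm)."""
        if not 1 <= pair <= self.n_pairs:
            raise GeometryError(f"leaf pair {pair} outside 1..{self.n_pairs}")
        b = self.boundaries
        return float(b[pair - 1]), float(b[pair])


@dataclass(frozen=True)
class Zone:
    """Which leaf pair owns an off-axis position and which sub-zone it is in.

    ``subzone`` is one of ``"mid-leaf"``, ``"tongue-strip"`` (strip just below
    an interior boundary, owned by the -y leaf whose tongue it is),
    ``"groove-strip"`` (just above, owned by the +y leaf), or
    ``"interleaf-boundary"`` (exactly on an interior boundary).
    """

    pair: int  # 1-based
    subzone: str


def build_millennium(**overrides) -> MLCModel:
    """Varian Millennium 120: 40 central 5 mm pairs (±10 cm) + 10 outer 10 mm
    pairs per side, 0.8 mm tongue/groove."""
    widths = (10.0,) * 10 + (5.0,) * 40 + (10.0,) * 10
    return MLCModel(name="millennium", leaf_widths=widths, **overrides)


def build_hdmlc(**overrides) -> MLCModel:
    """Varian HDMLC: 32 central 2.5 mm pairs (±4 cm) + 14 outer 5 mm pairs
    per side, 0.8 mm tongue/groove."""
    widths = (5.0,) * 14 + (2.5,) * 32 + (5.0,) * 14
    return MLCModel(name="hdmlc", leaf_widths=widths, **overrides)


_BUILTINS = {"millennium": build_millennium, "hdmlc": build_hdmlc}


def get_model(name: str, **overrides) -> MLCModel:
    try:
        return _BUILTINS[name.lower()](**overrides)
    except KeyError:
        raise KeyError(f"unknown MLC model {name!r}; built-ins: {sorted(_BUILTINS)}") from None


def zone_profile(model: MLCModel, y: float) -> Zone:
    """Classify off-axis position ``y`` (mm) into leaf pair and sub-zone.

    Raises :class:`GeometryError` for ``|y| > max_field_extent / 2``.
    """
    half = model.max_field_extent / 2.0
    if not -half <= y <= half:
        raise GeometryError(f"y = {y} mm outside leaf bank (±{half} mm)")
    b = model.boundaries
    # interior boundaries only: the outermost edges carry no neighbor strip
    interior = b[1:-1]
    d = y - interior
    hw = model.tg_width / 2.0
    hits = np.flatnonzero(np.abs(d) <= hw)
    if hits.size:
        k = int(hits[0])  # boundary between pairs k+1 and k+2
        if d[k] == 0.0:
            return Zone(pair=k + 1, subzone="interleaf-boundary")
        if d[k] < 0:  # below the boundary: top (tongue) strip of pair k+1
            return Zone(pair=k + 1, subzone="tongue-strip")
        return Zone(pair=k + 2, subzone="groove-strip")
    # searchsorted: boundaries b[p-1] < y <= b[p] -> pair p
    pair = int(np.searchsorted(b, y, side="left"))
    pair = min(max(pair, 1), model.n_pairs)
    return Zone(pair=pair, subzone="mid-leaf")


# -- JSON (de)serialization -------------------------------------------------


def save_model(model: MLCModel, path) -> None:
    doc = {
        "name": model.name,
        "leaf_widths": list(model.leaf_widths),
        "tg_width": model.tg_width,
        "transmissions": {
            "t_leaf": model.t_leaf,
            "t_interleaf": model.t_interleaf,
            "t_tg": model.t_tg,
        },
        "leaf_end": asdict(model.leaf_end),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_model(path) -> MLCModel:
    with open(path) as fh:
        doc = json.load(fh)
    tr = doc.get("transmissions", {})
    return MLCModel(
        name=doc["name"],
        leaf_widths=tuple(doc["leaf_widths"]),
        tg_width=doc.get("tg_width", DEFAULT_TG_WIDTH_MM),
        t_leaf=tr.get("t_leaf", DEFAULT_T_LEAF),
        t_interleaf=tr.get("t_interleaf", DEFAULT_T_INTERLEAF),
        t_tg=tr.get("t_tg", DEFAULT_T_TG),
        leaf_end=LeafEndCurve(**doc.get("leaf_end", {})),
    )
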