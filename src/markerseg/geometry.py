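"""Deterministic planar-geometry primitives for boundary refinement.

All coordinates are continuous 2D positions in micrometres; no pixel grid
or origin convention is assumed. Polygons are represented as
:class:`shapely.Polygon` objects whose exterior ring is oriented
counterclockwise and carries no interior rings (holes are filled by
:func:`fill_holes` before any downstream use).

Conventions fixed here and relied upon elsewhere:

* point-in-polygon is boundary-inclusive (``covers`` semantics);
* disk dilation uses 16 arc segments per quadrant;
* degenerate (collinear) point sets are buffered by a small epsilon before
  hulling so a flagged cell always yields a positive-area boundary;
* a union of disjoint parts is bridged with the convex hull of the parts,
  because a cell must end up with a single boundary polygon.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely import STRtree
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from shapely.validation import make_valid

from .errors import DegenerateGeometryError

#: arc segments per quarter circle used by :func:`dilate` and epsilon buffers
QUAD_SEGS = 16

#: width used to fuse polygon parts that touch at a single point (μm)
_FUSE_EPS = 1e-6

#: default buffer applied to degenerate point sets before hulling (μm)
DEFAULT_EPSILON_UM = 0.2


class GeometryWarning(UserWarning):
    """Non-fatal geometric fallback (largest part kept, disjoint bridge, ...)."""


def _as_polygonal(p: BaseGeometry | Sequence) -> BaseGeometry:
    if isinstance(p, BaseGeometry):
        return p
    return Polygon(p)


def _polygon_parts(geom: BaseGeometry) -> list[Polygon]:
    """Extract all positive-area polygon parts of an arbitrary geometry."""
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom] if geom.area > 0 else []
    if hasattr(geom, "geoms"):
        out: list[Polygon] = []
        for g in geom.geoms:
            out.extend(_polygon_parts(g))
        return out
    return []


def fill_holes(p: BaseGeometry | Sequence) -> Polygon:
    """Repair a polygon and remove interior rings.

    Self-intersecting rings are repaired with ``make_valid``. If the repair
    produces several parts that touch (e.g. the two lobes of a bowtie) they
    are fused through the contact point, preserving total area to numerical
    precision; genuinely disjoint parts trigger a :class:`GeometryWarning`
    and only the largest-area part is kept. The exterior extent of the
    input is never reduced.

    Raises
    ------
    DegenerateGeometryError
        If nothing with positive area survives repair.
    """
    geom = _as_polygonal(p)
    if isinstance(geom, Polygon) and geom.is_valid:
        if not geom.interiors:
            if geom.area <= 0:
                raise DegenerateGeometryError("polygon has zero area")
            return geom  # untouched: retention downstream must be bit-identical
        return orient(Polygon(geom.exterior))

    parts = [Polygon(q.exterior) for q in _polygon_parts(make_valid(geom))]
    if not parts:
        raise DegenerateGeometryError("geometry has zero area after repair")
    if len(parts) == 1:
        return orient(parts[0])

    merged = unary_union(parts)
    if isinstance(merged, Polygon):
        return orient(Polygon(merged.exterior))

    # several parts: fuse through point contacts, otherwise keep the largest
    touching = any(
        parts[i].distance(parts[j]) == 0.0
        for i in range(len(parts))
        for j in range(i + 1, len(parts))
    )
    if touching:
        fused = merged.buffer(_FUSE_EPS).buffer(-_FUSE_EPS)
        if not isinstance(fused, Polygon):
            fused = merged.buffer(_FUSE_EPS)
        if isinstance(fused, Polygon) and fused.area > 0:
            return orient(Polygon(fused.exterior))
    warnings.warn(
        "repair produced disjoint parts; keeping the largest-area part",
        GeometryWarning,
        stacklevel=2,
    )
    return orient(max(parts, key=lambda q: q.area))


def convex_hull(
    pts: Iterable[tuple[float, float]] | np.ndarray,
    epsilon_um: float = DEFAULT_EPSILON_UM,
) -> Polygon:
    """Smallest convex polygon containing all points.

    Collinear or coincident point sets have a degenerate (zero-area) hull;
    such sets are buffered by ``epsilon_um`` before hulling so the output
    always has positive area and still contains every input point.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 points are supplied.
    """
    arr = np.asarray(list(pts) if not isinstance(pts, np.ndarray) else pts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise DegenerateGeometryError(
            f"convex hull requires >= 3 points, got {0 if arr.ndim != 2 else arr.shape[0]}"
        )
    if not np.isfinite(arr).all():
        raise DegenerateGeometryError("non-finite point coordinates")
    mp = MultiPoint(arr)
    hull = mp.convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        hull = mp.buffer(epsilon_um, quad_segs=QUAD_SEGS).convex_hull
    return orient(hull)


def polygon_union(a: Polygon, b: Polygon, bridge_disjoint: bool = True) -> Polygon | BaseGeometry:
    """Union of two polygons as a single boundary.

    Overlapping or touching inputs yield the exact set union (any hole the
    union encloses is filled, since cell boundaries carry no interior
    rings). Disjoint inputs are bridged with the convex hull of both parts
    and a :class:`GeometryWarning` is recorded — a cell has one boundary.
    With ``bridge_disjoint=False`` (internal mode, used by invariance
    checks) the raw multi-part union is returned instead.
    """
    u = unary_union([_as_polygonal(a), _as_polygonal(b)])
    if isinstance(u, Polygon):
        return orient(Polygon(u.exterior))
    if not bridge_disjoint:
        return u
    warnings.warn(
        "union of disjoint polygons bridged with their convex hull",
        GeometryWarning,
        stacklevel=2,
    )
    return orient(u.convex_hull)


def point_in_polygon(pt: tuple[float, float] | Point, p: Polygon) -> bool:
    """Boundary-inclusive containment test (true for points on the edge)."""
    point = pt if isinstance(pt, Point) else Point(pt)
    return bool(shapely.covers(p, point))


def points_in_polygons(
    polygons: Sequence[Polygon],
    x: np.ndarray,
    y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bulk boundary-inclusive containment via an STR tree.

    Returns parallel index arrays ``(point_idx, polygon_idx)`` listing every
    (point, polygon) incidence. A point may appear zero or several times.
    """
    pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    tree = STRtree(list(polygons))
    pi, gi = tree.query(pts, predicate="covered_by")
    return pi, gi


def dilate(p: Polygon, r: float) -> Polygon:
    """Minkowski dilation by a disk of radius ``r`` μm.

    The disk is discretized with :data:`QUAD_SEGS` segments per quadrant.
    ``r = 0`` returns the input unchanged.
    """
    if r < 0:
        raise DegenerateGeometryError(f"dilation radius must be >= 0, got {r}")
    if r == 0:
        return p
    out = _as_polygonal(p).buffer(r, quad_segs=QUAD_SEGS)
    return orient(Polygon(out.exterior))


def area(p: Polygon | Sequence) -> float:
    """Shoelace area of the exterior ring, in μm² (always >= 0)."""
    return float(_as_polygonal(p).area)
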