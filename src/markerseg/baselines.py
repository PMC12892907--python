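"""Reference segmentations: nuclear expansion and default pass-through.

Nuclear-expansion segmentation dilates every (hole-filled) nucleus by a
uniform radius — 2 μm and 5 μm are the conventional settings. Expanded
boundaries are left overlapping at the polygon level; contested transcripts
are resolved at assignment time by the nearest-nucleus rule, a
generalized-Voronoi approximation of how expansion segmenters partition
space. Cells lacking a nucleus cannot be expanded and are dropped with a
warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely

from . import geometry
from .errors import DegenerateGeometryError
from .io_spatial import UNASSIGNED, CellRecord, Segmentation


def nuclear_expansion(seg: Segmentation, radius: float) -> Segmentation:
    """Segmentation whose boundaries are nuclei dilated by ``radius`` μm."""
    if radius < 0:
        raise DegenerateGeometryError(f"expansion radius must be >= 0, got {radius}")
    cells = []
    dropped = []
    for cell in seg:
        if cell.nucleus is None:
            dropped.append(cell.cell_id)
            continue
        nucleus = geometry.fill_holes(cell.nucleus)
        cells.append(
            CellRecord(
                cell.cell_id,
                geometry.dilate(nucleus, radius),
                nucleus,
                "nuclear_expansion",
            )
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} cell(s) without a nucleus dropped from the expansion baseline",
            stacklevel=2,
        )
    return Segmentation(cells)


def assign_by_expansion(expanded: Segmentation, transcripts: pd.DataFrame) -> pd.DataFrame:
    """Assign transcripts to expanded cells by containment + nearest nucleus.

    A transcript inside one expanded boundary goes to that cell; inside
    several, to the cell whose nucleus is nearest (distance to the nucleus
    polygon, so points inside a nucleus trivially win; ties fall back to
    the nucleus edge distance, then to the lexicographically smallest cell
    id). Outside all boundaries the transcript is unassigned.
    """
    cells = list(expanded)
    out = transcripts.copy()
    if not cells or out.empty:
        out["cell_id"] = UNASSIGNED
        return out
    polys = [c.boundary for c in cells]
    ids = np.array([c.cell_id for c in cells])
    nuclei = np.array([c.nucleus for c in cells], dtype=object)
    rings = np.array([c.nucleus.exterior for c in cells], dtype=object)

    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    pi, gi = geometry.points_in_polygons(polys, x, y)
    assigned = np.full(len(out), UNASSIGNED, dtype=object)
    if len(pi):
        pts = shapely.points(x[pi], y[pi])
        cand = pd.DataFrame(
            {
                "pt": pi,
                "d_nuc": shapely.distance(pts, nuclei[gi]),
                "d_edge": shapely.distance(pts, rings[gi]),
                "cell_id": ids[gi],
            }
        ).sort_values(["pt", "d_nuc", "d_edge", "cell_id"], kind="mergesort")
        best = cand.drop_duplicates("pt", keep="first")
        assigned[best["pt"].to_numpy()] = best["cell_id"].to_numpy()
    out["cell_id"] = assigned
    return out
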