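"""Synthetic sebaceous gland with ground truth and a corrupted default
segmentation.

The generator emulates the tissue the refinement method targets: an
elliptical gland whose periphery is a thin monolayer of small, KRT5-high
basal progenitors and whose interior is tiled by large KRT79/AWAT2-high
sebocytes. Geometry:

* the basal band (default 4 μm deep) is partitioned by arc length into
  thin quadrilateral cells (~5 μm along the perimeter);
* the interior is Voronoi-tessellated around Poisson-disk-sampled seeds,
  giving convex sebocyte-like cells of ~20 μm diameter;
* nuclei are the true cells shrunk about their centroid.

Per cell, each gene's transcript count is Poisson with a type-specific
rate; molecules are placed uniformly inside the true cell and jittered by
isotropic Gaussian noise (optical/decoding error), so with nonzero jitter
perfect recovery is impossible by construction. Quality values follow a
two-mode mixture (high mode mean 35, low mode mean 12, 5 % low by default)
so the standard QV >= 20 cutoff removes a realistic minority.

The *observed* ("default") segmentation reproduces the stain-driven failure
mode: every basal boundary is extended a further ``overextension_um``
(default 4 μm) into sebocyte territory, sebocyte polygons are clipped
accordingly, and transcripts are assigned by containment against these
corrupted boundaries. Ground truth (true cells, types, per-transcript
source cell) is returned alongside for benchmarking.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import voronoi_diagram

from .errors import ValidationError
from .io_spatial import CellRecord, Segmentation
from .resegmentation import reassign_transcripts

#: lipogenic genes driving the sebogenesis score
LIPOGENIC_GENES = ("FASN", "AWAT1", "AWAT2", "ACACA", "SREBF1")

#: per-cell Poisson rates for the default ("healthy") scenario
DEFAULT_RATES: dict[str, dict[str, float]] = {
    "basal": {
        "KRT5": 25.0,
        "KRT14": 15.0,
        "KRT79": 0.2,
        "AWAT2": 0.2,
        "FASN": 1.0,
        "AWAT1": 0.5,
        "ACACA": 1.0,
        "SREBF1": 1.0,
        "FABP5": 2.0,
        "CRABP2": 4.0,
        "MKI67": 2.0,
        "GATA6": 0.2,
    },
    "sebocyte": {
        "KRT5": 0.5,
        "KRT14": 1.0,
        "KRT79": 120.0,
        "AWAT2": 100.0,
        "FASN": 40.0,
        "AWAT1": 25.0,
        "ACACA": 25.0,
        "SREBF1": 18.0,
        "FABP5": 4.0,
        "CRABP2": 4.0,
        "MKI67": 0.3,
        "GATA6": 8.0,
    },
}


@dataclass
class GlandParams:
    """Generator parameters; the defaults are the study conditions.

    ``semi_axes`` are the gland ellipse semi-axes in μm; the defaults give
    roughly 220 cells (about 130 basal, 90 sebocytes) and ~35k transcripts.
    ``overextension_um`` is the depth by which the corrupted default
    segmentation pushes basal boundaries into sebocyte territory.
    """

    semi_axes: tuple[float, float] = (120.0, 90.0)
    basal_band_um: float = 4.0
    basal_cell_arc_um: float = 5.0
    sebocyte_diameter_um: float = 20.0
    rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_RATES)
    )
    jitter_sd_um: float = 0.5
    low_qv_fraction: float = 0.05
    overextension_um: float = 4.0
    nucleus_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.basal_band_um <= 0 or self.basal_cell_arc_um <= 0:
            raise ValidationError("basal band width and arc length must be > 0")
        if self.overextension_um < 0:
            raise ValidationError("overextension depth must be >= 0")
        if self.jitter_sd_um < 0 or not (0 <= self.low_qv_fraction <= 1):
            raise ValidationError("invalid noise parameters")
        if not (0 < self.nucleus_scale < 1):
            raise ValidationError("nucleus_scale must be in (0, 1)")
        for cell_type, table in self.rates.items():
            for gene, rate in table.items():
                if rate < 0:
                    raise ValidationError(f"negative rate for {cell_type}/{gene}")


@dataclass
class GlandTruth:
    """Ground truth: true segmentation, per-cell types, per-transcript cell."""

    segmentation: Segmentation
    cell_types: dict[str, str]
    true_cell: pd.Series  # indexed by transcript_id


def _ellipse_arc_angles(a: float, b: float, n: int) -> np.ndarray:
    """Angles of ``n`` equal-arc-length points on the ellipse (a, b)."""
    dense = np.linspace(0.0, 2 * np.pi, 8192, endpoint=False)
    dx = np.diff(np.r_[a * np.cos(dense), a])
    dy = np.diff(np.r_[b * np.sin(dense), b * 0.0])
    seg = np.hypot(dx, dy)
    cum = np.r_[0.0, np.cumsum(seg)]
    targets = np.linspace(0.0, cum[-1], n, endpoint=False)
    return np.interp(targets, cum, np.r_[dense, 2 * np.pi])


def _ellipse_points(a: float, b: float, angles: np.ndarray) -> np.ndarray:
    return np.column_stack([a * np.cos(angles), b * np.sin(angles)])


def _poisson_disk(
    rng: np.random.Generator,
    a: float,
    b: float,
    min_dist: float,
    max_attempts: int = 6000,
) -> np.ndarray:
    """Dart-throwing Poisson-disk sample inside the ellipse (a, b)."""
    accepted: list[np.ndarray] = []
    for _ in range(max_attempts):
        p = rng.uniform([-a, -b], [a, b])
        if (p[0] / a) ** 2 + (p[1] / b) ** 2 > 1.0:
            continue
        if accepted and np.min(np.hypot(*(np.array(accepted) - p).T)) < min_dist:
            continue
        accepted.append(p)
    return np.array(accepted)


def _uniform_in_polygon(rng: np.random.Generator, poly: Polygon, n: int) -> np.ndarray:
    """Rejection-sample ``n`` points strictly inside ``poly``."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out: list[np.ndarray] = []
    need = n
    while need > 0:
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(max(4 * need, 16), 2))
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        hits = cand[inside]
        out.append(hits[:need])
        need -= min(need, len(hits))
    return np.vstack(out)


def _shrink(poly: Polygon, factor: float) -> Polygon:
    c = poly.centroid
    return affinity.scale(poly, xfact=factor, yfact=factor, origin=(c.x, c.y))


def simulate_gland(
    params: GlandParams | None = None,
) -> tuple[pd.DataFrame, Segmentation, GlandTruth]:
    """Generate (transcripts, observed default segmentation, ground truth).

    Deterministic for a fixed seed (single PRNG stream). The transcript
    table's ``cell_id`` column holds the *observed* assignment — containment
    against the corrupted default boundaries with the standard priority
    rule; the true source cell of every transcript lives in the returned
    :class:`GlandTruth`.
    """
    params = params or GlandParams()
    rng = np.random.default_rng(params.seed)
    a, b = params.semi_axes
    w = params.basal_band_um
    delta = params.overextension_um
    if min(a, b) <= w + delta + params.sebocyte_diameter_um:
        raise ValidationError("gland too small for the requested band and cells")

    # --- ring discretization shared by band cells and interior -------------
    perimeter_n = int(round(2 * np.pi * np.sqrt((a**2 + b**2) / 2) / params.basal_cell_arc_um))
    if perimeter_n < 3:
        raise ValidationError("parameters yield fewer than 3 basal cells")
    subdiv = 3
    angles = _ellipse_arc_angles(a, b, perimeter_n * subdiv)
    outer = _ellipse_points(a, b, angles)
    inner = _ellipse_points(a - w, b - w, angles)
    inner_deep = (
        inner if delta == 0 else _ellipse_points(a - w - delta, b - w - delta, angles)
    )

    def band_quad(ring_out: np.ndarray, ring_in: np.ndarray, i: int) -> Polygon:
        idx = [(i * subdiv + k) % len(angles) for k in range(subdiv + 1)]
        return Polygon(np.vstack([ring_out[idx], ring_in[idx[::-1]]]))

    basal_true = [band_quad(outer, inner, i) for i in range(perimeter_n)]
    basal_obs = (
        basal_true if delta == 0 else [band_quad(outer, inner_deep, i) for i in range(perimeter_n)]
    )
    interior = Polygon(inner)
    interior_deep = interior if delta == 0 else Polygon(inner_deep)

    # --- sebocytes: Voronoi of Poisson-disk seeds ---------------------------
    seeds = _poisson_disk(
        rng, a - w - 2.0, b - w - 2.0, 0.8 * params.sebocyte_diameter_um
    )
    if len(seeds) < 1 or perimeter_n + len(seeds) < 3:
        raise ValidationError("parameters yield fewer than 3 cells")
    vor = voronoi_diagram(
        MultiPoint(seeds), envelope=box(-2 * a, -2 * b, 2 * a, 2 * b)
    )
    vor_cells = list(vor.geoms)
    tree = shapely.STRtree(vor_cells)
    seb_true: list[Polygon] = []
    seb_obs: list[Polygon] = []
    for sx, sy in seeds:
        hits = tree.query(shapely.points(sx, sy), predicate="within")
        cell = vor_cells[int(hits[0])]
        true_poly = cell.intersection(interior)
        if not isinstance(true_poly, Polygon):
            true_poly = max(
                (g for g in true_poly.geoms if isinstance(g, Polygon)),
                key=lambda g: g.area,
            )
        obs_poly = true_poly if delta == 0 else true_poly.intersection(interior_deep)
        if not isinstance(obs_poly, Polygon):
            parts = [g for g in getattr(obs_poly, "geoms", []) if isinstance(g, Polygon)]
            obs_poly = max(parts, key=lambda g: g.area) if parts else Polygon()
        seb_true.append(true_poly)
        seb_obs.append(obs_poly)

    # --- assemble segmentations --------------------------------------------
    ids = [f"basal_{i:04d}" for i in range(perimeter_n)] + [
        f"seb_{i:04d}" for i in range(len(seeds))
    ]
    types = ["basal"] * perimeter_n + ["sebocyte"] * len(seeds)
    true_polys = basal_true + seb_true
    obs_polys = basal_obs + seb_obs
    nuclei = [_shrink(p, params.nucleus_scale) for p in true_polys]

    truth_cells, obs_cells = [], []
    for cid, tp, op, nuc in zip(ids, true_polys, obs_polys, nuclei):
        truth_cells.append(CellRecord(cid, tp, nuc, "default"))
        if isinstance(op, Polygon) and op.area > 0:
            obs_cells.append(CellRecord(cid, op, nuc, "default"))
    truth_seg = Segmentation(truth_cells)
    observed_seg = Segmentation(obs_cells)
    cell_types = dict(zip(ids, types))

    # --- transcripts ---------------------------------------------------------
    genes = sorted({g for table in params.rates.values() for g in table})
    xs, ys, gene_col, true_col = [], [], [], []
    for cid, ctype, poly in zip(ids, types, true_polys):
        table = params.rates[ctype]
        for gene in genes:
            n = int(rng.poisson(table.get(gene, 0.0)))
            if n == 0:
                continue
            pts = _uniform_in_polygon(rng, poly, n)
            if params.jitter_sd_um > 0:
                pts = pts + rng.normal(0.0, params.jitter_sd_um, size=pts.shape)
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
            gene_col.extend([gene] * n)
            true_col.extend([cid] * n)
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    n_total = len(gene_col)
    low = rng.random(n_total) < params.low_qv_fraction
    qv = np.where(
        low, rng.normal(12.0, 3.0, n_total), rng.normal(35.0, 4.0, n_total)
    ).clip(min=0.0)
    tids = [f"t{i:06d}" for i in range(n_total)]
    transcripts = pd.DataFrame(
        {
            "transcript_id": tids,
            "x": x,
            "y": y,
            "gene": gene_col,
            "qv": qv,
            "cell_id": true_col,  # placeholder, replaced by observed assignment
        }
    )

    observed = reassign_transcripts(observed_seg, transcripts)
    truth = GlandTruth(
        segmentation=truth_seg,
        cell_types=cell_types,
        true_cell=pd.Series(true_col, index=pd.Index(tids, name="transcript_id")),
    )
    return observed, observed_seg, truth


def scenario_presets(name: str) -> GlandParams:
    """Named disease-state parameter sets.

    ``healthy`` is the documented defaults. ``comedo_like`` doubles the
    lipogenic rates and FABP5; ``pustule_like`` halves the lipogenic rates,
    triples FABP5 and halves CRABP2. The effect *directions* follow the
    comedo/pustule biology (hyperactive vs suppressed sebogenesis, shifted
    retinoid chaperone balance); the magnitudes are synthetic.
    """
    params = GlandParams()
    if name == "healthy":
        return params
    if name == "comedo_like":
        mult = {g: 2.0 for g in LIPOGENIC_GENES}
        mult["FABP5"] = 2.0
    elif name == "pustule_like":
        mult = {g: 0.5 for g in LIPOGENIC_GENES}
        mult["FABP5"] = 3.0
        mult["CRABP2"] = 0.5
    else:
        raise ValidationError(f"unknown scenario preset {name!r}")
    for table in params.rates.values():
        for gene, m in mult.items():
            if gene in table:
                table[gene] *= m
    return params
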