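"""On-disk formats: transcript CSV, boundary GeoJSON / CSV vertex lists,
and MatrixMarket count matrices.

The transcript table is a pandas DataFrame with the fixed columns
``transcript_id, x, y, gene, qv, cell_id`` (coordinates in μm, ``qv`` a
Phred-like decoding quality, ``cell_id`` either a cell id string or the
:data:`UNASSIGNED` sentinel). Readers validate strictly and reject rather
than coerce malformed records; every writer/reader pair round-trips
losslessly (coordinates kept as full-precision floats, counts as exact
integers).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Polygon

from . import geometry
from .errors import FormatError, ValidationError

#: sentinel cell id for transcripts not assigned to any cell
UNASSIGNED = "UNASSIGNED"

#: required transcript CSV columns, in canonical order
TRANSCRIPT_COLUMNS = ["transcript_id", "x", "y", "gene", "qv", "cell_id"]

#: vertex-list boundary CSV columns
VERTEX_COLUMNS = ["cell_id", "kind", "vertex_index", "x", "y"]

PROVENANCES = ("default", "marker_refined", "nuclear_expansion")


@dataclass
class CellRecord:
    """One cell: its boundary polygon, optional nucleus, and provenance."""

    cell_id: str
    boundary: Polygon
    nucleus: Polygon | None = None
    provenance: str = "default"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValidationError(
                f"unknown provenance {self.provenance!r} for cell {self.cell_id!r}"
            )


class Segmentation:
    """An ordered collection of :class:`CellRecord`, unique by ``cell_id``."""

    def __init__(self, cells: Iterable[CellRecord] = ()) -> None:
        self._cells: dict[str, CellRecord] = {}
        for c in cells:
            if c.cell_id in self._cells:
                raise ValidationError(f"duplicate cell_id {c.cell_id!r}")
            self._cells[c.cell_id] = c

    def __len__(self) -> int:
        return len(self._cells)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self._cells.values())

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._cells

    def __getitem__(self, cell_id: str) -> CellRecord:
        return self._cells[cell_id]

    @property
    def cell_ids(self) -> list[str]:
        return list(self._cells)


@dataclass
class CountMatrix:
    """Sparse cells × genes matrix of non-negative integer counts."""

    counts: sp.csr_matrix
    cell_ids: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.cell_ids), len(self.genes)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.genes)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_anndata(self):
        """View as an AnnData (cells as obs, genes as var)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.astype(np.float64),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------


def read_transcripts(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a transcript CSV.

    Raises :class:`FormatError` when a required column is missing and
    :class:`ValidationError` (citing the 0-based data row index) for
    non-finite coordinates, negative quality values, or duplicate
    transcript ids. Empty/missing cell assignments are normalized to
    :data:`UNASSIGNED`.
    """
    df = pd.read_csv(path, dtype={"transcript_id": str, "gene": str, "cell_id": str})
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"transcript CSV is missing required column(s): {', '.join(missing)}")
    df = df[TRANSCRIPT_COLUMNS].reset_index(drop=True)
    for col in ("x", "y", "qv"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy())
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"non-finite value in column {col!r} at row {row}")
        df[col] = vals.astype(float)
    if (df["qv"] < 0).any():
        row = int(df.index[df["qv"] < 0][0])
        raise ValidationError(f"negative quality value at row {row}")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValidationError(f"duplicate transcript_id {dup!r}")
    cid = df["cell_id"].fillna(UNASSIGNED)
    cid = cid.where(cid.str.strip() != "", UNASSIGNED)
    df["cell_id"] = cid
    return df


def write_transcripts(transcripts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a transcript table as CSV with the canonical column order."""
    transcripts[TRANSCRIPT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------


def _ring_coords(poly: Polygon) -> list[list[float]]:
    return [[float(x), float(y)] for x, y in poly.exterior.coords]


def read_boundaries(path: str | os.PathLike) -> Segmentation:
    """Read cell/nucleus boundary polygons.

    GeoJSON input must be a FeatureCollection whose features carry
    ``cell_id`` and ``kind`` (``cell`` or ``nucleus``) properties; files
    ending in ``.csv`` are parsed as the vertex-list dialect with columns
    ``cell_id, kind, vertex_index, x, y``. Polygons are repaired (holes
    filled, self-intersections resolved) on read. Duplicate
    ``(cell_id, kind)`` pairs and nuclei without a matching cell are
    rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        raw = _read_vertex_csv(path)
    else:
        raw = _read_geojson(path)

    cells: dict[str, Polygon] = {}
    nuclei: dict[str, Polygon] = {}
    provenance: dict[str, str] = {}
    for cell_id, kind, poly, prov in raw:
        table = cells if kind == "cell" else nuclei
        if cell_id in table:
            raise FormatError(f"duplicate feature for cell_id {cell_id!r}, kind {kind!r}")
        table[cell_id] = geometry.fill_holes(poly)
        if kind == "cell":
            provenance[cell_id] = prov
    orphans = sorted(set(nuclei) - set(cells))
    if orphans:
        raise FormatError(
            f"nucleus feature(s) without a matching cell: {', '.join(orphans)}"
        )
    return Segmentation(
        CellRecord(cid, cells[cid], nuclei.get(cid), provenance.get(cid, "default"))
        for cid in cells
    )


def _read_geojson(path: Path) -> list[tuple[str, str, Polygon, str]]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or data.get("type") != "FeatureCollection":
        raise FormatError("boundary GeoJSON must be a FeatureCollection")
    out = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        cell_id = props.get("cell_id")
        kind = props.get("kind")
        if cell_id is None or kind not in ("cell", "nucleus"):
            raise FormatError(
                f"feature {i}: properties must include cell_id and kind in {{cell, nucleus}}"
            )
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise FormatError(f"feature {i}: geometry must be a Polygon")
        rings = geom.get("coordinates") or []
        if not rings:
            raise FormatError(f"feature {i}: empty polygon")
        poly = Polygon(rings[0], holes=rings[1:])
        out.append((str(cell_id), kind, poly, props.get("provenance", "default")))
    return out


def _read_vertex_csv(path: Path) -> list[tuple[str, str, Polygon, str]]:
    df = pd.read_csv(path, dtype={"cell_id": str, "kind": str})
    missing = [c for c in VERTEX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"vertex CSV is missing required column(s): {', '.join(missing)}")
    bad = ~df["kind"].isin(["cell", "nucleus"])
    if bad.any():
        raise FormatError(f"vertex CSV: unknown kind {df.loc[bad, 'kind'].iloc[0]!r}")
    out = []
    for (cell_id, kind), grp in df.groupby(["cell_id", "kind"], sort=True):
        grp = grp.sort_values("vertex_index")
        if len(grp) < 3:
            raise FormatError(f"cell {cell_id!r} {kind}: fewer than 3 vertices")
        poly = Polygon(list(zip(grp["x"].astype(float), grp["y"].astype(float))))
        out.append((str(cell_id), str(kind), poly, "default"))
    return out


def write_boundaries(seg: Segmentation, path: str | os.PathLike) -> None:
    """Write a segmentation as a GeoJSON FeatureCollection (exterior rings only)."""
    features = []
    for cell in seg:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "cell_id": cell.cell_id,
                    "kind": "cell",
                    "provenance": cell.provenance,
                },
                "geometry": {"type": "Polygon", "coordinates": [_ring_coords(cell.boundary)]},
            }
        )
        if cell.nucleus is not None:
            features.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": cell.cell_id, "kind": "nucleus"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [_ring_coords(cell.nucleus)],
                    },
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket trio)
# ---------------------------------------------------------------------------


def write_counts(matrix: CountMatrix, prefix: str | os.PathLike) -> None:
    """Write ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` under ``prefix``.

    The MatrixMarket file stores genes × cells in integer coordinate format
    (the single-cell convention), so a write/read round trip is exact.
    """
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        prefix / "matrix.mtx", sp.coo_matrix(matrix.counts.T), field="integer"
    )
    pd.Series(matrix.cell_ids, dtype=str).to_csv(
        prefix / "barcodes.tsv", index=False, header=False, sep="\t"
    )
    pd.Series(matrix.genes, dtype=str).to_csv(
        prefix / "features.tsv", index=False, header=False, sep="\t"
    )


def read_counts(prefix: str | os.PathLike) -> CountMatrix:
    """Read the MatrixMarket trio written by :func:`write_counts`."""
    prefix = Path(prefix)
    mat = scipy.io.mmread(prefix / "matrix.mtx")
    mat = sp.csr_matrix(mat).T  # back to cells x genes
    cell_ids = _read_id_column(prefix / "barcodes.tsv")
    genes = _read_id_column(prefix / "features.tsv")
    return CountMatrix(counts=mat, cell_ids=cell_ids, genes=genes)


def _read_id_column(path: Path) -> list[str]:
    if path.stat().st_size == 0:
        return []
    return pd.read_csv(path, header=None, sep="\t", dtype=str)[0].tolist()
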