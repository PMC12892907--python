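"""QC filtering, count matrices, normalization, composite scores, and the
segmentation-method comparison statistics.

The quantification chain mirrors standard single-cell practice: transcripts
below the quality cutoff are dropped first, then cells with fewer than the
minimum number of remaining transcripts are excluded; the cell-by-gene
count matrix is normalized per cell to the median total and log1p
transformed. On top of that sit a gene-set composite score (unweighted mean
of normalized values, default the five sebaceous lipogenesis genes), a
pseudocounted group-level expression ratio (default FABP5:CRABP2), and a
one-way ANOVA with Tukey-corrected pairwise comparisons used to contrast
segmentation methods on per-cell metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .errors import UndefinedStatisticError, ValidationError
from .io_spatial import UNASSIGNED, CountMatrix, Segmentation

#: genes of the sebaceous lipogenesis ("sebogenesis") composite score
SEBOGENESIS_GENES = ("FASN", "AWAT1", "AWAT2", "ACACA", "SREBF1")


@dataclass
class NormalizedMatrix:
    """Dense cells × genes matrix of median-scaled, log1p expression."""

    values: np.ndarray
    cell_ids: list[str]
    genes: list[str]
    target_sum: float
    log_base: str = "e"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.genes)

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.genes:
            raise ValidationError(f"gene {gene!r} not in matrix")
        return pd.Series(
            self.values[:, self.genes.index(gene)], index=self.cell_ids, name=gene
        )


@dataclass
class GeneSetScoreSpec:
    """A named gene set scored as the mean of normalized expression."""

    name: str = "sebogenesis"
    genes: tuple[str, ...] = SEBOGENESIS_GENES

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValidationError("gene set must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene set contains duplicate genes")


@dataclass
class MethodComparison:
    """Per-cell metric rows plus ANOVA / Tukey group statistics."""

    per_cell: pd.DataFrame
    anova: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def qc_filter(
    transcripts: pd.DataFrame,
    min_qv: float = 20.0,
    min_transcripts_per_cell: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Quality filtering in the fixed order: quality first, then cell size.

    Transcripts with ``qv < min_qv`` are dropped; cells whose remaining
    assigned transcript count falls below ``min_transcripts_per_cell`` are
    excluded (their surviving transcripts become unassigned). Returns the
    filtered table and the sorted kept cell ids. Idempotent.
    """
    kept = transcripts[transcripts["qv"] >= min_qv].copy()
    assigned = kept[kept["cell_id"] != UNASSIGNED]
    counts = assigned.groupby("cell_id").size()
    kept_cells = counts[counts >= min_transcripts_per_cell].index
    kept.loc[~kept["cell_id"].isin(kept_cells), "cell_id"] = UNASSIGNED
    return kept, sorted(kept_cells)


def build_counts(transcripts: pd.DataFrame) -> CountMatrix:
    """Cells × genes integer counts from assigned transcripts.

    The matrix total equals the number of assigned rows; rows and columns
    are sorted lexicographically for determinism.
    """
    assigned = transcripts[transcripts["cell_id"] != UNASSIGNED]
    cell_ids = sorted(assigned["cell_id"].unique())
    genes = sorted(assigned["gene"].unique())
    if not cell_ids:
        return CountMatrix(sp.csr_matrix((0, 0), dtype=np.int64), [], [])
    ci = assigned["cell_id"].map({c: i for i, c in enumerate(cell_ids)}).to_numpy()
    gi = assigned["gene"].map({g: i for i, g in enumerate(genes)}).to_numpy()
    mat = sp.coo_matrix(
        (np.ones(len(assigned), dtype=np.int64), (ci, gi)),
        shape=(len(cell_ids), len(genes)),
    ).tocsr()
    return CountMatrix(mat, cell_ids, genes)


def normalize(counts: CountMatrix, target_sum: float | None = None) -> NormalizedMatrix:
    """Median-total scaling followed by natural log1p.

    Each cell's counts are scaled so its total equals ``target_sum``, then
    log1p transformed. By default ``target_sum`` is the median of the
    positive per-cell totals (the scanpy ``normalize_total`` / ``log1p``
    defaults); pass an explicit value when several matrices must share a
    common scale (see :func:`method_comparison_table`). An all-zero cell
    stays all zero; an all-zero matrix is an error.
    """
    if counts.total == 0:
        raise ValidationError("cannot normalize an all-zero count matrix")
    import scanpy as sc

    adata = counts.to_anndata()
    if target_sum is None:
        totals = np.asarray(counts.counts.sum(axis=1)).ravel().astype(float)
        target = float(np.median(totals[totals > 0]))
    else:
        target = float(target_sum)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.normalize_total(adata, target_sum=target)
        sc.pp.log1p(adata)
    values = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    return NormalizedMatrix(
        values=np.asarray(values, dtype=float),
        cell_ids=list(counts.cell_ids),
        genes=list(counts.genes),
        target_sum=target,
    )


def gene_set_score(norm: NormalizedMatrix, spec: GeneSetScoreSpec | None = None) -> pd.Series:
    """Per-cell composite score: mean normalized expression over the set.

    Genes absent from the matrix are skipped with a warning (so the score
    is invariant to padding the set with absent genes); if none of the
    genes are present the score is undefined and an error is raised.
    """
    spec = spec or GeneSetScoreSpec()
    present = [g for g in spec.genes if g in norm.genes]
    missing = [g for g in spec.genes if g not in norm.genes]
    if not present:
        raise ValidationError(
            f"none of the {spec.name!r} genes are present in the matrix"
        )
    if missing:
        warnings.warn(
            f"gene set {spec.name!r}: gene(s) absent from matrix and skipped: "
            f"{', '.join(missing)}",
            stacklevel=2,
        )
    idx = [norm.genes.index(g) for g in present]
    return pd.Series(norm.values[:, idx].mean(axis=1), index=norm.cell_ids, name=spec.name)


def expression_ratio(
    norm: NormalizedMatrix,
    groups: pd.Series,
    gene_a: str = "FABP5",
    gene_b: str = "CRABP2",
    delta: float = 0.01,
) -> pd.Series:
    """Per-group pseudocounted ratio of mean normalized expression.

    For each group ``g``: ``(mean_a(g) + delta) / (mean_b(g) + delta)``
    where the means run over the group's cells. Groups with no cells in the
    matrix are skipped with a warning.
    """
    a = norm.gene_values(gene_a)
    b = norm.gene_values(gene_b)
    groups = groups.reindex(norm.cell_ids)
    ratios: dict[str, float] = {}
    for name in pd.unique(groups.dropna()):
        mask = (groups == name).to_numpy()
        if not mask.any():
            warnings.warn(f"group {name!r} has no cells; skipped", stacklevel=2)
            continue
        ratios[name] = float((a[mask].mean() + delta) / (b[mask].mean() + delta))
    return pd.Series(ratios, name=f"{gene_a}:{gene_b}")


def per_cell_metrics(
    seg: Segmentation,
    transcripts: pd.DataFrame,
    norm_genes: tuple[str, ...] = (),
    min_qv: float = 20.0,
    min_transcripts_per_cell: int = 10,
    target_sum: float | None = None,
) -> pd.DataFrame:
    """QC-filtered per-cell metric table for one segmentation run.

    Columns: ``cell_id``, ``area_um2``, ``transcripts_per_cell`` and
    ``norm_<gene>`` for each requested gene. ``target_sum`` overrides the
    per-run median normalization target (needed when runs are compared).
    """
    kept, kept_cells = qc_filter(transcripts, min_qv, min_transcripts_per_cell)
    cm = build_counts(kept)
    rows = pd.DataFrame(
        {
            "cell_id": cm.cell_ids,
            "area_um2": [seg[c].boundary.area if c in seg else np.nan for c in cm.cell_ids],
            "transcripts_per_cell": np.asarray(cm.counts.sum(axis=1)).ravel(),
        }
    )
    if norm_genes:
        norm = normalize(cm, target_sum=target_sum)
        for g in norm_genes:
            rows[f"norm_{g}"] = (
                norm.gene_values(g).to_numpy() if g in norm.genes else 0.0
            )
    return rows


def method_comparison_table(
    runs: list[tuple[str, Segmentation, pd.DataFrame]],
    norm_genes: tuple[str, ...] = (),
    min_qv: float = 20.0,
    min_transcripts_per_cell: int = 10,
) -> pd.DataFrame:
    """Per-cell metric rows for several runs on a common normalization scale.

    Normalized values from separately median-scaled runs are not
    comparable — a segmentation that changes most cells' totals moves its
    own median with it. All runs are therefore scaled to one shared target:
    the median per-cell total pooled over every run's QC-passing cells.
    Returns the concatenated rows with a leading ``method`` column, ready
    for :func:`compare_methods`.
    """
    totals: list[np.ndarray] = []
    for _, _, transcripts in runs:
        kept, _ = qc_filter(transcripts, min_qv, min_transcripts_per_cell)
        cm = build_counts(kept)
        if cm.total:
            totals.append(np.asarray(cm.counts.sum(axis=1)).ravel())
    pooled = np.concatenate(totals) if totals else np.array([])
    if pooled.size == 0:
        raise ValidationError("no QC-passing cells in any run")
    target = float(np.median(pooled[pooled > 0]))

    frames = []
    for method, seg, transcripts in runs:
        rows = per_cell_metrics(
            seg,
            transcripts,
            norm_genes=norm_genes,
            min_qv=min_qv,
            min_transcripts_per_cell=min_transcripts_per_cell,
            target_sum=target,
        )
        rows.insert(0, "method", method)
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


def compare_methods(rows: pd.DataFrame, metrics: list[str] | None = None) -> MethodComparison:
    """One-way ANOVA plus Tukey-corrected pairwise comparisons per metric.

    ``rows`` holds per-cell records with a ``method`` column and one column
    per metric. For each metric the across-method ANOVA F and p are
    computed, and every method pair gets its mean difference, 95 %
    confidence interval, and Tukey-adjusted p (statsmodels
    ``pairwise_tukeyhsd``). Requires >= 2 methods with >= 2 cells each; if
    every group has zero within-group variance the F statistic is
    undefined and an error is raised.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if "method" not in rows.columns:
        raise ValidationError("per-cell rows must carry a 'method' column")
    if "cell_id" in rows.columns:
        dup = rows.duplicated(subset=["method", "cell_id"])
        if dup.any():
            raise ValidationError("duplicate (method, cell_id) pair in comparison rows")
    sizes = rows.groupby("method").size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValidationError("need >= 2 methods with >= 2 cells each")
    if metrics is None:
        metrics = [
            c
            for c in rows.columns
            if c not in ("method", "cell_id", "cell_type")
            and pd.api.types.is_numeric_dtype(rows[c])
        ]

    anova_rows, pair_rows = [], []
    for metric in metrics:
        sub = rows[["method", metric]].dropna()
        groups = [g[metric].to_numpy(float) for _, g in sub.groupby("method")]
        if all(np.var(g) == 0 for g in groups):
            raise UndefinedStatisticError(
                f"metric {metric!r}: zero within-group variance in every group"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = scipy.stats.f_oneway(*groups)
        anova_rows.append({"metric": metric, "F": float(f_stat), "p": float(p)})
        tuk = pairwise_tukeyhsd(
            sub[metric].to_numpy(float), sub["method"].to_numpy(), alpha=0.05
        )
        names = tuk.groupsunique
        for k, (i, j) in enumerate(zip(*np.triu_indices(len(names), k=1))):
            pair_rows.append(
                {
                    "metric": metric,
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(tuk.meandiffs[k]),
                    "ci_low": float(tuk.confint[k, 0]),
                    "ci_high": float(tuk.confint[k, 1]),
                    "p_adj": float(tuk.pvalues[k]),
                }
            )
    return MethodComparison(
        per_cell=rows.reset_index(drop=True),
        anova=pd.DataFrame(anova_rows),
        pairwise=pd.DataFrame(pair_rows),
    )


def misassignment_rate(
    assigned: pd.DataFrame,
    truth: "GlandTruth",
    gene: str,
    target_cell_type: str,
) -> float:
    """Fraction of a gene's assigned transcripts wrongly credited to a cell type.

    Among the gene's transcripts that carry a cell assignment, the fraction
    assigned to a cell of ``target_cell_type`` that differs from the
    transcript's true source cell. Zero when no transcripts of the gene are
    assigned.
    """
    sub = assigned[assigned["gene"] == gene]
    if sub.empty:
        raise ValidationError(f"gene {gene!r} absent from the transcript table")
    sub = sub[sub["cell_id"] != UNASSIGNED]
    if sub.empty:
        return 0.0
    assigned_type = sub["cell_id"].map(truth.cell_types)
    true_ids = truth.true_cell.reindex(sub["transcript_id"]).to_numpy()
    wrong = (assigned_type == target_cell_type).to_numpy() & (
        sub["cell_id"].to_numpy() != true_ids
    )
    return float(wrong.sum() / len(sub))
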