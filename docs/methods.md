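# Methods

## The refinement procedure

The method assumes that a marker gene identifies the mis-segmented cell
population and that the marker's transcripts are confined to the true cell
body. For each cell the pipeline:

1. **Repair.** Interior rings ("holes") in every cell and nucleus polygon
   are removed by extracting the exterior ring; invalid (self-intersecting)
   rings are first repaired with constructive validation. Repair never
   reduces a polygon's exterior extent. If repair yields several parts,
   parts touching at a point are fused through the contact (an ~1e-6 μm
   weld, area-preserving to numerical precision); genuinely disjoint parts
   keep only the largest, with a recorded warning.
2. **Flag.** Cells whose assigned marker transcripts number at least
   `min_marker_count` (default 3, also the convex-hull minimum) are
   flagged. By default only transcripts with quality value (QV) ≥ 20 are
   counted; `count_all_qv=True` counts before the quality filter — the
   choice is exposed because either reading of "contains N marker
   transcripts" is defensible.
3. **Refine.** The flagged cell's new boundary is the convex hull of its
   marker transcripts merged with the nucleus polygon. Collinear or
   coincident marker sets are buffered by ε = 0.2 μm before hulling so the
   boundary always has positive area. If hull and nucleus are disjoint the
   union is bridged with the convex hull of both parts — a cell must have
   one boundary. A flagged cell with no nucleus uses the hull alone; a cell
   with neither a formable hull nor a nucleus is retained unchanged. All
   fallbacks land in the per-cell audit table.
4. **Reassign.** Every transcript (regardless of QV, so low-quality
   molecules stay auditable) is tested against all boundaries with
   boundary-inclusive containment. Inside exactly one boundary → that cell;
   none → unassigned; several → marker-refined cells outrank others, then
   nearest nucleus centroid (boundary centroid when a cell has no nucleus),
   then the lexicographically smallest cell id. The refined boundaries are
   the correction, so they must win contested territory; the remaining
   tie-breaks only make the result deterministic. Reassignment is global —
   all transcripts against all cells — because refinement changes which
   cell "owns" space well beyond the flagged cells themselves.

Unflagged cells keep their input boundary objects bit-identically.

## Baselines

Nuclear expansion dilates each hole-filled nucleus by a uniform radius
(2 μm and 5 μm are the conventional settings) using a disk discretized at
16 segments per quadrant (area error < 0.2 % at these radii). Expanded
boundaries are not clipped against each other; contested transcripts go to
the cell with the nearest nucleus — a generalized-Voronoi approximation
that avoids fragile polygon partitioning and matches the intent of
expansion segmentation. Cells without nuclei cannot be expanded and are
dropped with a warning.

## Quantification

* **QC order is fixed:** transcripts with QV < 20 are dropped first, then
  cells with fewer than 10 remaining transcripts are excluded (a cell with
  12 transcripts of which 3 are low-quality is excluded). The filter is
  idempotent.
* **Normalization** scales each cell's counts to the median positive
  per-cell total, then applies natural log1p (delegated to scanpy's
  `normalize_total`/`log1p`). When several segmentation runs are compared,
  per-run medians are not comparable — a segmentation that shifts most
  cells' totals shifts its own median with it — so
  `method_comparison_table` scales every compared run to one shared
  target, the median per-cell total pooled over all runs. Single-run
  analyses keep the per-run median default.
* **Sebogenesis score** is the unweighted mean of normalized FASN, AWAT1,
  AWAT2, ACACA and SREBF1 — a plain composite, not a control-set-subtracted
  score; the gene list is configurable. Genes absent from the matrix are
  skipped (with a warning), so the score is invariant to padding the set.
* **FABP5:CRABP2 ratio** is computed at group level with a pseudocount:
  `(mean_a + δ)/(mean_b + δ)`, δ = 0.01, which keeps groups with zero
  CRABP2 finite while barely perturbing typical values (normalized means
  are O(1)).
* **Method comparison** uses one-way ANOVA per metric plus all pairwise
  Tukey-HSD contrasts (statsmodels), reporting mean difference, 95 % CI and
  adjusted p. Metrics are treated independently; no cross-metric
  correction. When every group has zero variance the F statistic is
  undefined and an error is raised rather than a fabricated p.
* **Misassignment rate** for gene *g* and cell type *T*: among *g*'s
  assigned transcripts, the fraction sitting in a cell of type *T* that is
  not the transcript's true source cell.

## The synthetic gland

The generator provides ground truth the real tissue cannot: every
transcript's source cell. It emulates one gland lobule:

* **Geometry.** An ellipse (default semi-axes 120 × 90 μm). The outer
  4 μm band is split by arc length into quadrilateral basal cells ~5 μm
  wide (~133 cells at the default size); the interior is Voronoi-tessellated
  around Poisson-disk-sampled seeds at ~0.8× the 20 μm sebocyte diameter
  (~83 sebocytes). Band and interior share one discretized inner ring, so
  true cells tile the gland without slivers. Nuclei are the true cells
  shrunk by 0.5 about their centroid.
* **Expression.** Per cell and gene, counts are Poisson with type-specific
  rates over a 12-gene panel: KRT5/KRT14/MKI67 high in basal; KRT79, AWAT2
  and the lipogenic set high in sebocytes; FABP5/CRABP2 at moderate,
  scenario-dependent levels. Molecules are placed uniformly inside the true
  cell and jittered by isotropic Gaussian noise (σ = 0.5 μm), so some
  transcripts genuinely cross boundaries — perfect recovery is impossible
  by construction, which is what the benchmark thresholds assume. QV is a
  two-mode mixture (means 35 and 12, 5 % low), so the QV ≥ 20 cutoff
  removes a realistic minority.
* **The corrupted default segmentation** extends every basal boundary a
  further δ = 4 μm into the gland (one basal-cell depth) and clips sebocyte
  polygons accordingly — the over-extension failure mode, reproduced with
  a partition so the corruption, not tie-breaking, drives the error.
  Observed transcript assignment is containment against these corrupted
  boundaries. δ = 0 and σ = 0 recover truth exactly; misassignment grows
  monotonically with δ.
* **Presets.** `healthy` is the default rate table; `comedo_like` doubles
  the lipogenic rates and FABP5; `pustule_like` halves the lipogenic rates,
  triples FABP5 and halves CRABP2. The directions mirror comedo/pustule
  biology (hyperactive vs suppressed sebogenesis, retinoid chaperone
  balance shifted toward FABP5); the magnitudes are synthetic choices, made
  once, and large enough that ~200-cell arms order the group scores
  decisively.

What the simulator does **not** model: other cell types (epidermis,
follicle, immune cells), spatially varying detection efficiency, segmentation
errors other than basal over-extension, multi-lobule anatomy, and 3D
sectioning effects. Passing benchmarks here show the method corrects the
targeted failure mode under controlled noise — not that it improves every
real tissue.

## Numerical and design notes

* Single PRNG stream per simulation, seeded explicitly; identical seeds
  give byte-identical outputs, and reassignment is independent of the
  thread count (transcripts are chunked, results concatenated in order).
* Containment is boundary-inclusive everywhere; the assignment priority
  rule, not geometry, resolves shared edges.
* Coordinates are abstract planar μm; no origin or axis orientation is
  assumed.
* Problem sizes used by the test suite and the acceptance script — one
  gland of ~216 cells / ~35k transcripts, and three ~216-cell preset arms —
  were chosen as the smallest sizes at which the basal population clears
  100 cells and the preset arms clear 200, keeping every group comparison
  well-powered.
* Known limitations: the convex marker hull cannot represent concave basal
  cells that wrap far around a sebocyte; a single stray high-QV marker
  transcript inside a neighbouring cell can pull that cell's hull outward
  (three are required before a cell is refined at all); and bridged
  disjoint unions deliberately over-cover the gap between hull and
  nucleus.
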