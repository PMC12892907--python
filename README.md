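# markerseg

Marker-transcript-directed cell resegmentation for imaging-based spatial
transcriptomics.

## The problem

Imaging platforms (Xenium-style) segment cells from nuclear and membrane
stains. That works for roundish cells but fails for thin cells wedged
against large neighbours: the basal progenitor monolayer at the periphery
of the sebaceous gland is the motivating case. Basal cells are small,
slender and KRT5-high; the sebocytes they wrap around are large,
lipid-filled and KRT79/AWAT2-high. Stain-driven ("default") segmentation
routinely extends basal boundaries into the lipid-filled sebocyte
territory, so sebocyte transcripts (KRT79, AWAT2, lipogenic genes) are
erroneously credited to basal cells, inflating their size and transcript
counts and diluting their own marker signal.

`markerseg` corrects this using the cells' own marker transcripts. For a
marker gene *g* (default KRT5) and each cell with at least 3
quality-passing *g* transcripts (QV ≥ 20), the refined boundary is

```
B' = convex_hull(marker transcripts of the cell) ∪ nucleus polygon
```

after filling any holes in the input polygons. All transcripts are then
reassigned by boundary-inclusive containment against the refined boundary
set (marker-refined cells win contested territory, then nearest nucleus
centroid, then lexicographic cell id). Cells below the marker threshold
retain their original boundaries. The package also provides the standard
2 μm / 5 μm nuclear-expansion baselines, the QC filters (QV ≥ 20 first,
then ≥ 10 transcripts per cell), median-total + log1p normalization, a
five-gene sebogenesis score (mean normalized FASN, AWAT1, AWAT2, ACACA,
SREBF1), the FABP5:CRABP2 expression ratio, one-way ANOVA with
Tukey-corrected pairwise comparisons for contrasting methods, and a
synthetic sebaceous-gland generator with full ground truth for
benchmarking.

## Worked example

```python
import markerseg as m

# synthetic gland: ~133 basal cells around ~83 sebocytes, with a corrupted
# default segmentation whose basal boundaries over-extend 4 um inward
transcripts, observed, truth = m.simulate_gland(m.GlandParams(seed=1))
result = m.run_marker_resegmentation(observed, transcripts)

rows = m.method_comparison_table(
    [("default", observed, transcripts),
     ("marker_refined", result.refined, result.reassigned)],
    norm_genes=("KRT5",),
)
basal = rows[rows.cell_id.isin(c for c, t in truth.cell_types.items() if t == "basal")]
print(basal.groupby("method")[["area_um2", "transcripts_per_cell", "norm_KRT5"]].median())
for seg_name, table in [("default", transcripts), ("refined", result.reassigned)]:
    print(seg_name, "KRT79 misassigned to basal:",
          round(m.misassignment_rate(table, truth, "KRT79", "basal"), 4))
```

prints

```
                 area_um2  transcripts_per_cell  norm_KRT5
method
default         38.100087                  66.0   3.178054
marker_refined  13.010896                  39.0   3.705614
default KRT79 misassigned to basal: 0.0968
refined KRT79 misassigned to basal: 0.0041
```

Refined basal cells are about a third of their corrupted size, carry ~40%
fewer transcripts, and the fraction of sebocyte KRT79 wrongly credited to
basal cells drops from ~9.7% to ~0.4%, while normalized KRT5 in basal
cells rises — the signature of boundaries snapping back onto the true thin
monolayer.

The same pipeline is available from the shell:

```bash
markerseg simulate --preset healthy --seed 1 --out-dir run/
markerseg resegment --transcripts run/transcripts.csv \
    --boundaries run/boundaries.geojson --out-dir run_refined/
markerseg compare --runs run/runlog.json run_refined/runlog.json \
    --metrics area,tpc,norm:KRT5 --out compare.tsv
```

## Layout

- `markerseg.io_spatial` — transcript CSV, boundary GeoJSON / vertex-list
  CSV, MatrixMarket counts; strict validation.
- `markerseg.geometry` — hole filling, convex hull, union, containment,
  dilation, area (shapely-backed, fixed conventions).
- `markerseg.resegmentation` — flagging, boundary refinement, global
  transcript reassignment.
- `markerseg.baselines` — nuclear-expansion segmentations.
- `markerseg.quantify` — QC, counts, normalization, scores, ratios,
  ANOVA/Tukey method comparison, misassignment rate.
- `markerseg.synthetic_gland` — the gland generator and disease-state
  presets.
- `markerseg.cli` — the `markerseg` command.

See `docs/methods.md` for the modelling choices and their rationale.
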