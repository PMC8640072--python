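# hepazone

Distance-based zonation analysis for liver spatial transcriptomics (ST).

Hepatocyte gene expression is organised along the lobular axis between
central and portal veins ("zonation"). Given an ST spot array, a gene-by-spot
count matrix and histological annotations of vein structures, this package
quantifies that organisation directly in physical space:

* **Vein distances** — the distance from a spot *s* to a structure *t* is the
  minimal Euclidean distance from the spot center to any pixel of the
  structure's mask, `d(s,t) = min_{p in M_t} d(s,p)`; the distance to a vein
  *class* uses the union of that class's masks. Pixel distances are converted
  to micrometers with the array calibration (400 µm = 142 px by default).
* **Expression by distance** — for a feature *x* and vein class *C*, the
  tuples `(d(s,C), x_s)` for spots within 400 µm are smoothed with loess
  (locally weighted polynomial regression, tricube kernel) into a curve with
  a ±1 SE envelope, approximating `x = f(d)`.
* **Bivariate distance model** — per gene,
  `y_sg ~ β0g + β1g·d_sc + β2g·d_sp` is fit by OLS together with its three
  nested reductions (drop the portal term, the central term, or both);
  likelihood-ratio tests (χ², df 1 or 2) decide which vein distances carry
  explanatory power for each gene.
* **Vein-type classification** — each structure gets a neighborhood
  expression profile (NEP): the expectation of a marker panel under weights
  `w_ts ∝ exp(-d(s,t)/σ)` over spots with `d(s,t) < T_N` (σ = 20 px,
  T_N = 400 µm). An L2-penalised logistic regression (strength 1, ≤1000
  iterations) on labelled NEPs predicts `P(central)`/`P(portal)` for veins
  whose histology is ambiguous, with section- and sample-level
  cross-validation.
* **Spatial statistics** — cluster-interaction permutation analysis on the
  4-nearest-neighbor spot graph, lag-vector spatial autocorrelation, module
  scores against bin-matched control genes, quantile scaling of proportion
  fields, bootstrap Pearson CIs for cell-type proportions, and a Spearman
  distance-correlation screen with Holm–Šidák correction.
* **Synthetic data** — `generate_dataset` plants vein masks and zonated
  genes (gradient, compartment, flat and capsule-region archetypes) on the
  real array geometry (150 µm neighbor pitch, 200 µm same-row pitch, 100 µm
  spots) with negative-binomial counts and per-spot depth variation, and
  keeps the full ground truth so every stage can be scored.

## Worked example

```python
import hepazone as hz

cfg = hz.SimulationConfig(
    frame_extent=(3000.0, 3200.0), n_samples=3, sections_per_sample=1,
    n_central=8, n_portal=8, n_ambiguous=2, min_separation_um=400.0, seed=42,
)
ds = hz.generate_dataset(cfg)

# which vein distances explain each gene?
design = hz.build_design(ds.expression, ds.distances, genes=["gradc_1", "flat_1"])
lrt, summary = hz.screen_genes(design)

# classify veins from neighborhood expression profiles
panel = [g.gene_id for g in cfg.gene_panel if g.archetype.startswith("gradient")]
profiles = hz.neighborhood_profiles(ds.spots, ds.masks, ds.expression, panel)
report = hz.cross_validate(profiles, level="sample", k=1)

train = [p for p in profiles if p.class_label in ("central", "portal")]
amb = [p for p in profiles if p.class_label == "ambiguous"]
model = hz.fit_vein_classifier(train)
calls = hz.annotate_ambiguous(model, amb)
```

This prints (abbreviated):

```
spots: 1260  genes: 35  structures: 57
observations within 400 um of both vein types: 132
   gene category
gradc_1     both
 flat_1  neither
gradc_1 vs intercept-only: LRT statistic 31.2 (df=2), p = 1.64e-07
sample-level CV accuracy: 1.000 over 48 held-out veins
 structure_id  p_central  p_portal predicted true_class
           17   0.993608  0.006392   central    central
           18   0.087884  0.912116    portal     portal
```

Reading: the simulated pericentral gradient gene `gradc_1` is strongly
explained by vein distance (the intercept-only reduction is rejected,
p ≈ 2·10⁻⁷) while the flat background gene is not; the vein-type classifier
separates held-out central from portal veins perfectly on this strongly
zonated dataset, and the hidden classes of the "ambiguous" veins are
recovered with confident probabilities.

A command-line surface mirrors the library:
`hepazone simulate|distances|curve|bivariate|classify|interact|autocorr|score|bootstrap|screen`
(see `hepazone --help`).

## Layout

```
src/hepazone/
  array_geometry.py        spots, masks, rasterization, distance tables
  synthetic_data.py        seeded generator with full ground truth
  expression_by_distance.py  distance-feature tuples, loess curves
  bivariate_model.py       OLS distance models, nested LRTs, gene screen
  vein_classifier.py       NEPs, logistic vein typing, grouped CV
  spatial_stats.py         interaction, autocorrelation, module scores,
                           quantile scaling, bootstrap CIs, Spearman screen
  cli.py                   thin command-line surface
docs/methods.md            model details, defaults and limitations
```
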