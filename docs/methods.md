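# Methods

This note documents the models and procedures hepazone implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that matter for
reproducibility.

## Distances to anatomical structures

Structures (central veins, portal veins, ambiguous veins, arbitrary tissue
regions) are pixel masks in the coordinate frame of the stained tissue
image: 0-based indices, x rightward, y downward, pixel centers at integer
coordinates, spot centers possibly fractional. The distance from a spot to a
structure is the minimal Euclidean center-to-pixel distance over the mask;
the distance to a class is the minimum over the union of the class's masks.
A spot whose center lies on a mask pixel therefore has distance 0 — interior
spots are included, not excluded. Pixel distances are converted to
micrometers with a per-dataset calibration, default 400/142 ≈ 2.8169 µm/px,
the printed calibration of the spotted array platform (so 400 µm ≡ 142 px
and 800 µm ≡ 284 px exactly).

Distance queries run through an exact nearest-neighbour search
(`scipy.spatial.cKDTree`) over mask pixels, so they agree with the
brute-force double loop to floating-point precision; the test suite asserts
agreement below 10⁻⁶ µm on random layouts.

Polygon annotations are rasterized by the pixel-center-in-polygon rule
(shapely `contains_xy`, strict interior); label images are accepted
directly. Distances beyond an optional cap are recorded as `inf` — a
numeric "beyond cap" sentinel that keeps ≤-cap filters trivial.

## Expression-by-distance curves

For a feature (a gene's normalized expression, a cell-type proportion, a
module score) and a vein class, every spot within 400 µm (inclusive)
contributes a (distance, value) tuple; tuples aggregate across sections by
default. A spot can contribute to both the central- and the portal-distance
curve — the two curves answer different questions.

The smoother is locally weighted polynomial regression (loess): at each
evaluation point the nearest `ceil(span·n)` observations get tricube
weights and a local polynomial is fit by weighted least squares; the fitted
value is the local intercept. Defaults span = 0.75, degree = 2 — the
classical loess defaults — both exposed. Curves are evaluated on a uniform
100-point grid over the observed distance range. The ±1 SE envelope uses
the equivalent-kernel rows `l(x)`: `se(x) = σ̂·‖l(x)‖` with
`σ̂² = RSS/(n − tr(L))` estimated from the smoother's residuals at the
observations. The smoother is implemented in-package (with the property,
asserted in tests, that polynomials up to the fit degree are reproduced
exactly); fewer than `max(degree+2, 10)` tuples or all-equal distances are
errors, and coincident evaluation/observation pile-ups fall back to
averaging the coincident points.

## Bivariate distance model and model comparison

Per gene, normalized expression is modelled as a linear function of the
distances to the nearest central and portal vein:

    full:          y ~ β0 + β1·d_c + β2·d_p
    central-only:  y ~ β0 + β1·d_c
    portal-only:   y ~ β0 + β2·d_p
    intercept:     y ~ β0

All four are ordinary least squares (statsmodels OLS, no regularization),
distances in µm untransformed. The observation domain defaults to spots
with both class distances ≤ 400 µm — the surveyed domain of the
distance-grid visualisations — and is configurable (`d_max=None` uses all
spots).

Nested models are compared by the likelihood-ratio statistic
Λ = 2(ℓ_full − ℓ_reduced) against χ² with 1 df (single-distance
reductions) or 2 df (intercept-only); the full model "outperforms" at
p < 0.05. The Gaussian log-likelihood uses the MLE variance σ̂² = RSS/n so
that the LRT is well defined; σ̂² is floored at 10⁻¹² to keep the
log-likelihood finite for exactly interpolated fits, and Λ is clipped at 0
(it can only go negative by numerical noise for nested OLS fits). The gene
screen categorizes each gene by which distances are influential: a distance
matters when the reduction lacking it is rejected. No multiple-testing
correction is applied across genes by default (per-gene p-values are
reported); the Monte-Carlo suite verifies nominal size (rejection rate
0.05 ± 0.02 under each reduced-model truth) and near-unit power at
5σ effects with n = 500.

## Neighborhood expression profiles and vein classification

The neighborhood of a structure is the set of spots strictly closer than
T_N = 400 µm = 142 px (the span of three consecutive same-row spot
centers). Its NEP is the weighted mean marker-panel expression with
weights `ŵ_ts = exp(−d_px/σ)` normalized to sum to one; σ = 20 and is
interpreted in pixels (the distance computations are pixel-based and the
value carries no unit in its source; 20 px ≈ 56.3 µm at the default
calibration). Weights are computed as `exp(−(d − d_min)/σ)` before
normalization — mathematically identical, but immune to underflow, so the
σ→0⁺ limit degrades gracefully to the nearest spot's expression and the
σ→∞ limit to the unweighted mean (both asserted numerically). Structures
with empty neighborhoods raise (or are skipped on request) rather than
being imputed; only spots of the structure's own section enter its
neighborhood.

Labelled NEPs (central vs portal) train `sklearn` logistic regression with
an L2 penalty at regularization strength C = 1 (inverse-strength
convention) and up to 1000 iterations, no feature standardization. Classes
are ordered lexicographically — central is class 1, portal class 2 — so
p_t = P(portal), reported alongside P(central) = 1 − p_t, and the hard
label is central when p_t ≤ 0.5 (ties go to class 1). Cross-validation
enumerates all combinations of K held-out groups at the section or sample
level; holding out a sample removes all its sections from training, and
folds whose training set lacks a class are skipped with a warning.
Ambiguous veins are scored by a model trained on unambiguous structures
only. Note that because the penalty weight is fixed, uniformly duplicating
the training profiles slightly sharpens the probabilities (it effectively
doubles C); the decisions themselves are unchanged.

## Spatial statistics

**Neighbor graph.** Per spot, the k = 4 nearest same-section spots within a
distance cap; ties break by (distance, spot id). The interaction analysis
defaults to a 155 µm cap — just above the 150 µm lattice pitch, so the
first neighbor shell is captured and the 200 µm same-row shell excluded
(the source analyses state a threshold but not its value);
autocorrelation defaults to the stated 150 µm.

**Cluster interaction.** Observed fraction of cluster-A members' neighbors
in cluster B (counts over A's total neighbor count), against a null from
100 random permutations of the cluster labels. Permutations are restricted
to within section, preserving each section's spot geometry; pairs more than
two null SDs from the null mean are flagged. Clusters with no neighbors
are reported missing, never zeroed.

**Spatial autocorrelation.** A gene's lag vector is the summed expression
over graph neighbors; the score is the Pearson correlation between
expression and lag. Only spots with a complete k-neighborhood are scored by
default: with a uniform neighbor count the summed lag is an affine image of
the neighborhood mean, making the score exactly invariant to affine
rescaling of the feature and keeping boundary spots with truncated
neighborhoods from deflating it (`require_full=False` restores the
any-neighbor variant). Zero-variance genes or lags are reported missing
with a reason.

**Module scores.** Genes are binned into 24 equal-frequency bins of their
dataset-average expression; for each program gene, 100 control genes are
drawn from its bin (without replacement when the bin allows, with
replacement otherwise, always seeded), and the per-spot score is the mean
program expression minus the mean control expression. Scores are invariant
to per-spot constants and center on zero when the program is exchangeable
with its pool (both asserted).

**Quantile scaling.** Values are clipped at the 0.95 sample quantile and
divided by the clipped maximum, mapping to [0, 1]; applied within every
(cell type, section) group. The clip threshold is the `higher` sample
quantile — an actual order statistic — because clipping at an interpolated
(type-7) quantile makes the two-step procedure non-idempotent
(counterexample [0, 1, 2]); with an order-statistic threshold it is exactly
idempotent. All-zero groups pass through unchanged with a flag; negative
input is an error.

**Bootstrap Pearson CIs.** For each cell-type pair, spots are resampled
with replacement 10,000 times; the mean bootstrap r is the representative
value, the 2.5th–97.5th percentiles the CI, and a pair is significant when
the CI excludes zero. Degenerate resamples are skipped and counted;
constant columns are reported missing.

**Distance-correlation screen.** Spots within 800 µm (= 284 px) of a
reference region are kept; per gene, Spearman's ρ between expression and
distance with its analytic p-value, adjusted across genes by Holm–Šidák
step-down (statsmodels `multipletests`); significance at adjusted p < 0.05.
Positive ρ means expression rises away from the region. The analytic
Spearman p-value is a t-approximation that is only accurate for comfortably
sized spot sets; the calibration suite therefore exercises the screen at
200 spots, where the familywise error is controlled at its nominal level.

## The synthetic generator

`generate_dataset` emulates the array geometry of the spotted ST platform:
an offset lattice with 200 µm within-row pitch and rows shifted by 100 µm
horizontally and √(150² − 100²) ≈ 111.80 µm vertically, so the
nearest-neighbor pitch is exactly 150 µm; frames span 6,200 × 6,400 µm
(~1,800 spots at the default margins — the frame extent, not a fixed spot
count, is the primitive), spot diameter 100 µm, coordinates emitted in
pixels at 400/142 µm/px.

Veins are non-overlapping disks (radius 60 µm) placed by rejection
sampling with ≥ 400 µm center separation, 18 central + 18 portal per
default frame. This density mirrors lobular anatomy — lobule radii of a few
hundred µm put nearly every spot within ~400 µm of both vein types, and it
is consistent with the hundreds of veins annotated across the source
study's eight frames. Ambiguous veins are true central/portal structures
whose emitted annotation says "ambiguous" while the ground truth retains
the hidden class, enabling end-to-end recovery tests. An optional
capsule-like region (default: a 500 µm strip along the left frame edge,
emulating the collagen-rich sheath at the tissue boundary) drives the
"region" gene archetype.

Gene archetypes set the noiseless mean for spot s:

* gradient (central/portal): `b + (a − b)·exp(−d/λ)`, λ ∈ {60…180} µm in
  the default panel, spanning steep to gradual zonation;
* compartment (central/portal): `a` within radius r (150 µm) of the vein
  class, else `b`;
* flat: constant `a`;
* region: `a` within the capsule region, else `b`.

The default panel is 5 gradient + 5 compartment genes per vein class, 10
flat and 5 region genes; the 5+5 gradient genes double as the marker panel
for vein classification. Counts are negative binomial with mean
`depth_s · m_sg / Σ_g m_sg` (depth lognormal, median ≈ 500 for the 35-gene
panel) and dispersion θ = 2 (variance μ + μ²/θ; θ = ∞ switches to
Poisson). The normalized layer is depth-scaled log1p,
`log(1 + count·median(depth)/depth_s)` — a deliberate, simple stand-in for
a variance-stabilising normalization, adequate because all downstream
analyses consume it generically. Cell-type proportions are Dirichlet draws
whose pericentral/periportal-hepatocyte concentrations are boosted by
`8·exp(−d/150 µm)` of the matching vein distance over a base concentration
of 2, giving the planted anti-correlation between the two hepatocyte
populations. True cluster labels (pericentral/periportal within 150 µm of
the matching vein, region inside the capsule, mid elsewhere) and the
noiseless means complete the ground truth.

What the generator does **not** emulate: tissue-shaped spot masks (all
lattice positions are "under tissue"), histology images, cell segmentation,
spatially correlated noise beyond the planted means, the schematic
one-central-per-six-portal lobule packing, and realistic transcriptome
breadth (tens of genes, not ~19,000). Passing tests therefore demonstrate
correctness of the procedures and their calibration under a faithful
geometric and count-noise model — not robustness to segmentation errors,
normalization artifacts or transcriptome-scale multiple testing.

## Problem sizes used by the verification suite

The acceptance computations run at desk scale: LRT size at 1,000 replicates
(n = 500 observations), power and OLS recovery at 200 replicates, vein
classification over 20 seeded datasets of 3 samples × (8+8+2) veins on
3,000 × 3,200 µm frames, bootstrap coverage over 50 datasets of 500 spots,
FWER over 2,000 replicates of a 20-gene × 200-spot null, and the module
score null over 40 seeded draws. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands.

## Known limitations

* The loess SE uses the one-delta approximation `σ̂²‖l(x)‖²`; it matches
  the classical loess envelope closely but is not a simultaneous band.
* The Gaussian OLS likelihood treats normalized expression as homoskedastic;
  count-level models (e.g. NB regression on distances) are out of scope.
* The interaction permutation preserves section geometry but not spatial
  autocorrelation of labels; its null is exchangeability within section.
* `p_t` is calibrated only as far as penalised logistic regression allows;
  with few training veins the probabilities shrink toward 0.5.
* The distance definition measures to mask pixels, so structures annotated
  as outlines (rather than filled polygons) should be filled before
  rasterization.
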