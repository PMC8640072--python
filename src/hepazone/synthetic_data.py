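"""Synthetic spatial-transcriptomics frames with planted liver zonation.

The generator emulates the array geometry of the spotted ST platform
(offset lattice, 150 um nearest-neighbour pitch, 200 um within-row pitch,
100 um spot diameter, 400 um = 142 px calibration), plants circular central
and portal vein masks, and draws negative-binomial counts for a configurable
gene panel whose noiseless means follow liver-lobule zonation archetypes:

* ``gradient-central`` / ``gradient-portal``: mean decays exponentially with
  distance to the assigned vein class (length scale ``length_scale_um``),
  mimicking gradually zonated genes;
* ``compartment-central`` / ``compartment-portal``: mean is high within a
  radius of the vein and drops to baseline outside, mimicking genes whose
  expression is confined to a pericentral/periportal compartment;
* ``flat``: spatially constant background;
* ``region``: elevated inside a confined tissue region (a capsule-like
  program), constant baseline elsewhere.

Every stochastic step flows from the single config seed, and the full ground
truth (structure classes, noiseless means, cluster labels, expected
proportions) is retained so downstream analyses can be scored against it.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .array_geometry import (
    DEFAULT_SCALE_UM_PER_PX,
    DistanceTable,
    SpotArray,
    Structure,
    StructureMaskSet,
    _min_distance_px,
    build_distance_table,
    px_to_um,
    rasterize_structures,
)
from .core import ExpressionMatrix

ARCHETYPES = (
    "compartment-central",
    "gradient-central",
    "compartment-portal",
    "gradient-portal",
    "flat",
    "region",
)


@dataclass
class GeneSpec:
    """Noiseless-mean specification for one simulated gene."""

    gene_id: str
    archetype: str
    amplitude: float = 8.0
    baseline: float = 0.5
    length_scale_um: float = 100.0  # gradient types
    radius_um: float = 150.0  # compartment / region types

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "flat":
            if self.amplitude <= 0:
                raise ValueError("flat gene needs amplitude > 0")
        elif not (self.amplitude > self.baseline >= 0):
            raise ValueError("require amplitude > baseline >= 0")
        if self.length_scale_um <= 0 or self.radius_um <= 0:
            raise ValueError("length scale and radius must be positive")


def default_gene_panel() -> list[GeneSpec]:
    """5 gradient + 5 compartment genes per vein class, 10 flat, 5 region.

    Mirrors the 5-central + 5-portal marker panel used for vein
    classification; gradient length scales span steep (60 um) to gradual
    (180 um) zonation profiles.
    """
    panel: list[GeneSpec] = []
    scales = [60.0, 90.0, 120.0, 150.0, 180.0]
    for i, lam in enumerate(scales, 1):
        panel.append(GeneSpec(f"gradc_{i}", "gradient-central", length_scale_um=lam))
        panel.append(GeneSpec(f"gradp_{i}", "gradient-portal", length_scale_um=lam))
    for i in range(1, 6):
        panel.append(GeneSpec(f"compc_{i}", "compartment-central", radius_um=150.0))
        panel.append(GeneSpec(f"compp_{i}", "compartment-portal", radius_um=150.0))
    for i in range(1, 11):
        panel.append(GeneSpec(f"flat_{i}", "flat", amplitude=2.0))
    for i in range(1, 6):
        panel.append(GeneSpec(f"region_{i}", "region", radius_um=150.0))
    return panel


DEFAULT_CELL_TYPES = (
    "pericentral-hepatocyte",
    "periportal-hepatocyte",
    "mid-hepatocyte",
    "endothelial",
    "kupffer",
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Geometry defaults follow the spotted-array layout (1000-spot-class frames
    of 6,200 x 6,400 um, 150/200 um pitches, 100 um spots, 400 um = 142 px);
    vein counts and radii give a lobule-scale vein spacing. ``n_rows`` /
    ``n_cols`` cap the lattice; by default the frame extent alone decides.
    """

    # lattice
    n_rows: int | None = None
    n_cols: int | None = None
    same_row_pitch: float = 200.0
    neighbor_pitch: float = 150.0
    spot_diameter: float = 100.0
    frame_extent: tuple[float, float] = (6200.0, 6400.0)
    scale: float = DEFAULT_SCALE_UM_PER_PX
    # sections / samples
    n_samples: int = 3
    sections_per_sample: int = 2
    # veins: density matches lobular anatomy (lobule radius a few hundred um),
    # so most spots lie within ~400 um of both vein types
    n_central: int = 18
    n_portal: int = 18
    n_ambiguous: int = 0
    vein_radius_um: float = 60.0
    min_separation_um: float = 400.0
    # capsule-like region: polygon in um coordinates. The default (set in
    # __post_init__) is a strip along the left frame edge, emulating the
    # collagen-rich capsule at the tissue boundary; pass False to disable.
    capsule_region: list[tuple[float, float]] | None | bool = None
    # expression
    gene_panel: list[GeneSpec] = field(default_factory=default_gene_panel)
    depth_log_mean: float = math.log(500.0)
    depth_log_sd: float = 0.35
    nb_dispersion: float = 2.0
    # proportions
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    prop_base_conc: float = 2.0
    prop_amplitude: float = 8.0
    prop_length_scale_um: float = 150.0
    # cluster-label radii
    pericentral_radius_um: float = 150.0
    periportal_radius_um: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.same_row_pitch <= 0 or self.neighbor_pitch <= 0:
            raise ValueError("pitches must be positive")
        if not self.neighbor_pitch <= self.same_row_pitch:
            raise ValueError("require 0 < neighbor_pitch <= same_row_pitch")
        if min(self.n_central, self.n_portal, self.n_ambiguous) < 0:
            raise ValueError("vein counts must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive (use inf for Poisson)")
        if self.capsule_region is None:
            ext_x, ext_y = self.frame_extent
            width = min(500.0, 0.25 * ext_x)
            self.capsule_region = [(0.0, 0.0), (width, 0.0), (width, ext_y), (0.0, ext_y)]
        elif self.capsule_region is False:
            self.capsule_region = None

    @property
    def row_step_um(self) -> float:
        """Vertical spacing between consecutive (offset) rows."""
        return math.sqrt(self.neighbor_pitch**2 - (self.same_row_pitch / 2.0) ** 2)

    @property
    def image_shape(self) -> tuple[int, int]:
        w = int(math.ceil(self.frame_extent[0] / self.scale))
        h = int(math.ceil(self.frame_extent[1] / self.scale))
        return (w, h)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["gene_panel"] = [dataclasses.asdict(g) for g in self.gene_panel]
        if d["capsule_region"] is None:
            d["capsule_region"] = False  # survives the round trip as "disabled"
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["gene_panel"] = [GeneSpec(**g) for g in d["gene_panel"]]
        for key in ("frame_extent", "cell_types"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("capsule_region") is not None:
            d["capsule_region"] = [tuple(p) for p in d["capsule_region"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------


def generate_frame(
    config: SimulationConfig, section_id: str = "S1", sample_id: str = "A"
) -> SpotArray:
    """Lay out one frame of spots on the offset lattice.

    Within a row, centers sit ``same_row_pitch`` apart; consecutive rows are
    shifted by half that pitch horizontally and by
    ``sqrt(neighbor_pitch^2 - (same_row_pitch/2)^2)`` vertically, so the
    nearest-neighbour center distance equals ``neighbor_pitch`` (150 um by
    default, 200 um within a row).
    """
    ext_x, ext_y = config.frame_extent
    margin = config.spot_diameter / 2.0
    step_y = config.row_step_um
    rows = []
    r = 0
    y = margin
    while y <= ext_y - margin + 1e-9:
        if config.n_rows is not None and r >= config.n_rows:
            break
        x0 = margin + (r % 2) * (config.same_row_pitch / 2.0)
        xs = np.arange(x0, ext_x - margin + 1e-9, config.same_row_pitch)
        if config.n_cols is not None:
            xs = xs[: config.n_cols]
        for c, x in enumerate(xs):
            rows.append((f"{section_id}:{r}x{c}", x, y, r, c))
        r += 1
        y = margin + r * step_y
    if not rows:
        raise ValueError("frame extent too small to fit a single spot")
    df = pd.DataFrame(rows, columns=["spot_id", "x_um", "y_um", "row", "col"])
    spots = pd.DataFrame(
        {
            "spot_id": df["spot_id"],
            "x_px": df["x_um"] / config.scale,
            "y_px": df["y_um"] / config.scale,
            "section_id": section_id,
            "sample_id": sample_id,
        }
    )
    return SpotArray(spots, config.scale, config.spot_diameter)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def _circle_polygon(cx: float, cy: float, radius: float, n: int = 64) -> list[list[float]]:
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = [[cx + radius * math.cos(a), cy + radius * math.sin(a)] for a in ang]
    ring.append(ring[0])
    return ring


def place_structures(
    config: SimulationConfig,
    rng: np.random.Generator,
    id_start: int = 1,
    max_tries: int = 5000,
):
    """Sample non-overlapping circular vein masks for one section.

    Returns ``(maskset, true_classes, geojson)``: the pixel masks with their
    *annotated* labels (ambiguous veins are labelled "ambiguous"), the hidden
    true class of every structure, and a GeoJSON FeatureCollection of the
    vein outlines in pixel coordinates.
    """
    n_total = config.n_central + config.n_portal + config.n_ambiguous
    if n_total == 0:
        raise ValueError("no structures requested")
    ext_x, ext_y = config.frame_extent
    r = config.vein_radius_um
    if 2 * r >= min(ext_x, ext_y):
        raise ValueError("vein radius does not fit in the frame")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_total:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_total} veins with separation "
                f"{config.min_separation_um} um in {max_tries} tries; "
                "reduce counts, radius or separation"
            )
        tries += 1
        cx = rng.uniform(r, ext_x - r)
        cy = rng.uniform(r, ext_y - r)
        if all((cx - px) ** 2 + (cy - py) ** 2 >= config.min_separation_um**2 for px, py in centers):
            centers.append((cx, cy))
    true = ["central"] * config.n_central + ["portal"] * config.n_portal
    amb_true = ["central" if i % 2 == 0 else "portal" for i in range(config.n_ambiguous)]
    labels = true + ["ambiguous"] * config.n_ambiguous
    true = true + amb_true

    w, h = config.image_shape
    structures, features = [], []
    true_classes: dict[int, str] = {}
    r_px = r / config.scale
    for i, ((cx, cy), lab, tru) in enumerate(zip(centers, labels, true)):
        sid = id_start + i
        cx_px, cy_px = cx / config.scale, cy / config.scale
        x0 = max(int(math.floor(cx_px - r_px)), 0)
        x1 = min(int(math.ceil(cx_px + r_px)), w - 1)
        y0 = max(int(math.floor(cy_px - r_px)), 0)
        y1 = min(int(math.ceil(cy_px + r_px)), h - 1)
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        inside = (xs - cx_px) ** 2 + (ys - cy_px) ** 2 <= r_px**2
        pixels = np.column_stack([xs[inside], ys[inside]])
        structures.append(Structure(sid, lab, pixels))
        true_classes[sid] = tru
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [_circle_polygon(cx_px, cy_px, r_px)],
                },
                "properties": {"structure_id": sid, "class": lab},
            }
        )
    if config.capsule_region is not None:
        sid = id_start + n_total
        ring_px = [[x / config.scale, y / config.scale] for x, y in config.capsule_region]
        if ring_px[0] != ring_px[-1]:
            ring_px.append(ring_px[0])
        capsule_set = rasterize_structures(
            [(sid, "region", shapely.Polygon(ring_px))], config.image_shape
        )
        structures.append(capsule_set.structures[0])
        true_classes[sid] = "region"
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring_px]},
                "properties": {"structure_id": sid, "class": "region"},
            }
        )
    maskset = StructureMaskSet(structures, config.image_shape)
    geojson = {"type": "FeatureCollection", "features": features}
    return maskset, true_classes, geojson


def true_class_distances(
    spot_array: SpotArray, maskset: StructureMaskSet, true_classes: dict[int, str]
) -> pd.DataFrame:
    """Per-spot distance (um) to each *true* structure class.

    Ambiguous annotations are resolved to their hidden class, so this is the
    ground-truth distance field the expression model is driven by.
    """
    pts = spot_array.coords_px()
    idx = pd.Index(spot_array.spot_ids, name="spot_id")
    cols = {}
    for cls in sorted(set(true_classes.values())):
        pix = np.concatenate(
            [s.pixels for s in maskset.structures if true_classes[s.structure_id] == cls]
        )
        cols[cls] = px_to_um(_min_distance_px(pts, pix), spot_array.scale)
    return pd.DataFrame(cols, index=idx)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def noiseless_means(gene_panel: list[GeneSpec], distances: pd.DataFrame) -> pd.DataFrame:
    """Noiseless mean expression (genes x spots) from the zonation archetypes.

    ``distances`` holds per-spot true-class distances in um (columns among
    ``central``, ``portal``, ``region``).
    """
    out = {}
    for g in gene_panel:
        if g.archetype == "flat":
            m = np.full(len(distances), g.amplitude)
        elif g.archetype.startswith("gradient"):
            cls = g.archetype.split("-")[1]
            d = _require_distance(distances, cls, g)
            m = g.baseline + (g.amplitude - g.baseline) * np.exp(-d / g.length_scale_um)
        elif g.archetype.startswith("compartment"):
            cls = g.archetype.split("-")[1]
            d = _require_distance(distances, cls, g)
            m = np.where(d <= g.radius_um, g.amplitude, g.baseline)
        else:  # region
            d = _require_distance(distances, "region", g)
            m = np.where(d <= g.radius_um, g.amplitude, g.baseline)
        out[g.gene_id] = m
    return pd.DataFrame(out, index=distances.index).T


def _require_distance(distances: pd.DataFrame, cls: str, g: GeneSpec) -> np.ndarray:
    if cls not in distances.columns:
        raise ValueError(
            f"gene {g.gene_id!r} ({g.archetype}) needs a {cls!r} distance field "
            "but none is available"
        )
    return distances[cls].to_numpy(float)


def simulate_expression(
    spot_array: SpotArray,
    maskset: StructureMaskSet | None,
    true_classes: dict[int, str] | None,
    gene_panel: list[GeneSpec],
    depth_log_mean: float,
    depth_log_sd: float,
    nb_dispersion: float,
    rng: np.random.Generator,
    distances: pd.DataFrame | None = None,
):
    """Draw counts for a spot array and return the matrix plus ground truth.

    Counts for spot ``s`` and gene ``g`` are negative binomial with mean
    ``depth_s * m_sg / sum_g m_sg`` (``depth_s`` lognormal) and dispersion
    ``nb_dispersion`` (variance ``mu + mu^2/dispersion``; ``inf`` switches to
    Poisson). The normalized layer is ``log(1 + count * median(depth)/depth_s)``.

    Returns ``(ExpressionMatrix, means, depths)``.
    """
    if distances is None:
        if maskset is None or true_classes is None:
            raise ValueError("need either precomputed distances or maskset + true classes")
        distances = true_class_distances(spot_array, maskset, true_classes)
    means = noiseless_means(gene_panel, distances)
    totals = means.sum(axis=0).to_numpy(float)
    if np.any(totals <= 0):
        raise ValueError("zero total noiseless mean in at least one spot")
    n_spots = len(spot_array)
    depths = rng.lognormal(depth_log_mean, depth_log_sd, size=n_spots)
    mu = means.to_numpy(float) / totals[None, :] * depths[None, :]
    if math.isinf(nb_dispersion):
        counts = rng.poisson(mu)
    else:
        p = nb_dispersion / (nb_dispersion + mu)
        counts = rng.negative_binomial(nb_dispersion, p)
    counts_df = pd.DataFrame(counts, index=means.index, columns=means.columns)
    norm = np.log1p(counts * (np.median(depths) / depths)[None, :])
    norm_df = pd.DataFrame(norm, index=means.index, columns=means.columns)
    depths_s = pd.Series(depths, index=means.columns, name="depth")
    return ExpressionMatrix(counts_df, norm_df), means, depths_s


def simulate_proportions(
    spot_array: SpotArray,
    distances: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Dirichlet cell-type proportions zonated toward the planted veins.

    Concentrations start at ``prop_base_conc`` per type; the pericentral
    (resp. periportal) hepatocyte concentration is boosted by
    ``prop_amplitude * exp(-d/prop_length_scale_um)`` of the matching vein
    distance. Returns ``(proportions, expected)`` with rows on the simplex.
    """
    types = list(config.cell_types)
    if len(types) < 1:
        raise ValueError("need at least one cell type")
    n = len(spot_array)
    idx = pd.Index(spot_array.spot_ids, name="spot_id")
    conc = np.full((n, len(types)), config.prop_base_conc, dtype=float)
    for j, t in enumerate(types):
        if t == "pericentral-hepatocyte" and "central" in distances.columns:
            conc[:, j] += config.prop_amplitude * np.exp(
                -distances["central"].to_numpy(float) / config.prop_length_scale_um
            )
        elif t == "periportal-hepatocyte" and "portal" in distances.columns:
            conc[:, j] += config.prop_amplitude * np.exp(
                -distances["portal"].to_numpy(float) / config.prop_length_scale_um
            )
    if len(types) == 1:
        props = np.ones((n, 1))
    else:
        gam = rng.gamma(conc)
        props = gam / gam.sum(axis=1, keepdims=True)
    expected = conc / conc.sum(axis=1, keepdims=True)
    return (
        pd.DataFrame(props, index=idx, columns=types),
        pd.DataFrame(expected, index=idx, columns=types),
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must rediscover."""

    structure_classes: dict[int, str]
    gene_panel: list[GeneSpec]
    means: pd.DataFrame  # genes x spots, noiseless
    cluster_labels: pd.Series  # per spot: pericentral/periportal/mid/region
    expected_proportions: pd.DataFrame
    true_distances: pd.DataFrame  # spots x true classes, um
    depths: pd.Series


@dataclass
class SyntheticDataset:
    """One fully simulated multi-section ST dataset plus its ground truth."""

    config: SimulationConfig
    spots: SpotArray
    masks: dict[str, StructureMaskSet]  # per section
    annotations: dict[str, dict]  # per section GeoJSON
    expression: ExpressionMatrix
    proportions: pd.DataFrame
    distances: DistanceTable  # from *annotated* labels (ambiguous excluded)
    truth: GroundTruth

    @property
    def cluster_labels(self) -> pd.Series:
        return self.truth.cluster_labels


def _cluster_labels(distances: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    d_c = distances["central"].to_numpy(float)
    d_p = distances["portal"].to_numpy(float)
    lab = np.where(
        (d_c <= config.pericentral_radius_um) & (d_c <= d_p),
        "pericentral",
        np.where((d_p <= config.periportal_radius_um) & (d_p < d_c), "periportal", "mid"),
    )
    if "region" in distances.columns:
        # inside the capsule mask up to one pixel of rasterization slack
        lab = np.where(distances["region"].to_numpy(float) <= config.scale, "region", lab)
    return pd.Series(lab, index=distances.index, name="cluster")


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a seeded multi-sample, multi-section dataset with ground truth."""
    rng = np.random.default_rng(config.seed)
    spot_frames, masks, annotations = [], {}, {}
    true_classes: dict[int, str] = {}
    true_dist_frames = []
    next_id = 1
    for i in range(config.n_samples):
        sample_id = f"sample{i + 1}"
        for j in range(config.sections_per_sample):
            section_id = f"{sample_id}_sec{j + 1}"
            frame = generate_frame(config, section_id=section_id, sample_id=sample_id)
            maskset, tc, geo = place_structures(config, rng, id_start=next_id)
            next_id += len(maskset.structures)
            true_classes.update(tc)
            masks[section_id] = maskset
            annotations[section_id] = geo
            spot_frames.append(frame.spots)
            true_dist_frames.append(true_class_distances(frame, maskset, tc))
    spots = SpotArray(pd.concat(spot_frames, ignore_index=True), config.scale, config.spot_diameter)
    true_dist = pd.concat(true_dist_frames)

    expr, means, depths = simulate_expression(
        spots,
        None,
        None,
        config.gene_panel,
        config.depth_log_mean,
        config.depth_log_sd,
        config.nb_dispersion,
        rng,
        distances=true_dist,
    )
    props, expected = simulate_proportions(spots, true_dist, config, rng)
    clusters = _cluster_labels(true_dist, config)

    # distances as an analyst would compute them: from the annotated labels
    annotated_tables = []
    for section_id, maskset in masks.items():
        sub = spots.section(section_id)
        classes = [c for c in ("central", "portal", "region") if c in maskset.classes]
        annotated_tables.append(build_distance_table(sub, maskset, classes=classes))
    dist_table = annotated_tables[0]
    for t in annotated_tables[1:]:
        dist_table = dist_table.concat(t)

    truth = GroundTruth(true_classes, config.gene_panel, means, clusters, expected, true_dist, depths)
    return SyntheticDataset(config, spots, masks, annotations, expr, props, dist_table, truth)


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, directory: str | os.PathLike) -> None:
    """Write the dataset in plain-text exchange formats.

    Emits spots TSV, counts MTX (+ gene/barcode TSVs) and normalized TSV,
    per-section GeoJSON annotations, proportions TSV, cluster-label TSV,
    a ground-truth JSON and the seeded config. Matrices round-trip exactly.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    dataset.spots.to_tsv(os.path.join(directory, "spots.tsv"))
    dataset.expression.write(directory)
    for section_id, geo in dataset.annotations.items():
        with open(os.path.join(directory, f"annotations_{section_id}.geojson"), "w") as fh:
            json.dump(geo, fh)
    dataset.proportions.to_csv(os.path.join(directory, "proportions.tsv"), sep="\t")
    dataset.cluster_labels.to_frame().to_csv(os.path.join(directory, "clusters.tsv"), sep="\t")
    dataset.distances.to_tsv(os.path.join(directory, "distances.tsv"))
    truth = dataset.truth
    with open(os.path.join(directory, "ground_truth.json"), "w") as fh:
        json.dump(
            {
                "structure_classes": {str(k): v for k, v in truth.structure_classes.items()},
                "gene_panel": [dataclasses.asdict(g) for g in truth.gene_panel],
            },
            fh,
            indent=1,
        )
    truth.means.to_csv(os.path.join(directory, "true_means.tsv"), sep="\t")
    truth.true_distances.to_csv(os.path.join(directory, "true_distances.tsv"), sep="\t")
    with open(os.path.join(directory, "config.json"), "w") as fh:
        fh.write(dataset.config.to_json())


def read_dataset(directory: str | os.PathLike):
    """Read back the core tables written by :func:`write_dataset`.

    Returns a dict with the spots, expression matrix, proportions, cluster
    labels, distance table and config.
    """
    directory = os.fspath(directory)
    with open(os.path.join(directory, "config.json")) as fh:
        config = SimulationConfig.from_json(fh.read())
    spots = SpotArray.from_tsv(os.path.join(directory, "spots.tsv"), scale=config.scale)
    expr = ExpressionMatrix.read(directory)
    props = pd.read_csv(os.path.join(directory, "proportions.tsv"), sep="\t", index_col="spot_id")
    clusters = pd.read_csv(os.path.join(directory, "clusters.tsv"), sep="\t", index_col="spot_id")["cluster"]
    distances = DistanceTable.from_tsv(os.path.join(directory, "distances.tsv"))
    return {
        "config": config,
        "spots": spots,
        "expression": expr,
        "proportions": props,
        "cluster_labels": clusters,
        "distances": distances,
    }
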