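"""Spot arrays, structure masks and spot-to-structure distances.

Distances are the backbone of every zonation analysis in this package: the
distance from a capture spot to an anatomical structure (e.g. a central or
portal vein) is the minimal Euclidean distance from the spot center to any
pixel of the structure's mask, computed in pixel space and converted to
micrometers with the array's pixel calibration (default 400 um = 142 px).
The distance to a *class* of structures (all central veins, say) is the
minimum over the union of the class's masks; a spot sitting on a mask pixel
has distance zero.

Coordinate convention: 0-based pixel indices, x rightward, y downward, pixel
centers at integer coordinates; spot centers may be fractional.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

#: pixel calibration printed on the arrays this package targets: 400 um = 142 px
DEFAULT_SCALE_UM_PER_PX: float = 400.0 / 142.0
#: capture-spot diameter in micrometers
DEFAULT_SPOT_DIAMETER_UM: float = 100.0

#: recognised structure class labels
STRUCTURE_CLASSES = ("central", "portal", "ambiguous", "region")

#: sentinel recorded for distances beyond a requested cap
BEYOND_CAP = np.inf


def px_to_um(d_px, scale: float = DEFAULT_SCALE_UM_PER_PX):
    """Convert a pixel distance to micrometers.

    Raises ``ValueError`` for negative distances or non-positive scale.
    """
    d_px = np.asarray(d_px, dtype=float)
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if np.any(d_px < 0):
        raise ValueError("pixel distance must be non-negative")
    out = d_px * scale
    return float(out) if out.ndim == 0 else out


def um_to_px(d_um, scale: float = DEFAULT_SCALE_UM_PER_PX, as_int: bool = False):
    """Convert a micrometer distance to pixels; round to nearest int on request."""
    d_um = np.asarray(d_um, dtype=float)
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if np.any(d_um < 0):
        raise ValueError("distance must be non-negative")
    out = d_um / scale
    if as_int:
        out = np.rint(out).astype(int)
        return int(out) if out.ndim == 0 else out
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpotArray:
    """Capture spots of one or more array sections.

    ``spots`` holds one row per spot with columns
    ``spot_id, x_px, y_px, section_id, sample_id``.
    """

    spots: pd.DataFrame
    scale: float = DEFAULT_SCALE_UM_PER_PX
    spot_diameter: float = DEFAULT_SPOT_DIAMETER_UM

    REQUIRED_COLUMNS = ("spot_id", "x_px", "y_px", "section_id", "sample_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.spots["spot_id"].duplicated().any():
            dup = self.spots["spot_id"][self.spots["spot_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate spot_id: {dup!r}")
        xy = self.spots[["x_px", "y_px"]].to_numpy(float)
        if not np.all(np.isfinite(xy)) or np.any(xy < 0):
            raise ValueError("spot coordinates must be finite and non-negative")
        self.spots = self.spots.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def spot_ids(self) -> pd.Series:
        return self.spots["spot_id"]

    def coords_px(self) -> np.ndarray:
        return self.spots[["x_px", "y_px"]].to_numpy(float)

    def coords_um(self) -> np.ndarray:
        return self.coords_px() * self.scale

    def section(self, section_id: str) -> "SpotArray":
        sub = self.spots[self.spots["section_id"] == section_id]
        if sub.empty:
            raise KeyError(f"no spots in section {section_id!r}")
        return SpotArray(sub.copy(), self.scale, self.spot_diameter)

    @property
    def section_ids(self) -> list[str]:
        return list(pd.unique(self.spots["section_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.spots["sample_id"]))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.spots.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | os.PathLike,
        scale: float = DEFAULT_SCALE_UM_PER_PX,
        spot_diameter: float = DEFAULT_SPOT_DIAMETER_UM,
    ) -> "SpotArray":
        df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "section_id": str, "sample_id": str})
        return cls(df, scale, spot_diameter)


@dataclass
class Structure:
    """One annotated structure: an integer id, a class label and a pixel mask."""

    structure_id: int
    class_label: str
    pixels: np.ndarray  # (n, 2) integer pixel positions (x, y)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        if len(self.pixels) == 0:
            raise ValueError(f"structure {self.structure_id} has an empty mask")


@dataclass
class StructureMaskSet:
    """Labelled pixel masks for the annotated structures of one section."""

    structures: list[Structure]
    image_shape: tuple[int, int]  # (width, height) in pixels

    def __post_init__(self) -> None:
        ids = [s.structure_id for s in self.structures]
        if len(ids) != len(set(ids)):
            raise ValueError("structure ids are not unique")
        w, h = self.image_shape
        for s in self.structures:
            if np.any(s.pixels[:, 0] < 0) or np.any(s.pixels[:, 0] >= w) or np.any(
                s.pixels[:, 1] < 0
            ) or np.any(s.pixels[:, 1] >= h):
                raise ValueError(f"structure {s.structure_id} has pixels outside image {self.image_shape}")

    def __len__(self) -> int:
        return len(self.structures)

    @property
    def classes(self) -> list[str]:
        return sorted({s.class_label for s in self.structures})

    def by_class(self, class_label: str) -> list[Structure]:
        out = [s for s in self.structures if s.class_label == class_label]
        if not out:
            raise KeyError(f"no structures of class {class_label!r}")
        return out

    def get(self, structure_id: int) -> Structure:
        for s in self.structures:
            if s.structure_id == structure_id:
                return s
        raise KeyError(f"no structure with id {structure_id}")

    def class_union_pixels(self, class_label: str) -> np.ndarray:
        return np.concatenate([s.pixels for s in self.by_class(class_label)], axis=0)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize_structures(
    annotations,
    image_shape: tuple[int, int],
) -> StructureMaskSet:
    """Rasterize polygon annotations into pixel masks.

    ``annotations`` is either a GeoJSON FeatureCollection dict (each feature a
    Polygon with properties ``structure_id`` and ``class``) or a list of
    ``(structure_id, class_label, shapely_polygon)`` triples. A pixel belongs
    to a structure when its center lies inside the (cleaned) polygon.
    """
    w, h = image_shape
    if w <= 0 or h <= 0:
        raise ValueError("image_shape must be positive")
    triples = _as_polygon_triples(annotations)
    structures = []
    for sid, label, poly in triples:
        poly = shapely.make_valid(poly)
        minx, miny, maxx, maxy = poly.bounds
        x0 = max(int(np.floor(minx)), 0)
        y0 = max(int(np.floor(miny)), 0)
        x1 = min(int(np.ceil(maxx)), w - 1)
        y1 = min(int(np.ceil(maxy)), h - 1)
        if x1 < x0 or y1 < y0:
            raise ValueError(f"structure {sid} lies entirely outside the image")
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel())
        if not inside.any():
            raise ValueError(f"structure {sid} rasterizes to an empty mask")
        pixels = np.column_stack([xs.ravel()[inside], ys.ravel()[inside]])
        structures.append(Structure(int(sid), str(label), pixels))
    return StructureMaskSet(structures, image_shape)


def _as_polygon_triples(annotations):
    if isinstance(annotations, dict) and annotations.get("type") == "FeatureCollection":
        triples = []
        for feat in annotations["features"]:
            props = feat.get("properties", {})
            geom = shapely.geometry.shape(feat["geometry"])
            triples.append((props["structure_id"], props["class"], geom))
        return triples
    return list(annotations)


def load_geojson(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def masks_from_label_image(labels: np.ndarray, class_map: dict) -> StructureMaskSet:
    """Build a mask set from an integer label image plus a ``{label: class}`` map.

    The image is indexed ``labels[y, x]``; label 0 is background.
    """
    labels = np.asarray(labels)
    structures = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        cls = class_map.get(int(lab)) or class_map.get(str(int(lab)))
        if cls is None:
            raise KeyError(f"label {lab} missing from class map")
        ys, xs = np.nonzero(labels == lab)
        structures.append(Structure(int(lab), str(cls), np.column_stack([xs, ys])))
    return StructureMaskSet(structures, (labels.shape[1], labels.shape[0]))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _min_distance_px(points_px: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """Exact minimal Euclidean distance (px) from each point to a pixel set."""
    tree = cKDTree(pixels.astype(float))
    d, _ = tree.query(np.atleast_2d(points_px))
    return d


def spot_structure_distance(
    spot_xy_px, structure: Structure, scale: float = DEFAULT_SCALE_UM_PER_PX
) -> float:
    """Minimal distance (um) from a spot center to any pixel of one structure."""
    d = _min_distance_px(np.asarray(spot_xy_px, float).reshape(1, 2), structure.pixels)
    return px_to_um(float(d[0]), scale)


def spot_class_distance(
    spot_xy_px,
    class_label: str,
    maskset: StructureMaskSet,
    scale: float = DEFAULT_SCALE_UM_PER_PX,
) -> float:
    """Minimal distance (um) from a spot center to the union of a class's masks."""
    pixels = maskset.class_union_pixels(class_label)
    d = _min_distance_px(np.asarray(spot_xy_px, float).reshape(1, 2), pixels)
    return px_to_um(float(d[0]), scale)


@dataclass
class DistanceTable:
    """Per-spot minimal distances (um) to structure classes and structures.

    ``class_distances``: spots x class labels; ``structure_distances``:
    spots x structure ids (optional). Distances beyond a requested cap are
    recorded as ``inf``.
    """

    class_distances: pd.DataFrame
    structure_distances: pd.DataFrame | None = None
    cap_um: float | None = None

    def __post_init__(self) -> None:
        if (self.class_distances.to_numpy(float) < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def spot_ids(self) -> pd.Index:
        return self.class_distances.index

    def to_class(self, class_label: str) -> pd.Series:
        if class_label not in self.class_distances.columns:
            raise KeyError(f"class {class_label!r} not in distance table")
        return self.class_distances[class_label]

    def to_structure(self, structure_id: int) -> pd.Series:
        if self.structure_distances is None:
            raise ValueError("structure distances were not computed")
        return self.structure_distances[structure_id]

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.class_distances.to_csv(path, sep="\t", index_label="spot_id")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DistanceTable":
        df = pd.read_csv(path, sep="\t", index_col="spot_id")
        df.index = df.index.astype(str)
        return cls(df)

    def concat(self, other: "DistanceTable") -> "DistanceTable":
        cd = pd.concat([self.class_distances, other.class_distances])
        sd = None
        if self.structure_distances is not None and other.structure_distances is not None:
            sd = pd.concat([self.structure_distances, other.structure_distances])
        return DistanceTable(cd, sd, self.cap_um)


def build_distance_table(
    spot_array: SpotArray,
    maskset: StructureMaskSet,
    classes=None,
    cap_um: float | None = None,
    include_structures: bool = False,
) -> DistanceTable:
    """Distances from every spot to every requested class (and structure).

    Each class distance is the min over the union of that class's mask pixels
    (exact nearest-neighbour query, equivalent to the brute-force definition).
    With ``cap_um`` given, entries beyond the cap become ``inf``.
    """
    if len(spot_array) == 0:
        raise ValueError("empty spot array")
    if classes is None:
        classes = maskset.classes
    missing = [c for c in classes if c not in maskset.classes]
    if missing:
        raise KeyError(f"classes not present in mask set: {missing}")
    pts = spot_array.coords_px()
    idx = pd.Index(spot_array.spot_ids, name="spot_id")
    cls_cols = {}
    for c in classes:
        d_um = px_to_um(_min_distance_px(pts, maskset.class_union_pixels(c)), spot_array.scale)
        cls_cols[c] = d_um
    class_df = pd.DataFrame(cls_cols, index=idx)
    struct_df = None
    if include_structures:
        st_cols = {}
        for s in maskset.structures:
            st_cols[s.structure_id] = px_to_um(_min_distance_px(pts, s.pixels), spot_array.scale)
        struct_df = pd.DataFrame(st_cols, index=idx)
    if cap_um is not None:
        class_df = class_df.where(class_df <= cap_um, BEYOND_CAP)
        if struct_df is not None:
            struct_df = struct_df.where(struct_df <= cap_um, BEYOND_CAP)
    return DistanceTable(class_df, struct_df, cap_um)
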