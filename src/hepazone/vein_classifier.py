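"""Neighborhood expression profiles and vein-type classification.

A structure's neighborhood is the set of spots strictly closer than a
threshold T_N (default 400 um = 142 px, the span of three consecutive
same-row spot centers). Its neighborhood expression profile (NEP) is the
weighted mean expression of a marker panel over that neighborhood, with
weights exp(-d_px / sigma) (sigma = 20 px by default) normalized to sum to
one. Labelled NEPs (central vs portal) train an L2-penalized logistic
regression (regularization strength 1, up to 1000 iterations); ambiguous
veins are then assigned soft class probabilities P(central) / P(portal).

Class orientation is fixed by sorting labels lexicographically: "central" is
class 1, "portal" class 2, so p_t = P(portal) and the hard label is central
when p_t <= 0.5 (the tie goes to class 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .array_geometry import (
    DEFAULT_SCALE_UM_PER_PX,
    SpotArray,
    StructureMaskSet,
    _min_distance_px,
    px_to_um,
)
from .core import ExpressionMatrix

DEFAULT_T_N_UM = 400.0
DEFAULT_SIGMA_PX = 20.0


@dataclass
class NeighborhoodProfile:
    """Distance-weighted mean marker expression around one structure."""

    structure_id: int
    class_label: str
    values: pd.Series  # indexed by panel gene
    n_neighbors: int
    t_n_um: float
    t_n_px: float
    sigma_px: float
    section_id: str | None = None
    sample_id: str | None = None


def neighborhood_profile(
    structure_id: int,
    class_label: str,
    spot_distances_um: pd.Series,
    expr_panel: pd.DataFrame,
    scale: float = DEFAULT_SCALE_UM_PER_PX,
    t_n_um: float = DEFAULT_T_N_UM,
    sigma_px: float = DEFAULT_SIGMA_PX,
    section_id: str | None = None,
    sample_id: str | None = None,
) -> NeighborhoodProfile:
    """Build one NEP from per-spot distances (um) to the structure.

    ``expr_panel`` is genes x spots (normalized layer); the neighborhood is
    the set of spots with distance strictly below ``t_n_um``; weights are
    exp(-d_px / sigma_px), normalized over the neighborhood.
    """
    common = spot_distances_um.index.intersection(expr_panel.columns)
    d = spot_distances_um.loc[common]
    nbr = d[d < t_n_um]
    if len(nbr) == 0:
        raise ValueError(f"structure {structure_id} has an empty neighborhood (T_N={t_n_um} um)")
    d_px = nbr.to_numpy(float) / scale
    # shifting by the minimum distance leaves the normalized weights unchanged
    # but keeps exp() from underflowing for small sigma
    w_hat = np.exp(-(d_px - d_px.min()) / sigma_px)
    w = w_hat / w_hat.sum()
    profile = expr_panel[nbr.index].to_numpy(float) @ w
    return NeighborhoodProfile(
        structure_id,
        class_label,
        pd.Series(profile, index=expr_panel.index),
        len(nbr),
        t_n_um,
        t_n_um / scale,
        sigma_px,
        section_id,
        sample_id,
    )


def neighborhood_profiles(
    spots: SpotArray,
    masks: dict[str, StructureMaskSet],
    expr: ExpressionMatrix,
    panel,
    layer: str = "normalized",
    t_n_um: float = DEFAULT_T_N_UM,
    sigma_px: float = DEFAULT_SIGMA_PX,
    skip_empty: bool = False,
) -> list[NeighborhoodProfile]:
    """NEPs for every structure of every section.

    ``masks`` maps section id to that section's mask set; only spots of the
    structure's own section enter its neighborhood. Structures with empty
    neighborhoods raise unless ``skip_empty``.
    """
    mat = expr.layer(layer)
    missing = [g for g in panel if g not in mat.index]
    if missing:
        raise KeyError(f"panel genes missing from expression matrix: {missing}")
    mat = mat.loc[list(panel)]
    out = []
    for section_id, maskset in masks.items():
        sub = spots.section(section_id)
        sample_id = sub.spots["sample_id"].iloc[0]
        pts = sub.coords_px()
        idx = pd.Index(sub.spot_ids)
        for s in maskset.structures:
            d_um = pd.Series(px_to_um(_min_distance_px(pts, s.pixels), spots.scale), index=idx)
            try:
                out.append(
                    neighborhood_profile(
                        s.structure_id,
                        s.class_label,
                        d_um,
                        mat,
                        scale=spots.scale,
                        t_n_um=t_n_um,
                        sigma_px=sigma_px,
                        section_id=section_id,
                        sample_id=sample_id,
                    )
                )
            except ValueError:
                if not skip_empty:
                    raise
    return out


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


@dataclass
class VeinClassifierModel:
    """Fitted logistic vein-type classifier over a marker panel."""

    coefficients: pd.Series  # over the panel
    intercept: float
    panel: list[str]
    classes: tuple[str, str]  # (class 1, class 2) = lexicographic order
    regularization: str = "l2"
    C: float = 1.0
    max_iter: int = 1000
    converged: bool = True
    training_sections: list[str] = field(default_factory=list)
    training_samples: list[str] = field(default_factory=list)

    def decision(self, values: pd.Series) -> float:
        x = values.reindex(self.panel)
        if x.isna().any():
            missing = list(x.index[x.isna()])
            raise KeyError(f"profile missing panel genes: {missing}")
        return float(self.coefficients @ x.to_numpy(float) + self.intercept)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "panel": self.panel,
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "classes": list(self.classes),
                "regularization": self.regularization,
                "C": self.C,
                "max_iter": self.max_iter,
                "converged": self.converged,
                "training_sections": self.training_sections,
                "training_samples": self.training_samples,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "VeinClassifierModel":
        import json

        d = json.loads(text)
        return cls(
            pd.Series(d["coefficients"], index=d["panel"]),
            d["intercept"],
            d["panel"],
            tuple(d["classes"]),
            d["regularization"],
            d["C"],
            d["max_iter"],
            d["converged"],
            d["training_sections"],
            d["training_samples"],
        )


def fit_vein_classifier(
    profiles: list[NeighborhoodProfile],
    C: float = 1.0,
    max_iter: int = 1000,
) -> VeinClassifierModel:
    """L2-penalized logistic regression on labelled (central/portal) NEPs."""
    labelled = [p for p in profiles if p.class_label in ("central", "portal")]
    if not labelled:
        raise ValueError("no labelled (central/portal) profiles to train on")
    labels = {p.class_label for p in labelled}
    if len(labels) < 2:
        raise ValueError(f"training needs both classes, found only {sorted(labels)}")
    for cls in ("central", "portal"):
        if sum(p.class_label == cls for p in labelled) < 2:
            warnings.warn(f"fewer than 2 training structures of class {cls!r}", stacklevel=2)
    panel = list(labelled[0].values.index)
    X = np.stack([p.values.reindex(panel).to_numpy(float) for p in labelled])
    y = np.array([p.class_label for p in labelled])
    clf = LogisticRegression(penalty="l2", C=C, max_iter=max_iter)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X, y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # sklearn orders classes lexicographically: classes_ = [central, portal]
    classes = tuple(clf.classes_)
    return VeinClassifierModel(
        pd.Series(clf.coef_[0], index=panel),
        float(clf.intercept_[0]),
        panel,
        classes,
        "l2",
        C,
        max_iter,
        converged,
        sorted({p.section_id for p in labelled if p.section_id is not None}),
        sorted({p.sample_id for p in labelled if p.sample_id is not None}),
    )


@dataclass
class VeinPrediction:
    """Soft and hard vein-type call for one structure."""

    structure_id: int
    p_t: float  # P(class 2) = P(portal)
    p_central: float
    p_portal: float
    hard_label: str  # central if p_t <= 0.5 else portal


def predict_vein_type(model: VeinClassifierModel, profile: NeighborhoodProfile) -> VeinPrediction:
    """Soft probabilities and the tie-inclusive hard call for one NEP."""
    z = model.decision(profile.values)
    p_t = 1.0 / (1.0 + np.exp(-z))  # P(portal)
    hard = model.classes[0] if p_t <= 0.5 else model.classes[1]
    return VeinPrediction(profile.structure_id, float(p_t), float(1.0 - p_t), float(p_t), hard)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Grouped cross-validation results for the vein classifier."""

    level: str
    k: int
    predictions: pd.DataFrame  # fold, structure_id, true, predicted, p_portal
    fold_accuracies: pd.Series
    accuracy: float
    confusion: pd.DataFrame
    skipped_folds: list[tuple[str, ...]]


def cross_validate(
    profiles: list[NeighborhoodProfile],
    level: str = "sample",
    k: int = 1,
    C: float = 1.0,
    max_iter: int = 1000,
) -> CVReport:
    """Leave-k-groups-out cross-validation at the section or sample level.

    All combinations of ``k`` held-out groups are enumerated; holding out a
    sample removes every section of that sample from training. Folds whose
    training set lacks a class are skipped with a warning.
    """
    if level not in ("section", "sample"):
        raise ValueError("level must be 'section' or 'sample'")
    labelled = [p for p in profiles if p.class_label in ("central", "portal")]
    key = (lambda p: p.sample_id) if level == "sample" else (lambda p: p.section_id)
    groups = sorted({key(p) for p in labelled})
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups at level {level!r}, found {groups}")
    if k >= len(groups):
        raise ValueError(f"k={k} must be smaller than the number of groups ({len(groups)})")
    rows, fold_acc, skipped = [], {}, []
    for held in itertools.combinations(groups, k):
        train = [p for p in labelled if key(p) not in held]
        test = [p for p in labelled if key(p) in held]
        if len({p.class_label for p in train}) < 2 or not test:
            warnings.warn(f"fold {held} skipped: training set lacks a class", stacklevel=2)
            skipped.append(held)
            continue
        model = fit_vein_classifier(train, C=C, max_iter=max_iter)
        fold_name = "+".join(held)
        correct = 0
        for p in test:
            pred = predict_vein_type(model, p)
            rows.append(
                {
                    "fold": fold_name,
                    "structure_id": p.structure_id,
                    "true": p.class_label,
                    "predicted": pred.hard_label,
                    "p_portal": pred.p_portal,
                }
            )
            correct += pred.hard_label == p.class_label
        fold_acc[fold_name] = correct / len(test)
    if not rows:
        raise ValueError("every cross-validation fold was skipped")
    preds = pd.DataFrame(rows)
    confusion = pd.crosstab(preds["true"], preds["predicted"]).reindex(
        index=["central", "portal"], columns=["central", "portal"], fill_value=0
    )
    accuracy = float((preds["true"] == preds["predicted"]).mean())
    return CVReport(level, k, preds, pd.Series(fold_acc), accuracy, confusion, skipped)


def annotate_ambiguous(
    model: VeinClassifierModel, profiles: list[NeighborhoodProfile]
) -> pd.DataFrame:
    """Soft-classify ambiguous structures; table sorted by structure id."""
    rows = []
    for p in profiles:
        pred = predict_vein_type(model, p)
        rows.append(
            {
                "structure_id": pred.structure_id,
                "p_central": pred.p_central,
                "p_portal": pred.p_portal,
                "predicted": pred.hard_label,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["structure_id", "p_central", "p_portal", "predicted"])
    return pd.DataFrame(rows).sort_values("structure_id").reset_index(drop=True)
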