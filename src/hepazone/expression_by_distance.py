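"""Univariate feature-by-distance curves.

For a feature x (a gene's normalized expression, or any per-spot value such
as a deconvolved cell-type proportion) and a structure class C, every spot s
within a distance cap contributes a tuple (d(s,C), x_s). Locally weighted
polynomial regression (loess, tricube kernel) smooths the tuples into a
curve on a uniform distance grid, with a pointwise one-standard-error
envelope, treating the feature as an approximate function of vein distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_geometry import DistanceTable, SpotArray
from .core import ExpressionMatrix


@dataclass
class DistanceFeatureTuples:
    """Distance-feature pairs for one feature and one structure class."""

    feature: str
    class_label: str
    pairs: pd.DataFrame  # columns: distance_um, value, section_id, sample_id, spot_id

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def distances(self) -> np.ndarray:
        return self.pairs["distance_um"].to_numpy(float)

    @property
    def values(self) -> np.ndarray:
        return self.pairs["value"].to_numpy(float)


@dataclass
class CurveEstimate:
    """A smoothed feature-by-distance curve with its SE envelope."""

    feature: str
    class_label: str
    grid: np.ndarray  # um, strictly increasing
    fitted: np.ndarray
    se: np.ndarray
    span: float
    degree: int
    n_pairs: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature,
                "class": self.class_label,
                "distance_um": self.grid,
                "fitted": self.fitted,
                "se": self.se,
            }
        )


def assemble_pairs(
    feature: pd.Series,
    distance_table: DistanceTable,
    class_label: str,
    spots: SpotArray,
    max_dist: float = 400.0,
    sections=None,
    feature_name: str | None = None,
) -> DistanceFeatureTuples:
    """Collect (distance, value) tuples for spots within ``max_dist`` (inclusive).

    ``feature`` is indexed by spot id. Tuples from all sections are
    aggregated by default; pass ``sections`` to restrict.
    """
    d = distance_table.to_class(class_label)
    meta = spots.spots.set_index("spot_id")[["section_id", "sample_id"]]
    common = d.index.intersection(feature.index).intersection(meta.index)
    d = d.loc[common]
    keep = d[d <= max_dist].index
    if sections is not None:
        keep = [s for s in keep if meta.loc[s, "section_id"] in set(sections)]
    if len(keep) == 0:
        raise ValueError(f"no spots within {max_dist} um of class {class_label!r}")
    pairs = pd.DataFrame(
        {
            "distance_um": d.loc[keep].to_numpy(float),
            "value": feature.loc[keep].to_numpy(float),
            "section_id": meta.loc[keep, "section_id"].to_numpy(),
            "sample_id": meta.loc[keep, "sample_id"].to_numpy(),
            "spot_id": list(keep),
        }
    )
    if pairs[["distance_um", "value"]].isna().any().any():
        raise ValueError("missing values in distance-feature tuples")
    return DistanceFeatureTuples(feature_name or str(feature.name), class_label, pairs)


# ---------------------------------------------------------------------------
# loess
# ---------------------------------------------------------------------------


def _loess_rows(x: np.ndarray, x0: float, span: float, degree: int) -> np.ndarray:
    """Equivalent-kernel row l(x0): fitted(x0) = l(x0) @ y."""
    n = len(x)
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    d = np.abs(x - x0)
    h = np.sort(d)[q - 1]
    if h <= 0:
        # duplicate-x pile-up at the target: average the coincident points
        w = (d == 0).astype(float)
    else:
        u = np.clip(d / h, 0, 1)
        w = (1 - u**3) ** 3
    if w.sum() <= 0:
        raise ValueError("degenerate loess weights (all zero)")
    X = np.vander(x - x0, degree + 1, increasing=True)  # col 0 = intercept
    W = w[:, None]
    XtWX = X.T @ (W * X)
    XtW = X.T * w[None, :]
    try:
        beta_row = np.linalg.solve(XtWX, XtW)
    except np.linalg.LinAlgError:
        beta_row = np.linalg.pinv(XtWX) @ XtW
    return beta_row[0]  # intercept row = fitted value at x0


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
):
    """Locally weighted polynomial regression with pointwise SEs.

    At each evaluation point the nearest ``ceil(span * n)`` observations are
    weighted with the tricube kernel and a degree-``degree`` polynomial is
    fit by weighted least squares; the fitted value is the local intercept.
    The residual scale is estimated from the smoother's trace
    (``sigma^2 = RSS / (n - tr(L))``) and ``se(x0) = sigma * ||l(x0)||``.

    Returns ``(fitted, se)`` over ``x_eval``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x_eval = np.asarray(x_eval, float)
    n = len(x)
    if n < max(degree + 2, 10):
        raise ValueError(f"need at least {max(degree + 2, 10)} pairs, got {n}")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("all distances identical; curve undefined")
    # smoother rows at the observations, for the residual scale
    L = np.empty((n, n))
    for i, xi in enumerate(x):
        L[i] = _loess_rows(x, xi, span, degree)
    resid = y - L @ y
    dof = n - np.trace(L)
    sigma2 = float(resid @ resid) / dof if dof > 1e-8 else 0.0
    fitted = np.empty(len(x_eval))
    se = np.empty(len(x_eval))
    for j, x0 in enumerate(x_eval):
        row = _loess_rows(x, x0, span, degree)
        fitted[j] = row @ y
        se[j] = np.sqrt(max(sigma2, 0.0) * float(row @ row))
    return fitted, se


def loess_curve(
    tuples: DistanceFeatureTuples,
    span: float = 0.75,
    degree: int = 2,
    grid_n: int = 100,
) -> CurveEstimate:
    """Smooth distance-feature tuples onto a uniform grid over [min d, max d]."""
    x, y = tuples.distances, tuples.values
    grid = np.linspace(x.min(), x.max(), grid_n)
    fitted, se = loess(x, y, grid, span=span, degree=degree)
    return CurveEstimate(tuples.feature, tuples.class_label, grid, fitted, se, span, degree, len(tuples))


def curve_report(
    expr: ExpressionMatrix,
    genes,
    classes,
    distance_table: DistanceTable,
    spots: SpotArray,
    layer: str = "normalized",
    max_dist: float = 400.0,
    span: float = 0.75,
    degree: int = 2,
    grid_n: int = 100,
):
    """Fit one curve per (gene, class); return the curves and a tidy table.

    Failures for individual (gene, class) combinations are re-raised with
    context so a caller knows which curve could not be estimated.
    """
    mat = expr.layer(layer)
    curves: dict[tuple[str, str], CurveEstimate] = {}
    frames = []
    for gene in genes:
        if gene not in mat.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        for cls in classes:
            try:
                tup = assemble_pairs(mat.loc[gene], distance_table, cls, spots, max_dist=max_dist)
                est = loess_curve(tup, span=span, degree=degree, grid_n=grid_n)
            except ValueError as err:
                raise ValueError(f"curve for gene {gene!r}, class {cls!r}: {err}") from err
            curves[(gene, cls)] = est
            frames.append(est.as_frame())
    return curves, pd.concat(frames, ignore_index=True)


def plot_curves(curves, ax=None):
    """Minimal matplotlib helper: fitted curves with +/- 1 SE envelopes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (gene, cls), est in curves.items():
        (line,) = ax.plot(est.grid, est.fitted, label=f"{gene} ({cls})")
        ax.fill_between(est.grid, est.fitted - est.se, est.fitted + est.se, alpha=0.25, color=line.get_color())
    ax.set_xlabel("distance to structure class (um)")
    ax.set_ylabel("feature value")
    ax.legend(fontsize="small")
    return ax
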