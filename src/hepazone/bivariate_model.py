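"""Bivariate expression-by-distance linear models and nested LRT comparison.

The full model expresses a gene's (normalized) expression in observation s as

    y_sg ~ b0g + b1g * d_sc + b2g * d_sp

with d_sc / d_sp the distances (um) to the nearest central / portal vein.
Three nested reductions drop the portal term, the central term, or both.
All four are fit by ordinary least squares (no regularization); nested pairs
are compared with a likelihood-ratio test under the Gaussian log-likelihood
with the maximum-likelihood variance (sigma^2 = RSS/n), using 1 degree of
freedom for the single-distance reductions and 2 for the intercept-only
model; the full model "outperforms" a reduction at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .array_geometry import DistanceTable
from .core import ExpressionMatrix

MODEL_FORMS = ("full", "central-only", "portal-only", "intercept")
#: covariates of each model form
_FORM_COVARIATES = {
    "full": ("d_central", "d_portal"),
    "central-only": ("d_central",),
    "portal-only": ("d_portal",),
    "intercept": (),
}
#: LRT degrees of freedom of each reduction against the full model
REDUCTION_DF = {"central-only": 1, "portal-only": 1, "intercept": 2}

_VARIANCE_FLOOR = 1e-12  # guards the log-likelihood for exactly-interpolated fits


@dataclass
class DistanceDesign:
    """Observations for the distance models: y (obs x genes) and distances."""

    y: pd.DataFrame  # observations x genes
    d_central: np.ndarray  # um
    d_portal: np.ndarray  # um

    def __post_init__(self) -> None:
        self.d_central = np.asarray(self.d_central, float)
        self.d_portal = np.asarray(self.d_portal, float)
        n = len(self.y)
        if len(self.d_central) != n or len(self.d_portal) != n:
            raise ValueError("distance vectors must match the observation count")
        for arr, name in ((self.d_central, "d_central"), (self.d_portal, "d_portal")):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if not np.all(np.isfinite(self.y.to_numpy(float))):
            raise ValueError("y contains non-finite values")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def genes(self) -> list[str]:
        return list(self.y.columns)


def build_design(
    expr: ExpressionMatrix,
    distance_table: DistanceTable,
    genes=None,
    layer: str = "normalized",
    d_max: float | None = 400.0,
) -> DistanceDesign:
    """Assemble the modelling design from expression and class distances.

    By default only spots with both vein-class distances at most ``d_max``
    (the surveyed domain, 400 um) are used; ``d_max=None`` keeps all spots.
    """
    mat = expr.layer(layer)
    if genes is not None:
        missing = [g for g in genes if g not in mat.index]
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing}")
        mat = mat.loc[genes]
    dc = distance_table.to_class("central")
    dp = distance_table.to_class("portal")
    common = dc.index.intersection(mat.columns)
    dc, dp = dc.loc[common], dp.loc[common]
    keep = common
    if d_max is not None:
        mask = (dc <= d_max) & (dp <= d_max)
        keep = common[mask.to_numpy()]
    if len(keep) == 0:
        raise ValueError("no observations in the surveyed distance domain")
    return DistanceDesign(
        mat[keep].T.astype(float), dc.loc[keep].to_numpy(), dp.loc[keep].to_numpy()
    )


@dataclass
class DistanceModelFit:
    """One OLS fit of a distance model for one gene."""

    gene_id: str
    form: str
    coefficients: pd.Series  # const (+ d_central, d_portal as applicable)
    log_likelihood: float
    n: int
    sigma2: float  # MLE residual variance
    standard_errors: pd.Series | None = None  # classical OLS coefficient SEs

    def predict(self, d_central, d_portal) -> np.ndarray:
        d_central = np.asarray(d_central, float)
        d_portal = np.asarray(d_portal, float)
        out = np.full(np.broadcast(d_central, d_portal).shape, self.coefficients["const"])
        if "d_central" in self.coefficients:
            out = out + self.coefficients["d_central"] * d_central
        if "d_portal" in self.coefficients:
            out = out + self.coefficients["d_portal"] * d_portal
        return out


def _design_matrix(design: DistanceDesign, form: str) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(design.n_obs)})
    for cov in _FORM_COVARIATES[form]:
        X[cov] = getattr(design, cov)
    return X


def fit_distance_model(design: DistanceDesign, gene: str, form: str = "full") -> DistanceModelFit:
    """Ordinary least squares fit of one model form for one gene.

    The recorded log-likelihood is the Gaussian likelihood at the MLE
    variance (RSS/n, floored at 1e-12 so exact interpolation stays finite).
    """
    if form not in MODEL_FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {MODEL_FORMS}")
    if gene not in design.y.columns:
        raise KeyError(f"gene {gene!r} not in design")
    X = _design_matrix(design, form)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more than {k} observations for form {form!r}, got {n}")
    for cov in _FORM_COVARIATES[form]:
        if np.ptp(X[cov].to_numpy()) == 0:
            raise ValueError(f"covariate {cov} is constant; form {form!r} is degenerate")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        raise ValueError(f"rank-deficient design for form {form!r}: collinear covariates {list(X.columns)}")
    y = design.y[gene].to_numpy(float)
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    sigma2 = max(rss / n, _VARIANCE_FLOOR)
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + rss / (n * sigma2))
    return DistanceModelFit(gene, form, res.params.copy(), float(llf), n, sigma2, res.bse.copy())


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of the full model against one reduction."""

    gene_id: str
    reduced_form: str
    statistic: float  # 2 * (llf_full - llf_reduced), clipped at 0
    df: int
    p_value: float
    full_outperforms: bool  # p < 0.05


def likelihood_ratio_test(
    full_fit: DistanceModelFit, reduced_fit: DistanceModelFit, alpha: float = 0.05
) -> LRTResult:
    """Chi-square LRT of the full model against a nested reduction."""
    if full_fit.form != "full":
        raise ValueError("first argument must be the full-model fit")
    if reduced_fit.form not in REDUCTION_DF:
        raise ValueError(f"{reduced_fit.form!r} is not a reduction of the full model")
    if full_fit.gene_id != reduced_fit.gene_id or full_fit.n != reduced_fit.n:
        raise ValueError("fits compare different genes or observation sets")
    lam = max(2.0 * (full_fit.log_likelihood - reduced_fit.log_likelihood), 0.0)
    df = REDUCTION_DF[reduced_fit.form]
    p = float(scipy.stats.chi2.sf(lam, df))
    return LRTResult(full_fit.gene_id, reduced_fit.form, lam, df, p, p < alpha)


def predict_grid(fit: DistanceModelFit, d_max: float = 400.0, grid_n: int = 50):
    """Predictions of the full model on a (d_central, d_portal) lattice.

    Returns ``(grid, values)`` where ``grid`` is the shared 1-D axis over
    [0, d_max] and ``values[i, j]`` is the prediction at
    (d_central = grid[i], d_portal = grid[j]); rendering between nodes is by
    linear interpolation.
    """
    if fit.form != "full":
        raise ValueError("grid prediction is defined for the full model")
    grid = np.linspace(0.0, d_max, grid_n)
    dc, dp = np.meshgrid(grid, grid, indexing="ij")
    return grid, fit.predict(dc, dp)


def screen_genes(design: DistanceDesign, alpha: float = 0.05):
    """Fit all four forms per gene and run all three reductions' LRTs.

    Returns ``(lrt_table, summary)``. The summary categorizes each gene by
    which vein distances are influential: a distance matters when dropping it
    (the reduction lacking it) is rejected.
    """
    lrt_rows, summary_rows = [], []
    for gene in design.genes:
        try:
            full = fit_distance_model(design, gene, "full")
            results = {}
            for red in REDUCTION_DF:
                reduced = fit_distance_model(design, gene, red)
                results[red] = likelihood_ratio_test(full, reduced, alpha=alpha)
        except ValueError as err:
            summary_rows.append({"gene": gene, "category": "failed", "error": str(err)})
            continue
        for res in results.values():
            lrt_rows.append(
                {
                    "gene": gene,
                    "reduced_form": res.reduced_form,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "full_outperforms": res.full_outperforms,
                }
            )
        central_matters = results["portal-only"].full_outperforms
        portal_matters = results["central-only"].full_outperforms
        if central_matters and portal_matters:
            category = "both"
        elif central_matters:
            category = "central-only"
        elif portal_matters:
            category = "portal-only"
        else:
            category = "neither"
        summary_rows.append(
            {
                "gene": gene,
                "category": category,
                "beta_central": full.coefficients.get("d_central", np.nan),
                "beta_portal": full.coefficients.get("d_portal", np.nan),
                "error": "",
            }
        )
    return pd.DataFrame(lrt_rows), pd.DataFrame(summary_rows)
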