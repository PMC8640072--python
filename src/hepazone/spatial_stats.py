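"""Spatial statistics: cluster interactions, lag autocorrelation, module
scores, quantile scaling, bootstrap correlation CIs, and the distance
correlation screen.

These are the permutation/bootstrap style analyses that complement the
distance models: a 4-nearest-neighbour graph on the spot lattice underpins
the cluster-interaction permutation test and the lag-vector spatial
autocorrelation; module scores contrast a gene program against
expression-matched control genes; quantile scaling maps proportion fields to
[0, 1] robustly; bootstrap resampling yields Pearson CIs for cell-type
proportions; and a Spearman screen with Holm-Sidak correction finds genes
whose expression tracks distance to a reference region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .array_geometry import SpotArray

DEFAULT_INTERACTION_DIST_UM = 155.0  # just above the 150 um lattice pitch
DEFAULT_AUTOCORR_DIST_UM = 150.0


# ---------------------------------------------------------------------------
# neighbor graph
# ---------------------------------------------------------------------------


@dataclass
class NeighborGraph:
    """Per-spot k-nearest-neighbour lists (same section, distance-capped)."""

    neighbors: dict[str, list[tuple[str, float]]]  # spot_id -> [(nbr_id, d_um)]
    sections: pd.Series  # spot_id -> section_id
    k: int
    max_dist_um: float

    @property
    def spot_ids(self) -> list[str]:
        return list(self.neighbors)


def neighbor_graph(
    spots: SpotArray, k: int = 4, max_dist_um: float = DEFAULT_INTERACTION_DIST_UM
) -> NeighborGraph:
    """The k nearest same-section spots within ``max_dist_um`` of each spot.

    Ties are broken by (distance, spot_id); isolated spots keep empty lists.
    """
    neighbors: dict[str, list[tuple[str, float]]] = {}
    for section_id in spots.section_ids:
        sub = spots.section(section_id)
        if len(sub) < 2:
            raise ValueError(f"section {section_id!r} has fewer than 2 spots")
        ids = sub.spot_ids.to_numpy()
        xy = sub.coords_um()
        tree = cKDTree(xy)
        ball = tree.query_ball_point(xy, r=max_dist_um)
        for i, idxs in enumerate(ball):
            cand = [
                (round(float(np.hypot(*(xy[j] - xy[i]))), 9), ids[j])
                for j in idxs
                if j != i
            ]
            cand.sort()
            neighbors[ids[i]] = [(sid, d) for d, sid in cand[:k]]
    sections = spots.spots.set_index("spot_id")["section_id"]
    return NeighborGraph(neighbors, sections, k, max_dist_um)


# ---------------------------------------------------------------------------
# cluster interaction
# ---------------------------------------------------------------------------


@dataclass
class InteractionReport:
    """Observed vs permutation-null neighbour fractions per cluster pair."""

    fractions: pd.DataFrame  # index (cluster_a, cluster_b): observed, null_mean, null_sd, flagged
    n_permutations: int
    missing_clusters: list[str]  # clusters with no neighbours at all


def _fraction_matrix(codes: np.ndarray, src: np.ndarray, nbr: np.ndarray, k: int) -> np.ndarray:
    counts = np.zeros((k, k))
    np.add.at(counts, (codes[src], codes[nbr]), 1.0)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return counts / totals[:, None]


def cluster_interaction(
    labels: pd.Series,
    graph: NeighborGraph,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> InteractionReport:
    """Neighbour-label fractions per cluster against a label-permutation null.

    For each cluster A, the observed fraction of A-members' neighbours that
    belong to each cluster B (counts divided by A's total neighbour count) is
    compared against ``n_perm`` random permutations of the cluster labels
    (permuted within section, preserving spot geometry). Pairs whose observed
    fraction departs from the null mean by more than two null SDs are flagged.
    """
    rng = np.random.default_rng() if rng is None else rng
    spot_ids = list(graph.spot_ids)
    missing = [s for s in spot_ids if s not in labels.index]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} spots in the graph")
    labels = labels.loc[spot_ids].astype(str)
    clusters = sorted(labels.unique())
    k = len(clusters)
    code_of = {c: i for i, c in enumerate(clusters)}
    codes = labels.map(code_of).to_numpy()
    pos = {s: i for i, s in enumerate(spot_ids)}
    src, nbr = [], []
    for sid in spot_ids:
        for nid, _ in graph.neighbors[sid]:
            src.append(pos[sid])
            nbr.append(pos[nid])
    src = np.asarray(src, dtype=int)
    nbr = np.asarray(nbr, dtype=int)
    observed = pd.DataFrame(_fraction_matrix(codes, src, nbr, k), index=clusters, columns=clusters)
    sec_codes = pd.factorize(graph.sections.loc[spot_ids])[0]
    section_members = [np.flatnonzero(sec_codes == s) for s in np.unique(sec_codes)]
    perm = np.empty((n_perm, k, k))
    for b in range(n_perm):
        shuffled = codes.copy()
        for members in section_members:
            shuffled[members] = shuffled[rng.permutation(members)]
        perm[b] = _fraction_matrix(shuffled, src, nbr, k)
    null_mean = np.nanmean(perm, axis=0)
    null_sd = np.nanstd(perm, axis=0)
    rows = []
    missing_clusters = []
    for i, a in enumerate(clusters):
        if not np.isfinite(observed.loc[a].to_numpy()).any():
            missing_clusters.append(a)
            warnings.warn(f"cluster {a!r} has no neighbours; fractions undefined", stacklevel=2)
        for j, c in enumerate(clusters):
            obs = observed.loc[a, c]
            rows.append(
                {
                    "cluster_a": a,
                    "cluster_b": c,
                    "observed": obs,
                    "null_mean": null_mean[i, j],
                    "null_sd": null_sd[i, j],
                    "flagged": bool(
                        np.isfinite(obs) and abs(obs - null_mean[i, j]) > 2 * null_sd[i, j]
                    ),
                }
            )
    frame = pd.DataFrame(rows).set_index(["cluster_a", "cluster_b"])
    return InteractionReport(frame, n_perm, missing_clusters)


# ---------------------------------------------------------------------------
# spatial autocorrelation
# ---------------------------------------------------------------------------


def spatial_autocorrelation(
    expr: pd.DataFrame, graph: NeighborGraph, require_full: bool = True
) -> pd.DataFrame:
    """Lag-vector autocorrelation score per gene.

    The lag vector of a gene is, for each spot, the summed expression over
    its graph neighbours; the score is the Pearson correlation between
    expression and lag. By default only spots with a complete neighbourhood
    (all ``k`` neighbours present) are scored: with a uniform neighbour
    count the summed lag is an affine image of the neighbourhood mean, so
    the score is invariant to affine rescaling of the feature and boundary
    spots with truncated neighbourhoods cannot distort it.
    ``require_full=False`` scores every spot with at least one neighbour.
    Genes (or lags) with zero variance get a missing score with a reason.
    """
    needed = graph.k if require_full else 1
    spot_ids = [
        s for s in graph.spot_ids if s in expr.columns and len(graph.neighbors[s]) >= needed
    ]
    if len(spot_ids) < 3:
        raise ValueError("fewer than 3 spots with neighbours and expression")
    pos = {s: i for i, s in enumerate(expr.columns)}
    X = expr.to_numpy(float)
    cols = [pos[s] for s in spot_ids]
    lag = np.zeros((X.shape[0], len(spot_ids)))
    for out_i, s in enumerate(spot_ids):
        nbr_cols = [pos[n] for n, _ in graph.neighbors[s] if n in pos]
        lag[:, out_i] = X[:, nbr_cols].sum(axis=1)
    sub = X[:, cols]
    rows = []
    for gi, gene in enumerate(expr.index):
        x, y = sub[gi], lag[gi]
        if np.ptp(x) == 0:
            rows.append({"gene": gene, "score": np.nan, "reason": "zero-variance expression"})
        elif np.ptp(y) == 0:
            rows.append({"gene": gene, "score": np.nan, "reason": "zero-variance lag"})
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"gene": gene, "score": r, "reason": ""})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# module scores
# ---------------------------------------------------------------------------


def module_score(
    expr: pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Program score per spot: mean program expression minus bin-matched control.

    All genes are binned into ``n_bins`` equal-frequency bins of their
    dataset-average expression; for every program gene, ``n_ctrl`` control
    genes are drawn from its bin (without replacement when the bin is large
    enough, with replacement otherwise). The score of a spot is the mean
    expression of the program minus the mean expression of the pooled
    controls.
    """
    rng = np.random.default_rng() if rng is None else rng
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError("gene set shares no genes with the expression matrix")
    if expr.shape[0] < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes, got {expr.shape[0]}")
    avg = expr.mean(axis=1)
    # equal-frequency binning on average expression; ties share a bin
    order = avg.rank(method="first")
    bins = pd.qcut(order, q=n_bins, labels=False)
    ctrl_genes: list[str] = []
    for g in present:
        pool = bins.index[(bins == bins[g]).to_numpy()]
        if len(pool) >= n_ctrl:
            chosen = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            chosen = rng.choice(pool, size=n_ctrl, replace=True)
        ctrl_genes.extend(chosen)
    score = expr.loc[present].mean(axis=0) - expr.loc[ctrl_genes].mean(axis=0)
    score.name = "module_score"
    return score


# ---------------------------------------------------------------------------
# quantile scaling
# ---------------------------------------------------------------------------


def quantile_scale(values, q: float = 0.95):
    """Clip at the q-th sample quantile, then divide by the clipped maximum.

    Maps non-negative values to [0, 1] robustly to outliers. The clip
    threshold is the ``higher`` sample quantile (the smallest order
    statistic at or above the target rank): clipping at an actual sample
    value makes the two-step procedure exactly idempotent, which the
    interpolated (type-7) quantile is not. All-zero input is returned
    unchanged with ``flagged=True``. Returns ``(scaled, flagged)``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if np.any(arr < 0):
        raise ValueError("quantile scaling requires non-negative values")
    hi = np.quantile(arr, q, method="higher")
    clipped = np.minimum(arr, hi)
    mx = clipped.max()
    if mx == 0:
        out = clipped
        flagged = True
    else:
        out = clipped / mx
        flagged = False
    if isinstance(values, pd.Series):
        out = pd.Series(out, index=values.index, name=values.name)
    return out, flagged


def quantile_scale_proportions(
    proportions: pd.DataFrame, sections: pd.Series, q: float = 0.95
) -> pd.DataFrame:
    """Apply :func:`quantile_scale` within every (cell type, section) group."""
    out = proportions.copy().astype(float)
    sections = sections.loc[proportions.index]
    for sec in sections.unique():
        mask = (sections == sec).to_numpy()
        for col in proportions.columns:
            scaled, _ = quantile_scale(proportions.loc[mask, col].to_numpy(), q=q)
            out.loc[mask, col] = scaled
    return out


# ---------------------------------------------------------------------------
# bootstrap Pearson CIs
# ---------------------------------------------------------------------------


def bootstrap_pearson(
    proportions: pd.DataFrame,
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Bootstrap Pearson correlations between cell-type proportion columns.

    Spots are resampled with replacement ``n_boot`` times; per pair the mean
    bootstrap r is the representative value, the CI spans the 2.5th-97.5th
    percentiles, and a pair is significant when its CI excludes zero.
    Degenerate resamples (zero variance in either column) are skipped and
    counted; constant columns are reported missing.
    """
    rng = np.random.default_rng() if rng is None else rng
    n, m = proportions.shape
    if n < 3:
        raise ValueError("need at least 3 spots")
    if m < 2:
        raise ValueError("need at least 2 cell types")
    X = proportions.to_numpy(float)
    idx = rng.integers(0, n, size=(n_boot, n))
    rows = []
    cols = list(proportions.columns)
    for i in range(m):
        for j in range(i + 1, m):
            if np.ptp(X[:, i]) == 0 or np.ptp(X[:, j]) == 0:
                rows.append(
                    {
                        "type_a": cols[i],
                        "type_b": cols[j],
                        "mean_r": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "significant": False,
                        "n_degenerate": n_boot,
                    }
                )
                continue
            xi, xj = X[idx, i], X[idx, j]  # (n_boot, n)
            xi_c = xi - xi.mean(axis=1, keepdims=True)
            xj_c = xj - xj.mean(axis=1, keepdims=True)
            num = (xi_c * xj_c).sum(axis=1)
            den = np.sqrt((xi_c**2).sum(axis=1) * (xj_c**2).sum(axis=1))
            valid = den > 0
            r = num[valid] / den[valid]
            lo, hi = np.percentile(r, ci)
            rows.append(
                {
                    "type_a": cols[i],
                    "type_b": cols[j],
                    "mean_r": float(r.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "significant": bool(lo > 0 or hi < 0),
                    "n_degenerate": int(n_boot - valid.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance-correlation screen
# ---------------------------------------------------------------------------


def holm_sidak(p_values: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values."""
    with np.errstate(divide="ignore"):  # raw p of exactly 1.0 hits log1p(-1)
        return multipletests(p_values, method="holm-sidak")[1]


def distance_correlation_screen(
    expr: pd.DataFrame,
    region_distance: pd.Series,
    max_dist_um: float = 800.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman screen for genes zonated with respect to a reference region.

    Spots within ``max_dist_um`` (default 800 um = 284 px) of the region are
    kept; per gene, the Spearman correlation between expression and distance
    is computed with its analytic p-value, adjusted across genes by the
    Holm-Sidak step-down method; significance is adjusted p < 0.05. Positive
    correlations mean expression rises away from the region. Zero-variance
    genes are reported missing and excluded from the adjustment.
    """
    common = region_distance.index.intersection(expr.columns)
    d = region_distance.loc[common]
    keep = d[d <= max_dist_um].index
    if len(keep) < 3:
        raise ValueError(f"fewer than 3 spots within {max_dist_um} um of the region")
    dist = d.loc[keep].to_numpy(float)
    sub = expr[list(keep)]
    rows = []
    for gene in sub.index:
        x = sub.loc[gene].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append({"gene": gene, "rho": np.nan, "p_value": np.nan, "reason": "zero variance"})
            continue
        rho, p = scipy.stats.spearmanr(x, dist)
        rows.append({"gene": gene, "rho": float(rho), "p_value": float(p), "reason": ""})
    out = pd.DataFrame(rows).set_index("gene")
    tested = out.index[out["p_value"].notna()]
    out["p_adjusted"] = np.nan
    if len(tested):
        out.loc[tested, "p_adjusted"] = holm_sidak(out.loc[tested, "p_value"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    out["direction"] = np.where(
        out["rho"].isna(), "", np.where(out["rho"] > 0, "up-with-distance", "down-with-distance")
    )
    return out
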