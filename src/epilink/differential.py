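"""Cluster-level differential accessibility.

DA peaks are called one-vs-rest per cluster with a logistic
likelihood-ratio test conditioning on sequencing depth: the full model is
``in_cluster ~ 1 + x + log_depth``, the null drops ``x`` (the log1p
depth-normalised peak signal), and the statistic is compared to chi-square
with 1 df.  Calls require BH-adjusted p <= alpha and positive average log
fold change.  Downstream, the cross-cluster overlap matrix records, for
each cluster's DA peaks, the percentage detectable (any read, no minimum
count) in every other cluster; the overlap profiles are hierarchically
clustered with correlation distance and average linkage.

The logistic fits use a small dedicated Newton/IRLS solver: separating or
otherwise degenerate peaks are refit with a weak L2 penalty (1e-4) on the
slope coefficients of both models, keeping the statistic finite and the
procedure deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError, validate_cell_table, PeakMatrix

RIDGE = 1e-4
_MAX_ITER = 60
_BETA_CAP = 30.0


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, float, bool]:
    """Damped Newton (step-halving) logistic fit; monotone in the objective.

    ``ridge`` penalises all non-intercept coefficients.  Returns
    (beta, unpenalised log-likelihood, converged); separated fits (ridge 0)
    are reported as non-converged so callers can refit with a penalty.
    """
    n, p = X.shape
    pen = np.full(p, ridge)
    pen[0] = 0.0  # intercept unpenalised

    def objective(b: np.ndarray) -> float:
        eta = X @ b
        return _loglik(y, eta) - 0.5 * float(pen @ (b * b))

    beta = np.zeros(p)
    pbar = min(max(y.mean(), 1e-9), 1 - 1e-9)
    beta[0] = np.log(pbar / (1 - pbar))
    f = objective(beta)
    converged = False
    for _ in range(_MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(hess, grad, rcond=None)
        t, cand, fc = 1.0, None, -np.inf
        for _half in range(40):
            cand = beta + t * step
            fc = objective(cand)
            if fc >= f:
                break
            t /= 2.0
        else:
            converged = True  # no ascent direction left: at a maximum
            break
        moved = np.abs(t * step).max()
        beta, f = cand, fc
        if moved < 1e-9:
            converged = True
            break
    if ridge == 0.0 and np.abs(beta[1:]).max(initial=0.0) > _BETA_CAP:
        converged = False  # separation: slope diverging
    return beta, _loglik(y, X @ beta), converged


def lr_test_peak(
    y: np.ndarray, x: np.ndarray, covariate: np.ndarray
) -> tuple[float, float, bool]:
    """Likelihood-ratio test of a peak signal on cluster membership.

    ``y`` is the in-cluster indicator, ``x`` the normalised peak signal and
    ``covariate`` the per-cell log total count.  Returns
    (statistic, p_value, ridge_flagged); the flag marks fits that needed
    the L2-stabilised refit (e.g. perfectly separating peaks).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    covariate = np.asarray(covariate, float)
    if not (np.isfinite(x).all() and np.isfinite(covariate).all()):
        raise ValidationError("lr_test_peak requires finite x and covariate")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("y must contain both classes")
    if np.ptp(x) == 0:
        return 0.0, 1.0, False  # nested models coincide
    ones = np.ones_like(y)
    X_full = np.column_stack([ones, x, covariate])
    X_null = np.column_stack([ones, covariate])
    b_f, ll_f, ok_f = _fit_logistic(X_full, y)
    b_n, ll_n, ok_n = _fit_logistic(X_null, y)
    flagged = False
    if not (ok_f and ok_n):
        flagged = True
        _, ll_f, _ = _fit_logistic(X_full, y, ridge=RIDGE)
        _, ll_n, _ = _fit_logistic(X_null, y, ridge=RIDGE)
    stat = max(2.0 * (ll_f - ll_n), 0.0)
    return stat, float(chi2.sf(stat, df=1)), flagged


# ---------------------------------------------------------------------------
# DA peak detection
# ---------------------------------------------------------------------------


def _group_indicator(cluster_ids: np.ndarray, clusters: list) -> sp.csr_matrix:
    rows = np.array([clusters.index(c) for c in cluster_ids])
    data = np.ones(len(cluster_ids))
    return sp.csr_matrix((data, (rows, np.arange(len(cluster_ids)))), shape=(len(clusters), len(cluster_ids)))


def normalized_signal(matrix: PeakMatrix) -> tuple[np.ndarray, np.ndarray]:
    """log1p of median-depth-normalised counts and the per-cell log depth."""
    depth = matrix.total_counts().astype(float)
    med = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    scale = np.where(depth > 0, med / np.maximum(depth, 1e-12), 0.0)
    xmat = np.log1p(np.asarray(matrix.counts.todense()) * scale[:, None])
    log_depth = np.log(np.maximum(depth, 1.0))
    return xmat, log_depth


def find_da_peaks(
    matrix: PeakMatrix,
    cells: pd.DataFrame,
    min_pct: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest DA peaks per cluster (LR test, depth covariate).

    Peaks are tested only when max(pct_in, pct_out) >= ``min_pct``; BH
    adjustment is applied within each cluster; calls satisfy
    adj_p <= ``alpha`` and avg_log_fc > 0.
    """
    validate_cell_table(cells)
    if list(cells["barcode"]) != list(matrix.barcodes):
        raise ValidationError("cell table and matrix barcodes differ")
    clusters = sorted(cells["cluster_id"].unique().tolist())
    if len(clusters) < 2:
        raise ValidationError("need >= 2 clusters")
    cl = cells["cluster_id"].to_numpy()
    sizes = np.array([(cl == c).sum() for c in clusters], float)
    if (sizes == 0).any():
        raise ValidationError("empty cluster")

    G = _group_indicator(cl, clusters)
    nz = (matrix.counts > 0).astype(np.float64)
    nz_per_cluster = np.asarray((G @ nz).todense())  # clusters x peaks
    total_nz = nz_per_cluster.sum(axis=0)
    xmat, log_depth = normalized_signal(matrix)
    mean_per_cluster = np.asarray(G.todense()) @ xmat / sizes[:, None]
    grand_sum = xmat.sum(axis=0)
    n_cells = len(cells)

    results = []
    for ci, c in enumerate(clusters):
        y = (cl == c).astype(float)
        n_in = sizes[ci]
        pct_in = nz_per_cluster[ci] / n_in
        pct_out = (total_nz - nz_per_cluster[ci]) / (n_cells - n_in)
        tested = np.nonzero(np.maximum(pct_in, pct_out) >= min_pct)[0]
        if tested.size == 0:
            continue
        mean_in = mean_per_cluster[ci, tested]
        mean_out = (grand_sum[tested] - mean_per_cluster[ci, tested] * n_in) / (n_cells - n_in)
        fc = mean_in - mean_out
        pvals = np.empty(tested.size)
        flags = np.empty(tested.size, bool)
        for k, pi in enumerate(tested):
            _, pvals[k], flags[k] = lr_test_peak(y, xmat[:, pi], log_depth)
        adj = multipletests(pvals, method="fdr_bh")[1]
        keep = (adj <= alpha) & (fc > 0)
        for k in np.nonzero(keep)[0]:
            pi = int(tested[k])
            pk = matrix.peaks[pi]
            results.append(
                dict(
                    chrom=pk.chrom,
                    start=pk.start,
                    end=pk.end,
                    peak_index=pi,
                    cluster_id=c,
                    avg_log_fc=float(fc[k]),
                    pct_in=float(pct_in[tested[k]]),
                    pct_out=float(pct_out[tested[k]]),
                    p_value=float(pvals[k]),
                    adj_p=float(adj[k]),
                    ridge_flag=bool(flags[k]),
                )
            )
    return pd.DataFrame(
        results,
        columns=[
            "chrom", "start", "end", "peak_index", "cluster_id", "avg_log_fc",
            "pct_in", "pct_out", "p_value", "adj_p", "ridge_flag",
        ],
    )


# ---------------------------------------------------------------------------
# Cross-cluster overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapMatrix:
    """percent[d, c]: % of cluster c's DA peaks with any read in cluster d."""

    percent: pd.DataFrame  # rows: detecting cluster d; columns: owning cluster c
    peak_counts: pd.Series  # DA peaks per owning cluster


def cluster_sums(matrix: PeakMatrix, cells: pd.DataFrame) -> pd.DataFrame:
    clusters = sorted(cells["cluster_id"].unique().tolist())
    G = _group_indicator(cells["cluster_id"].to_numpy(), clusters)
    sums = np.asarray((G @ matrix.counts).todense())
    return pd.DataFrame(sums, index=clusters)


def overlap_matrix(da: pd.DataFrame, matrix: PeakMatrix, cells: pd.DataFrame) -> OverlapMatrix:
    """Pooled-per-cluster detectability of each cluster's DA peaks.

    A DA peak counts as overlapping cluster d iff the summed count over
    d's cells is > 0 (no minimum read threshold).  Clusters without DA
    peaks yield an undefined (NaN) column.
    """
    sums = cluster_sums(matrix, cells)
    clusters = list(sums.index)
    if len(da) and da["peak_index"].max() >= matrix.counts.shape[1]:
        raise ValidationError("DA peak index outside matrix")
    percent = pd.DataFrame(np.nan, index=clusters, columns=clusters, dtype=float)
    counts = pd.Series(0, index=clusters, dtype=int)
    for c in clusters:
        idx = da.loc[da["cluster_id"] == c, "peak_index"].to_numpy()
        counts[c] = len(idx)
        if len(idx) == 0:
            continue
        detect = (sums.iloc[:, idx].to_numpy() > 0).mean(axis=1) * 100.0
        percent[c] = detect
    return OverlapMatrix(percent=percent, peak_counts=counts)


@dataclass
class Dendrogram:
    linkage: np.ndarray
    labels: list
    leaf_order: list


def _correlation_distance(rows: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson; zero-variance rows sit at the maximal distance 2."""
    n = rows.shape[0]
    centered = rows - rows.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    dist = np.full((n, n), 2.0)
    np.fill_diagonal(dist, 0.0)
    ok = norm > 0
    if ok.any():
        sub = centered[ok] / norm[ok, None]
        corr = np.clip(sub @ sub.T, -1.0, 1.0)
        dist[np.ix_(ok, ok)] = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
    return dist


def cluster_overlap_profiles(om: OverlapMatrix) -> Dendrogram:
    """UPGMA tree of cluster overlap-row profiles (1 - Pearson distance)."""
    profiles = om.percent.dropna(axis=1)
    if profiles.shape[0] < 3:
        raise ValidationError("need >= 3 clusters with defined profiles")
    rows = profiles.to_numpy(float)
    dist = _correlation_distance(rows)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = sch.linkage(condensed, method="average")
    order = sch.leaves_list(Z).tolist()
    labels = list(om.percent.index)
    return Dendrogram(linkage=Z, labels=labels, leaf_order=[labels[i] for i in order])


def dendrogram_to_newick(dg: Dendrogram) -> str:
    """Serialise the merge tree as Newick with heights as branch lengths."""
    Z = dg.linkage
    n = len(dg.labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(dg.labels[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


def binarize_by_cluster(
    matrix: PeakMatrix, cells: pd.DataFrame, da: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cluster-by-peak open/closed matrix: 1 iff pooled cluster count > 0.

    With ``da`` given, columns are restricted to the distinct DA peak
    indices (sorted).
    """
    sums = cluster_sums(matrix, cells)
    binary = (sums.to_numpy() > 0).astype(int)
    out = pd.DataFrame(binary, index=sums.index)
    if da is not None:
        cols = sorted(set(int(i) for i in da["peak_index"]))
        out = out.loc[:, cols]
    return out
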