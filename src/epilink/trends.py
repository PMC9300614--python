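"""Pseudotime-binned trajectories, trend clustering and transition counts.

Cells are divided into equal-width pseudotime bins; per gene and modality
(RNA, GAS, ENH) the bin means are centred and scaled into a z trajectory.
Differentially expressed genes are grouped by hierarchical clustering of
the concatenated three-modality z vectors (correlation distance, average
linkage, the cut chosen by maximal mean silhouette over k in 2..8 with a
deterministic smallest-k tie-break); groups below the minimum size fall
into 'other', and retained groups are labelled early / late / transition
from the direction of their mean trajectory.  Enhancers linked to up- or
down-regulated genes across the maturation transitions (AP->BP, BP->N,
AP->N) are tallied as activated or decommissioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, ValidationError
from .differential import _correlation_distance, lr_test_peak
from .scoring import ScoreMatrix

MODALITIES = ("RNA", "GAS", "ENH")
TRANSITIONS = (("AP", "BP"), ("BP", "N"), ("AP", "N"))


def bin_pseudotime(cells: pd.DataFrame, n_bins: int = 10) -> np.ndarray:
    """Equal-width bins over [min, max]; returns bin index in 1..n_bins.

    Interior edges are left-closed (a value exactly on an edge goes to the
    right bin); the right edge of the last bin is inclusive.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    t = cells["pseudotime"].to_numpy(float)
    lo, hi = t.min(), t.max()
    if lo == hi:
        raise ValidationError("all pseudotimes equal: bins undefined")
    width = (hi - lo) / n_bins
    idx = np.floor((t - lo) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1) + 1


@dataclass
class TrajectorySet:
    """Per-gene z trajectories for one modality, with degeneracy flags."""

    modality: str
    z: pd.DataFrame  # genes x bins (columns 1..n_bins)
    constant_genes: set = field(default_factory=set)
    interpolated_bins: dict = field(default_factory=dict)  # gene -> [bin, ...]

    def tidy(self) -> pd.DataFrame:
        long = self.z.reset_index(names="gene_id").melt(
            id_vars="gene_id", var_name="bin", value_name="z"
        )
        long["modality"] = self.modality
        return long[["gene_id", "modality", "bin", "z"]]


def zscore_trajectories(
    score_matrix: ScoreMatrix,
    cells: pd.DataFrame,
    bins: np.ndarray,
    n_bins: int | None = None,
    ddof: int = 1,
) -> TrajectorySet:
    """Bin-mean each gene's signal, then centre and scale across bins.

    Scaling uses the sample standard deviation (``ddof=1``, matching R's
    ``scale()``); pass ``ddof=0`` for the population variant.  Constant
    trajectories become all-zero and are flagged; empty bins are linearly
    interpolated from neighbouring bins and flagged.
    """
    n_bins = n_bins or int(bins.max())
    values = score_matrix.dense()
    means = np.full((n_bins, values.shape[1]), np.nan)
    occupied = np.zeros(n_bins, dtype=bool)
    for b in range(1, n_bins + 1):
        mask = bins == b
        if mask.any():
            means[b - 1] = values[mask].mean(axis=0)
            occupied[b - 1] = True
    interpolated: dict[str, list[int]] = {}
    if not occupied.all():
        empty = np.nonzero(~occupied)[0]
        xp = np.nonzero(occupied)[0]
        for g in range(values.shape[1]):
            means[empty, g] = np.interp(empty, xp, means[xp, g])
        for gname in score_matrix.gene_ids:
            interpolated[gname] = (empty + 1).tolist()
    center = means - means.mean(axis=0)
    sd = means.std(axis=0, ddof=ddof)
    constant = set(np.asarray(score_matrix.gene_ids)[sd == 0].tolist())
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, center / np.where(sd == 0, 1.0, sd), 0.0)
    frame = pd.DataFrame(z.T, index=score_matrix.gene_ids, columns=range(1, n_bins + 1))
    return TrajectorySet(
        modality=score_matrix.kind, z=frame, constant_genes=constant, interpolated_bins=interpolated
    )


# ---------------------------------------------------------------------------
# Trend clustering
# ---------------------------------------------------------------------------


def _concat_modalities(trajs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate modality z matrices over the union of genes (zeros fill)."""
    genes = sorted(set().union(*[set(m.index) for m in trajs.values()]))
    parts = []
    for mod in sorted(trajs):
        m = trajs[mod].reindex(genes).fillna(0.0)
        m.columns = [f"{mod}:{c}" for c in m.columns]
        parts.append(m)
    return pd.concat(parts, axis=1)


def cluster_trajectories(
    trajs: dict[str, pd.DataFrame],
    min_group: int = 6,
    k_range: tuple[int, int] = (2, 8),
    direction_threshold: float = 0.5,
) -> pd.DataFrame:
    """Group genes by their concatenated RNA/GAS/ENH trajectories.

    Returns a frame (gene_id, group, label) where ``group`` is -1 for
    genes in clusters smaller than ``min_group`` (label 'other'); retained
    groups are labelled 'early' when the group's mean modality-averaged z
    falls by more than ``direction_threshold`` from first to last bin,
    'late' for the mirrored rise, else 'transition'.
    """
    mat = _concat_modalities(trajs)
    genes = list(mat.index)
    n = len(genes)
    if n < min_group:
        return pd.DataFrame({"gene_id": genes, "group": -1, "label": "other"})
    dist = _correlation_distance(mat.to_numpy(float))
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = sch.linkage(condensed, method="average")
    best_k, best_sil = None, -np.inf
    for k in range(k_range[0], min(k_range[1], n - 1) + 1):
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(dist, labels, metric="precomputed")
        if sil > best_sil + 1e-12:  # strict improvement: ties keep smallest k
            best_k, best_sil = k, sil
    labels = sch.fcluster(Z, t=best_k, criterion="maxclust") if best_k else np.ones(n, int)

    n_mod = len(trajs)
    n_bins = mat.shape[1] // n_mod
    profile = mat.to_numpy(float).reshape(n, n_mod, n_bins).mean(axis=1)

    out = pd.DataFrame({"gene_id": genes, "group": labels})
    out["label"] = "other"
    for g in np.unique(labels):
        members = labels == g
        if members.sum() < min_group:
            out.loc[members, "group"] = -1
            continue
        mean_prof = profile[members].mean(axis=0)
        drop = mean_prof[0] - mean_prof[-1]
        if drop > direction_threshold:
            lab = "early"
        elif -drop > direction_threshold:
            lab = "late"
        else:
            lab = "transition"
        out.loc[members, "label"] = lab
    return out


def matched_heatmap_order(trajs: dict[str, pd.DataFrame]) -> tuple[list[str], np.ndarray]:
    """One dendrogram from the concatenated matrix; shared leaf order.

    The returned gene order is applied identically to all modality
    matrices; rows (bins) stay in pseudotime order.
    """
    mat = _concat_modalities(trajs)
    dist = _correlation_distance(mat.to_numpy(float))
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = sch.linkage(condensed, method="average")
    order = sch.leaves_list(Z)
    genes = list(mat.index)
    return [genes[i] for i in order], Z


# ---------------------------------------------------------------------------
# DEGs between maturation states + enhancer transition counts
# ---------------------------------------------------------------------------


def find_state_degs(
    expression: ExpressionMatrix,
    cells: pd.DataFrame,
    transitions: tuple = TRANSITIONS,
    lfc_threshold: float = 0.1,
) -> pd.DataFrame:
    """One-vs-one DEGs between maturation states (logistic LR, depth covariate).

    ``lfc`` is mean log1p depth-normalised expression in the later state
    minus the earlier one; BH adjustment per transition.  Genes with
    |lfc| < ``lfc_threshold`` are not tested (p and adj_p set to 1),
    which suppresses compositional artifacts of depth normalisation under
    global expression shifts.
    """
    depth = expression.total_counts().astype(float)
    med = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    scale = np.where(depth > 0, med / np.maximum(depth, 1e-12), 0.0)
    xmat = np.log1p(np.asarray(expression.counts.todense()) * scale[:, None])
    log_depth = np.log(np.maximum(depth, 1.0))
    state = cells["state"].to_numpy(object)

    rows = []
    for a, b in transitions:
        mask = (state == a) | (state == b)
        if mask.sum() == 0 or len(np.unique(state[mask])) < 2:
            raise ValidationError(f"transition {a}->{b}: missing state cells")
        y = (state[mask] == b).astype(float)
        cov = log_depth[mask]
        pvals, lfcs = [], []
        for gi, gid in enumerate(expression.gene_ids):
            x = xmat[mask, gi]
            lfc = x[y == 1].mean() - x[y == 0].mean()
            if np.ptp(x) == 0 or abs(lfc) < lfc_threshold:
                p = 1.0
            else:
                _, p, _ = lr_test_peak(y, x, cov)
            pvals.append(p)
            lfcs.append(lfc)
        adj = multipletests(np.asarray(pvals), method="fdr_bh")[1]
        for gid, lfc, p, ap in zip(expression.gene_ids, lfcs, pvals, adj):
            rows.append(dict(gene_id=gid, transition=f"{a}->{b}", lfc=float(lfc), p_value=float(p), adj_p=float(ap)))
    return pd.DataFrame(rows)


def count_enhancer_transitions(
    deg_table: pd.DataFrame,
    enhancer_links: pd.DataFrame,
    alpha: float = 0.05,
    transitions: tuple = TRANSITIONS,
) -> pd.DataFrame:
    """Distinct enhancers linked to up-/down-regulated DEGs per transition.

    ``enhancer_links`` maps genes to enhancer intervals (gene_id, chrom,
    start, end).  An enhancer linked to both an up- and a down-gene counts
    in both tallies.  Ratio is activated/decommissioned; infinite when no
    enhancer is decommissioned (flagged).
    """
    link_key = enhancer_links.assign(
        key=enhancer_links["chrom"].astype(str)
        + ":"
        + enhancer_links["start"].astype(str)
        + "-"
        + enhancer_links["end"].astype(str)
    )[["gene_id", "key"]]
    rows = []
    for a, b in transitions:
        t = f"{a}->{b}"
        sub = deg_table.loc[(deg_table["transition"] == t) & (deg_table["adj_p"] <= alpha)]
        up = set(sub.loc[sub["lfc"] > 0, "gene_id"])
        down = set(sub.loc[sub["lfc"] < 0, "gene_id"])
        n_act = link_key.loc[link_key["gene_id"].isin(up), "key"].nunique()
        n_dec = link_key.loc[link_key["gene_id"].isin(down), "key"].nunique()
        ratio = n_act / n_dec if n_dec > 0 else float("inf")
        rows.append(
            dict(
                transition=t,
                n_activated=int(n_act),
                n_decommissioned=int(n_dec),
                ratio=ratio,
                ratio_defined=n_dec > 0,
            )
        )
    return pd.DataFrame(rows)
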