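"""Co-accessibility links, TSS-cRE classification and the gene-peak model.

The co-accessibility estimator here is a declared stand-in for the
published graphical-lasso tool: cells are pooled into metacells of fixed
size by pseudotime order within (region, state), pooled counts are
binarised, and the score of a same-chromosome peak pair within the window
is the Pearson correlation of the binarised profiles.  Externally computed
link tables (chromA, startA, endA, chromB, startB, endB, score) are
accepted everywhere a link frame is, so the downstream filtering and
classification logic can also post-process real tool output.

A link is a TSS-cRE connection when exactly one anchor overlaps a gene TSS
and the other anchor overlaps no promoter window of any gene; the
non-TSS anchor is the candidate cis-regulatory element.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from scipy.stats import chi2

from .core_io import (
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    PeakMatrix,
    ValidationError,
    overlap_pairs,
)
from .differential import _fit_logistic
from .scoring import promoter_windows

LINK_COLUMNS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "score"]
TSS_LINK_COLUMNS = ["gene_id", "chrom", "start", "end", "score", "provenance"]
PAIR_COLUMNS = ["gene_id", "chrom", "start", "end", "peak_index", "sign", "p_value", "adj_p"]


def read_links_table(path: str | Path) -> pd.DataFrame:
    links = pd.read_csv(path, sep="\t")
    missing = [c for c in LINK_COLUMNS if c not in links.columns]
    if missing:
        raise ValidationError(f"{path}: links table missing columns {missing}")
    return links


# ---------------------------------------------------------------------------
# Metacell binarisation + correlation scores
# ---------------------------------------------------------------------------


def metacell_assignment(cells: pd.DataFrame, metacell_size: int = 50) -> np.ndarray:
    """Metacell index per cell: pseudotime-ordered chunks within (region, state).

    Remainder cells smaller than ``metacell_size`` are merged into the last
    metacell of their group, so every metacell has >= metacell_size cells.
    """
    if len(cells) < 2 * metacell_size:
        raise ValidationError(f"need >= {2 * metacell_size} cells for metacell pooling")
    assign = np.full(len(cells), -1, dtype=int)
    next_id = 0
    pos = np.arange(len(cells))
    frame = cells.reset_index(drop=True)
    for (_, _), grp in frame.groupby(["region", "state"], sort=True):
        order = grp.sort_values(["pseudotime", "barcode"], kind="stable").index.to_numpy()
        n_full = max(len(order) // metacell_size, 1)
        for k in range(n_full):
            lo = k * metacell_size
            hi = (k + 1) * metacell_size if k < n_full - 1 else len(order)
            assign[pos[order[lo:hi]]] = next_id
            next_id += 1
    return assign


def binarized_metacell_matrix(
    matrix: PeakMatrix, cells: pd.DataFrame, metacell_size: int = 50
) -> np.ndarray:
    """Metacell-by-peak 0/1 matrix: pooled count > 0."""
    assign = metacell_assignment(cells, metacell_size)
    n_meta = assign.max() + 1
    import scipy.sparse as sp

    G = sp.csr_matrix(
        (np.ones(len(assign)), (assign, np.arange(len(assign)))),
        shape=(n_meta, len(assign)),
    )
    pooled = np.asarray((G @ matrix.counts).todense())
    return (pooled > 0).astype(float)


def _interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        raise ValidationError("gap undefined across chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def coaccessibility_scores(
    matrix: PeakMatrix,
    cells: pd.DataFrame,
    window: int = 500_000,
    metacell_size: int = 50,
) -> pd.DataFrame:
    """Score all same-chromosome peak pairs within ``window`` bp.

    Peaks with constant binarised metacell profiles are excluded from
    pairing.  Output rows have peak_a < peak_b by coordinate.
    """
    if list(matrix.barcodes) != list(cells["barcode"]):
        raise ValidationError("matrix and cell table barcodes differ")
    B = binarized_metacell_matrix(matrix, cells, metacell_size)
    n_meta = B.shape[0]
    sd = B.std(axis=0)
    usable = sd > 0
    centered = B - B.mean(axis=0)
    norm = np.linalg.norm(centered, axis=0)
    unit = np.zeros_like(centered)
    unit[:, usable] = centered[:, usable] / norm[usable]

    order = sorted(range(len(matrix.peaks)), key=lambda i: (matrix.peaks[i].chrom, matrix.peaks[i].start, matrix.peaks[i].end))
    rows = []
    for oi, i in enumerate(order):
        if not usable[i]:
            continue
        pi = matrix.peaks[i]
        for j in order[oi + 1 :]:
            pj = matrix.peaks[j]
            if pj.chrom != pi.chrom:
                break
            if pj.start - pi.end > window:
                break
            if not usable[j]:
                continue
            if _interval_gap(pi, pj) > window:
                continue
            score = float(np.clip(unit[:, i] @ unit[:, j], -1.0, 1.0))
            a, b = (pi, pj) if (pi.start, pi.end) <= (pj.start, pj.end) else (pj, pi)
            rows.append((a.chrom, a.start, a.end, b.chrom, b.start, b.end, score))
    links = pd.DataFrame(rows, columns=LINK_COLUMNS)
    links.attrs["n_metacells"] = n_meta
    return links


def filter_links(links: pd.DataFrame, min_score: float = 0.25) -> pd.DataFrame:
    """Retain links with score >= min_score (inclusive threshold)."""
    return links.loc[links["score"] >= min_score].reset_index(drop=True)


def classify_tss_links(
    links: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    tss_slop: int = 0,
    upstream: int = 2000,
) -> pd.DataFrame:
    """TSS-cRE connections from filtered links.

    Emits one row per (overlapped TSS gene, link) when exactly one anchor
    overlaps >= 1 TSS (point, optionally +/- tss_slop) and the other anchor
    overlaps no promoter window of any gene; provenance is 'coaccess'.
    """
    windows = [w.interval for w in promoter_windows(annotation, upstream)]
    tss_points = [
        GenomicInterval(g.chrom, max(0, g.tss - tss_slop), g.tss + tss_slop + 1)
        for g in annotation
    ]
    gene_ids = [g.gene_id for g in annotation]

    anchors_a = [
        GenomicInterval(r.chrom_a, int(r.start_a), int(r.end_a)) for r in links.itertuples()
    ]
    anchors_b = [
        GenomicInterval(r.chrom_b, int(r.start_b), int(r.end_b)) for r in links.itertuples()
    ]

    def tss_hits(anchors: list[GenomicInterval]) -> list[list[str]]:
        hits: list[list[str]] = [[] for _ in anchors]
        for ai, gi in overlap_pairs(anchors, tss_points):
            hits[ai].append(gene_ids[gi])
        return hits

    def promoter_hit(anchors: list[GenomicInterval]) -> np.ndarray:
        flag = np.zeros(len(anchors), dtype=bool)
        for ai, _ in overlap_pairs(anchors, windows):
            flag[ai] = True
        return flag

    hits_a, hits_b = tss_hits(anchors_a), tss_hits(anchors_b)
    prom_a, prom_b = promoter_hit(anchors_a), promoter_hit(anchors_b)

    rows = []
    for i, link in enumerate(links.itertuples()):
        a_is_tss, b_is_tss = bool(hits_a[i]), bool(hits_b[i])
        if a_is_tss == b_is_tss:
            continue  # both or neither anchor on a TSS
        genes, cre, cre_prom = (
            (hits_a[i], anchors_b[i], prom_b[i]) if a_is_tss else (hits_b[i], anchors_a[i], prom_a[i])
        )
        if cre_prom:
            continue  # cRE side may not intersect any promoter window
        for gid in genes:
            rows.append((gid, cre.chrom, cre.start, cre.end, float(link.score), "coaccess"))
    return pd.DataFrame(rows, columns=TSS_LINK_COLUMNS)


def count_links_by_group(
    matrix: PeakMatrix,
    cells: pd.DataFrame,
    groupby: str,
    min_score: float = 0.25,
    seed: int = 0,
    window: int = 500_000,
    metacell_size: int = 50,
) -> pd.Series:
    """Per-group link counts after downsampling groups to equal cell numbers.

    Each group is downsampled without replacement to the smallest group's
    size and the co-accessibility estimator is re-run per group (rather
    than subsetting precomputed links).
    """
    if groupby not in ("region", "state"):
        raise ValidationError("groupby must be 'region' or 'state'")
    groups = sorted(cells[groupby].unique().tolist())
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    sizes = {g: int((cells[groupby] == g).sum()) for g in groups}
    n_min = min(sizes.values())
    if n_min < 2 * metacell_size:
        raise ValidationError(
            f"smallest group has {n_min} cells; need >= {2 * metacell_size}"
        )
    rng = np.random.default_rng(seed)
    counts = {}
    for g in groups:
        idx = np.nonzero((cells[groupby] == g).to_numpy())[0]
        take = np.sort(rng.choice(idx, size=n_min, replace=False))
        sub_cells = cells.iloc[take].reset_index(drop=True)
        sub = PeakMatrix(
            counts=matrix.counts[take],
            barcodes=[matrix.barcodes[i] for i in take],
            peaks=list(matrix.peaks),
        )
        links = coaccessibility_scores(sub, sub_cells, window=window, metacell_size=metacell_size)
        counts[g] = int((links["score"] >= min_score).sum())
    return pd.Series(counts, name="n_links")


# ---------------------------------------------------------------------------
# Expression -> binarised peak logistic model
# ---------------------------------------------------------------------------


def predict_gene_peak_pairs(
    expression: ExpressionMatrix,
    matrix: PeakMatrix,
    annotation: Sequence[GeneAnnotation],
    window: int = 500_000,
    alpha: float = 0.05,
    upstream: int = 2000,
) -> pd.DataFrame:
    """Gene-peak associations: expression predicting binarised peak state.

    For each gene with a TSS-overlapping peak of nonzero total count, every
    non-promoter peak within a +/- window/2 span around the TSS is tested
    with a likelihood-ratio test of ``P(count > 0) ~ 1 + expr`` against the
    intercept-only model; BH adjustment is genome-wide and pairs with
    adjusted p <= ``alpha`` are retained.
    """
    if list(expression.barcodes) != list(matrix.barcodes):
        raise ValidationError("expression and peak matrix barcodes differ")
    half = window // 2
    windows = [w.interval for w in promoter_windows(annotation, upstream)]
    is_promoter = np.zeros(len(matrix.peaks), dtype=bool)
    for pi, _ in overlap_pairs(matrix.peaks, windows):
        is_promoter[pi] = True

    depth = expression.total_counts().astype(float)
    med = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    scale = np.where(depth > 0, med / np.maximum(depth, 1e-12), 0.0)
    expr_mat = np.log1p(np.asarray(expression.counts.todense()) * scale[:, None])
    gene_col = {g: i for i, g in enumerate(expression.gene_ids)}

    peak_nz = np.asarray((matrix.counts > 0).todense())
    col_tot = np.asarray(matrix.counts.sum(axis=0)).ravel()

    # TSS-overlapping peaks per gene
    tss_points = [GenomicInterval(g.chrom, g.tss, g.tss + 1) for g in annotation]
    tss_peaks: dict[int, list[int]] = {}
    for pi, gi in overlap_pairs(matrix.peaks, tss_points):
        tss_peaks.setdefault(gi, []).append(pi)

    peaks_sorted = sorted(
        range(len(matrix.peaks)),
        key=lambda i: (matrix.peaks[i].chrom, matrix.peaks[i].start, matrix.peaks[i].end),
    )
    by_chrom: dict[str, list[int]] = {}
    for i in peaks_sorted:
        by_chrom.setdefault(matrix.peaks[i].chrom, []).append(i)
    starts_by_chrom = {
        c: (np.array([matrix.peaks[i].start for i in idx]), idx) for c, idx in by_chrom.items()
    }

    rows = []
    pvals = []
    for gi, gene in enumerate(annotation):
        tps = tss_peaks.get(gi, [])
        if not tps or col_tot[tps].sum() == 0:
            continue  # TSS peak absent or all-zero across barcodes
        if gene.gene_id not in gene_col:
            continue
        expr = expr_mat[:, gene_col[gene.gene_id]]
        if np.ptp(expr) == 0:
            continue  # constant expression: pairs skipped
        if gene.chrom not in starts_by_chrom:
            continue
        starts, idx = starts_by_chrom[gene.chrom]
        max_len = max(p.length for p in matrix.peaks)
        lo = int(np.searchsorted(starts, gene.tss - half - max_len, side="left"))
        for k in range(lo, len(idx)):
            pi = idx[k]
            p = matrix.peaks[pi]
            if p.start > gene.tss + half:
                break
            if p.end <= gene.tss - half or is_promoter[pi]:
                continue
            y = peak_nz[:, pi].astype(float)
            if y.min() == y.max():
                continue  # constant peak: skipped
            X_full = np.column_stack([np.ones_like(y), expr])
            b_f, ll_f, ok = _fit_logistic(X_full, y)
            if not ok:
                b_f, ll_f, _ = _fit_logistic(X_full, y, ridge=1e-4)
            pbar = y.mean()
            ll_null = len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
            stat = max(2.0 * (ll_f - ll_null), 0.0)
            pvals.append(float(chi2.sf(stat, df=1)))
            rows.append(
                (gene.gene_id, p.chrom, p.start, p.end, pi, int(np.sign(b_f[1])))
            )
    if not rows:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    adj = multipletests(np.asarray(pvals), method="fdr_bh")[1]
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS[:6])
    out["p_value"] = pvals
    out["adj_p"] = adj
    return out.loc[out["adj_p"] <= alpha].reset_index(drop=True)
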