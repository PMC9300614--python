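"""Integration of the two enhancer-prediction routes and histone overlap.

The co-accessibility route supplies TSS-cRE connections with their link
scores; the model route supplies gene-peak pairs with adjusted p values
(scored as -log10 adj p, infinities from underflowed p capped at
``cap_multiplier`` x the largest finite value over the whole score table).
Scores are percentile-ranked per gene, TSS-overlapping peaks are excluded,
intervals are extended 500 bp both ways and merged; the two merged sets are
then combined by union (all presumptive enhancers) or base-pair
intersection (the stringent list), and finally filtered to peaks
intersecting H3K27ac to give the high-confidence enhancer candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import (
    GeneAnnotation,
    GenomicInterval,
    HistonePeakSet,
    ValidationError,
    merge_intervals,
    overlap_pairs,
    overlaps_any,
)
from .scoring import promoter_windows

CANDIDATE_COLUMNS = ["chrom", "start", "end", "provenance", "genes", "best_rank"]


def percentile_rank_per_gene(
    scores: Mapping[str, Sequence[float]], cap_multiplier: float = 2.0
) -> dict[str, np.ndarray]:
    """Average-tie percentile ranks in (0, 1] per gene.

    Infinite scores (e.g. -log10 of an underflowed adjusted p value) are
    replaced by ``cap_multiplier`` times the greatest finite value over the
    entire score table before ranking.
    """
    all_vals = np.concatenate([np.asarray(v, float) for v in scores.values()]) if scores else np.array([])
    finite = all_vals[np.isfinite(all_vals)]
    has_inf = bool(np.isinf(all_vals).any())
    if has_inf and finite.size == 0:
        raise ValidationError("all scores infinite: no finite maximum to cap against")
    cap = cap_multiplier * finite.max() if finite.size else 0.0
    out = {}
    for gene, vals in scores.items():
        v = np.asarray(vals, float)
        if v.size == 0:
            raise ValidationError(f"empty score list for gene {gene}")
        v = np.where(np.isinf(v), cap, v)
        out[gene] = rankdata(v, method="average") / v.size
    return out


def extend_and_merge(
    intervals: Sequence[GenomicInterval], flank: int = 500
) -> list[GenomicInterval]:
    """Grow each interval by ``flank`` bp both ways (clamped at 0), merge.

    Overlapping or bookended results are joined; output is sorted and
    pairwise disjoint.
    """
    grown = [
        GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank) for iv in intervals
    ]
    return merge_intervals(grown, merge_bookended=True)


@dataclass
class PredictionSet:
    """One method's merged cRE intervals plus pre-merge per-gene ranks."""

    method: str  # 'coaccess' or 'model'
    intervals: list[GenomicInterval]
    ranks: pd.DataFrame  # gene_id, chrom, start, end, rank (pre-merge intervals)


def build_prediction_set(
    scored_cres: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    method: str,
    flank: int = 500,
    cap_multiplier: float = 2.0,
) -> PredictionSet:
    """From per-gene scored cREs (gene_id, chrom, start, end, score).

    Excludes intervals overlapping any gene TSS, percentile-ranks scores
    per gene, then extends and merges the surviving intervals.
    """
    tss_points = [GenomicInterval(g.chrom, g.tss, g.tss + 1) for g in annotation]
    ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in scored_cres.itertuples()
    ]
    on_tss = overlaps_any(ivs, tss_points)
    kept = scored_cres.loc[~on_tss].reset_index(drop=True)
    per_gene = {g: grp["score"].to_numpy(float) for g, grp in kept.groupby("gene_id")}
    ranks = percentile_rank_per_gene(per_gene, cap_multiplier) if per_gene else {}
    rank_col = np.empty(len(kept))
    seen: dict[str, int] = {}
    for i, gid in enumerate(kept["gene_id"]):
        j = seen.get(gid, 0)
        rank_col[i] = ranks[gid][j]
        seen[gid] = j + 1
    ranked = kept[["gene_id", "chrom", "start", "end"]].copy()
    ranked["rank"] = rank_col
    merged = extend_and_merge(
        [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in kept.itertuples()], flank
    )
    return PredictionSet(method=method, intervals=merged, ranks=ranked)


def _annotate(intervals: list[GenomicInterval], prov: list[str], rank_tables: list[pd.DataFrame]) -> pd.DataFrame:
    ranks = pd.concat(rank_tables, ignore_index=True) if rank_tables else pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "rank"]
    )
    rank_ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in ranks.itertuples()
    ]
    genes: list[set[str]] = [set() for _ in intervals]
    best = np.zeros(len(intervals))
    for ii, ri in overlap_pairs(intervals, rank_ivs):
        genes[ii].add(ranks["gene_id"].iloc[ri])
        best[ii] = max(best[ii], ranks["rank"].iloc[ri])
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "provenance": prov,
            "genes": [";".join(sorted(g)) for g in genes],
            "best_rank": best,
        }
    )


def combine_predictions(
    coaccess: PredictionSet, model: PredictionSet, mode: str = "intersect"
) -> pd.DataFrame:
    """Union or base-pair intersection of the two merged cRE sets.

    Union re-merges the concatenation (provenance: contributing methods);
    intersect returns base-pair intersections with provenance 'both'.
    Per-gene ranks are carried through by interval overlap.
    """
    rank_tables = [coaccess.ranks, model.ranks]
    if mode == "union":
        merged = merge_intervals(list(coaccess.intervals) + list(model.intervals))
        prov = []
        for iv in merged:
            from_co = overlaps_any([iv], coaccess.intervals)[0]
            from_mo = overlaps_any([iv], model.intervals)[0]
            prov.append("both" if from_co and from_mo else ("coaccess" if from_co else "model"))
        return _annotate(merged, prov, rank_tables)
    if mode == "intersect":
        pieces: list[GenomicInterval] = []
        for i, j in overlap_pairs(coaccess.intervals, model.intervals):
            piece = coaccess.intervals[i].intersection(model.intervals[j])
            if piece is not None:
                pieces.append(piece)
        pieces = merge_intervals(pieces)
        return _annotate(pieces, ["both"] * len(pieces), rank_tables)
    raise ValidationError(f"mode must be 'union' or 'intersect', got {mode!r}")


def filter_by_h3k27ac(
    candidates: pd.DataFrame, histone_sets: Sequence[HistonePeakSet]
) -> pd.DataFrame:
    """Retain candidates overlapping (>=1 bp) the union of H3K27ac sets."""
    k27 = [hs for hs in histone_sets if hs.mark == "H3K27ac"]
    if not k27:
        raise ValidationError("no H3K27ac peak set provided")
    union: list[GenomicInterval] = [iv for hs in k27 for iv in hs.intervals]
    ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in candidates.itertuples()]
    hit = overlaps_any(ivs, union)
    out = candidates.copy()
    out["h3k27ac_supported"] = hit
    return out.loc[hit].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Histone-overlap quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapReport:
    label: str
    n_a: int
    n_b: int
    n_intersect: int  # min of per-side hit counts (conservative Venn core)
    percent_a_overlapping: float  # NaN when A is empty ("missing")


def percent_overlap(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval], label: str = ""
) -> OverlapReport:
    """Share of A intervals intersecting >= 1 interval of B."""
    hits_a = int(overlaps_any(list(set_a), list(set_b)).sum())
    hits_b = int(overlaps_any(list(set_b), list(set_a)).sum())
    percent = 100.0 * hits_a / len(set_a) if len(set_a) else float("nan")
    return OverlapReport(
        label=label,
        n_a=len(set_a),
        n_b=len(set_b),
        n_intersect=min(hits_a, hits_b),
        percent_a_overlapping=percent,
    )


def histone_overlap_comparisons(
    atac_peaks: Sequence[GenomicInterval],
    windows: Sequence[GenomicInterval],
    tss_links: pd.DataFrame,
    histone_sets: Sequence[HistonePeakSet],
    region: str,
) -> list[OverlapReport]:
    """The three per-region ATAC/histone Venn comparisons.

    (1) promoter-overlapping ATAC peaks vs promoter-overlapping H3K4me3;
    (2) non-promoter ATAC peaks vs non-promoter H3K27ac;
    (3) the subset of (2) that is the cRE of >= 1 TSS link, vs the same
    H3K27ac set.  Raises naming the comparison if a mark set is missing.
    """
    k4 = [hs for hs in histone_sets if hs.mark == "H3K4me3" and hs.region == region]
    k27 = [hs for hs in histone_sets if hs.mark == "H3K27ac" and hs.region == region]
    if not k4:
        raise ValidationError(
            f"missing H3K4me3 set for {region}: promoter comparison skipped"
        )
    if not k27:
        raise ValidationError(
            f"missing H3K27ac set for {region}: non-promoter comparisons skipped"
        )
    windows = list(windows)
    atac = list(atac_peaks)
    at_prom = overlaps_any(atac, windows)
    a_prom = [p for p, f in zip(atac, at_prom) if f]
    a_dist = [p for p, f in zip(atac, at_prom) if not f]
    k4_iv = [iv for hs in k4 for iv in hs.intervals]
    k27_iv = [iv for hs in k27 for iv in hs.intervals]
    b_prom = [iv for iv, f in zip(k4_iv, overlaps_any(k4_iv, windows)) if f]
    b_dist = [iv for iv, f in zip(k27_iv, overlaps_any(k27_iv, windows)) if not f]

    cre_ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in tss_links.itertuples()
    ]
    linked = [p for p, f in zip(a_dist, overlaps_any(a_dist, cre_ivs)) if f]

    return [
        percent_overlap(a_prom, b_prom, label=f"{region}:promoter_atac_vs_h3k4me3"),
        percent_overlap(a_dist, b_dist, label=f"{region}:nonpromoter_atac_vs_h3k27ac"),
        percent_overlap(linked, b_dist, label=f"{region}:linked_nonpromoter_atac_vs_h3k27ac"),
    ]


def reports_frame(reports: Sequence[OverlapReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                label=r.label,
                n_a=r.n_a,
                n_b=r.n_b,
                n_intersect=r.n_intersect,
                percent_a_overlapping=r.percent_a_overlapping,
            )
            for r in reports
        ]
    )


# ---------------------------------------------------------------------------
# Full pipeline convenience
# ---------------------------------------------------------------------------


def high_confidence_enhancers(
    tss_links: pd.DataFrame,
    gene_peak_pairs: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    histone_sets: Sequence[HistonePeakSet],
    mode: str = "intersect",
    flank: int = 500,
    cap_multiplier: float = 2.0,
) -> pd.DataFrame:
    """TSS links + model pairs -> combined, H3K27ac-supported candidates."""
    co_scored = tss_links[["gene_id", "chrom", "start", "end", "score"]].copy()
    with np.errstate(divide="ignore"):
        model_score = -np.log10(gene_peak_pairs["adj_p"].to_numpy(float))
    mo_scored = gene_peak_pairs[["gene_id", "chrom", "start", "end"]].copy()
    mo_scored["score"] = model_score
    co = build_prediction_set(co_scored, annotation, "coaccess", flank, cap_multiplier)
    mo = build_prediction_set(mo_scored, annotation, "model", flank, cap_multiplier)
    combined = combine_predictions(co, mo, mode=mode)
    return filter_by_h3k27ac(combined, histone_sets)
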