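"""Barcode-level quality filtering.

Two filters are provided: Tukey's fence method for far-out outliers
(``[Q1 - k*(Q3 - Q1), Q3 + k*(Q3 - Q1)]`` with k = 3), applied to any set
of per-barcode metrics with removal on *any* violated metric, and the
alternative fixed-range filter on log10 total counts and promoter ratio.

Quartiles use the linear-interpolation definition ("type 7", the numpy
default); the discontinuous variants can be selected via ``method`` for
reproducibility comparisons.  Fences are computed once on the full input,
never recomputed on the filtered set, and boundary values are kept
(removal requires a strictly outside value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ValidationError


@dataclass(frozen=True)
class FencePair:
    lower: float
    upper: float
    q1: float
    q3: float
    k: float

    def contains(self, value: float) -> bool:
        """True iff the value is inside the closed retained interval."""
        return self.lower <= value <= self.upper


def tukey_fences(values: Sequence[float], k: float = 3.0, method: str = "linear") -> FencePair:
    """Far-out fences from the printed formula; requires >= 4 finite values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValidationError(f"tukey_fences needs >= 4 values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValidationError("tukey_fences requires finite values")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=method)
    iqr = q3 - q1
    return FencePair(lower=q1 - k * iqr, upper=q3 + k * iqr, q1=float(q1), q3=float(q3), k=k)


def filter_barcodes(
    cells: pd.DataFrame,
    metric_names: Sequence[str],
    k: float = 3.0,
    method: str = "linear",
) -> tuple[list[str], pd.DataFrame]:
    """Remove barcodes outlying in ANY listed metric.

    Returns the kept barcodes (input order) and a removal report with one
    row per (barcode, violated metric): barcode, metric, value, fence
    violated ('lower'/'upper'), and the fence value.
    """
    unknown = [m for m in metric_names if m not in cells.columns]
    if unknown:
        raise ValidationError(f"unknown metric names: {unknown}")
    fences = {m: tukey_fences(cells[m].to_numpy(float), k=k, method=method) for m in metric_names}
    removed = np.zeros(len(cells), dtype=bool)
    report_rows = []
    for m in metric_names:
        f = fences[m]
        vals = cells[m].to_numpy(float)
        low, high = vals < f.lower, vals > f.upper
        removed |= low | high
        for idx in np.nonzero(low | high)[0]:
            report_rows.append(
                dict(
                    barcode=cells["barcode"].iloc[idx],
                    metric=m,
                    value=vals[idx],
                    fence="lower" if low[idx] else "upper",
                    fence_value=f.lower if low[idx] else f.upper,
                )
            )
    kept = cells.loc[~removed, "barcode"].tolist()
    report = pd.DataFrame(
        report_rows, columns=["barcode", "metric", "value", "fence", "fence_value"]
    )
    return kept, report


def range_filter(
    cells: pd.DataFrame,
    log10_umi_range: tuple[float, float] = (3.0, 6.0),
    promoter_ratio_range: tuple[float, float] = (0.05, 0.6),
) -> list[str]:
    """Keep barcodes with log10(UMI) and promoter ratio inside closed ranges."""
    totals = cells["total_counts"].to_numpy(float)
    if (totals <= 0).any():
        raise ValidationError("range_filter requires positive total counts per barcode")
    log_umi = np.log10(totals)
    ratio = cells["promoter_ratio"].to_numpy(float)
    lo_u, hi_u = log10_umi_range
    lo_r, hi_r = promoter_ratio_range
    keep = (log_umi >= lo_u) & (log_umi <= hi_u) & (ratio >= lo_r) & (ratio <= hi_r)
    return cells.loc[keep, "barcode"].tolist()
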