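"""Domain types, genomic-interval algebra, and file I/O.

Coordinates are 0-based, half-open (BED convention) everywhere inside the
package.  Chromosome names are compared as exact strings; helpers emit a
warning listing chromosomes present in one input but not another rather
than silently normalising (``chr1`` vs ``1`` mismatches are the dominant
interval-bug class).

Counts travel as Cellranger-like Matrix Market triples:
``matrix.mtx`` (cell x feature), a barcodes file (one per line) and a
feature index (BED for peaks, one-id-per-line for genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

VALID_STRANDS = ("+", "-", ".")
REGIONS = ("MGE", "LGE", "CGE", "CTX")
STATES = ("AP", "BP", "N")
HISTONE_MARKS = ("H3K4me3", "H3K27ac", "H3K27me3")


class FormatError(ValueError):
    """Malformed or mutually inconsistent input files."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (exact-string chrom match)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Single-transcript gene model: TSS, first exon and gene body.

    ``tss`` is the first transcribed base; on the minus strand it is the
    rightmost base of the gene body. The promoter side is determined by
    ``strand`` (see :func:`epilink.scoring.promoter_windows`).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    first_exon: GenomicInterval
    gene_body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene strand must be + or -, got {self.strand!r}")
        if self.first_exon.chrom != self.chrom or self.gene_body.chrom != self.chrom:
            raise ValidationError(f"{self.gene_id}: exon/body chromosome mismatch")
        if not (
            self.gene_body.start <= self.first_exon.start
            and self.first_exon.end <= self.gene_body.end
        ):
            raise ValidationError(f"{self.gene_id}: first exon not contained in gene body")
        if not self.gene_body.start <= self.tss < self.gene_body.end:
            raise ValidationError(f"{self.gene_id}: TSS outside gene body")


@dataclass
class CountMatrix:
    """Sparse nonnegative cell-by-feature count matrix with ordered indices."""

    counts: sp.csr_matrix
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if self.counts.shape[0] != len(self.barcodes):
            raise FormatError(
                f"matrix has {self.counts.shape[0]} rows but {len(self.barcodes)} barcodes"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class PeakMatrix(CountMatrix):
    """Cell-by-peak fragment counts; columns indexed by genomic intervals."""

    peaks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.counts.shape[1] != len(self.peaks):
            raise FormatError(
                f"matrix has {self.counts.shape[1]} columns but {len(self.peaks)} peaks"
            )
        if len(set(self.peaks)) != len(self.peaks):
            raise ValidationError("peak intervals must be unique")


@dataclass
class ExpressionMatrix(CountMatrix):
    """Cell-by-gene expression counts."""

    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.counts.shape[1] != len(self.gene_ids):
            raise FormatError(
                f"matrix has {self.counts.shape[1]} columns but {len(self.gene_ids)} genes"
            )


@dataclass(frozen=True)
class HistonePeakSet:
    """Peak calls for one histone mark in one brain region."""

    mark: str
    region: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.mark not in HISTONE_MARKS:
            raise ValidationError(f"unknown histone mark {self.mark!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        object.__setattr__(self, "intervals", tuple(self.intervals))


#: Required columns of a cell table (a plain pandas DataFrame).
CELL_TABLE_COLUMNS = ("barcode", "region", "state", "cluster_id", "pseudotime")


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the per-barcode metadata table invariants and return it."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing columns: {missing}")
    if cells["barcode"].duplicated().any():
        dups = cells.loc[cells["barcode"].duplicated(), "barcode"].tolist()
        raise ValidationError(f"duplicate barcodes in cell table: {dups[:5]}")
    if not np.isfinite(cells["pseudotime"].to_numpy(float)).all():
        raise ValidationError("pseudotime must be finite")
    bad_region = set(cells["region"]) - set(REGIONS)
    bad_state = set(cells["state"]) - set(STATES)
    if bad_region:
        raise ValidationError(f"unknown regions in cell table: {sorted(bad_region)}")
    if bad_state:
        raise ValidationError(f"unknown states in cell table: {sorted(bad_state)}")
    return cells


# ---------------------------------------------------------------------------
# Interval algebra (vectorised; brute-force oracles live in the test suite)
# ---------------------------------------------------------------------------


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in intervals],
            "start": np.fromiter((i.start for i in intervals), dtype=np.int64, count=len(intervals)),
            "end": np.fromiter((i.end for i in intervals), dtype=np.int64, count=len(intervals)),
            "strand": [i.strand for i in intervals],
        }
    )


def frame_to_intervals(frame: pd.DataFrame) -> list[GenomicInterval]:
    strands = frame["strand"] if "strand" in frame.columns else ["."] * len(frame)
    return [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in zip(frame["chrom"], frame["start"], frame["end"], strands)
    ]


def warn_chrom_mismatch(
    a: Iterable[str], b: Iterable[str], label_a: str = "first", label_b: str = "second"
) -> None:
    """Warn about chromosomes present in only one of two inputs."""
    sa, sb = set(a), set(b)
    only_a, only_b = sorted(sa - sb), sorted(sb - sa)
    if only_a or only_b:
        warnings.warn(
            f"chromosome sets differ: only in {label_a}: {only_a}; only in {label_b}: {only_b}",
            stacklevel=3,
        )


def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean array: does each query overlap (>=1 bp) any subject interval?"""
    out = np.zeros(len(queries), dtype=bool)
    if not len(queries) or not len(subjects):
        return out
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in subjects:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        cur_s, cur_e = ivs[0]
        for s0, e0 in ivs[1:]:
            if s0 < cur_e:  # overlapping (not merely bookended): union for hit-testing
                cur_e = max(cur_e, e0)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s0, e0
        starts.append(cur_s)
        ends.append(cur_e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    for i, q in enumerate(queries):
        if q.chrom not in merged:
            continue
        starts, ends = merged[q.chrom]
        j = np.searchsorted(starts, q.end, side="left")  # subjects starting before q.end
        out[i] = j > 0 and bool((ends[:j] > q.start).any())
    return out


def overlap_pairs(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (i, j) index pairs with a[i] overlapping b[j], sorted."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, s in enumerate(b):
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end, j))
    pairs: list[tuple[int, int]] = []
    for chrom, items in by_chrom.items():
        items.sort()
        starts = np.asarray([x[0] for x in items])
        ends = np.asarray([x[1] for x in items])
        idx = np.asarray([x[2] for x in items])
        for i, q in enumerate(a):
            if q.chrom != chrom:
                continue
            hi = np.searchsorted(starts, q.end, side="left")
            hit = np.nonzero(ends[:hi] > q.start)[0]
            pairs.extend((i, int(idx[h])) for h in hit)
    pairs.sort()
    return pairs


def merge_intervals(
    intervals: Sequence[GenomicInterval], merge_bookended: bool = True
) -> list[GenomicInterval]:
    """Union of intervals: sorted, pairwise disjoint.

    With ``merge_bookended`` (default) abutting intervals (end == start) are
    joined as well, matching ``GenomicRanges::reduce`` semantics.
    """
    if not intervals:
        return []
    out: list[GenomicInterval] = []
    key = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    cur = key[0]
    cs, ce = cur.start, cur.end
    for nxt in key[1:]:
        joined = nxt.chrom == cur.chrom and (
            nxt.start < ce or (merge_bookended and nxt.start == ce)
        )
        if joined:
            ce = max(ce, nxt.end)
        else:
            out.append(GenomicInterval(cur.chrom, cs, ce))
            cur, cs, ce = nxt, nxt.start, nxt.end
    out.append(GenomicInterval(cur.chrom, cs, ce))
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; parse errors name the offending line number."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 fields: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates: {line!r}") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    extra_columns: pd.DataFrame | None = None,
    bed6: bool = False,
) -> None:
    """Write intervals as BED3 (or BED6 with '.' name / 0 score), plus extras.

    Round-trips exactly through :func:`read_bed`.
    """
    if extra_columns is not None and len(extra_columns) != len(intervals):
        raise ValidationError("extra_columns length does not match intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if bed6:
                cols += [".", "0", iv.strand]
            if extra_columns is not None:
                cols += [str(v) for v in extra_columns.iloc[i]]
            fh.write("\t".join(cols) + "\n")


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_peak_matrix(
    matrix_path: str | Path, barcodes_path: str | Path, peaks_path: str | Path
) -> PeakMatrix:
    """Read a Matrix Market triplet + barcodes TSV + peaks BED triple."""
    counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    barcodes = _read_lines(barcodes_path)
    peaks = read_bed(peaks_path)
    return PeakMatrix(counts=counts, barcodes=barcodes, peaks=peaks)


def read_expression_matrix(
    matrix_path: str | Path, barcodes_path: str | Path, features_path: str | Path
) -> ExpressionMatrix:
    counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    barcodes = _read_lines(barcodes_path)
    gene_ids = [ln.split("\t")[0] for ln in _read_lines(features_path)]
    return ExpressionMatrix(counts=counts, barcodes=barcodes, gene_ids=gene_ids)


def write_count_matrix(
    matrix: CountMatrix, matrix_path: str | Path, barcodes_path: str | Path
) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(matrix.counts))
    with open(barcodes_path, "w") as fh:
        fh.writelines(b + "\n" for b in matrix.barcodes)


ANNOTATION_COLUMNS = (
    "gene_id",
    "chrom",
    "strand",
    "tss",
    "exon1_start",
    "exon1_end",
    "body_start",
    "body_end",
)


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the gene-annotation TSV (header per ``ANNOTATION_COLUMNS``)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    dup = table.loc[table["gene_id"].duplicated(), "gene_id"].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate gene_id entries: {dup}")
    genes: list[GeneAnnotation] = []
    for row in table.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {row.gene_id}: bad strand {row.strand!r}")
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                first_exon=GenomicInterval(str(row.chrom), int(row.exon1_start), int(row.exon1_end)),
                gene_body=GenomicInterval(str(row.chrom), int(row.body_start), int(row.body_end)),
            )
        )
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    rows = [
        (
            g.gene_id,
            g.chrom,
            g.strand,
            g.tss,
            g.first_exon.start,
            g.first_exon.end,
            g.gene_body.start,
            g.gene_body.end,
        )
        for g in genes
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return validate_cell_table(pd.read_csv(path, sep="\t"))


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(cells).to_csv(path, sep="\t", index=False)
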