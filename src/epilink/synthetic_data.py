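"""Synthetic multiome generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume for an
embryonic-forebrain atlas: 4 brain regions (MGE/LGE/CGE/CTX) x 3 maturation
states (AP/BP/N), region/state-specific accessibility programs, planted
enhancer-gene links, per-cell depth variation, chromatin opening one
maturation state before transcript upregulation, planted depth outliers,
and region-matched histone peak emission.

Gene activity is modelled with continuous per-gene on/off thresholds on the
pseudotime axis (state rank + jitter in [0, 3)): "early" genes switch off at
a gene-specific time tau_off, "late" genes switch on at tau_on, and
region-restricted genes may also be constitutively on within their region.
Accessibility uses the same window with the onset shifted earlier by
``rna_lag`` maturation states.  All elements of a gene (promoter, first
exon, planted enhancers) share the gene's accessibility indicator, which is
what induces the planted co-accessibility.

Genes are placed ~600 kb apart so each gene's regulatory neighbourhood is
isolated at the 0.5 Mb co-accessibility window; enhancers and local
background peaks sit on a 10 kb offset grid within +/-200 kb of the TSS and
never overlap any promoter window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    REGIONS,
    STATES,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    HistonePeakSet,
    PeakMatrix,
    ValidationError,
    overlaps_any,
    write_bed,
    write_cell_table,
    write_count_matrix,
    write_gene_annotation,
)
from .scoring import promoter_windows

PEAK_ROLES = ("promoter", "exon1", "enhancer", "background")


class SizingError(ValueError):
    """Requested gene density does not fit on the simulated chromosomes."""


@dataclass
class SimulationDesign:
    """Parameters of the default study-scale simulation.

    Rates are Poisson means per element per cell at depth multiplier 1;
    ``depth_lognormal`` gives (mu, sigma) of the log-normal per-cell depth.
    ``rna_lag`` is the number of maturation states by which accessibility
    precedes expression.  ``dispersion`` is a hook for gamma-Poisson
    overdispersion (None = pure Poisson).
    """

    n_genes: int = 200
    n_enhancers_per_gene: tuple[int, int] = (1, 3)
    cells_per_group: int = 150
    regions: tuple[str, ...] = REGIONS
    states: tuple[str, ...] = STATES
    chrom_count: int = 4
    chrom_length: int = 32_000_000
    depth_lognormal: tuple[float, float] = (0.0, 0.4)
    open_rate_high: float = 0.5
    open_rate_low: float = 0.0004
    # promoters keep partial accessibility when the gene is off and close
    # later than enhancers after downregulation (decommissioning is
    # enhancer-led; promoter openness partially persists)
    promoter_floor_frac: float = 0.05
    promoter_close_lag: float = 0.5
    rna_lag: int = 1
    outlier_fraction: float = 0.05
    h3k27ac_false_negative_rate: float = 0.1
    seed: int = 0
    # program composition
    pan_region_prob: float = 0.2
    region_weights: tuple[float, ...] = (0.13, 0.13, 0.13, 0.61)
    temporal_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # early, late, constant
    # geometry (bp)
    gene_spacing: int = 600_000
    gene_body_length: int = 20_000
    exon1_length: int = 200
    enhancer_width: int = 500
    background_width: int = 400
    n_background_per_gene: int = 2
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.open_rate_low < self.open_rate_high):
            raise ValidationError("need 0 < open_rate_low < open_rate_high")
        if self.rna_lag not in (0, 1):
            raise ValidationError("rna_lag must be 0 or 1")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValidationError("outlier_fraction must be in [0, 0.5)")
        if self.cells_per_group <= 0:
            raise ValidationError("cells_per_group must be positive (empty design group)")
        lo, hi = self.n_enhancers_per_gene
        if not (0 <= lo <= hi):
            raise ValidationError("invalid n_enhancers_per_gene range")
        if len(self.region_weights) != len(self.regions):
            raise ValidationError("region_weights length must match regions")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationDesign":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in (
            "n_enhancers_per_gene",
            "depth_lognormal",
            "regions",
            "states",
            "region_weights",
            "temporal_probs",
        ):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted truth tables used as the oracle by recovery tests."""

    gene_params: pd.DataFrame  # gene_id, scope, temporal_class, tau_on, tau_off, acc_on
    gene_program: pd.DataFrame  # gene_id, region, state, active
    peak_table: pd.DataFrame  # chrom, start, end, role, gene_id (aligned with peak order)
    true_links: pd.DataFrame  # gene_id, chrom, start, end
    planted_outliers: list[str] = field(default_factory=list)
    early_genes: set[str] = field(default_factory=set)
    late_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.early_genes & self.late_genes:
            raise ValidationError("early and late gene sets must be disjoint")


@dataclass
class SimulatedDataset:
    design: SimulationDesign
    genes: list[GeneAnnotation]
    peaks: list[GenomicInterval]
    ground_truth: GroundTruth
    atac: PeakMatrix
    rna: ExpressionMatrix
    cells: pd.DataFrame
    histone_sets: list[HistonePeakSet]


# ---------------------------------------------------------------------------
# Genome / program layout
# ---------------------------------------------------------------------------

_ENH_MARGIN = 250_000  # chromosomal margin so offset grid stays on-chromosome


def _offset_grid() -> np.ndarray:
    """Candidate element offsets from the TSS: +/- 15..95 kb in 10 kb steps.

    Bounded at 95 kb so that, at the default 600 kb gene spacing, every
    element stays outside the 0.5 Mb pairing window of the neighbouring
    genes' anchors.
    """
    mags = np.arange(15_000, 100_000, 10_000)
    return np.concatenate([mags, -mags])


def simulate_genome(
    design: SimulationDesign, seed: int | None = None
) -> tuple[list[GeneAnnotation], list[GenomicInterval], GroundTruth]:
    """Lay out genes, peaks and the activity program; counts come later.

    Returns the annotation, the ordered peak list, and a GroundTruth whose
    ``planted_outliers`` is still empty (filled by :func:`simulate_counts`).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_chrom = design.chrom_count
    per_chrom = -(-design.n_genes // n_chrom)  # ceil
    needed = 2 * _ENH_MARGIN + per_chrom * design.gene_spacing
    if needed > design.chrom_length:
        raise SizingError(
            f"{design.n_genes} genes need {needed} bp per chromosome "
            f"(spacing {design.gene_spacing}), have {design.chrom_length}"
        )

    genes: list[GeneAnnotation] = []
    peak_rows: list[tuple[str, int, int, str, str]] = []
    params_rows: list[dict] = []
    grid = _offset_grid()

    n_early = 0
    for gi in range(design.n_genes):
        gene_id = f"gene{gi:04d}"
        chrom = f"chr{gi % n_chrom + 1}"
        slot = gi // n_chrom
        tss = _ENH_MARGIN + slot * design.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            body = GenomicInterval(chrom, tss, tss + design.gene_body_length)
            exon1 = GenomicInterval(chrom, tss, tss + design.exon1_length)
        else:
            body = GenomicInterval(chrom, tss - design.gene_body_length + 1, tss + 1)
            exon1 = GenomicInterval(chrom, tss - design.exon1_length + 1, tss + 1)
        gene = GeneAnnotation(gene_id, chrom, strand, tss, exon1, body)
        genes.append(gene)

        # activity program
        if rng.random() < design.pan_region_prob:
            scope = "pan"
            pe, pl, _ = design.temporal_probs
            temporal = "early" if rng.random() < pe / (pe + pl) else "late"
        else:
            w = np.asarray(design.region_weights, float)
            scope = str(rng.choice(list(design.regions), p=w / w.sum()))
            temporal = str(
                rng.choice(["early", "late", "constant"], p=np.asarray(design.temporal_probs))
            )
        n_states = len(design.states)
        if temporal == "early":
            tau_on = 0.0
            # most early genes decommission late (progressive repression):
            # their expression drop falls in the BP->N transition
            tau_off = rng.uniform(2.0, 2.4) if rng.random() < 0.9 else rng.uniform(0.6, 1.0)
            n_early += 1
        elif temporal == "late":
            # activation onset straddles the AP->BP boundary
            tau_on = rng.uniform(1.2, 1.8)
            tau_off = float(n_states)
        else:
            tau_on, tau_off = 0.0, float(n_states)
        params_rows.append(
            dict(
                gene_id=gene_id,
                chrom=chrom,
                tss=tss,
                strand=strand,
                scope=scope,
                temporal_class=temporal,
                tau_on=round(tau_on, 6),
                tau_off=round(tau_off, 6),
                acc_on=round(tau_on - design.rna_lag, 6),
            )
        )

        # peaks: promoter window, first exon, enhancers + local background
        pw = promoter_windows([gene])[0].interval
        peak_rows.append((chrom, pw.start, pw.end, "promoter", gene_id))
        peak_rows.append((chrom, exon1.start, exon1.end, "exon1", gene_id))
        k_enh = int(rng.integers(design.n_enhancers_per_gene[0], design.n_enhancers_per_gene[1] + 1))
        n_slots = k_enh + design.n_background_per_gene
        offsets = rng.choice(grid, size=n_slots, replace=False)
        for j, off in enumerate(offsets):
            role = "enhancer" if j < k_enh else "background"
            width = design.enhancer_width if role == "enhancer" else design.background_width
            start = int(tss + off)
            peak_rows.append((chrom, start, start + width, role, gene_id))

    peak_table = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "role", "gene_id"])
    peak_table = peak_table.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
        drop=True
    )
    peaks = [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in peak_table.itertuples()
    ]

    gene_params = pd.DataFrame(params_rows)
    program = _state_program(gene_params, design)
    enh = peak_table[peak_table["role"] == "enhancer"]
    true_links = enh[["gene_id", "chrom", "start", "end"]].reset_index(drop=True)

    truth = GroundTruth(
        gene_params=gene_params,
        gene_program=program,
        peak_table=peak_table,
        true_links=true_links,
        early_genes=set(gene_params.loc[gene_params.temporal_class == "early", "gene_id"]),
        late_genes=set(gene_params.loc[gene_params.temporal_class == "late", "gene_id"]),
    )
    return genes, peaks, truth


def _state_program(gene_params: pd.DataFrame, design: SimulationDesign) -> pd.DataFrame:
    """Discretise expression windows to on/off per (gene, region, state).

    A gene is 'on' in a state iff its expression window covers at least half
    of the state's unit pseudotime interval, and the region is in scope.
    """
    rows = []
    for g in gene_params.itertuples():
        for region in design.regions:
            in_scope = g.scope in ("pan", region)
            for si, state in enumerate(design.states):
                cov = max(0.0, min(g.tau_off, si + 1) - max(g.tau_on, si))
                rows.append(
                    dict(
                        gene_id=g.gene_id,
                        region=region,
                        state=state,
                        active=bool(in_scope and cov >= 0.5),
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _poisson(rng: np.random.Generator, lam: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion:
        lam = lam * rng.gamma(1.0 / dispersion, dispersion, size=lam.shape)
    return rng.poisson(lam)


def simulate_counts(
    annotation: Sequence[GeneAnnotation],
    ground_truth: GroundTruth,
    design: SimulationDesign,
    seed: int | None = None,
) -> tuple[PeakMatrix, ExpressionMatrix, pd.DataFrame]:
    """Draw ATAC and RNA counts plus the cell table for the planted program.

    Outlier barcodes are re-drawn with their ATAC depth scaled so their
    total count lands at ~2x the Tukey far-out upper fence (k=3) of the
    remaining cells, i.e. planted outliers are outliers by construction.
    Fills ``ground_truth.planted_outliers`` in place.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    regions, states = list(design.regions), list(design.states)
    n_group = design.cells_per_group
    groups = [(r, s) for r in regions for s in states]
    n_cells = n_group * len(groups)

    barcodes, cregion, cstate, cluster = [], [], [], []
    for r, s in groups:
        for i in range(n_group):
            barcodes.append(f"{r}_{s}_{i:04d}")
            cregion.append(r)
            cstate.append(s)
            cluster.append(regions.index(r) * len(states) + states.index(s))
    state_rank = np.array([states.index(s) for s in cstate], float)
    pseudotime = state_rank + rng.uniform(0.0, 1.0, size=n_cells)

    gp = ground_truth.gene_params.set_index("gene_id")
    gene_ids = [g.gene_id for g in annotation]
    tau_on = gp.loc[gene_ids, "tau_on"].to_numpy(float)
    tau_off = gp.loc[gene_ids, "tau_off"].to_numpy(float)
    acc_on = gp.loc[gene_ids, "acc_on"].to_numpy(float)
    scope = gp.loc[gene_ids, "scope"].to_numpy(object)

    region_arr = np.asarray(cregion, dtype=object)
    in_scope = (scope[None, :] == "pan") | (scope[None, :] == region_arr[:, None])
    t = pseudotime[:, None]
    active_expr = in_scope & (t >= tau_on[None, :]) & (t < tau_off[None, :])
    active_acc = in_scope & (t >= acc_on[None, :]) & (t < tau_off[None, :])

    mu, sigma = design.depth_lognormal
    depth_atac = rng.lognormal(mu, sigma, size=n_cells)
    depth_rna = rng.lognormal(mu, sigma, size=n_cells)

    # per-peak rates from the owning gene's accessibility indicator
    pt = ground_truth.peak_table
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    peak_gene = pt["gene_id"].map(gene_index).to_numpy()
    is_element = (pt["role"] != "background").to_numpy()
    rate = np.full((n_cells, len(pt)), design.open_rate_low)
    elem_cols = np.nonzero(is_element)[0]
    rate[:, elem_cols] = np.where(
        active_acc[:, peak_gene[elem_cols]], design.open_rate_high, design.open_rate_low
    )
    # promoter peaks: constitutive floor and delayed closing
    prom_cols = np.nonzero((pt["role"] == "promoter").to_numpy())[0]
    active_prom = (
        in_scope
        & (t >= acc_on[None, :])
        & (t < (tau_off + design.promoter_close_lag)[None, :])
    )
    rate[:, prom_cols] = np.where(
        active_prom[:, peak_gene[prom_cols]], design.open_rate_high, design.open_rate_low
    )
    floor = design.promoter_floor_frac * design.open_rate_high
    rate[:, prom_cols] = np.maximum(rate[:, prom_cols], floor)
    lam_atac = depth_atac[:, None] * rate
    atac_counts = _poisson(rng, lam_atac, design.dispersion)

    lam_rna = depth_rna[:, None] * np.where(
        active_expr, design.open_rate_high, design.open_rate_low
    )
    rna_counts = _poisson(rng, lam_rna, design.dispersion)

    # plant depth outliers beyond the far-out fence of the normal cells
    n_out = int(np.floor(design.outlier_fraction * n_cells))
    out_idx = rng.choice(n_cells, size=n_out, replace=False) if n_out else np.array([], int)
    if n_out:
        normal = np.setdiff1d(np.arange(n_cells), out_idx)
        totals = atac_counts.sum(axis=1).astype(float)
        q1, q3 = np.percentile(totals[normal], [25, 75])
        target = 2.0 * (q3 + 3.0 * (q3 - q1)) + 10.0
        for i in out_idx:
            f = max(target / max(totals[i], 1.0), 1.0)
            atac_counts[i] = _poisson(rng, lam_atac[i] * f, design.dispersion)
    ground_truth.planted_outliers = sorted(barcodes[i] for i in out_idx)

    import scipy.sparse as sp

    atac = PeakMatrix(
        counts=sp.csr_matrix(atac_counts),
        barcodes=list(barcodes),
        peaks=[GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in pt.itertuples()],
    )
    rna = ExpressionMatrix(
        counts=sp.csr_matrix(rna_counts), barcodes=list(barcodes), gene_ids=list(gene_ids)
    )

    windows = [w.interval for w in promoter_windows(annotation)]
    in_promoter = overlaps_any(atac.peaks, windows)
    totals = atac.total_counts().astype(float)
    prom_reads = np.asarray(atac.counts[:, np.nonzero(in_promoter)[0]].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        promoter_ratio = np.where(totals > 0, prom_reads / np.maximum(totals, 1.0), 0.0)

    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "region": cregion,
            "state": cstate,
            "cluster_id": cluster,
            "pseudotime": pseudotime,
            "total_counts": totals,
            "promoter_ratio": promoter_ratio,
        }
    )
    return atac, rna, cells


# ---------------------------------------------------------------------------
# Histone peaks
# ---------------------------------------------------------------------------


def simulate_histone_peaks(
    annotation: Sequence[GeneAnnotation],
    ground_truth: GroundTruth,
    design: SimulationDesign,
    seed: int | None = None,
) -> list[HistonePeakSet]:
    """Emit per-region histone peak sets keyed to the planted program.

    H3K4me3 marks promoters of genes active in the region, H3K27me3
    promoters of inactive genes, and H3K27ac the true enhancers of active
    genes, each dropped independently with the design's false-negative rate.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    windows = {w.gene_id: w.interval for w in promoter_windows(annotation)}
    prog = ground_truth.gene_program
    active_by_region = (
        prog.groupby(["region", "gene_id"])["active"].any().unstack(level=0)
    )
    links = ground_truth.true_links
    out: list[HistonePeakSet] = []
    for region in design.regions:
        active = active_by_region[region]
        k4 = [windows[g] for g in active.index if active[g] and g in windows]
        k27me3 = [windows[g] for g in active.index if not active[g] and g in windows]
        k27ac: list[GenomicInterval] = []
        for row in links.itertuples():
            if not active.get(row.gene_id, False):
                continue
            if rng.random() < design.h3k27ac_false_negative_rate:
                continue
            k27ac.append(GenomicInterval(row.chrom, int(row.start), int(row.end)))
        out.append(HistonePeakSet("H3K4me3", region, tuple(sorted(k4))))
        out.append(HistonePeakSet("H3K27ac", region, tuple(sorted(k27ac))))
        out.append(HistonePeakSet("H3K27me3", region, tuple(sorted(k27me3))))
    return out


# ---------------------------------------------------------------------------
# Convenience + persistence
# ---------------------------------------------------------------------------


def simulate_dataset(design: SimulationDesign | None = None, seed: int | None = None) -> SimulatedDataset:
    """Run the full generator (genome, counts, histone sets) for one seed."""
    design = design or SimulationDesign()
    base = design.seed if seed is None else seed
    ss = np.random.SeedSequence(base).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    genes, peaks, truth = simulate_genome(design, seeds[0])
    atac, rna, cells = simulate_counts(genes, truth, design, seeds[1])
    histones = simulate_histone_peaks(genes, truth, design, seeds[2])
    return SimulatedDataset(design, genes, peaks, truth, atac, rna, cells, histones)


def write_dataset(dataset: SimulatedDataset, directory: str | Path, seed: int | None = None) -> None:
    """Persist a simulated dataset in the package's interchange formats."""
    root = Path(directory)
    (root / "atac").mkdir(parents=True, exist_ok=True)
    (root / "rna").mkdir(exist_ok=True)
    (root / "histone").mkdir(exist_ok=True)
    (root / "ground_truth").mkdir(exist_ok=True)

    write_count_matrix(dataset.atac, root / "atac" / "matrix.mtx", root / "atac" / "barcodes.tsv")
    write_bed(dataset.atac.peaks, root / "atac" / "peaks.bed")
    write_count_matrix(dataset.rna, root / "rna" / "matrix.mtx", root / "rna" / "barcodes.tsv")
    with open(root / "rna" / "features.tsv", "w") as fh:
        fh.writelines(g + "\n" for g in dataset.rna.gene_ids)
    write_gene_annotation(dataset.genes, root / "genes.tsv")
    write_cell_table(dataset.cells, root / "cells.tsv")
    for hs in dataset.histone_sets:
        write_bed(list(hs.intervals), root / "histone" / f"{hs.mark}_{hs.region}.bed")

    gt = dataset.ground_truth
    gt.gene_params.to_csv(root / "ground_truth" / "gene_params.tsv", sep="\t", index=False)
    gt.gene_program.to_csv(root / "ground_truth" / "gene_program.tsv", sep="\t", index=False)
    gt.peak_table.to_csv(root / "ground_truth" / "peak_table.tsv", sep="\t", index=False)
    gt.true_links.to_csv(root / "ground_truth" / "links.tsv", sep="\t", index=False)
    pd.DataFrame({"barcode": gt.planted_outliers}).to_csv(
        root / "ground_truth" / "outliers.tsv", sep="\t", index=False
    )
    manifest = {"design": asdict(dataset.design), "seed": dataset.design.seed if seed is None else seed}
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
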