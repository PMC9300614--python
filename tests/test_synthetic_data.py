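import numpy as np
import pandas as pd
import pytest

from epilink import qc
from epilink.core_io import GenomicInterval, overlaps_any, read_peak_matrix
from epilink.scoring import promoter_windows
from epilink.synthetic_data import (
    SimulationDesign,
    SizingError,
    simulate_counts,
    simulate_dataset,
    simulate_genome,
    simulate_histone_peaks,
    write_dataset,
)
from epilink.linkage import binarized_metacell_matrix
from conftest import small_design


class TestDesignValidation:
    def test_rate_ordering_enforced(self):
        with pytest.raises(Exception):
            SimulationDesign(open_rate_low=0.5, open_rate_high=0.1)

    def test_outlier_fraction_bounds(self):
        with pytest.raises(Exception):
            SimulationDesign(outlier_fraction=0.5)

    def test_rna_lag_must_be_0_or_1(self):
        with pytest.raises(Exception):
            SimulationDesign(rna_lag=2)

    def test_empty_group_rejected(self):
        with pytest.raises(Exception):
            SimulationDesign(cells_per_group=0)

    def test_yaml_roundtrip(self, tmp_path):
        d = small_design(seed=9)
        d.to_yaml(tmp_path / "d.yaml")
        assert SimulationDesign.from_yaml(tmp_path / "d.yaml") == d


class TestGenomeLayout:
    def test_single_gene_design_yields_promoter_exon_enhancer(self):
        d = small_design(n_genes=1, n_enhancers_per_gene=(1, 1))
        genes, peaks, truth = simulate_genome(d, seed=0)
        assert len(peaks) >= 3
        window = promoter_windows(genes)[0].interval
        pt = truth.peak_table
        prom = pt[pt.role == "promoter"]
        assert len(prom) == 1
        assert GenomicInterval(prom.chrom.iloc[0], prom.start.iloc[0], prom.end.iloc[0]).overlaps(window)
        # no enhancer or background peak intrudes into the promoter window
        distal = pt[pt.role.isin(["enhancer", "background"])]
        distal_iv = [GenomicInterval(r.chrom, r.start, r.end) for r in distal.itertuples()]
        assert not overlaps_any(distal_iv, [window]).any()

    def test_enhancers_overlap_no_promoter_window(self):
        genes, peaks, truth = simulate_genome(SimulationDesign(), seed=3)
        windows = [w.interval for w in promoter_windows(genes)]
        enh = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in truth.true_links.itertuples()
        ]
        assert not overlaps_any(enh, windows).any()

    def test_enhancers_within_500kb_of_their_tss(self):
        genes, _, truth = simulate_genome(SimulationDesign(), seed=3)
        tss = {g.gene_id: g.tss for g in genes}
        for r in truth.true_links.itertuples():
            assert abs(r.start - tss[r.gene_id]) <= 500_000

    def test_same_seed_reproduces_annotation_exactly(self):
        d = SimulationDesign()
        a1 = simulate_genome(d, seed=5)
        a2 = simulate_genome(d, seed=5)
        assert [g.__dict__ for g in a1[0]] == [g.__dict__ for g in a2[0]]
        pd.testing.assert_frame_equal(a1[2].peak_table, a2[2].peak_table)

    def test_overdense_layout_raises_sizing_error(self):
        with pytest.raises(SizingError):
            simulate_genome(small_design(n_genes=1000, chrom_length=1_000_000), seed=0)

    def test_early_late_sets_disjoint_and_lag_recorded(self):
        d = SimulationDesign()
        _, _, truth = simulate_genome(d, seed=2)
        assert not (truth.early_genes & truth.late_genes)
        gp = truth.gene_params
        late = gp[gp.temporal_class == "late"]
        # accessibility onset precedes expression onset by one state (rna_lag=1)
        assert np.allclose(late.acc_on, late.tau_on - 1.0)


class TestCounts:
    def test_determinism_of_full_dataset(self):
        d1 = simulate_dataset(seed=11)
        d2 = simulate_dataset(seed=11)
        assert (d1.atac.counts != d2.atac.counts).nnz == 0
        assert (d1.rna.counts != d2.rna.counts).nnz == 0
        pd.testing.assert_frame_equal(d1.cells, d2.cells)
        d3 = simulate_dataset(seed=12)
        same_shape = d1.atac.counts.shape == d3.atac.counts.shape
        assert not (same_shape and (d1.atac.counts != d3.atac.counts).nnz == 0)

    def test_planted_outliers_fall_outside_farout_fences(self, ds):
        fences = qc.tukey_fences(ds.cells["total_counts"], k=3)
        totals = dict(zip(ds.cells.barcode, ds.cells.total_counts))
        for bc in ds.ground_truth.planted_outliers:
            assert totals[bc] > fences.upper

    def test_accessibility_precedes_expression_for_late_genes(self, ds):
        """With rna_lag=1, a late gene's elements are open one state early."""
        gt = ds.ground_truth
        gp = gt.gene_params.set_index("gene_id")
        late = gp[gp.temporal_class == "late"].index[:10]
        atac = np.asarray(ds.atac.counts.todense())
        rna = np.asarray(ds.rna.counts.todense())
        pt = gt.peak_table
        t = ds.cells.pseudotime.to_numpy()
        for g in late:
            row = gp.loc[g]
            cols = pt.index[(pt.gene_id == g) & (pt.role == "enhancer")].to_numpy()
            sel = (ds.cells.region == row.scope) if row.scope != "pan" else np.ones(len(t), bool)
            pre = sel & (t >= row.acc_on) & (t < row.tau_on)  # lag window
            if pre.sum() < 10:
                continue
            gi = ds.rna.gene_ids.index(g)
            assert atac[pre][:, cols].mean() > 10 * max(rna[pre, gi].mean(), 0.001)

    def test_linked_enhancer_correlates_more_than_random_peak(self):
        """Binarised promoter vs linked enhancer beats a random unlinked peak."""
        wins = 0
        for seed in range(20):
            d = simulate_dataset(small_design(cells_per_group=170, n_genes=30), seed=seed)
            pt = d.ground_truth.peak_table
            nz = np.asarray((d.atac.counts > 0).todense()).astype(float)
            rng = np.random.default_rng(seed)
            r_links, r_rands = [], []
            for g in pt.gene_id.unique()[:8]:
                prom = pt.index[(pt.gene_id == g) & (pt.role == "promoter")][0]
                enh = pt.index[(pt.gene_id == g) & (pt.role == "enhancer")]
                if not len(enh):
                    continue
                other = pt.index[(pt.gene_id != g) & (pt.role == "enhancer")]
                with np.errstate(invalid="ignore"):
                    r_link = np.corrcoef(nz[:, prom], nz[:, enh[0]])[0, 1]
                    r_rand = np.corrcoef(nz[:, prom], nz[:, rng.choice(other)])[0, 1]
                if np.isfinite(r_link) and np.isfinite(r_rand):
                    r_links.append(r_link)
                    r_rands.append(r_rand)
            wins += np.mean(r_links) > np.mean(r_rands)
        assert wins >= 19

    def test_planted_pairs_beat_distance_matched_null(self, ds):
        """Metacell co-accessibility of true pairs exceeds the null 95th pct."""
        B = binarized_metacell_matrix(ds.atac, ds.cells)
        pt = ds.ground_truth.peak_table
        sd = B.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(B.T)
        true_scores, null_scores = [], []
        rng = np.random.default_rng(0)
        for g, grp in pt.groupby("gene_id"):
            proms = grp.index[grp.role == "promoter"]
            enhs = grp.index[grp.role == "enhancer"]
            bgs = grp.index[grp.role == "background"]
            for p in proms:
                if sd[p] == 0:
                    continue
                for e in enhs:
                    if sd[e] > 0:
                        true_scores.append(corr[p, e])
                for b in bgs:  # same distance scale, not co-regulated
                    if sd[b] > 0:
                        null_scores.append(corr[p, b])
        assert np.mean(true_scores) > np.quantile(null_scores, 0.95)


class TestHistonePeaks:
    def test_marks_track_regional_activity(self):
        d = small_design(h3k27ac_false_negative_rate=0.0)
        genes, peaks, truth = simulate_genome(d, seed=4)
        sets = {(h.mark, h.region): h for h in simulate_histone_peaks(genes, truth, d, seed=4)}
        prog = truth.gene_program
        active = prog.groupby(["region", "gene_id"]).active.any()
        windows = {w.gene_id: w.interval for w in promoter_windows(genes)}
        for region in d.regions:
            k4 = sets[("H3K4me3", region)].intervals
            k27me3 = sets[("H3K27me3", region)].intervals
            for g in windows:
                if active[(region, g)]:
                    assert windows[g] in k4 and windows[g] not in k27me3
                else:
                    assert windows[g] in k27me3 and windows[g] not in k4

    @pytest.mark.parametrize("fnr,expect_all,expect_none", [(0.0, True, False), (1.0, False, True)])
    def test_h3k27ac_false_negative_extremes(self, fnr, expect_all, expect_none):
        d = small_design(h3k27ac_false_negative_rate=fnr)
        genes, peaks, truth = simulate_genome(d, seed=4)
        sets = simulate_histone_peaks(genes, truth, d, seed=4)
        k27 = {iv for h in sets if h.mark == "H3K27ac" for iv in h.intervals}
        prog = truth.gene_program
        active_any = prog.groupby("gene_id").active.any()
        enh_active = {
            GenomicInterval(r.chrom, r.start, r.end)
            for r in truth.true_links.itertuples()
            if active_any[r.gene_id]
        }
        if expect_all:
            assert enh_active <= k27
        if expect_none:
            assert not k27


class TestWriteDataset:
    def test_roundtrip_and_manifest(self, tmp_path):
        d = small_design(seed=21)
        data = simulate_dataset(d, seed=21)
        write_dataset(data, tmp_path / "out", seed=21)
        back = read_peak_matrix(
            tmp_path / "out/atac/matrix.mtx",
            tmp_path / "out/atac/barcodes.tsv",
            tmp_path / "out/atac/peaks.bed",
        )
        assert (back.counts != data.atac.counts).nnz == 0
        assert back.peaks == [GenomicInterval(p.chrom, p.start, p.end) for p in data.peaks]
        import yaml

        manifest = yaml.safe_load((tmp_path / "out/manifest.yaml").read_text())
        assert manifest["seed"] == 21
        links = pd.read_csv(tmp_path / "out/ground_truth/links.tsv", sep="\t")
        assert len(links) == len(data.ground_truth.true_links)
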