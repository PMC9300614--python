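import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.optimize import minimize

from epilink.core_io import GenomicInterval, PeakMatrix, ValidationError
from epilink.differential import (
    _fit_logistic,
    binarize_by_cluster,
    cluster_overlap_profiles,
    dendrogram_to_newick,
    find_da_peaks,
    lr_test_peak,
    overlap_matrix,
    OverlapMatrix,
)


def toy_dataset(rng, n_per_cluster=60, n_clusters=3, n_noise_peaks=8):
    """Counts with one strong marker peak per cluster plus noise peaks."""
    n = n_per_cluster * n_clusters
    cluster = np.repeat(np.arange(n_clusters), n_per_cluster)
    depth = rng.lognormal(0, 0.2, n)
    peaks, cols = [], []
    for c in range(n_clusters):
        lam = np.where(cluster == c, 2.0, 0.02) * depth
        cols.append(rng.poisson(lam))
        peaks.append(GenomicInterval("chr1", 1000 * (c + 1), 1000 * (c + 1) + 200))
    for j in range(n_noise_peaks):
        cols.append(rng.poisson(0.5 * depth))
        peaks.append(GenomicInterval("chr2", 1000 * (j + 1), 1000 * (j + 1) + 200))
    counts = np.column_stack(cols)
    matrix = PeakMatrix(
        counts=sp.csr_matrix(counts), barcodes=[f"bc{i}" for i in range(n)], peaks=peaks
    )
    cells = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "region": "MGE",
            "state": "AP",
            "cluster_id": cluster,
            "pseudotime": np.linspace(0, 1, n),
        }
    )
    return matrix, cells


class TestLrTest:
    def test_constant_x_gives_null_result(self):
        y = np.array([0, 0, 1, 1, 0, 1], float)
        stat, p, flagged = lr_test_peak(y, np.full(6, 2.0), np.log(np.arange(1, 7)))
        assert (stat, p) == (0.0, 1.0) and not flagged

    def test_single_class_y_rejected(self):
        with pytest.raises(ValidationError):
            lr_test_peak(np.ones(6), np.arange(6.0), np.ones(6))

    def test_fit_matches_statsmodels_on_wellposed_data(self, rng):
        n = 400
        x = rng.normal(size=n)
        cov = rng.normal(size=n)
        eta = -0.5 + 1.2 * x + 0.3 * cov
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(n), x, cov])
        beta, ll, ok = _fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert ok
        assert np.allclose(beta, ref.params, atol=1e-6)
        assert ll == pytest.approx(ref.llf, abs=1e-8)

    def test_separating_x_uses_ridge_and_matches_penalised_oracle(self):
        """Perfect separation: finite statistic via the L2-stabilised refit."""
        n = 40
        y = np.repeat([0.0, 1.0], n // 2)
        x = np.concatenate([np.arange(n // 2), np.arange(30, 30 + n // 2)]).astype(float)
        cov = np.zeros(n)
        stat, p, flagged = lr_test_peak(y, x, cov)
        assert flagged and np.isfinite(stat) and p < 1e-6

        # penalised-likelihood oracle on a 10-cell example
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], float)
        x = np.array([0, 1, 2, 3, 4, 10, 11, 12, 13, 14], float)
        cov = np.zeros(10)
        X = np.column_stack([np.ones(10), x, cov])
        pen = np.array([0.0, 1e-4, 1e-4])

        def nll(b):
            eta = X @ b
            return -(y @ eta - np.logaddexp(0, eta).sum()) + 0.5 * pen @ (b * b)

        oracle = minimize(nll, np.zeros(3), method="BFGS", options=dict(gtol=1e-10))
        beta, ll, _ = _fit_logistic(X, y, ridge=1e-4)
        assert -nll(beta) >= -nll(oracle.x) - 1e-6  # at least as good a mode

    def test_null_rejection_rate_is_calibrated(self, rng):
        n = 400
        y = (rng.random(n) < 0.3).astype(float)
        cov = np.log(rng.lognormal(3, 0.3, n))
        rejections = 0
        n_tests = 500
        for _ in range(n_tests):
            x = np.log1p(rng.poisson(0.4, n).astype(float))
            if np.ptp(x) == 0:
                continue
            _, p, _ = lr_test_peak(y, x, cov)
            rejections += p < 0.05
        rate = rejections / n_tests
        half = 2.807 * np.sqrt(0.05 * 0.95 / n_tests)  # 99.5% interval at this n
        assert 0.05 - half <= rate <= 0.05 + half


class TestFindDaPeaks:
    def test_marker_peaks_recovered_per_cluster(self, rng):
        matrix, cells = toy_dataset(rng)
        calls = find_da_peaks(matrix, cells)
        for c in range(3):
            assert c in set(calls.loc[calls.peak_index == c, "cluster_id"])

    def test_low_prevalence_peak_not_tested(self, rng):
        matrix, cells = toy_dataset(rng)
        counts = np.asarray(matrix.counts.todense())
        sparse_col = np.zeros(len(cells), int)
        sparse_col[:10] = 1  # ~6% prevalence everywhere: below min_pct
        counts = np.column_stack([counts, sparse_col])
        matrix2 = PeakMatrix(
            counts=sp.csr_matrix(counts),
            barcodes=matrix.barcodes,
            peaks=matrix.peaks + [GenomicInterval("chr3", 10, 20)],
        )
        calls = find_da_peaks(matrix2, cells, min_pct=0.2)
        assert (calls.peak_index != counts.shape[1] - 1).all()

    def test_negative_fold_change_excluded(self, rng):
        matrix, cells = toy_dataset(rng)
        calls = find_da_peaks(matrix, cells)
        assert (calls.avg_log_fc > 0).all()
        assert (calls.adj_p <= 0.05).all()
        # the cluster-0 marker is significant but depleted for cluster 1
        assert not ((calls.peak_index == 0) & (calls.cluster_id == 1)).any()

    def test_single_cluster_rejected(self, rng):
        matrix, cells = toy_dataset(rng)
        cells["cluster_id"] = 0
        with pytest.raises(ValidationError):
            find_da_peaks(matrix, cells)


class TestOverlapMatrix:
    def test_matches_bruteforce_recount(self, rng):
        matrix, cells = toy_dataset(rng)
        da = find_da_peaks(matrix, cells)
        om = overlap_matrix(da, matrix, cells)
        counts = np.asarray(matrix.counts.todense())
        clusters = sorted(cells.cluster_id.unique())
        for c in clusters:
            idx = da.loc[da.cluster_id == c, "peak_index"].to_numpy()
            for d in clusters:
                expected = np.nan
                if len(idx):
                    in_d = counts[(cells.cluster_id == d).to_numpy()][:, idx]
                    expected = 100.0 * (in_d.sum(axis=0) > 0).mean()
                got = om.percent.loc[d, c]
                assert (np.isnan(got) and np.isnan(expected)) or got == pytest.approx(expected)

    def test_diagonal_is_100_for_clusters_with_calls(self, rng):
        matrix, cells = toy_dataset(rng)
        da = find_da_peaks(matrix, cells)
        om = overlap_matrix(da, matrix, cells)
        for c in om.percent.columns:
            if om.peak_counts[c] > 0:
                assert om.percent.loc[c, c] == 100.0

    def test_single_read_counts_as_overlap(self):
        counts = np.array([[5, 0], [0, 1], [0, 0], [0, 0]])
        matrix = PeakMatrix(
            counts=sp.csr_matrix(counts),
            barcodes=list("abcd"),
            peaks=[GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)],
        )
        cells = pd.DataFrame(
            dict(barcode=list("abcd"), region="MGE", state="AP",
                 cluster_id=[0, 1, 0, 1], pseudotime=[0.0, 0.1, 0.2, 0.3])
        )
        da = pd.DataFrame(
            dict(chrom="chr1", start=[0], end=[10], peak_index=[0], cluster_id=[0])
        )
        om = overlap_matrix(da, matrix, cells)
        assert om.percent.loc[0, 0] == 100.0
        assert om.percent.loc[1, 0] == 0.0  # zero reads in cluster 1


class TestProfileClustering:
    def test_identical_profiles_merge_at_height_zero(self):
        percent = pd.DataFrame(
            [[100.0, 10.0, 0.0], [100.0, 10.0, 0.0], [0.0, 90.0, 100.0]],
            index=[0, 1, 2],
            columns=[0, 1, 2],
        )
        om = OverlapMatrix(percent=percent, peak_counts=pd.Series([5, 5, 5]))
        dg = cluster_overlap_profiles(om)
        first = dg.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1} and first[2] == pytest.approx(0.0)

    def test_correlated_pair_merges_before_anticorrelated_profile(self):
        percent = pd.DataFrame(
            [[10.0, 20.0, 30.0], [11.0, 21.0, 33.0], [30.0, 20.0, 10.0]],
            index=list("ABC"),
            columns=[0, 1, 2],
        )
        om = OverlapMatrix(percent=percent, peak_counts=pd.Series([1, 1, 1], index=list("ABC")))
        dg = cluster_overlap_profiles(om)
        assert {int(dg.linkage[0][0]), int(dg.linkage[0][1])} == {0, 1}
        assert dg.leaf_order.index("C") in (0, 2)

    def test_constant_profile_sits_at_maximal_distance(self):
        percent = pd.DataFrame(
            [[10.0, 20.0, 30.0], [12.0, 22.0, 31.0], [50.0, 50.0, 50.0]],
            index=list("ABC"),
            columns=[0, 1, 2],
        )
        om = OverlapMatrix(percent=percent, peak_counts=pd.Series([1, 1, 1], index=list("ABC")))
        dg = cluster_overlap_profiles(om)
        assert dg.linkage[-1][2] == pytest.approx(2.0)

    def test_leaf_order_deterministic_and_newick_wellformed(self, rng):
        matrix, cells = toy_dataset(rng)
        da = find_da_peaks(matrix, cells)
        om = overlap_matrix(da, matrix, cells)
        d1 = cluster_overlap_profiles(om)
        d2 = cluster_overlap_profiles(om)
        assert d1.leaf_order == d2.leaf_order
        nwk = dendrogram_to_newick(d1)
        assert nwk.endswith(";") and all(str(lbl) in nwk for lbl in d1.labels)


class TestBinarize:
    def test_row_patterns_follow_read_presence(self):
        counts = np.array([[0, 3], [0, 0], [2, 0], [0, 0]])
        matrix = PeakMatrix(
            counts=sp.csr_matrix(counts),
            barcodes=list("abcd"),
            peaks=[GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)],
        )
        cells = pd.DataFrame(
            dict(barcode=list("abcd"), region="MGE", state="AP",
                 cluster_id=[0, 0, 1, 1], pseudotime=[0.0, 0.1, 0.2, 0.3])
        )
        out = binarize_by_cluster(matrix, cells)
        assert out.to_numpy().tolist() == [[0, 1], [1, 0]]

    def test_planted_program_recovered_as_blocks(self, ds):
        """Cluster-level open/closed calls track the planted accessibility."""
        binary = binarize_by_cluster(ds.atac, ds.cells)
        pt = ds.ground_truth.peak_table
        gp = ds.ground_truth.gene_params.set_index("gene_id")
        cl = ds.cells.drop_duplicates("cluster_id").set_index("cluster_id")
        correct = total = 0
        for pi in pt.index[(pt.role == "enhancer")]:
            g = gp.loc[pt.loc[pi, "gene_id"]]
            for c in binary.index:
                region, state = cl.loc[c, "region"], cl.loc[c, "state"]
                s = ["AP", "BP", "N"].index(state)
                in_scope = g.scope in ("pan", region)
                cov = max(0.0, min(g.tau_off, s + 1) - max(g.acc_on, s))
                planted_open = in_scope and cov > 0
                correct += int(bool(binary.loc[c, pi]) == planted_open)
                total += 1
        assert correct / total >= 0.9
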