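import numpy as np
import pytest

from epilink.core_io import GenomicInterval
from epilink import linkage
from epilink.synthetic_data import SimulationDesign, simulate_dataset

N_SEEDS = 10


def random_intervals(rng, n, n_chroms=3, max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(
            GenomicInterval(
                f"chr{int(rng.integers(1, n_chroms + 1))}",
                start,
                start + int(rng.integers(1, max_len + 1)),
            )
        )
    return out


def small_design(**overrides) -> SimulationDesign:
    """A reduced-scale design for fast construction-level tests."""
    base = dict(
        n_genes=40,
        cells_per_group=30,
        chrom_count=2,
        chrom_length=13_000_000,
        outlier_fraction=0.05,
    )
    base.update(overrides)
    return SimulationDesign(**base)


@pytest.fixture(scope="session")
def ds():
    """The default study-scale simulation (seed 1)."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def sim_bank():
    """Default simulations for seeds 1..N_SEEDS (shared across tests)."""
    return {seed: simulate_dataset(seed=seed) for seed in range(1, N_SEEDS + 1)}


@pytest.fixture(scope="session")
def tss_link_bank(sim_bank):
    """Filtered TSS-cRE connections per seed from the full link pipeline."""
    out = {}
    for seed, d in sim_bank.items():
        links = linkage.coaccessibility_scores(d.atac, d.cells)
        out[seed] = linkage.classify_tss_links(linkage.filter_links(links), d.genes)
    return out


@pytest.fixture(scope="session")
def pair_bank(sim_bank):
    """Gene-peak model pairs per seed."""
    return {
        seed: linkage.predict_gene_peak_pairs(d.rna, d.atac, d.genes)
        for seed, d in sim_bank.items()
    }


@pytest.fixture(scope="session")
def true_link_sets(sim_bank):
    return {
        seed: set(
            map(
                tuple,
                d.ground_truth.true_links[["gene_id", "chrom", "start", "end"]].itertuples(
                    index=False
                ),
            )
        )
        for seed, d in sim_bank.items()
    }


@pytest.fixture(scope="session")
def true_enhancer_map(ds):
    enh = {}
    for r in ds.ground_truth.true_links.itertuples():
        enh.setdefault(r.gene_id, []).append(GenomicInterval(r.chrom, r.start, r.end))
    return enh


@pytest.fixture(scope="session")
def da_calls(ds):
    from epilink import differential

    return differential.find_da_peaks(ds.atac, ds.cells)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
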