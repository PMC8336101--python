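import numpy as np
import pytest
import scipy.sparse as sp

from hicscape import ContactMatrix, GenomeLayout
from hicscape.simulate import SimConfig, generate_truth, simulate_hic


def decay_matrix(n_bins: int, depth: float, seed: int | None = None,
                 alpha: float = 1.0, bias: np.ndarray | None = None,
                 resolution: int = 5000) -> ContactMatrix:
    """Distance-decay-only contact matrix; Poisson noise when seeded."""
    layout = GenomeLayout({"chr1": n_bins * resolution})
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    mean = (1.0 + d) ** (-alpha)
    if bias is not None:
        mean = mean * np.outer(bias, bias)
    iu, ju = np.triu_indices(n_bins)
    vals = mean[iu, ju] * (depth / mean[iu, ju].sum())
    if seed is not None:
        vals = np.random.default_rng(seed).poisson(vals).astype(float)
    keep = vals > 0
    m = sp.coo_matrix((vals[keep], (iu[keep], ju[keep])), shape=(n_bins, n_bins))
    return ContactMatrix(layout, resolution, {"chr1": m})


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced study for tests that only need plausible structure."""
    return SimConfig(seed=101, chrom_lengths={"chr1": 10_000_000},
                     depth=400_000, n_domains_per_chrom=5,
                     n_loops_common=4, n_loops_specific1=1,
                     n_loops_specific2=2, n_genes_per_chrom=120,
                     n_patients=60)


@pytest.fixture(scope="session")
def small_truth(small_sim_config):
    return generate_truth(small_sim_config)


@pytest.fixture(scope="session")
def small_matrices(small_sim_config, small_truth):
    return simulate_hic(small_truth, small_sim_config)
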