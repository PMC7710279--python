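import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from regenmap import synthdata
from regenmap.containers import make_count_matrix, make_peak_matrix


@pytest.fixture(scope="session")
def rna_small():
    """600 cells, 4 planted states, 5 regulons, zonation gradient."""
    return synthdata.gen_rna_counts(n_cells=600, n_genes=300, n_clusters=4, seed=7)


@pytest.fixture(scope="session")
def atac_small():
    """300 nuclei, 4 topic blocks, fragments, 20% bad nuclei."""
    return synthdata.gen_atac_data(
        n_cells=300, n_regions=1000, n_topics=4, seed=7, bad_share=0.2
    )


@pytest.fixture(scope="session")
def genome_small():
    return synthdata.gen_genome(40, seed=7)


@pytest.fixture(scope="session")
def refs():
    return synthdata.gen_reference_profiles(seed=7)


@pytest.fixture()
def tiny_counts():
    """3 cells x 4 genes with known entries."""
    x = np.array([[10, 0, 3, 1], [0, 5, 5, 0], [2, 2, 2, 2]])
    return make_count_matrix(
        sp.csr_matrix(x), ["c1", "c2", "c3"], ["g1", "g2", "g3", "g4"]
    )


def random_peak_matrix(rng, n_cells, n_peaks, mean=2.0):
    counts = rng.poisson(mean, (n_cells, n_peaks))
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_peaks) * 1000,
            "end": np.arange(n_peaks) * 1000 + 400,
            "peak_id": [f"p{i:04d}" for i in range(n_peaks)],
        }
    )
    return make_peak_matrix(
        sp.csr_matrix(counts), peaks, [f"c{i:04d}" for i in range(n_cells)]
    )
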