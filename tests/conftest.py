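import numpy as np
import pandas as pd
import pytest

from soyblup import SimConfig, simulate_genotypes
from soyblup.marker_io import GenotypeMatrix


def make_matrix(dosage, chrom=None, positions=None, line_ids=None):
    """Convenience constructor for small literal dosage matrices."""
    dosage = np.asarray(dosage, dtype=float)
    n, p = dosage.shape
    meta = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(p)],
            "chromosome": chrom if chrom is not None else ["1"] * p,
            "position": positions if positions is not None else np.arange(1, p + 1),
            "major_allele": ["A"] * p,
            "minor_allele": ["C"] * p,
        }
    )
    ids = line_ids if line_ids is not None else [f"L{i}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, marker_meta=meta, line_ids=ids)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_lines=60,
        n_families=10,
        n_chromosomes=4,
        markers_per_chromosome=40,
        n_qtl=30,
        n_locations=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    matrix, truth = simulate_genotypes(small_cfg)
    return matrix, truth, small_cfg
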