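import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from founderscan.genotype_model import (  # noqa: E402
    GenotypeTable,
    SampleRecord,
)
from founderscan.synthetic_data import SimParams, simulate_bundle  # noqa: E402


def make_table(
    genotypes,
    positions=None,
    chroms=None,
    species=None,
    degeneracy=None,
    ancestral=None,
    depth=None,
    qual=None,
):
    """Compact builder for small hand-written genotype tables."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if chroms is None:
        chroms = ["chr1"] * n_sites
    if species is None:
        species = ["selfer"] * n_samples
    samples = [
        SampleRecord(f"S{i + 1}", sp, "Greek" if sp == "selfer" else "outcrosser")
        for i, sp in enumerate(species)
    ]
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "C",
            "cM": np.nan,
            "degeneracy": degeneracy if degeneracy is not None else "4-fold",
            "ancestral": ancestral if ancestral is not None else "ref",
        }
    )
    return GenotypeTable(
        sites=sites,
        samples=samples,
        genotypes=g,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        qual=None if qual is None else np.asarray(qual, dtype=np.float32),
    )


@pytest.fixture(scope="session")
def clean_bundle_k10():
    """Error-free default-demography bundle with 10 founders (painting regime)."""
    params = SimParams(
        n_windows=400, seed=77, k_founders=10, err_het=0.0, miss_rate=0.0, f_allo=0.0
    )
    return simulate_bundle(params)


@pytest.fixture(scope="session")
def noisy_bundle_default():
    """Default study conditions including genotyping noise and allozygosity."""
    params = SimParams(n_windows=300, seed=55)
    return simulate_bundle(params)


@pytest.fixture(scope="session")
def painted_k10(clean_bundle_k10):
    from founderscan.haplotype_painting import paint_genome

    table, truth = clean_bundle_k10
    painting, calls, invariant = paint_genome(table)
    return table, truth, painting, calls, invariant
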