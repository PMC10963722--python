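import numpy as np
import pandas as pd
import pytest

from hubseek.genotypes import PolarizedGenotypes


def make_geno(calls, populations=None, ploidy=None, chrom=None, polarized=True,
              pos=None):
    """Small helper: build a PolarizedGenotypes from a dense call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    populations = populations or [f"pop{j}" for j in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * n_sites,
            "pos": pos if pos is not None else np.arange(1, n_sites + 1) * 10,
            "ref": "A",
            "alt": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(n_samples)],
            "population": populations,
            "ploidy": ploidy if ploidy is not None else [2] * n_samples,
        }
    )
    return PolarizedGenotypes(sites=sites, samples=samples, calls=calls,
                              polarized=polarized)


@pytest.fixture
def toy_geno():
    # 5 sites × 3 diploid samples; s0 is a reference-style column
    return make_geno(
        [
            [2, 1, 0],
            [1, 0, 2],
            [1, 1, -1],
            [0, 2, 1],
            [0, 0, 0],
        ]
    )
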