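import numpy as np
import pandas as pd
import pytest

from karyoadapt import GenomeBuild
from karyoadapt.simulate import yeast_genome


@pytest.fixture(scope="session")
def haploid_yeast() -> GenomeBuild:
    return yeast_genome(basal_ploidy=1)


@pytest.fixture(scope="session")
def diploid_yeast() -> GenomeBuild:
    return yeast_genome(basal_ploidy=2)


@pytest.fixture
def toy_genome() -> GenomeBuild:
    """Four equal 100-kb chromosomes, small enough for per-read oracles."""
    return GenomeBuild(
        (("chr1", 100_000), ("chr2", 100_000), ("chr3", 100_000), ("chr4", 100_000)),
        basal_ploidy=1,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180319)


def make_call_matrix(n_strains: int, chrom_events: dict, ploidy: int = 1,
                     chromosomes=None) -> pd.DataFrame:
    """Integer call matrix with prescribed per-chromosome event strain sets.

    ``chrom_events`` maps chromosome -> (copy, set of strain indices).
    """
    if chromosomes is None:
        chromosomes = list(chrom_events)
    mat = pd.DataFrame(
        ploidy, index=[f"s{i}" for i in range(n_strains)], columns=chromosomes
    )
    for chrom, (copy, strains) in chrom_events.items():
        mat.iloc[sorted(strains), mat.columns.get_loc(chrom)] = copy
    return mat
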