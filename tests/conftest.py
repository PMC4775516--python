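import numpy as np
import pandas as pd
import pytest

from clonalpop.io import GenotypeDataset, Locus
from clonalpop.simulate import SimConfig, simulate_metapopulation, table1_like_fixture


@pytest.fixture(scope="session")
def survey_fixture():
    """The bundled survey-shaped fixture (17 sites, 3 types, 21 planted
    unanalyzable colonies), generated once per session."""
    return table1_like_fixture(0)


@pytest.fixture
def sim():
    """Factory for small, fully controlled synthetic datasets."""

    def factory(**kw):
        defaults = dict(
            n_types=1,
            regions_per_type=1,
            sites_per_region=1,
            genets_per_site=20,
            ramet_mean=1.0,
            type_drift=0.0,
            region_drift=0.0,
            f_is=0.0,
            null_rate=0.0,
            missing_rate=0.0,
            somatic_mu=0.0,
            heteroplasmy_rate=0.0,
            seed=0,
        )
        defaults.update(kw)
        return simulate_metapopulation(SimConfig(**defaults))

    return factory


def make_dataset(genotypes, sites=None, regions=None, mito="mtL"):
    """Hand-rolled GenotypeDataset from a genotype array."""
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    sites = sites if sites is not None else ["s1"] * n
    regions = regions if regions is not None else sites
    mito = [mito] * n if isinstance(mito, str) else mito
    colonies = pd.DataFrame(
        {
            "colony_id": [f"c{i}" for i in range(n)],
            "site": sites,
            "region": regions,
            "mito_type": mito,
        }
    )
    loci = [Locus(f"L{l + 1}") for l in range(genotypes.shape[1])]
    return GenotypeDataset(loci=loci, genotypes=genotypes, colonies=colonies)
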