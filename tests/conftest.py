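import numpy as np
import pytest

from wildrice.genotype_io import Genotype, GenotypeTable, Locus, SampleRecord
from wildrice.synthetic_data import PopGenSimConfig, simulate_ssr_genotypes


def make_table(rows, loci=None, ploidy=2):
    """Build a GenotypeTable from ``rows``: list of
    (sample_id, site, lon, lat, {locus: allele tuple})."""
    if loci is None:
        names = sorted({l for *_, genos in rows for l in genos})
        loci = [Locus(name=n) for n in names]
    samples = []
    for sid, site, lon, lat, genos in rows:
        samples.append(
            SampleRecord(
                sample_id=sid,
                species="test",
                site_id=site,
                lon=lon,
                lat=lat,
                genotypes={
                    l.name: Genotype(genos.get(l.name, ()), declared_ploidy=ploidy)
                    for l in loci
                },
            )
        )
    return GenotypeTable(loci=loci, samples=samples)


@pytest.fixture(scope="session")
def two_deme_table():
    """Two isolated demes (no migration): strong differentiation."""
    cfg = PopGenSimConfig(
        n_populations=2, n_individuals_per_pop=12, migration_rate=0.0,
        n_generations=150, n_loci=8, seed=11,
    )
    return simulate_ssr_genotypes(cfg)


@pytest.fixture(scope="session")
def ibd_table():
    """Stepping-stone demes on a line: isolation by distance."""
    cfg = PopGenSimConfig(
        n_populations=5, n_individuals_per_pop=8, migration_rate=0.05,
        migration_model="stepping_stone", n_generations=200, n_loci=11, seed=7,
    )
    return simulate_ssr_genotypes(cfg)


@pytest.fixture(scope="session")
def tetraploid_table():
    cfg = PopGenSimConfig(
        n_populations=2, n_individuals_per_pop=15, ploidy=4,
        migration_rate=0.005, n_generations=60, n_loci=6, seed=5,
    )
    return simulate_ssr_genotypes(cfg)
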