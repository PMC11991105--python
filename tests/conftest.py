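import numpy as np
import pytest

from islandadapt import (
    EnvTable,
    GenotypeMatrix,
    GeaSimConfig,
    StructureSimConfig,
    sim_env,
    sim_structured_genotypes,
)


def make_matrix(dosages, pos=None, chrom=None, pops=None):
    """Small GenotypeMatrix from a dosage array (samples x snps)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, s = dosages.shape
    pos = np.arange(1, s + 1) * 100 if pos is None else np.asarray(pos)
    chrom = np.full(s, "chr1", dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    pops = np.full(n, "pop0", dtype=object) if pops is None else np.asarray(pops, dtype=object)
    return GenotypeMatrix(
        dosages=dosages,
        chrom=chrom,
        pos=pos,
        ref_allele=np.full(s, "A", dtype=object),
        alt_allele=np.full(s, "T", dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        pop_of_sample=pops,
    )


def make_env(values_current, variables=None, site_ids=None, **futures):
    values_current = np.asarray(values_current, dtype=float)
    n_sites, n_vars = values_current.shape
    variables = variables or [f"V{i+1}" for i in range(n_vars)]
    site_ids = site_ids or [f"site{i+1}" for i in range(n_sites)]
    values = {"current": values_current}
    values.update({k: np.asarray(v, dtype=float) for k, v in futures.items()})
    return EnvTable(site_ids=site_ids, variables=list(variables), values=values)


@pytest.fixture(scope="session")
def structured_matrix():
    """Moderately sized five-deme Balding-Nichols dataset."""
    return sim_structured_genotypes(
        StructureSimConfig(n_pops=5, n_per_pop=6, n_snps=2000, fst=0.1, seed=11)
    )


@pytest.fixture(scope="session")
def gea_bundle():
    """Structured genotypes + env table + planted associations."""
    cfg = StructureSimConfig(n_pops=5, n_per_pop=20, n_snps=3000, fst=0.1, seed=5)
    g = sim_structured_genotypes(cfg)
    gcfg = GeaSimConfig(n_adaptive_loci=60, seed=5)
    env = sim_env(gcfg, n_pops=5)
    g2, truth = __import__("islandadapt").inject_env_association(g, env, gcfg)
    return g2, env, truth
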