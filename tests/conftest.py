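import numpy as np
import pytest

from featurexcan import GenotypeSet, SimConfig, Variant, simulate_genotypes, simulate_idps


def make_variants(n, chrom="1", alleles=("A", "G"), maf=0.3, start_pos=1000, rs_offset=0):
    """Toy variant list with non-ambiguous alleles and evenly spaced positions."""
    return [
        Variant(chrom=chrom, pos=start_pos + 1000 * j, rsid=f"rs{rs_offset + j + 1}",
                a0=alleles[0], a1=alleles[1], maf=maf)
        for j in range(n)
    ]


def toy_genotypes(n=50, P=20, seed=0, chrom="1"):
    """Small random dosage matrix (no LD structure) with variant metadata."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.5, size=P)
    dosages = rng.binomial(2, freqs, size=(n, P)).astype(float)
    # guard against monomorphic columns at tiny n
    for j in range(P):
        if dosages[:, j].std() == 0:
            dosages[0, j] = (dosages[0, j] + 1) % 3
    variants = make_variants(P, chrom=chrom)
    return GenotypeSet(dosages=dosages, variants=variants)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared LD-structured cohort: n=500, P=600, two chromosomes."""
    cfg = SimConfig(n=500, P=600, K=10, seed=101)
    geno = simulate_genotypes(cfg)
    idps, L, R = simulate_idps(geno, cfg)
    return cfg, geno, idps, L, R
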