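import numpy as np
import pytest

from popdiv.model import GenotypeMatrix, VariantSite
from popdiv.simulate import make_toy_genome


def matrix_from_genotypes(genotypes, chrom="Chr01", start_pos=100, spacing=50,
                          ref="A", alt="G"):
    """Build a biallelic SNP matrix from a list of per-site genotype lists.

    Each genotype is a pair of allele indices or None for missing.
    """
    genotypes = [list(g) for g in genotypes]
    n_samples = len(genotypes[0])
    sites, rows = [], []
    for i, site_gts in enumerate(genotypes):
        sites.append(
            VariantSite(chrom, start_pos + i * spacing, ref, (alt,))
        )
        rows.append(
            [(-1, -1) if g is None else tuple(g) for g in site_gts]
        )
    calls = np.array(rows, dtype=np.int16)
    samples = [f"s{j}" for j in range(n_samples)]
    return GenotypeMatrix(sites, samples, calls)


@pytest.fixture(scope="session")
def toy():
    """Implanted-variant toy genome with its truth ledger."""
    return make_toy_genome(seed=1)
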