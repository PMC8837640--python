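"""Filter a raw call set into the simply-filtered and core SNP subsets.

Simulates a small inbred panel, applies the two filters and prints the
per-chromosome core counts — the retained fraction shows how much the
missingness/heterozygosity/MAF thresholds bite.
"""

import numpy as np

from popdiv import chrom_counts, core_filter, simple_filter
from popdiv.simulate import simulate_frequencies, simulate_genotypes

rng = np.random.default_rng(0)
matrix = simulate_genotypes(
    simulate_frequencies(2000, "sfs", n_chromosome_copies=100, rng=rng),
    n_samples=50,
    missing_rate=0.08,
    het_deficit=0.9,  # self-pollinating lines: few heterozygotes
    rng=rng,
    chrom_length=1_000_000,
)

simple = simple_filter(matrix)
core = core_filter(simple)  # missing <= 10%, het <= 10%, MAF >= 2%

print(f"input sites            {matrix.n_sites}")
print(f"simply filtered (biallelic, polymorphic SNPs): {simple.n_sites}")
print(f"core set (quality thresholds):                 {core.n_sites}")
print("\ncore SNPs per chromosome:")
print(chrom_counts(core).to_string())
# The core/simple ratio is driven mostly by the MAF >= 2% cut: under a
# neutral frequency spectrum many sites are rare variants.
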