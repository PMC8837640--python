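"""LD decay curve and half-decay distance on haplotypes with known LD.

The copying-Markov simulator produces r2(d) = exp(-d/L); the half-decay
distance of that curve is L ln 2, so with L = 100 kb the estimate should
print close to 69 kb.
"""

import numpy as np

from popdiv import half_decay_distance, ld_curve
from popdiv.simulate import haplotypes_to_matrix, simulate_ld_haplotypes

rng = np.random.default_rng(2)
L = 100_000
positions = np.sort(rng.choice(np.arange(1, 1_000_001), size=500, replace=False))
haplotypes = simulate_ld_haplotypes(positions, L, n_haplotypes=200, rng=rng)
matrix = haplotypes_to_matrix(haplotypes, positions, rng=rng)

curve = ld_curve(matrix, max_dist=1_000_000, bin_width=5_000)
half = half_decay_distance(curve)

print(f"max r2 (first bin)    {curve.max_r2:.3f}")
print(f"half-decay distance   {half / 1e3:.1f} kb  (target L ln2 = {L * np.log(2) / 1e3:.1f} kb)")
print("\nfirst bins of the decay curve:")
print(curve.to_frame().head(8).to_string(index=False))
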