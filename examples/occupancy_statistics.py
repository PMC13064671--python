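"""Bead occupancy statistics at the experimentally used inoculation rates.

The Poisson rate λ (expected cells per microbead) is the main experimental
dial: λ = 0.02 makes nearly every filled bead a monoculture (used to test
isolated growth), while λ = 0.3 maximises two-cell beads relative to beads
with three or more cells (used to probe pairwise interactions).
"""

import numpy as np

from beadweb import OccupancySpec, bead_composition_fractions, conditional_occupancy

for lam in (0.02, 0.3):
    occ = conditional_occupancy(OccupancySpec(lam))
    print(f"λ = {lam}:")
    print(f"  filled beads with exactly one cell : {100 * occ['p1_given_ge1']:.2f}%")
    print(f"  multi-cell beads with two cells    : {100 * occ['p2_given_ge2']:.2f}%")
    print(f"  filled beads with three or more    : {100 * occ['p_ge3_given_ge1']:.2f}%")

# composition of the bead pool for a three-member inoculum at λ = 0.3
p = np.array([0.5, 0.3, 0.2])
comp = bead_composition_fractions(OccupancySpec(0.3), p)
print("\ninoculum proportions", p, "at λ = 0.3:")
for i in range(3):
    print(f"  fraction of beads with one cell of type {i}: {comp.singleton_fractions[i]:.4f}")
for i in range(3):
    for j in range(i, 3):
        print(f"  fraction of beads with the pair {{{i},{j}}}:   {comp.pair_fraction(i, j):.4f}")
print(
    "\nSingleton fractions sum to the Poisson mass at k=1 and pair fractions"
    "\nto the mass at k=2; beads with more than two cells are ignored."
)
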