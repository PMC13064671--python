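"""Forward growth model: from interaction parameters to final proportions.

Each bead grows according to its inoculated content: a pair bead {i, j}
ends with G_ij cells of which a fraction f_i|ij belong to type i.  Pooling
the sorted beads predicts the final cell-type proportions p(T).

The worked example: in a pool made only of pair beads of a helper strain B
and a partner C, B grows on a limiting glucose pulse to about 2 cells per
bead while the bead fills to 9 cells in total (G_BC = 9 in absolute cell
numbers, f_B|BC = 2/9), so the pooled share of B is 2/9 ≈ 0.22.
"""

import numpy as np

from beadweb import (
    InteractionParameters,
    OccupancySpec,
    bead_composition_fractions,
    expected_final_proportions,
    parameter_count,
)

params = InteractionParameters(
    growth_single=np.array([0.0, 0.0]),       # neither strain grows alone
    growth_pair=np.array([[0.0, 9.0], [9.0, 0.0]]),
    fraction_pair=np.array([[1.0, 2 / 9], [7 / 9, 1.0]]),
    type_labels=["B", "C"],
)
comp = bead_composition_fractions(OccupancySpec(0.3), np.array([0.5, 0.5]))
out = expected_final_proportions(comp, params)
print(f"final proportion of B: {out.proportions[0]:.2f}  (expected ~0.22)")
print(f"final proportion of C: {out.proportions[1]:.2f}")

# the identifiability bookkeeping behind multi-experiment designs
for n in (3, 4, 6):
    c = parameter_count(n)
    print(
        f"N={n}: {c['n_growth_pair']} growth terms + {c['n_fraction_pair']} fractions "
        f"to fit, {c['n_independent_measurements_per_experiment']} independent "
        "measurements per experiment"
    )
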