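# beadweb

Inference of pairwise microbial interactions from label-free microbead
co-encapsulation experiments.

## The problem

Microbial consortia are shaped by pairwise interactions — cross-feeding,
facilitation, amensalism — that are hard to measure without isolating and
genetically labelling every member. A label-free alternative: encapsulate
the whole consortium at a low Poisson rate λ (expected cells per bead) in
~10⁷ picolitre agarose microbeads, so that each bead receives zero, one or
two founder cells; grow to stationary phase; sort out the beads that grew
to medium depletion; and compare cell-type counts of ~96–1000 sampled
colonies before encapsulation (d(0)) and after sorting (d(T)). Each
two-cell bead is a tiny pairwise co-culture, so the shift from d(0) to
d(T) encodes which pairs grow together and who dominates the pair.

`beadweb` implements the computational side of this method:

- **occupancy** — the Poisson–multinomial model of bead content: the
  fraction φ_ij of beads inoculated with one cell of type *i* and one of
  type *j*, given λ and the inoculum proportions p(0). Beads with more
  than two cells are ignored (at λ = 0.3 only 1% of filled beads hold
  three or more).
- **growth** — the pairwise interaction model: a bead seeded with pair
  {i, j} ends with G_ij cells, a fraction f_i|ij of them of type *i*
  (f_i|ij + f_j|ij = 1); a bead seeded with a single cell of type *i*
  ends with G_i cells. Only relative growth is observable, so the G of a
  chosen reference pair is fixed to 1. Expected final proportions:

      p_i(T) ∝ φ_i G_i + φ_ii G_i + Σ_{j≠i} φ_ij G_ij f_i|ij

- **inference** — Bayesian estimation of {G, f} from one or more
  experiments. Both count vectors are modelled as multinomial samples:
  d(0) of the latent true inoculum proportions p(0) (Dirichlet prior
  around the intended design, concentration κ), d(T) of the predicted
  p(T). Default priors: f uniform on (0, 1), G log-uniform
  (P(G) ∝ 1/G); log-normal / Dirichlet / fixed-value priors can carry
  information from earlier experiments. The posterior is sampled with an
  affine-invariant ensemble (emcee) in unconstrained coordinates; each
  parameter is reported as its maximum-posterior (MAP) value with a 68%
  posterior probability interval (16th–84th percentile).
- **simulate / validate** — a seeded generator of synthetic experiments
  (preset 3–6-member consortium designs with or without isolated growth,
  optionally amensal) and scoring of inference errors |MAP − truth| with
  the t-test machinery to compare designs, sampling depths and numbers of
  experiments.

## Worked example

A bead pool containing only B–C pair beads that fill to nine cells, two of
which come from the helper strain B (G_BC = 9 cells, f_B|BC = 2/9):

```bash
$ python examples/forward_growth_model.py
final proportion of B: 0.22  (expected ~0.22)
final proportion of C: 0.78
```

Occupancy statistics at the two experimentally used rates
(`examples/occupancy_statistics.py`): at λ = 0.02, 99.00% of filled beads
hold a single cell (the monoculture-growth check); at λ = 0.3, 90.25% of
multi-cell beads hold exactly two cells, 85.75% of filled beads hold one
cell, and only 1.39% hold three or more — the design point for pairwise
inference.

End-to-end inference on a simulated three-member consortium
(`examples/infer_interactions.py`), three experiments of 1000 colonies:

```
pair      true G   MAP G   68% ppi          true f   MAP f   68% ppi
T0,T1      1.00    1.00  [ 1.00, 1.00]    0.50    0.48  [ 0.46, 0.50] (reference)
T0,T2      1.00    0.88  [ 0.45, 1.23]    0.30    0.42  [ 0.17, 0.59]
T1,T2      1.00    1.05  [ 0.74, 1.19]    0.30    0.21  [ 0.15, 0.25]
```

Growth terms are relative to the reference pair; a near-zero G flags a
pair that does not grow when co-localised. Interval widths vary strongly
with how well the random inoculum compositions happen to separate the
parameters — see `docs/methods.md` for what limits accuracy at these
sampling depths.

`examples/validation_sweep.py` runs a small error sweep and reproduces the
headline qualitative result: inference errors are significantly higher
when a consortium member grows in isolation, because its singleton beads
dominate the sorted pool and dilute the pair-bead signal.

The command-line interface mirrors the library:
`beadweb occupancy|simulate|infer|validate|pipeline --help`.

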