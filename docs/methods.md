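# Methods

## Model

### Bead occupancy

The number of cells inoculated into a microbead is Poisson with rate λ;
conditional on k cells, their types are i.i.d. draws from the inoculum
proportions p(0). The model tracks only beads with k = 1 and k = 2:

- singleton fractions φ_i = Pois(1; λ) p_i,
- pair fractions φ_ij = Pois(2; λ)·2 p_i p_j for i ≠ j and
  φ_ii = Pois(2; λ) p_i².

Beads with k > 2 are *dropped*, not renormalised into k ≤ 2. Because every
downstream observable is a proportion, the discarded constant cancels; at
the working rate λ = 0.3 the discarded mass is ~1% of filled beads.
Same-type pairs {i, i} are modelled explicitly: they arise with
probability p_i² and must enter the growth model.

### Growth

Each bead grows independently to stationary phase. A mixed pair bead
{i, j} ends with G_ij cells, of which a fraction f_i|ij are type i; a
singleton bead of type i ends with G_i cells. A same-type pair bead {i, i}
is given G_ii = G_i: the final cell number is set by medium depletion (or
the lack of growth), not by whether one or two founder cells were present.
Growth-based sorting is not modelled as a hard threshold; combinations
that do not grow simply carry a near-zero G, which is also how the
inference reports them. Pooling over the sorted beads, the expected final
proportions are

    p_i(T) ∝ φ_i G_i + φ_ii G_i + Σ_{j≠i} φ_ij G_ij f_i|ij .

Only relative growth is identifiable from proportions, so the G of a
designated reference pair is fixed to 1 ("growth until medium depletion")
and all growth terms are reported relative to it. No kinetics, no
time-resolved dynamics, no third-order interactions: the model maps
inoculation directly to a single post-growth composition.

### Observation model and priors

Each experiment contributes two multinomial observations: d(0) at depth n₀
from the latent true inoculum proportions p(0), and d(T) at depth n_T from
p(T). p(0) is latent and sampled jointly with the interaction parameters —
plugging in the observed initial frequencies would understate the reported
uncertainty. Its prior is Dirichlet(κ·intended), centred on the intended
design proportions with preparation precision κ (default 100, i.e. the
preparation is roughly as precise as a 100-colony count; it is a config
field, as the appropriate value is apparatus-specific). With no intended
design given, the prior is flat Dirichlet.

Default parameter priors are uninformative: f_i|ij uniform on (0, 1);
G log-uniform, P(G) ∝ 1/G, on [10⁻⁶, 10³] relative units (equal weight to
G near 0.5 and near 2; the lower bound leaves margin below the smallest
values typically inferred for non-growing pairs, ~10⁻⁵). When an earlier
experiment provides information, per-parameter priors can be log-normal
(G, parameterised by the mean and variance of G itself), two-component
Dirichlet i.e. Beta (f, mean and variance), or fixed values — the
fixed-value mode is how a previously characterised pair is carried into a
new consortium.

### Posterior computation

Sampling runs in unconstrained coordinates — ln G, logit f, additive
log-ratio of p(0) — with all change-of-variable Jacobians included, using
the emcee affine-invariant ensemble sampler with a vectorised
log-posterior. Walkers start from the MAP point plus small Gaussian
scatter. The MAP is the best of n_starts (default 8) L-BFGS-B
maximisations of the transformed-space log-posterior, started from a
data-informed centre (G_pair = 1, f = ½, p(0) at smoothed observed
frequencies) plus seeded perturbations; gradients are batched central
differences through the vectorised density; ties are broken by the first
optimum found. If the sampler encounters a better point than the
optimiser, that point is reported instead.

Reported per parameter: the MAP value and the central 68% posterior
probability interval (16th–84th percentile of the marginal samples). The
central interval is used rather than a highest-density interval because it
is unambiguous and stable under reparameterisation of the other
coordinates; in skewed posteriors the MAP can fall outside it, which is
legitimate and preserved. Convergence is monitored with split-R̂ computed
across walkers; values above 1.05 set a warning flag in the diagnostics
(not an exception), and a zero-variance parameter sets a
degenerate-posterior flag. All randomness derives from a single integer
seed via `numpy.random.SeedSequence`.

## Synthetic data generator

`simulate_dataset` emulates the measurement process the inference assumes,
step by step: intended inoculum proportions uniform on the simplex
(symmetric Dirichlet(1) — the simplest reading of "random initial
fractions"); true p(0) ~ Dirichlet(κ·intended) preparation noise; p(T)
through the truncated occupancy model and the growth model; d(0) and d(T)
multinomial at the colony depth (96 = high noise, 1000 = low noise; other
depths are allowed for convergence checks). Seeds are a pure function of
(master_seed, replicate, experiment), so datasets are byte-identical
across runs and matched across conditions that share a master seed.

Preset consortium designs cover the validated families: no member growing
alone, one or two isolated growers, and an amensal variant. Interacting
pairs form a cross-feeding ring over all N members; the reference pair
(0, 1) is symmetric (G = 1, f = ½), other ring pairs grow to depletion
with an asymmetric split (helper share 0.3), off-ring pairs do not grow
(G = 10⁻⁴), isolated growers have G_i = 1, all other members background
growth G_i = 10⁻². In the amensal variant the pair formed by the two
isolated growers still fills to depletion (the unaffected member grows
fully) but the suppressed member ends at a 0.1 share. These true values
are documented reconstructions of plausible designs — the validation
literature for this method does not print its simulation tables — and
every one of them can be overridden.

What the generator does *not* emulate: bead-size heterogeneity, bead loss
or FACS threshold effects during sorting, biological growth variability
between beads of identical content, and higher-order (≥3 member) effects.
Passing tests therefore demonstrate the statistical machinery under the
model's own assumptions, not robustness to these real-data features.

## Validation workflow

Inference error is |MAP − truth| per parameter, in two families: growth
terms (all inferred pairs; the reference pair is fixed by construction and
not scored) and strain fractions, the latter only for pairs whose *true*
G exceeds 0.1 — the fraction of a pair that does not grow is meaningless.
The gate uses the true G because validation is the setting where truth is
known. Conditions are compared by two-sample t-tests on replicate-level
mean errors (5 replicates per condition; pooled across the experiment-grid
when two grid values are compared as one condition), one-sided for
directional claims.

Two deliberate choices in this workflow:

- **Singleton growth is pinned.** The validation fits only the pair
  parameters, fixing each G_i at its design value, mirroring the two-step
  experimental protocol in which monoculture growth is established first
  at λ = 0.02 before pair inference at λ = 0.3 (and matching the parameter
  count (N−1)N/2 + (N−1)N/2 of the computational validation). Fitting
  singletons freely remains available through `PriorSpec`.
- **The growth prior is capped at 10 relative units.** Growth terms are
  relative to growth-until-depletion, so the bead's carrying capacity
  makes values far above 1 physically impossible. Without the cap, an
  underdetermined condition (e.g. four members with only two experiments:
  11 free pair parameters against 6 independent measurements) lets the MAP
  sit anywhere on a likelihood ridge up to the generic prior bound of 10³,
  and the "inference error" then measures the prior bound, not the method.

## Accuracy limits at the studied sampling depths

Two structural effects dominate the validation results and are worth
stating explicitly, because they bound what any estimator can do with
these data:

- **Three experiments barely determine a three-member consortium.** N = 3
  with 3 experiments yields 6 independent final-proportion measurements
  for 5 free pair parameters. Multinomial noise at depth 1000 is ~1.5%
  per component, and random Dirichlet(1) inoculum compositions are
  frequently near-collinear, which amplifies that noise strongly into the
  parameters. Measured across seeded replicates, MAP fractions land
  within ±0.05 of truth and growth terms within a factor 1.2 in only a
  minority of replicates; the same estimator reaches errors of ~0.006 (f)
  and ×1.08 (G) at depth 10⁵, confirming an information limit rather than
  an estimator defect. Interval *coverage* is unaffected: the 68% ppi
  covers the truth at the nominal rate (within three binomial standard
  errors over 200 replicates) — the posterior is honest about its width.
- **The pair formed by two isolated growers is nearly unidentifiable.**
  Its pair beads contribute a few percent of those types' final cells
  against their dominant singleton growth, so its fraction estimate stays
  near the prior centre (½) at any modest number of experiments. A design
  whose amensal pair has true f = 0.9 therefore shows systematically
  larger fraction errors (≈|0.9 − ½|) than the same design with f = 0.3
  (≈|0.3 − ½|), a structural difference that small validation grids flag
  as statistically significant. In the well-determined regime (6
  experiments, 1000 colonies) the expected orderings hold: errors with one
  isolated grower are significantly higher than with none (one-sided
  p ≈ 0.017 for both parameter families in the shipped example sweep),
  and deeper colony sampling never increases the mean error on matched
  seeds.

## Numerical notes and limitations

- Likelihood conventions: 0·log 0 = 0; a positive count on a
  zero-probability type yields −∞ (not an exception); all-zero expected
  mass raises a no-growth error in the forward model and −∞ in the
  sampler.
- Optimiser bounds keep log-uniform coordinates strictly inside their
  support (margin 10⁻³ in log units) so finite-difference gradients stay
  finite.
- Problem sizes in the shipped tests and examples (three to four members,
  2–6 experiments, 5–200 replicates, MCMC chains of 600–1500 steps with
  24–70 walkers) were chosen so a full run completes on a single CPU in
  minutes; all of them are plain function arguments and scale up
  unchanged.
- The reported MAP is the mode of the posterior density in the
  *transformed* space; modes are parameterisation-dependent, and the
  uniform-f prior's logit-space density mildly favours ½ on flat
  likelihood directions. With informative data the effect is negligible.
- The method identifies interactions only up to what relative abundances
  at a single time point can reveal: no growth rates, no dynamics, no
  mechanism. Amensalism vs. competition, for example, is distinguished by
  which member's pair share collapses, not by any temporal signature.
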