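"""Synthetic microbead-experiment generator for inference validation.

Generates count datasets with exactly the statistical structure the
inference model assumes: random intended inoculum proportions (uniform on
the simplex), Dirichlet preparation noise around them, Poisson bead
occupancy truncated at two cells, deterministic pairwise growth, and
multinomial colony sampling at depth 96 ("high noise") or 1000 ("low
noise").

Consortium presets mirror the two validated families of designs: consortia
where no member grows alone, and consortia where one or two members are
capable of isolated growth (optionally with an amensal interaction between
the two isolated growers).  Interacting pairs are arranged in a
cross-feeding ring over all members; the true parameter values are
documented reconstructions (see docs/methods.md), not measured values, and
every one of them can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import InteractionParameters, expected_final_proportions, _pairs
from .inference import ExperimentDataset
from .occupancy import OccupancySpec, bead_composition_fractions

__all__ = [
    "ConsortiumDesign",
    "SimulationConfig",
    "PRESETS",
    "make_design",
    "simulate_dataset",
    "simulate_replicate",
    "derive_seed",
]

PRESETS = ("no_isolated", "one_isolated", "two_isolated", "two_isolated_amensal")

# default true-parameter levels (relative units, depletion = 1)
DEPLETION_GROWTH = 1.0
BACKGROUND_SINGLE = 1e-2
NON_GROWING_PAIR = 1e-4
FACILITATION_FRACTION = 0.3  # fraction of the lower-index (helper) member
AMENSAL_FRACTION = 0.9  # fraction of the unaffected member


@dataclass(frozen=True)
class ConsortiumDesign:
    """A simulated consortium: its true interaction parameters and which
    members are capable of isolated growth (growth alone until medium
    depletion, G_i = 1) versus background-only growth (G_i << 1)."""

    n_types: int
    true_params: InteractionParameters
    isolated_growth_flags: np.ndarray
    design_label: str

    def __post_init__(self) -> None:
        flags = np.asarray(self.isolated_growth_flags, dtype=bool)
        if flags.shape != (self.n_types,):
            raise ValueError("isolated_growth_flags must have one entry per type")
        object.__setattr__(self, "isolated_growth_flags", flags)
        gs = self.true_params.growth_single
        if np.any(flags & (gs < DEPLETION_GROWTH)):
            raise ValueError("isolated growers must have depletion-level growth (G_i = 1)")
        if np.any(~flags & (gs > BACKGROUND_SINGLE)):
            raise ValueError("non-isolated types must have background-level growth")


@dataclass(frozen=True)
class SimulationConfig:
    """Experiment-level simulation settings.

    ``n_colonies`` is the multinomial sampling depth of both d(0) and d(T)
    (96 and 1000 are the studied high- and low-noise depths; larger values
    are allowed for convergence checks).  Per-dataset randomness derives
    deterministically from ``master_seed`` via
    :func:`derive_seed`(master_seed, replicate, experiment).
    """

    lambda_rate: float = 0.3
    n_colonies: int = 96
    n_experiments: int = 3
    n_replicates: int = 5
    master_seed: int = 0
    preparation_precision: float = 100.0

    def __post_init__(self) -> None:
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be > 0")
        for name in ("n_colonies", "n_experiments", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.preparation_precision <= 0:
            raise ValueError("preparation_precision must be > 0")


def _ring_pairs(n: int) -> set[tuple[int, int]]:
    """Unordered pairs of the cross-feeding ring over n types."""
    ring = {(k, (k + 1) % n) for k in range(n)}
    return {(min(i, j), max(i, j)) for i, j in ring}


def make_design(
    preset: str, n_types: int, overrides: dict | None = None
) -> ConsortiumDesign:
    """Build a preset consortium design.

    Presets
    -------
    - ``no_isolated``: no member grows alone (background singleton growth
      G_i = 1e-2); interacting pairs form a cross-feeding ring.
    - ``one_isolated``: the last member additionally grows alone until
      depletion (G_i = 1).
    - ``two_isolated``: the last two members grow alone.
    - ``two_isolated_amensal``: as ``two_isolated`` but the pair of
      isolated growers interacts amensally — the pair bead still fills to
      depletion while the suppressed member ends at a 0.1 share.

    In every preset the reference pair (0, 1) is a symmetric cross-feeding
    pair with G = 1, f = 1/2; other ring pairs grow to depletion with an
    asymmetric split (helper at 0.3); pairs off the ring do not grow
    (G = 1e-4).

    ``overrides`` may contain ``pair_growth`` / ``pair_fraction`` dicts
    keyed by unordered index pairs (fractions refer to the lower index),
    a ``growth_single`` vector, and/or ``reference_pair``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    if n_types < 3:
        raise ValueError("presets are defined for consortia of 3 or more members")

    flags = np.zeros(n_types, dtype=bool)
    if preset == "one_isolated":
        flags[-1] = True
    elif preset in ("two_isolated", "two_isolated_amensal"):
        flags[-2:] = True

    growth_single = np.where(flags, DEPLETION_GROWTH, BACKGROUND_SINGLE).astype(float)
    ring = _ring_pairs(n_types)
    growth_pair = np.zeros((n_types, n_types))
    fraction = np.full((n_types, n_types), 0.5)
    np.fill_diagonal(fraction, 1.0)
    for (i, j) in _pairs(n_types):
        if (i, j) in ring:
            g = DEPLETION_GROWTH
            f = 0.5 if (i, j) == (0, 1) else FACILITATION_FRACTION
        else:
            g, f = NON_GROWING_PAIR, 0.5
        growth_pair[i, j] = growth_pair[j, i] = g
        fraction[i, j] = f
        fraction[j, i] = 1.0 - f
    if preset == "two_isolated_amensal":
        i, j = n_types - 2, n_types - 1
        growth_pair[i, j] = growth_pair[j, i] = DEPLETION_GROWTH
        fraction[i, j] = AMENSAL_FRACTION  # lower index unaffected
        fraction[j, i] = 1.0 - AMENSAL_FRACTION

    overrides = overrides or {}
    unknown = set(overrides) - {"pair_growth", "pair_fraction", "growth_single", "reference_pair"}
    if unknown:
        raise ValueError(f"unknown override keys: {sorted(unknown)}")
    for (i, j), g in overrides.get("pair_growth", {}).items():
        i, j = min(i, j), max(i, j)
        growth_pair[i, j] = growth_pair[j, i] = g
    for (i, j), f in overrides.get("pair_fraction", {}).items():
        i, j = min(i, j), max(i, j)
        fraction[i, j] = f
        fraction[j, i] = 1.0 - f
    if "growth_single" in overrides:
        growth_single = np.asarray(overrides["growth_single"], dtype=float)
    np.fill_diagonal(growth_pair, growth_single)

    params = InteractionParameters(
        growth_single=growth_single,
        growth_pair=growth_pair,
        fraction_pair=fraction,
        reference_pair=overrides.get("reference_pair", (0, 1)),
    )
    return ConsortiumDesign(
        n_types=n_types,
        true_params=params,
        isolated_growth_flags=flags,
        design_label=preset,
    )


def derive_seed(
    master_seed: int, replicate_index: int, experiment_index: int
) -> np.random.SeedSequence:
    """Pure, collision-free seed derivation per (replicate, experiment)."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(replicate_index, experiment_index)
    )


def simulate_dataset(
    design: ConsortiumDesign,
    config: SimulationConfig,
    replicate_index: int,
    experiment_index: int,
) -> ExperimentDataset:
    """Simulate one experiment's before/after count vectors.

    Steps: draw intended inoculum proportions uniformly on the simplex;
    perturb them with Dirichlet preparation noise (concentration
    κ·intended) to get the true p(0); push p(0) through the truncated
    occupancy model and the pairwise growth model to get p(T); sample
    d(0) ~ Multinomial(n_colonies, p(0)) and d(T) ~ Multinomial(n_colonies,
    p(T)).  Byte-identical results for identical seeds.
    """
    rng = np.random.default_rng(
        derive_seed(config.master_seed, replicate_index, experiment_index)
    )
    n = design.n_types
    intended = rng.dirichlet(np.ones(n))
    p0 = rng.dirichlet(config.preparation_precision * intended)
    # guard against exact zeros from extreme Dirichlet draws
    p0 = np.clip(p0, 1e-12, None)
    p0 = p0 / p0.sum()
    comp = bead_composition_fractions(OccupancySpec(config.lambda_rate), p0)
    pT = expected_final_proportions(comp, design.true_params).proportions
    d0 = rng.multinomial(config.n_colonies, p0)
    dT = rng.multinomial(config.n_colonies, pT)
    return ExperimentDataset(
        type_labels=tuple(design.true_params.type_labels),
        lambda_rate=config.lambda_rate,
        counts_initial=d0,
        counts_final=dT,
        intended_proportions=intended,
    )


def simulate_replicate(
    design: ConsortiumDesign, config: SimulationConfig, replicate_index: int
) -> list[ExperimentDataset]:
    """All ``config.n_experiments`` datasets of one replicate."""
    return [
        simulate_dataset(design, config, replicate_index, e)
        for e in range(config.n_experiments)
    ]
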