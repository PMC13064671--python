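"""Poisson–multinomial model of cell occupancy in picolitre microbeads.

When a dilute cell suspension is emulsified into ~10^7 agarose microbeads,
the number of cells landing in a bead is Poisson distributed with a rate
``lambda_rate`` (expected cells per bead) set by the inoculum concentration.
Conditional on a bead holding ``k`` cells, the cell-type content is a
multinomial draw from the inoculum proportions.  At the working rate
λ = 0.3 beads with three or more cells are rare, so the model tracks only
singly and doubly occupied beads; the fraction of beads holding one cell of
type *i* and one of type *j* is written φ_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "OccupancySpec",
    "CompositionDistribution",
    "bead_count_pmf",
    "conditional_occupancy",
    "bead_composition_fractions",
]


@dataclass(frozen=True)
class OccupancySpec:
    """Poisson occupancy specification for a microbead emulsion.

    Parameters
    ----------
    lambda_rate
        Expected number of cells per microbead (Poisson rate), >= 0.
    truncation_order
        Maximum bead occupancy retained by the model.  The default of 2
        keeps singly and doubly occupied beads; beads with more cells are
        dropped from the model (their mass is discarded, not renormalised,
        which cancels in the relative abundances used downstream).
    """

    lambda_rate: float
    truncation_order: int = 2

    def __post_init__(self) -> None:
        if self.lambda_rate < 0:
            raise ValueError(f"lambda_rate must be >= 0, got {self.lambda_rate}")
        if self.truncation_order < 1:
            raise ValueError(
                f"truncation_order must be >= 1, got {self.truncation_order}"
            )


@dataclass(frozen=True)
class CompositionDistribution:
    """Fractions of beads by inoculated cell-type content.

    ``singleton_fractions[i]`` is the fraction of *all* beads holding exactly
    one cell, of type ``i``.  ``pair_fractions[i, j]`` is the fraction of all
    beads holding exactly two cells whose unordered type content is ``{i, j}``
    (the matrix is symmetric and each unordered pair's mass is split evenly
    between the ``(i, j)`` and ``(j, i)`` entries so that the sum over the
    full matrix equals the total pair mass).
    """

    singleton_fractions: np.ndarray
    pair_fractions: np.ndarray
    lambda_rate: float

    @property
    def n_types(self) -> int:
        return self.singleton_fractions.shape[0]

    def pair_fraction(self, i: int, j: int) -> float:
        """Fraction of beads inoculated with the unordered pair ``{i, j}``."""
        if i == j:
            return float(self.pair_fractions[i, i])
        return float(self.pair_fractions[i, j] + self.pair_fractions[j, i])


def bead_count_pmf(spec: OccupancySpec, k: int) -> float:
    """Probability that a bead is inoculated with exactly ``k`` cells.

    Poisson pmf ``exp(-λ) λ^k / k!`` evaluated at ``k``.
    """
    if k < 0:
        raise ValueError(f"cell count k must be >= 0, got {k}")
    return float(stats.poisson.pmf(k, spec.lambda_rate))


def conditional_occupancy(spec: OccupancySpec) -> dict[str, float]:
    """Occupancy of *filled* beads under the untruncated Poisson law.

    Returns a dict with

    - ``p1_given_ge1``: P(k = 1 | k >= 1), the fraction of filled beads
      holding a single cell (99% at λ = 0.02; 86% at λ = 0.3),
    - ``p2_given_ge2``: P(k = 2 | k >= 2) (90.25% at λ = 0.3, the design
      point that maximises pair beads while keeping triplets rare),
    - ``p_ge3_given_ge1``: P(k >= 3 | k >= 1) (1% at λ = 0.3).
    """
    lam = spec.lambda_rate
    if lam <= 0:
        raise ValueError(
            "conditional occupancy is undefined at lambda_rate = 0: "
            "the conditioning event {k >= 1} has probability 0"
        )
    p0 = stats.poisson.pmf(0, lam)
    p1 = stats.poisson.pmf(1, lam)
    p2 = stats.poisson.pmf(2, lam)
    p_ge1 = 1.0 - p0
    p_ge2 = p_ge1 - p1
    p_ge3 = p_ge2 - p2
    return {
        "p1_given_ge1": float(p1 / p_ge1),
        "p2_given_ge2": float(p2 / p_ge2),
        "p_ge3_given_ge1": float(p_ge3 / p_ge1),
    }


def bead_composition_fractions(
    spec: OccupancySpec, initial_proportions: np.ndarray
) -> CompositionDistribution:
    """Expected bead-content fractions φ from λ and inoculum proportions.

    For inoculum proportions ``p`` the fraction of beads holding one cell of
    type ``i`` is ``Poisson(1; λ) p_i`` and the fraction holding the
    unordered pair ``{i, j}`` is ``Poisson(2; λ) · 2 p_i p_j`` for ``i ≠ j``
    and ``Poisson(2; λ) · p_i²`` for ``i = j`` (the multinomial thinning of
    the Poisson inoculum).  Beads with more cells than the spec's
    ``truncation_order`` are dropped.

    Parameters
    ----------
    spec
        Occupancy specification (λ and truncation order).
    initial_proportions
        Probability vector of cell-type proportions in the inoculum; must be
        nonnegative and sum to 1 within 1e-9.
    """
    p = np.asarray(initial_proportions, dtype=float)
    if p.ndim != 1:
        raise ValueError("initial_proportions must be a 1-D probability vector")
    if np.any(p < 0):
        raise ValueError("initial_proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"initial_proportions must sum to 1 (got {p.sum():.12g})"
        )
    n = p.shape[0]
    c1 = bead_count_pmf(spec, 1)
    singletons = c1 * p
    if spec.truncation_order >= 2:
        c2 = bead_count_pmf(spec, 2)
        # split each unordered pair's mass 2*c2*p_i*p_j over (i,j) and (j,i)
        pairs = c2 * np.outer(p, p)
    else:
        pairs = np.zeros((n, n))
    return CompositionDistribution(
        singleton_fractions=singletons, pair_fractions=pairs, lambda_rate=spec.lambda_rate
    )


def occupancy_report(
    spec: OccupancySpec, initial_proportions: np.ndarray | None = None
) -> dict:
    """JSON-ready occupancy summary: conditional occupancies and, when
    inoculum proportions are given, the φ composition table."""
    report: dict = {"lambda": spec.lambda_rate}
    report.update(conditional_occupancy(spec))
    if initial_proportions is not None:
        comp = bead_composition_fractions(spec, np.asarray(initial_proportions, float))
        report["singleton_fractions"] = comp.singleton_fractions.tolist()
        report["pair_fractions"] = comp.pair_fractions.tolist()
    return report
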