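"""Pairwise interaction growth model for microbead sub-communities.

Each inoculated bead grows to stationary phase in isolation.  The outcome
for a bead seeded with an unordered pair {i, j} is summarised by two
parameters: the growth term G_ij, the average final number of cells in the
bead, and the strain-fraction term f_i|ij, the fraction of those cells that
are of type i (so f_i|ij + f_j|ij = 1).  Singly seeded beads of type i grow
to G_i cells.  Because growth-based sorting only yields relative
abundances, all growth terms are relative: the G of a designated reference
pair is fixed to 1, interpreted as growth until medium depletion.

Pooling the sorted beads, the expected number of cells of type i is the
composition-weighted sum of per-bead contributions, which normalised gives
the expected final proportions p(T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .occupancy import CompositionDistribution

__all__ = [
    "InteractionParameters",
    "FinalProportions",
    "expected_final_proportions",
    "parameter_count",
]


def _pairs(n: int) -> list[tuple[int, int]]:
    """Unordered distinct type pairs (i, j), i < j, in lexicographic order."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass
class InteractionParameters:
    """Interaction parameters of an N-member consortium.

    Parameters
    ----------
    growth_single
        Vector G_i >= 0: final cells in a bead seeded with one cell of type
        i, in the same relative units as the pair terms.
    growth_pair
        Symmetric matrix G_ij >= 0: average final cells in a bead seeded
        with an {i, j} pair.  The diagonal G_ii (two cells of the same
        type) defaults to G_i — a bead seeded with two i cells grows iff i
        grows alone, to the same depletion ceiling.
    fraction_pair
        Matrix with f_i|ij in entry (i, j): the fraction of final cells of
        type i in an {i, j} bead.  Constrained so that
        f_i|ij + f_j|ij = 1 for i != j and f_i|ii = 1.
    reference_pair
        Unordered pair whose growth term is fixed to 1 (growth until medium
        depletion); all other G are relative to it.
    type_labels
        Optional cell-type names; defaults to T0, T1, ...
    """

    growth_single: np.ndarray
    growth_pair: np.ndarray
    fraction_pair: np.ndarray
    reference_pair: tuple[int, int] = (0, 1)
    type_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.growth_single = np.asarray(self.growth_single, dtype=float)
        self.growth_pair = np.asarray(self.growth_pair, dtype=float)
        self.fraction_pair = np.asarray(self.fraction_pair, dtype=float)
        n = self.growth_single.shape[0]
        if self.growth_pair.shape != (n, n) or self.fraction_pair.shape != (n, n):
            raise ValueError("growth_pair and fraction_pair must be (n_types, n_types)")
        if np.any(self.growth_single < 0) or np.any(self.growth_pair < 0):
            raise ValueError("growth terms must be nonnegative")
        if not np.allclose(self.growth_pair, self.growth_pair.T, atol=1e-12):
            raise ValueError("growth_pair must be symmetric (G_ij = G_ji)")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(
            (self.fraction_pair + self.fraction_pair.T)[off], 1.0, atol=1e-9
        ):
            raise ValueError("fraction_pair must satisfy f_i|ij + f_j|ij = 1")
        if not np.allclose(np.diag(self.fraction_pair), 1.0, atol=1e-9):
            raise ValueError("fraction_pair diagonal (f_i|ii) must be 1")
        i, j = self.reference_pair
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"reference_pair must be two distinct types, got {self.reference_pair}")
        self.reference_pair = (min(i, j), max(i, j))
        if self.type_labels is None:
            self.type_labels = [f"T{k}" for k in range(n)]

    @property
    def n_types(self) -> int:
        return self.growth_single.shape[0]

    def normalized(self) -> "InteractionParameters":
        """Rescale all growth terms so the reference pair's G equals 1."""
        i, j = self.reference_pair
        ref = self.growth_pair[i, j]
        if ref <= 0:
            raise ValueError("reference pair growth term must be positive")
        return InteractionParameters(
            growth_single=self.growth_single / ref,
            growth_pair=self.growth_pair / ref,
            fraction_pair=self.fraction_pair.copy(),
            reference_pair=self.reference_pair,
            type_labels=list(self.type_labels),
        )

    def to_dict(self) -> dict:
        """JSON-serialisable representation."""
        i, j = self.reference_pair
        return {
            "type_labels": list(self.type_labels),
            "growth_single": self.growth_single.tolist(),
            "growth_pair": self.growth_pair.tolist(),
            "fraction_pair": self.fraction_pair.tolist(),
            "reference_pair": [self.type_labels[i], self.type_labels[j]],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionParameters":
        labels = list(d["type_labels"])
        ref = tuple(labels.index(x) for x in d["reference_pair"])
        return cls(
            growth_single=np.asarray(d["growth_single"], float),
            growth_pair=np.asarray(d["growth_pair"], float),
            fraction_pair=np.asarray(d["fraction_pair"], float),
            reference_pair=ref,  # type: ignore[arg-type]
            type_labels=labels,
        )


@dataclass(frozen=True)
class FinalProportions:
    """Expected cell-type composition p(T) of the sorted, pooled population."""

    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")
        object.__setattr__(self, "proportions", p)


class NoGrowthError(ValueError):
    """No bead population grows under the supplied parameters (all masses 0)."""


def expected_final_proportions(
    comp: CompositionDistribution, params: InteractionParameters
) -> FinalProportions:
    """Expected post-sorting proportions p(T) from bead composition and
    interaction parameters.

    The unnormalised expected cell mass of type i pooled over beads is

        m_i = φ_i G_i + φ_ii G_ii + Σ_{j≠i} φ_ij G_ij f_i|ij

    and p(T) = m / Σ m.  Multiplying every growth term by a common positive
    constant leaves the result unchanged (only relative growth is
    identifiable).
    """
    if comp.n_types != params.n_types:
        raise ValueError(
            f"composition has {comp.n_types} types but parameters have {params.n_types}"
        )
    mass = _expected_mass(
        comp.singleton_fractions,
        comp.pair_fractions,
        params.growth_single,
        params.growth_pair,
        params.fraction_pair,
    )
    total = mass.sum()
    if total <= 0:
        raise NoGrowthError(
            "no bead population grows under these parameters (all masses zero)"
        )
    return FinalProportions(proportions=mass / total)


def _expected_mass(
    singletons: np.ndarray,
    pairs: np.ndarray,
    growth_single: np.ndarray,
    growth_pair: np.ndarray,
    fraction_pair: np.ndarray,
) -> np.ndarray:
    """Unnormalised per-type expected final cell mass.

    ``pairs`` holds the symmetric split of unordered pair fractions, so the
    unordered mass φ_ij (i≠j) is ``pairs[i,j] + pairs[j,i] = 2 pairs[i,j]``
    and type i receives φ_ij G_ij f_i|ij.  The diagonal contributes
    φ_ii G_ii with G_ii = G_i (f_i|ii = 1).
    """
    n = singletons.shape[0]
    gp = growth_pair.copy()
    np.fill_diagonal(gp, growth_single)  # same-type pairs grow like singles
    weights = np.full((n, n), 2.0)
    np.fill_diagonal(weights, 1.0)
    pair_mass = (weights * pairs * gp * fraction_pair).sum(axis=1)
    return singletons * growth_single + pair_mass


def parameter_count(n_types: int) -> dict[str, int]:
    """Bookkeeping for the identifiability of an N-member consortium.

    An N-type consortium has (N−1)N/2 pair growth terms and as many
    strain-fraction terms to fit, while each experiment contributes only
    N−1 independent proportion measurements — which is why multiple
    experiments with distinct inoculum compositions are needed as N grows.
    """
    if n_types < 2:
        raise ValueError(f"n_types must be >= 2, got {n_types}")
    n_pairs = (n_types - 1) * n_types // 2
    return {
        "n_growth_pair": n_pairs,
        "n_fraction_pair": n_pairs,
        "n_independent_measurements_per_experiment": n_types - 1,
    }
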