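"""Scoring of inference accuracy against simulated ground truth.

The inference error of a parameter is the absolute difference between its
maximum-posterior estimate and the value used in the simulation.  Errors
are collected in two families — growth terms G_ij and strain fractions
f_i|ij — with fraction errors only counted for pairs whose true growth term
exceeds 0.1 (fractions of essentially non-growing pairs are unidentifiable
and scientifically meaningless).  Conditions (consortium design, number of
experiments, sampling depth) are compared by two-sample t-tests on
replicate-level mean errors: one-sided for a directional increase,
two-sided for a difference in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth import InteractionParameters, _pairs
from .inference import PosteriorSummary, PriorSpec, GrowthPrior, SamplerConfig, fit_posterior
from .simulate import ConsortiumDesign, SimulationConfig, make_design, simulate_replicate

__all__ = [
    "FRACTION_ERROR_GATE",
    "inference_errors",
    "compare_conditions",
    "TTestResult",
    "run_validation_sweep",
]

# fractions are only scored for pairs whose true growth term exceeds this
FRACTION_ERROR_GATE = 0.1


def inference_errors(
    true_params: InteractionParameters, summary: PosteriorSummary
) -> dict[str, dict[tuple[int, int], float]]:
    """Absolute MAP-estimation errors per unordered pair.

    ``growth_errors`` covers every inferred pair growth term (the reference
    pair, fixed to 1 by construction in both truth and fit, is excluded);
    ``fraction_errors`` covers f_i|ij for pairs with true G above
    :data:`FRACTION_ERROR_GATE`.
    """
    n = true_params.n_types
    if len(summary.type_labels) != n:
        raise ValueError(
            f"summary has {len(summary.type_labels)} types, truth has {n}"
        )
    growth_errors: dict[tuple[int, int], float] = {}
    fraction_errors: dict[tuple[int, int], float] = {}
    for (i, j) in _pairs(n):
        g_true = float(true_params.growth_pair[i, j])
        if (i, j) != true_params.reference_pair:
            g_map = summary.growth_pair_estimate(i, j).map_estimate
            growth_errors[(i, j)] = abs(g_map - g_true)
        if g_true > FRACTION_ERROR_GATE:
            f_map = summary.fraction_estimate(i, j).map_estimate
            fraction_errors[(i, j)] = abs(f_map - float(true_params.fraction_pair[i, j]))
    return {"growth_errors": growth_errors, "fraction_errors": fraction_errors}


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test outcome for a condition comparison."""

    statistic: float
    pvalue: float
    sided: str
    n_a: int
    n_b: int


def compare_conditions(
    errors_a: np.ndarray, errors_b: np.ndarray, sided: str = "two"
) -> TTestResult:
    """Two-sample t-test on replicate-level error summaries.

    ``sided="one"`` tests the directional hypothesis that condition A's
    errors exceed condition B's (alternative mean(a) > mean(b)); swapping
    the arguments negates the statistic.  ``sided="two"`` tests for a
    difference in either direction.  Identical zero-variance samples are
    reported as no difference (t = 0, p = 1).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicate-level summaries per condition")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    scale = 1.0 + abs(a.mean()) + abs(b.mean())
    if (
        a.std() <= 1e-13 * scale
        and b.std() <= 1e-13 * scale
        and abs(a.mean() - b.mean()) <= 1e-13 * scale
    ):
        return TTestResult(0.0, 1.0, sided, a.size, b.size)
    alternative = "greater" if sided == "one" else "two-sided"
    res = stats.ttest_ind(a, b, alternative=alternative)
    return TTestResult(float(res.statistic), float(res.pvalue), sided, a.size, b.size)


def _validation_prior(design: ConsortiumDesign) -> PriorSpec:
    """Prior used in the validation workflow.

    Pair terms get the uninformative defaults, except that the growth
    support is capped at 10 relative units: growth terms are relative to
    growth until medium depletion, so the bead's carrying capacity makes
    values far above 1 physically impossible, and without the cap an
    underdetermined fit can park a growth term at an arbitrary point of a
    likelihood ridge.  Singleton growth is pinned to the design values (the
    monoculture growth of each member is established in a separate low-λ
    experiment before pair inference, so the validation treats it as
    known)."""
    overrides = {
        i: GrowthPrior(kind="fixed", value=float(g))
        for i, g in enumerate(design.true_params.growth_single)
    }
    return PriorSpec(
        growth_pair=GrowthPrior(kind="log_uniform", low=1e-6, high=10.0),
        growth_single_overrides=overrides,
    )


def run_validation_sweep(
    presets: list[str],
    n_types: int,
    n_experiments_grid: list[int],
    colonies_grid: list[int],
    n_replicates: int = 5,
    master_seed: int = 0,
    lambda_rate: float = 0.3,
    sampler_config: SamplerConfig | None = None,
) -> pd.DataFrame:
    """Simulate, infer, and score a grid of validation conditions.

    For every (preset, n_experiments, n_colonies, replicate) cell: simulate
    the replicate's datasets, fit the posterior, and record one row per
    scored parameter with its absolute inference error.  Matched seeds
    across conditions: the underlying random inoculum draws depend only on
    (master_seed, replicate, experiment), so colony-depth conditions see
    the same inoculum sequences.

    Returns a long-format table with columns
    (design, n_experiments, n_colonies, replicate, parameter, error_type,
    error) ready for box plots or t-tests.
    """
    base_cfg = sampler_config or SamplerConfig()
    rows = []
    for preset in presets:
        design = make_design(preset, n_types)
        prior = _validation_prior(design)
        for n_colonies in colonies_grid:
            for n_exp in n_experiments_grid:
                cfg = SimulationConfig(
                    lambda_rate=lambda_rate,
                    n_colonies=n_colonies,
                    n_experiments=n_exp,
                    n_replicates=n_replicates,
                    master_seed=master_seed,
                )
                for rep in range(n_replicates):
                    datasets = simulate_replicate(design, cfg, rep)
                    fit_seed = int(
                        np.random.SeedSequence(
                            entropy=master_seed, spawn_key=(rep, n_exp, n_colonies)
                        ).generate_state(1)[0]
                        >> np.uint32(1)
                    )
                    summary = fit_posterior(
                        datasets,
                        spec=prior,
                        reference_pair=design.true_params.reference_pair,
                        sampler_config=SamplerConfig(
                            seed=fit_seed,
                            n_walkers=base_cfg.n_walkers,
                            n_steps=base_cfg.n_steps,
                            n_burnin=base_cfg.n_burnin,
                            n_starts=base_cfg.n_starts,
                        ),
                    )
                    errs = inference_errors(design.true_params, summary)
                    labels = design.true_params.type_labels
                    for error_type, key in (
                        ("growth", "growth_errors"),
                        ("fraction", "fraction_errors"),
                    ):
                        for (i, j), e in errs[key].items():
                            rows.append(
                                {
                                    "design": preset,
                                    "n_experiments": n_exp,
                                    "n_colonies": n_colonies,
                                    "replicate": rep,
                                    "parameter": f"{labels[i]},{labels[j]}",
                                    "error_type": error_type,
                                    "error": e,
                                }
                            )
    return pd.DataFrame(rows)


def replicate_mean_errors(
    table: pd.DataFrame, design: str, error_type: str, **filters
) -> np.ndarray:
    """Replicate-level mean errors for one condition of a sweep table.

    Extra keyword filters (e.g. ``n_colonies=1000``) restrict the rows;
    replicate-level aggregation is the mean error over the condition's
    scored parameters, pooled over any remaining grid columns.
    """
    sel = (table["design"] == design) & (table["error_type"] == error_type)
    for col, val in filters.items():
        sel &= table[col] == val
    sub = table[sel]
    group_cols = ["replicate"] + [
        c for c in ("n_experiments", "n_colonies") if c not in filters
    ]
    return sub.groupby(group_cols)["error"].mean().to_numpy()
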