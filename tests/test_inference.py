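"""Likelihood, priors and posterior fitting."""

import itertools

import numpy as np
import pytest
from scipy import special

from beadweb import (
    ExperimentDataset,
    FractionPrior,
    GrowthPrior,
    InteractionParameters,
    OccupancySpec,
    PriorSpec,
    SamplerConfig,
    bead_composition_fractions,
    expected_final_proportions,
    fit_posterior,
    log_likelihood,
    log_prior,
)


def _pair_only_params(f_first: float) -> InteractionParameters:
    return InteractionParameters(
        growth_single=np.array([0.0, 0.0]),
        growth_pair=np.array([[0.0, 1.0], [1.0, 0.0]]),
        fraction_pair=np.array([[1.0, f_first], [1.0 - f_first, 1.0]]),
    )


def _dataset(d0, dT, lam=0.3, intended=None):
    d0 = np.asarray(d0)
    return ExperimentDataset(
        type_labels=tuple(f"T{i}" for i in range(len(d0))),
        lambda_rate=lam,
        counts_initial=d0,
        counts_final=np.asarray(dT),
        intended_proportions=intended,
    )


class TestLogLikelihood:
    def test_certain_outcome_contributes_zero(self):
        """All final counts on the only type that can end up in the pool."""
        params = InteractionParameters(
            growth_single=np.array([1.0, 0.0]),
            growth_pair=np.zeros((2, 2)),
            fraction_pair=np.array([[1.0, 0.5], [0.5, 1.0]]),
        )
        ds = _dataset([5, 5], [10, 0])
        p0 = np.array([0.5, 0.5])
        ll = log_likelihood([ds], params, [p0])
        # final term is log(1) = 0; what remains is the d(0) multinomial
        from scipy.stats import multinomial

        assert ll == pytest.approx(multinomial.logpmf([5, 5], 10, p0), abs=1e-9)

    def test_impossible_count_gives_minus_inf(self):
        params = InteractionParameters(
            growth_single=np.array([1.0, 0.0]),
            growth_pair=np.zeros((2, 2)),
            fraction_pair=np.array([[1.0, 0.5], [0.5, 1.0]]),
        )
        ds = _dataset([5, 5], [9, 1])  # a type-1 colony can never appear
        assert log_likelihood([ds], params, [np.array([0.5, 0.5])]) == -np.inf

    def test_exhaustive_enumeration_oracle(self):
        """On a tiny instance the log-likelihood equals the log of the exact
        probability found by enumerating every ordered outcome of both
        samplings."""
        params = _pair_only_params(0.3)
        p0 = np.array([0.6, 0.4])
        comp = bead_composition_fractions(OccupancySpec(0.3), p0)
        pT = expected_final_proportions(comp, params).proportions
        d0, dT = np.array([3, 1]), np.array([1, 3])

        def exact_prob(counts, probs):
            total = 0.0
            for seq in itertools.product(range(2), repeat=int(counts.sum())):
                c = np.bincount(seq, minlength=2)
                if np.array_equal(c, counts):
                    total += np.prod(probs[list(seq)])
            return total

        expected = np.log(exact_prob(d0, p0)) + np.log(exact_prob(dT, pT))
        ll = log_likelihood([_dataset(d0, dT)], params, [p0])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_symmetric_data_maximized_at_even_split(self):
        ds = _dataset([48, 48], [48, 48])
        p0 = np.array([0.5, 0.5])
        center = log_likelihood([ds], _pair_only_params(0.5), [p0])
        for f in (0.3, 0.45, 0.55, 0.7):
            assert log_likelihood([ds], _pair_only_params(f), [p0]) < center


class TestLogPrior:
    def test_log_uniform_growth_is_flat_in_log_scale(self):
        """Equal weight near 0.5 and near 2: density ratio equals G ratio."""
        spec = PriorSpec()
        base = InteractionParameters(
            np.array([1.0, 1.0, 1.0]),
            np.ones((3, 3)),
            np.full((3, 3), 0.5) + np.eye(3) * 0.5,
        )

        def with_g(g):
            gp = base.growth_pair.copy()
            gp[0, 2] = gp[2, 0] = g
            return InteractionParameters(base.growth_single, gp, base.fraction_pair)

        lp_half = log_prior(with_g(0.5), [], spec)
        lp_two = log_prior(with_g(2.0), [], spec)
        assert lp_half - lp_two == pytest.approx(np.log(2.0 / 0.5), abs=1e-12)

    def test_uniform_fraction_density_is_one(self):
        spec = PriorSpec(
            growth_single=GrowthPrior(kind="fixed", value=1.0),
            growth_pair=GrowthPrior(kind="fixed", value=1.0),
        )
        params = _pair_only_params(0.37)
        assert log_prior(params, [], spec) == pytest.approx(0.0, abs=1e-12)

    def test_dirichlet_fraction_prior_matches_formula(self):
        """Beta/Dirichlet prior log-density agrees with the Gamma-function
        formula evaluated directly."""
        mean, var = 0.3, 0.01
        spec = PriorSpec(
            growth_single=GrowthPrior(kind="fixed", value=1.0),
            growth_pair=GrowthPrior(kind="fixed", value=1.0),
            fraction_pair=FractionPrior(kind="dirichlet", mean=mean, variance=var),
        )
        f = 0.3
        nu = mean * (1 - mean) / var - 1
        a, b = mean * nu, (1 - mean) * nu
        expected = (
            special.gammaln(a + b)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1) * np.log(f)
            + (b - 1) * np.log(1 - f)
        )
        assert log_prior(_pair_only_params(f), [], spec) == pytest.approx(expected, abs=1e-10)

    def test_out_of_support_growth_is_minus_inf(self):
        spec = PriorSpec(growth_pair=GrowthPrior(kind="log_uniform", low=0.1, high=10))
        params = InteractionParameters(
            np.ones(3),
            np.ones((3, 3)) * 0.5 + np.eye(3) * 0.5,
            np.full((3, 3), 0.5) + np.eye(3) * 0.5,
        )
        gp = params.growth_pair.copy()
        gp[0, 2] = gp[2, 0] = 0.01  # below the support
        bad = InteractionParameters(params.growth_single, gp, params.fraction_pair)
        assert log_prior(bad, [], spec) == -np.inf

    def test_latent_initials_use_preparation_dirichlet(self):
        from scipy.stats import dirichlet

        spec = PriorSpec(
            growth_single=GrowthPrior(kind="fixed", value=1.0),
            growth_pair=GrowthPrior(kind="fixed", value=1.0),
            fraction_pair=FractionPrior(kind="fixed", value=0.5),
            preparation_precision=50.0,
        )
        intended = np.array([0.6, 0.4])
        p0 = np.array([0.55, 0.45])
        lp = log_prior(_pair_only_params(0.5), [p0], spec, intended_proportions=[intended])
        assert lp == pytest.approx(dirichlet.logpdf(p0, 50.0 * intended), abs=1e-10)


class TestFitPosterior:
    def test_prior_only_posterior_is_uniform_for_fractions(self):
        """With no data the fraction posterior is its uniform prior: the
        16th/84th percentiles sit at 0.16/0.84 up to MC error."""
        summary = fit_posterior(
            [],
            spec=PriorSpec(growth_single=GrowthPrior(kind="fixed", value=1.0)),
            type_labels=["A", "B"],
            sampler_config=SamplerConfig(seed=11, n_steps=4000, n_burnin=1000),
        )
        est = summary.fraction_estimate(0, 1)
        assert est.ppi_low == pytest.approx(0.16, abs=0.03)
        assert est.ppi_high == pytest.approx(0.84, abs=0.03)

    def test_skewed_final_counts_push_fraction_up(self):
        """Pair-only beads with d(T) favouring type 0 must put the MAP of
        f_0|01 above one half."""
        spec = PriorSpec(
            growth_single=GrowthPrior(kind="fixed", value=0.0),
        )
        ds = _dataset([48, 48], [80, 16], intended=np.array([0.5, 0.5]))
        summary = fit_posterior(
            [ds], spec=spec, sampler_config=SamplerConfig(seed=3, n_steps=600)
        )
        assert summary.fraction_estimate(0, 1).map_estimate > 0.5
        assert summary.fraction_estimate(1, 0).map_estimate < 0.5

    def test_reproducible_given_seed(self):
        spec = PriorSpec(growth_single=GrowthPrior(kind="fixed", value=0.0))
        ds = _dataset([48, 48], [60, 36], intended=np.array([0.5, 0.5]))
        cfg = SamplerConfig(seed=7, n_steps=400)
        a = fit_posterior([ds], spec=spec, sampler_config=cfg)
        b = fit_posterior([ds], spec=spec, sampler_config=cfg)
        for name in a.estimates:
            assert a.estimates[name] == b.estimates[name]
        assert a.diagnostics["acceptance_rate"] == b.diagnostics["acceptance_rate"]

    def test_interval_ordering_and_fraction_range(self):
        spec = PriorSpec(growth_single=GrowthPrior(kind="fixed", value=0.0))
        ds = _dataset([48, 48], [60, 36], intended=np.array([0.5, 0.5]))
        summary = fit_posterior(
            [ds], spec=spec, sampler_config=SamplerConfig(seed=5, n_steps=400)
        )
        for name, est in summary.estimates.items():
            assert est.ppi_low <= est.ppi_high
            if name.startswith("f["):
                assert 0.0 <= est.ppi_low <= 1.0
                assert 0.0 <= est.map_estimate <= 1.0

    def test_label_swap_symmetry_of_densities(self):
        """Swapping the two type labels everywhere mirrors the likelihood
        and the prior exactly."""
        params = _pair_only_params(0.3)
        swapped = _pair_only_params(0.7)
        ds = _dataset([30, 66], [20, 76])
        ds_swapped = _dataset([66, 30], [76, 20])
        p0 = np.array([0.3, 0.7])
        assert log_likelihood([ds], params, [p0]) == pytest.approx(
            log_likelihood([ds_swapped], swapped, [p0[::-1]]), abs=1e-10
        )
        spec = PriorSpec()
        assert log_prior(params, [p0], spec, [p0]) == pytest.approx(
            log_prior(swapped, [p0[::-1]], spec, [p0[::-1]]), abs=1e-10
        )

    def test_requires_labels_without_data(self):
        with pytest.raises(ValueError):
            fit_posterior([], spec=PriorSpec())


class TestDatasetValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _dataset([5, -1], [3, 3])

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDataset(("A",), 0.3, np.array([1, 2]), np.array([1, 2]))
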