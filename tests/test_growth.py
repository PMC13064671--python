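"""Pairwise growth model: final proportions, parameter counting, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beadweb import (
    InteractionParameters,
    OccupancySpec,
    bead_composition_fractions,
    expected_final_proportions,
    make_design,
    parameter_count,
)
from beadweb.growth import NoGrowthError


def _random_params(rng, n):
    g_single = rng.uniform(0, 1.5, n)
    gp = rng.uniform(0.05, 2.0, (n, n))
    gp = (gp + gp.T) / 2
    f = rng.uniform(0.05, 0.95, (n, n))
    frac = np.ones((n, n))
    iu = np.triu_indices(n, 1)
    frac[iu] = f[iu]
    frac[(iu[1], iu[0])] = 1 - f[iu]
    return InteractionParameters(g_single, gp, frac)


class TestExpectedFinalProportions:
    def test_symmetric_pair_splits_evenly(self, two_type_pair_only_params):
        comp = bead_composition_fractions(OccupancySpec(0.3), np.array([0.5, 0.5]))
        out = expected_final_proportions(comp, two_type_pair_only_params(0.5))
        np.testing.assert_allclose(out.proportions, [0.5, 0.5], atol=1e-12)

    def test_helper_strain_share_two_of_nine(self, two_type_pair_only_params):
        """A pool of pair beads growing to nine cells of which the helper
        contributes two ends with the helper at a 0.22 share."""
        comp = bead_composition_fractions(OccupancySpec(0.3), np.array([0.5, 0.5]))
        out = expected_final_proportions(comp, two_type_pair_only_params(2 / 9))
        assert round(float(out.proportions[0]), 2) == 0.22

    def test_no_growth_raises(self, two_type_pair_only_params):
        comp = bead_composition_fractions(OccupancySpec(0.3), np.array([1.0, 0.0]))
        # only type-0 beads exist and nothing containing type 0 grows
        with pytest.raises(NoGrowthError):
            expected_final_proportions(comp, two_type_pair_only_params(0.5))

    def test_degenerate_limit_single_grower(self):
        """If only singleton beads of one type grow, the pool is that type."""
        params = InteractionParameters(
            growth_single=np.array([1.0, 0.0, 0.0]),
            growth_pair=np.zeros((3, 3)),
            fraction_pair=np.full((3, 3), 0.5) + np.eye(3) * 0.5,
        )
        comp = bead_composition_fractions(
            OccupancySpec(0.3), np.array([0.2, 0.3, 0.5])
        )
        out = expected_final_proportions(comp, params)
        np.testing.assert_allclose(out.proportions, [1.0, 0.0, 0.0], atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 6), scale=st.floats(0.01, 50))
    def test_scale_invariance(self, seed, n, scale):
        """Multiplying all growth terms by a constant leaves p(T) unchanged:
        only relative growth is identifiable."""
        rng = np.random.default_rng(seed)
        params = _random_params(rng, n)
        comp = bead_composition_fractions(OccupancySpec(0.3), rng.dirichlet(np.ones(n)))
        base = expected_final_proportions(comp, params).proportions
        scaled = InteractionParameters(
            params.growth_single * scale,
            params.growth_pair * scale,
            params.fraction_pair,
        )
        out = expected_final_proportions(comp, scaled).proportions
        np.testing.assert_allclose(out, base, rtol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 5))
    def test_label_permutation_equivariance(self, seed, n):
        rng = np.random.default_rng(seed)
        params = _random_params(rng, n)
        p = rng.dirichlet(np.ones(n))
        perm = rng.permutation(n)
        comp = bead_composition_fractions(OccupancySpec(0.3), p)
        base = expected_final_proportions(comp, params).proportions
        permuted = InteractionParameters(
            params.growth_single[perm],
            params.growth_pair[np.ix_(perm, perm)],
            params.fraction_pair[np.ix_(perm, perm)],
        )
        comp_p = bead_composition_fractions(OccupancySpec(0.3), p[perm])
        out = expected_final_proportions(comp_p, permuted).proportions
        np.testing.assert_allclose(out, base[perm], rtol=1e-9)

    def test_monte_carlo_bead_oracle(self, rng):
        """p(T) matches a brute-force per-bead simulation: draw each bead's
        occupancy and content, grow it according to its G and f, and pool
        the final cells over one million beads."""
        design = make_design("one_isolated", 4)
        params = design.true_params
        p = rng.dirichlet(np.ones(4))
        comp = bead_composition_fractions(OccupancySpec(0.3), p)
        analytic = expected_final_proportions(comp, params).proportions

        n_beads, n_batches = 1_000_000, 20
        k = rng.poisson(0.3, n_beads)
        types = np.full((n_beads, 2), -1)
        m1, m2 = k == 1, k == 2
        types[m1, 0] = rng.choice(4, size=m1.sum(), p=p)
        types[m2] = rng.choice(4, size=(m2.sum(), 2), p=p)
        mass = np.zeros((n_batches, 4))
        batch = np.repeat(np.arange(n_batches), n_beads // n_batches)
        a, b = types[:, 0], types[:, 1]
        # singleton beads: G_i cells of type i
        np.add.at(mass, (batch[m1], a[m1]), params.growth_single[a[m1]])
        same = m2 & (a == b)
        np.add.at(mass, (batch[same], a[same]), params.growth_single[a[same]])
        mixed = m2 & (a != b)
        g = params.growth_pair[a[mixed], b[mixed]]
        np.add.at(mass, (batch[mixed], a[mixed]), g * params.fraction_pair[a[mixed], b[mixed]])
        np.add.at(mass, (batch[mixed], b[mixed]), g * params.fraction_pair[b[mixed], a[mixed]])
        props = mass / mass.sum(axis=1, keepdims=True)
        mc = props.mean(axis=0)
        se = props.std(axis=0, ddof=1) / np.sqrt(n_batches)
        assert np.all(np.abs(mc - analytic) < 3 * se + 1e-9)


class TestParameterCount:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (2, (1, 1, 1)),
            (3, (3, 3, 2)),  # pairs {12, 13, 23}, 2 free proportions
            (6, (15, 15, 5)),
        ],
    )
    def test_counts(self, n, expected):
        c = parameter_count(n)
        assert (
            c["n_growth_pair"],
            c["n_fraction_pair"],
            c["n_independent_measurements_per_experiment"],
        ) == expected

    def test_rejects_degenerate_consortium(self):
        with pytest.raises(ValueError):
            parameter_count(1)


class TestInteractionParameters:
    def test_asymmetric_growth_rejected(self):
        with pytest.raises(ValueError):
            InteractionParameters(
                np.ones(2), np.array([[1.0, 2.0], [3.0, 1.0]]), np.full((2, 2), 0.5) + np.eye(2) * 0.5
            )

    def test_fraction_complement_enforced(self):
        with pytest.raises(ValueError):
            InteractionParameters(
                np.ones(2), np.ones((2, 2)), np.array([[1.0, 0.3], [0.4, 1.0]])
            )

    def test_normalization_fixes_reference_to_one(self):
        params = InteractionParameters(
            np.ones(2) * 4.0,
            np.array([[4.0, 2.0], [2.0, 4.0]]),
            np.full((2, 2), 0.5) + np.eye(2) * 0.5,
        )
        norm = params.normalized()
        assert norm.growth_pair[0, 1] == 1.0
        assert norm.growth_single[0] == 2.0

    def test_dict_round_trip(self):
        params = _random_params(np.random.default_rng(3), 4)
        back = InteractionParameters.from_dict(params.to_dict())
        np.testing.assert_allclose(back.growth_pair, params.growth_pair)
        np.testing.assert_allclose(back.fraction_pair, params.fraction_pair)
        assert back.reference_pair == params.reference_pair
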