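"""Bayesian inference of pairwise interaction parameters from colony counts.

The observables of one microbead experiment are two small count vectors:
d(0), the cell-type counts among ~96 (or 1000) colonies sampled from the
inoculum, and d(T), the counts sampled from the pooled growth-sorted beads.
Both are modelled as multinomial draws — d(0) from the latent true inoculum
proportions p(0), and d(T) from the final proportions p(T) predicted by the
occupancy and growth models.  The latent p(0) of every experiment is
inferred jointly with the interaction parameters rather than plugged in,
so multinomial sampling noise at both time points propagates into the
reported intervals.

Priors follow the usual uninformative defaults: strain fractions f_i|ij are
uniform on the unit interval and growth terms are uniform in log scale,
P(G) ∝ 1/G, bounded to [1e-6, 1e3] relative units so the prior is proper.
When an earlier experiment supplies information, log-normal (for G) and
Beta/Dirichlet (for f) priors with stated mean and variance, or outright
fixed values, can be given per parameter.  True inoculum proportions get a
Dirichlet prior concentrated around the intended design proportions with a
preparation-precision parameter κ.

The posterior is explored with an affine-invariant ensemble sampler
(:mod:`emcee`) in unconstrained coordinates — log G, logit f, additive
log-ratio p(0) — and the maximum-posterior point is located by multi-start
quasi-Newton optimisation of the same transformed-space density.  Reported
per parameter: the MAP value and the central 68% posterior probability
interval (16th–84th percentile of the marginal posterior).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats

from .growth import InteractionParameters, _pairs
from .occupancy import OccupancySpec, bead_composition_fractions
from .growth import expected_final_proportions

__all__ = [
    "ExperimentDataset",
    "GrowthPrior",
    "FractionPrior",
    "PriorSpec",
    "SamplerConfig",
    "ParamEstimate",
    "PosteriorSummary",
    "log_likelihood",
    "log_prior",
    "fit_posterior",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class ExperimentDataset:
    """Count data of one microbead experiment.

    ``counts_initial`` (d(0)) and ``counts_final`` (d(T)) are colony counts
    per cell type at sampling depths n0 and nT; ``intended_proportions`` is
    the designed inoculum composition (centre of the preparation prior) and
    may be None when the design is unknown, in which case a flat Dirichlet
    prior is used for the latent p(0).
    """

    type_labels: tuple[str, ...]
    lambda_rate: float
    counts_initial: np.ndarray
    counts_final: np.ndarray
    intended_proportions: np.ndarray | None = None
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        d0 = np.asarray(self.counts_initial)
        dT = np.asarray(self.counts_final)
        n = len(self.type_labels)
        if d0.shape != (n,) or dT.shape != (n,):
            raise ValueError("count vectors must align with type_labels")
        for name, d in (("counts_initial", d0), ("counts_final", dT)):
            if np.any(d < 0) or not np.allclose(d, np.round(d)):
                raise ValueError(f"{name} must be nonnegative integers")
        if d0.sum() < 1 or dT.sum() < 1:
            raise ValueError("sampling depths n0 and nT must be >= 1")
        object.__setattr__(self, "counts_initial", d0.astype(np.int64))
        object.__setattr__(self, "counts_final", dT.astype(np.int64))
        if self.intended_proportions is not None:
            q = np.asarray(self.intended_proportions, dtype=float)
            if q.shape != (n,) or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
                raise ValueError("intended_proportions must be a probability vector")
            object.__setattr__(self, "intended_proportions", q)

    @property
    def n_types(self) -> int:
        return len(self.type_labels)

    @property
    def depth_initial(self) -> int:
        return int(self.counts_initial.sum())

    @property
    def depth_final(self) -> int:
        return int(self.counts_final.sum())


@dataclass(frozen=True)
class GrowthPrior:
    """Prior for one growth term G (singleton or pair).

    kind:
      - "log_uniform": P(G) ∝ 1/G on [low, high]  (default, uninformative)
      - "log_normal": mean/variance are of G itself; converted to the
        matching log-normal
      - "fixed": G pinned to ``value`` (not sampled)
    """

    kind: str = "log_uniform"
    low: float = 1e-6
    high: float = 1e3
    mean: float | None = None
    variance: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("log_uniform", "log_normal", "fixed"):
            raise ValueError(f"unknown growth prior kind {self.kind!r}")
        if self.kind == "log_uniform" and not (0 < self.low < self.high):
            raise ValueError("log_uniform prior needs 0 < low < high")
        if self.kind == "log_normal" and (
            self.mean is None or self.variance is None or self.mean <= 0 or self.variance <= 0
        ):
            raise ValueError("log_normal prior needs positive mean and variance")
        if self.kind == "fixed" and (self.value is None or self.value < 0):
            raise ValueError("fixed growth prior needs a nonnegative value")

    def lognormal_mu_sigma(self) -> tuple[float, float]:
        """(mu, sigma) of ln G matching the stated mean and variance of G."""
        s2 = math.log1p(self.variance / self.mean**2)
        return math.log(self.mean) - s2 / 2.0, math.sqrt(s2)


@dataclass(frozen=True)
class FractionPrior:
    """Prior for one strain-fraction term f_i|ij on (0, 1).

    kind "uniform" (default), "dirichlet" (two-component Dirichlet = Beta,
    parameterised by mean and variance of f), or "fixed".
    """

    kind: str = "uniform"
    mean: float | None = None
    variance: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "dirichlet", "fixed"):
            raise ValueError(f"unknown fraction prior kind {self.kind!r}")
        if self.kind == "dirichlet":
            m, v = self.mean, self.variance
            if m is None or v is None or not (0 < m < 1) or v <= 0:
                raise ValueError("dirichlet prior needs mean in (0,1) and variance > 0")
            if v >= m * (1 - m):
                raise ValueError("dirichlet prior variance must be < mean*(1-mean)")
        if self.kind == "fixed" and (self.value is None or not (0 <= self.value <= 1)):
            raise ValueError("fixed fraction prior needs a value in [0, 1]")

    def beta_shapes(self) -> tuple[float, float]:
        """(a, b) of the Beta prior matching the stated mean and variance."""
        nu = self.mean * (1 - self.mean) / self.variance - 1.0
        return self.mean * nu, (1 - self.mean) * nu


@dataclass(frozen=True)
class PriorSpec:
    """Prior configuration for a whole consortium.

    Defaults apply to every parameter of the given class; ``*_overrides``
    replace them per type index (singletons) or per unordered index pair.
    ``preparation_precision`` is the Dirichlet concentration κ of the true
    inoculum proportions around the intended design proportions.
    """

    growth_single: GrowthPrior = field(default_factory=GrowthPrior)
    growth_pair: GrowthPrior = field(default_factory=GrowthPrior)
    fraction_pair: FractionPrior = field(default_factory=FractionPrior)
    growth_single_overrides: dict = field(default_factory=dict)
    growth_pair_overrides: dict = field(default_factory=dict)
    fraction_pair_overrides: dict = field(default_factory=dict)
    preparation_precision: float = 100.0

    def __post_init__(self) -> None:
        if self.preparation_precision <= 0:
            raise ValueError("preparation_precision must be > 0")

    def single_prior(self, i: int) -> GrowthPrior:
        return self.growth_single_overrides.get(i, self.growth_single)

    def pair_prior(self, i: int, j: int) -> GrowthPrior:
        key = (min(i, j), max(i, j))
        return self.growth_pair_overrides.get(key, self.growth_pair)

    def fraction_prior(self, i: int, j: int) -> FractionPrior:
        """Prior on f_{min(i,j) | ij} (the fraction of the lower index)."""
        key = (min(i, j), max(i, j))
        return self.fraction_pair_overrides.get(key, self.fraction_pair)


@dataclass(frozen=True)
class SamplerConfig:
    """Settings of the MCMC sampler and the multi-start MAP optimiser."""

    seed: int = 0
    n_walkers: int | None = None  # default: max(2*ndim + 2, 24), even
    n_steps: int = 1000
    n_burnin: int | None = None  # default: n_steps // 2
    n_starts: int = 8
    rhat_threshold: float = 1.05


@dataclass(frozen=True)
class ParamEstimate:
    """MAP value and central 68% posterior probability interval."""

    map_estimate: float
    ppi_low: float
    ppi_high: float


# ---------------------------------------------------------------------------
# public densities (natural parameter space)


def _multinomial_logpmf(counts: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial log-pmf with the 0·log 0 = 0 convention; -inf when
    a positive count falls on a zero-probability type."""
    counts = np.asarray(counts, dtype=np.int64)
    probs = np.asarray(probs, dtype=float)
    if np.any((counts > 0) & (probs <= 0)):
        return -np.inf
    active = counts > 0
    n = counts.sum()
    return float(
        special.gammaln(n + 1)
        - special.gammaln(counts + 1).sum()
        + (counts[active] * np.log(probs[active])).sum()
    )


def log_likelihood(
    datasets: list[ExperimentDataset],
    params: InteractionParameters,
    latent_initials: list[np.ndarray],
) -> float:
    """Joint log-likelihood of all experiments.

    For each experiment, d(0) is multinomial given the latent true inoculum
    proportions p(0), and d(T) is multinomial given the final proportions
    predicted by the occupancy + growth forward model at that experiment's
    λ (bead occupancy truncated at two cells).
    """
    if len(latent_initials) != len(datasets):
        raise ValueError("need one latent initial-proportion vector per dataset")
    total = 0.0
    for ds, p0 in zip(datasets, latent_initials):
        p0 = np.asarray(p0, dtype=float)
        comp = bead_composition_fractions(OccupancySpec(ds.lambda_rate), p0)
        pT = expected_final_proportions(comp, params).proportions
        total += _multinomial_logpmf(ds.counts_initial, p0)
        total += _multinomial_logpmf(ds.counts_final, pT)
        if not np.isfinite(total):
            return -np.inf
    return total


def log_prior(
    params: InteractionParameters,
    latent_initials: list[np.ndarray],
    spec: PriorSpec,
    intended_proportions: list[np.ndarray | None] | None = None,
) -> float:
    """Joint log-prior density in natural parameter space.

    Sums the densities of every *free* parameter: singleton and pair growth
    terms (the reference pair, being fixed to 1, contributes nothing),
    strain fractions, and one Dirichlet(κ·intended) term per latent p(0)
    (flat Dirichlet when the intended proportions are unknown).
    """
    n = params.n_types
    total = 0.0
    for i in range(n):
        total += _growth_log_density(spec.single_prior(i), params.growth_single[i])
    for (i, j) in _pairs(n):
        if (i, j) == params.reference_pair:
            continue
        total += _growth_log_density(spec.pair_prior(i, j), params.growth_pair[i, j])
    for (i, j) in _pairs(n):
        total += _fraction_log_density(spec.fraction_prior(i, j), params.fraction_pair[i, j])
    intended = intended_proportions or [None] * len(latent_initials)
    for p0, q in zip(latent_initials, intended):
        p0 = np.asarray(p0, dtype=float)
        alpha = np.ones(n) if q is None else spec.preparation_precision * np.asarray(q, float)
        if np.any(p0 <= 0):
            return -np.inf
        total += float(stats.dirichlet.logpdf(p0 / p0.sum(), alpha))
    return total


def _growth_log_density(prior: GrowthPrior, g: float) -> float:
    if prior.kind == "fixed":
        return 0.0  # point mass, not a density over a free parameter
    if g <= 0:
        return -np.inf
    if prior.kind == "log_uniform":
        if not (prior.low <= g <= prior.high):
            return -np.inf
        return -math.log(g) - math.log(math.log(prior.high / prior.low))
    mu, sigma = prior.lognormal_mu_sigma()
    return float(stats.lognorm.logpdf(g, s=sigma, scale=math.exp(mu)))


def _fraction_log_density(prior: FractionPrior, f: float) -> float:
    if prior.kind == "fixed":
        return 0.0
    if not (0 < f < 1):
        return -np.inf
    if prior.kind == "uniform":
        return 0.0
    a, b = prior.beta_shapes()
    return float(stats.beta.logpdf(f, a, b))


# ---------------------------------------------------------------------------
# transformed-space machinery (sampling coordinates)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class _ParamSpace:
    """Index bookkeeping between the flat unconstrained sampling vector and
    the model parameters.

    Layout: [ln G_i for free singletons | ln G_ij for free pairs |
    logit f_i|ij for free fractions | alr p(0) per dataset].  The reference
    pair's growth term is always fixed to 1; parameters with "fixed" priors
    are excluded from the vector.
    """

    def __init__(
        self,
        n_types: int,
        datasets: list[ExperimentDataset],
        prior: PriorSpec,
        reference_pair: tuple[int, int],
        type_labels: list[str],
    ):
        self.n = n_types
        self.datasets = datasets
        self.n_datasets = len(datasets)
        self.prior = prior
        self.ref = (min(reference_pair), max(reference_pair))
        self.labels = type_labels
        self.pairs = _pairs(n_types)

        self.fixed_single = np.zeros(n_types)
        self.free_single: list[int] = []
        for i in range(n_types):
            p = prior.single_prior(i)
            if p.kind == "fixed":
                self.fixed_single[i] = p.value
            else:
                self.free_single.append(i)

        self.fixed_pair = np.zeros((n_types, n_types))
        self.free_pair: list[tuple[int, int]] = []
        for (i, j) in self.pairs:
            if (i, j) == self.ref:
                self.fixed_pair[i, j] = self.fixed_pair[j, i] = 1.0
                continue
            p = prior.pair_prior(i, j)
            if p.kind == "fixed":
                self.fixed_pair[i, j] = self.fixed_pair[j, i] = p.value
            else:
                self.free_pair.append((i, j))

        self.fixed_frac = np.zeros((n_types, n_types))
        np.fill_diagonal(self.fixed_frac, 1.0)
        self.free_frac: list[tuple[int, int]] = []
        for (i, j) in self.pairs:
            p = prior.fraction_prior(i, j)
            if p.kind == "fixed":
                self.fixed_frac[i, j] = p.value
                self.fixed_frac[j, i] = 1.0 - p.value
            else:
                self.free_frac.append((i, j))

        self.n_single = len(self.free_single)
        self.n_pair = len(self.free_pair)
        self.n_frac = len(self.free_frac)
        self.n_alr = (n_types - 1) * self.n_datasets
        self.ndim = self.n_single + self.n_pair + self.n_frac + self.n_alr
        if self.ndim == 0:
            raise ValueError("no free parameters to infer")
        self.sl_single = slice(0, self.n_single)
        self.sl_pair = slice(self.n_single, self.n_single + self.n_pair)
        o = self.n_single + self.n_pair
        self.sl_frac = slice(o, o + self.n_frac)
        self.sl_alr = slice(o + self.n_frac, self.ndim)

        # per-coordinate prior constants for the vectorized transformed density
        self._g_bounds = []  # (index, lo, hi) in log space, log-uniform coords
        self._g_norm = []  # (index, mu, sigma)
        coords = [(self.sl_single.start + k, prior.single_prior(i)) for k, i in enumerate(self.free_single)]
        coords += [(self.sl_pair.start + k, prior.pair_prior(i, j)) for k, (i, j) in enumerate(self.free_pair)]
        self._logu_const = 0.0
        for idx, p in coords:
            if p.kind == "log_uniform":
                self._g_bounds.append((idx, math.log(p.low), math.log(p.high)))
                self._logu_const -= math.log(math.log(p.high / p.low))
            else:
                mu, sigma = p.lognormal_mu_sigma()
                self._g_norm.append((idx, mu, sigma))
        self._f_ab = np.ones((self.n_frac, 2))
        self._f_const = 0.0
        for k, (i, j) in enumerate(self.free_frac):
            p = prior.fraction_prior(i, j)
            if p.kind == "dirichlet":
                a, b = p.beta_shapes()
                self._f_ab[k] = (a, b)
                self._f_const -= float(special.betaln(a, b))
        # Dirichlet concentrations of latent p(0), one row per dataset
        self._alpha = np.ones((self.n_datasets, n_types))
        self._alpha_const = 0.0
        for d, ds in enumerate(datasets):
            if ds.intended_proportions is not None:
                self._alpha[d] = prior.preparation_precision * ds.intended_proportions
            a = self._alpha[d]
            self._alpha_const += float(special.gammaln(a.sum()) - special.gammaln(a).sum())

    # -- transforms --------------------------------------------------------

    def unpack(self, X: np.ndarray):
        """Map (S, ndim) sampling vectors to natural-space parameter arrays:
        Gs (S,n), Gp (S,n,n), F (S,n,n), logP0 (S,D,n)."""
        S = X.shape[0]
        n = self.n
        Gs = np.broadcast_to(self.fixed_single, (S, n)).copy()
        if self.n_single:
            Gs[:, self.free_single] = np.exp(X[:, self.sl_single])
        Gp = np.broadcast_to(self.fixed_pair, (S, n, n)).copy()
        if self.n_pair:
            vals = np.exp(X[:, self.sl_pair])
            pi = [i for i, _ in self.free_pair]
            pj = [j for _, j in self.free_pair]
            Gp[:, pi, pj] = vals
            Gp[:, pj, pi] = vals
        F = np.broadcast_to(self.fixed_frac, (S, n, n)).copy()
        if self.n_frac:
            f = special.expit(X[:, self.sl_frac])
            fi = [i for i, _ in self.free_frac]
            fj = [j for _, j in self.free_frac]
            F[:, fi, fj] = f
            F[:, fj, fi] = 1.0 - f
        if self.n_datasets:
            Z = X[:, self.sl_alr].reshape(S, self.n_datasets, n - 1)
            Zaug = np.concatenate([Z, np.zeros((S, self.n_datasets, 1))], axis=-1)
            logP0 = Zaug - special.logsumexp(Zaug, axis=-1, keepdims=True)
        else:
            logP0 = np.zeros((S, 0, n))
        return Gs, Gp, F, logP0

    def pack(
        self,
        params: InteractionParameters,
        latent_initials: list[np.ndarray] | None = None,
    ) -> np.ndarray:
        """Inverse of :meth:`unpack` for a single parameter set."""
        x = np.empty(self.ndim)
        x[self.sl_single] = np.log(params.growth_single[self.free_single])
        x[self.sl_pair] = np.log([params.growth_pair[i, j] for i, j in self.free_pair])
        x[self.sl_frac] = special.logit(
            np.array([params.fraction_pair[i, j] for i, j in self.free_frac])
        )
        if self.n_datasets:
            z = np.concatenate(
                [np.log(p[:-1] / p[-1]) for p in latent_initials]
            )
            x[self.sl_alr] = z
        return x

    def params_at(self, x: np.ndarray) -> tuple[InteractionParameters, list[np.ndarray]]:
        Gs, Gp, F, logP0 = self.unpack(x[None, :])
        gp = Gp[0]
        np.fill_diagonal(gp, Gs[0])
        params = InteractionParameters(
            growth_single=Gs[0],
            growth_pair=gp,
            fraction_pair=F[0],
            reference_pair=self.ref,
            type_labels=list(self.labels),
        )
        latents = [np.exp(logP0[0, d]) for d in range(self.n_datasets)]
        return params, latents

    # -- names -------------------------------------------------------------

    def free_names(self) -> list[str]:
        L = self.labels
        names = [f"G[{L[i]}]" for i in self.free_single]
        names += [f"G[{L[i]},{L[j]}]" for i, j in self.free_pair]
        names += [f"f[{L[i]}|{L[i]},{L[j]}]" for i, j in self.free_frac]
        for d in range(self.n_datasets):
            names += [f"p0[{d}][{L[i]}]" for i in range(self.n - 1)]
        return names

    def natural_samples(self, flat_chain: np.ndarray) -> dict[str, np.ndarray]:
        """Marginal posterior samples per free parameter in natural units."""
        out: dict[str, np.ndarray] = {}
        names = self.free_names()
        X = flat_chain
        k = 0
        for _ in range(self.n_single + self.n_pair):
            out[names[k]] = np.exp(X[:, k])
            k += 1
        for _ in range(self.n_frac):
            out[names[k]] = special.expit(X[:, k])
            k += 1
        if self.n_datasets:
            S = X.shape[0]
            Z = X[:, self.sl_alr].reshape(S, self.n_datasets, self.n - 1)
            Zaug = np.concatenate([Z, np.zeros((S, self.n_datasets, 1))], axis=-1)
            P0 = np.exp(Zaug - special.logsumexp(Zaug, axis=-1, keepdims=True))
            for d in range(self.n_datasets):
                for i in range(self.n - 1):
                    out[names[k]] = P0[:, d, i]
                    k += 1
        return out

    # -- optimiser bounds and starting points ------------------------------

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = []
        margin = 1e-3
        lu = {idx: (lo, hi) for idx, lo, hi in self._g_bounds}
        for idx in range(self.n_single + self.n_pair):
            if idx in lu:
                lo, hi = lu[idx]
                b.append((lo + margin, hi - margin))
            else:
                b.append((-50.0, 50.0))
        b += [(-30.0, 30.0)] * self.n_frac
        b += [(-30.0, 30.0)] * self.n_alr
        return b

    def heuristic_start(self) -> np.ndarray:
        """Data-informed centre for the MAP starts: G_pair = 1, f = 1/2,
        G_single at the geometric centre of its prior, p(0) at smoothed
        observed initial frequencies."""
        x = np.zeros(self.ndim)
        for k, i in enumerate(self.free_single):
            p = self.prior.single_prior(i)
            if p.kind == "log_uniform":
                x[self.sl_single.start + k] = 0.5 * (math.log(p.low) + math.log(p.high))
            else:
                x[self.sl_single.start + k] = p.lognormal_mu_sigma()[0]
        for k, (i, j) in enumerate(self.free_pair):
            p = self.prior.pair_prior(i, j)
            if p.kind == "log_normal":
                x[self.sl_pair.start + k] = p.lognormal_mu_sigma()[0]
        z = []
        for ds in self.datasets:
            freq = (ds.counts_initial + 0.5) / (ds.counts_initial + 0.5).sum()
            z.append(np.log(freq[:-1] / freq[-1]))
        if z:
            x[self.sl_alr] = np.concatenate(z)
        return x


class _Posterior:
    """Vectorized log-posterior density in the transformed coordinates
    (prior × likelihood × change-of-variable Jacobians)."""

    def __init__(self, space: _ParamSpace):
        self.space = space
        D = space.n_datasets
        n = space.n
        self.d0 = np.zeros((D, n))
        self.dT = np.zeros((D, n))
        self.c1 = np.zeros(D)
        self.c2 = np.zeros(D)
        self.lgamma_const = 0.0
        for d, ds in enumerate(space.datasets):
            self.d0[d] = ds.counts_initial
            self.dT[d] = ds.counts_final
            self.c1[d] = stats.poisson.pmf(1, ds.lambda_rate)
            self.c2[d] = stats.poisson.pmf(2, ds.lambda_rate)
            self.lgamma_const += float(
                special.gammaln(ds.depth_initial + 1)
                - special.gammaln(ds.counts_initial + 1).sum()
                + special.gammaln(ds.depth_final + 1)
                - special.gammaln(ds.counts_final + 1).sum()
            )
        self.weights = np.full((n, n), 2.0)
        np.fill_diagonal(self.weights, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sp = self.space
        S = X.shape[0]
        lp = np.full(S, self._prior_const())

        # growth coordinates: log-uniform support / log-normal density
        for idx, lo, hi in sp._g_bounds:
            xi = X[:, idx]
            lp = np.where((xi < lo) | (xi > hi), -np.inf, lp)
        for idx, mu, sigma in sp._g_norm:
            xi = X[:, idx]
            lp += -0.5 * ((xi - mu) / sigma) ** 2 - math.log(sigma * math.sqrt(2 * math.pi))
        # fraction coordinates: Beta(a,b) density times the logit Jacobian
        if sp.n_frac:
            Y = X[:, sp.sl_frac]
            ab = sp._f_ab
            lp += -(ab[:, 0] * _softplus(-Y) + ab[:, 1] * _softplus(Y)).sum(axis=1)

        Gs, Gp, F, logP0 = sp.unpack(X)
        if sp.n_datasets:
            # Dirichlet(alpha) prior on p(0) including the alr Jacobian:
            # sum_i alpha_i * ln p_i  (Jacobian merges the usual alpha_i - 1)
            lp += (sp._alpha[None] * logP0).sum(axis=(1, 2))
            lp += self._log_likelihood(Gs, Gp, F, logP0)
        bad = ~np.isfinite(lp)
        lp[bad] = -np.inf
        return lp

    def _prior_const(self) -> float:
        sp = self.space
        return sp._logu_const + sp._f_const + sp._alpha_const + self.lgamma_const

    def _log_likelihood(self, Gs, Gp, F, logP0) -> np.ndarray:
        sp = self.space
        P0 = np.exp(logP0)  # (S, D, n)
        gp = Gp.copy()
        idx = np.arange(sp.n)
        gp[:, idx, idx] = Gs  # same-type pairs grow like singletons
        A = self.weights[None] * gp * F  # (S, n, n)
        pair_mass = np.einsum("sij,sdj->sdi", A, P0)
        m = self.c1[None, :, None] * P0 * Gs[:, None, :] + self.c2[None, :, None] * P0 * pair_mass
        tot = m.sum(axis=-1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            logpT = np.log(m) - np.log(tot)
        ll = (self.d0[None] * logP0).sum(axis=(1, 2))
        with np.errstate(invalid="ignore"):
            contrib = np.where(self.dT[None] > 0, self.dT[None] * logpT, 0.0)
        ll += contrib.sum(axis=(1, 2))
        ll[~np.isfinite(ll)] = -np.inf
        ll = np.where(tot[..., 0].min(axis=-1) <= 0, -np.inf, ll)
        return ll


# ---------------------------------------------------------------------------
# posterior summary


@dataclass
class PosteriorSummary:
    """Per-parameter MAP estimates with 68% posterior probability intervals,
    the MAP parameter set, and sampler diagnostics."""

    type_labels: list[str]
    estimates: dict[str, ParamEstimate]
    map_params: InteractionParameters
    map_initial_proportions: list[np.ndarray]
    diagnostics: dict
    samples: dict[str, np.ndarray] | None = None

    def growth_pair_estimate(self, i: int, j: int) -> ParamEstimate:
        i, j = min(i, j), max(i, j)
        L = self.type_labels
        name = f"G[{L[i]},{L[j]}]"
        if name in self.estimates:
            return self.estimates[name]
        g = float(self.map_params.growth_pair[i, j])  # fixed (e.g. reference)
        return ParamEstimate(g, g, g)

    def fraction_estimate(self, i: int, j: int) -> ParamEstimate:
        """Estimate of f_i|ij (fraction of type i in the {i, j} bead)."""
        a, b = min(i, j), max(i, j)
        L = self.type_labels
        name = f"f[{L[a]}|{L[a]},{L[b]}]"
        if name in self.estimates:
            est = self.estimates[name]
        else:
            f = float(self.map_params.fraction_pair[a, b])
            est = ParamEstimate(f, f, f)
        if i == a:
            return est
        return ParamEstimate(
            1.0 - est.map_estimate, 1.0 - est.ppi_high, 1.0 - est.ppi_low
        )

    def growth_single_estimate(self, i: int) -> ParamEstimate:
        name = f"G[{self.type_labels[i]}]"
        if name in self.estimates:
            return self.estimates[name]
        g = float(self.map_params.growth_single[i])
        return ParamEstimate(g, g, g)

    def to_frame(self):
        """Flat table (parameter, map, ppi_low, ppi_high)."""
        import pandas as pd

        rows = [
            {"parameter": k, "map": e.map_estimate, "ppi_low": e.ppi_low, "ppi_high": e.ppi_high}
            for k, e in self.estimates.items()
        ]
        return pd.DataFrame(rows, columns=["parameter", "map", "ppi_low", "ppi_high"])


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-R̂ per parameter for a (n_steps, n_walkers, ndim) chain."""
    nsteps = chain.shape[0] - (chain.shape[0] % 2)
    half = nsteps // 2
    if half < 2:
        return np.ones(chain.shape[-1])
    segs = np.concatenate([chain[:half], chain[half:nsteps]], axis=1)  # (half, 2W, d)
    m = segs.shape[1]
    means = segs.mean(axis=0)  # (2W, d)
    vars_ = segs.var(axis=0, ddof=1)
    W = vars_.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W <= 1e-300, 1.0, rhat)


def fit_posterior(
    datasets: list[ExperimentDataset],
    spec: PriorSpec | None = None,
    reference_pair: tuple[int, int] = (0, 1),
    sampler_config: SamplerConfig | None = None,
    type_labels: list[str] | None = None,
    keep_samples: bool = False,
) -> PosteriorSummary:
    """Fit the interaction-parameter posterior from one or more experiments.

    The reference pair's growth term is fixed to 1 and not sampled; all
    other free parameters (growth terms, strain fractions, and one latent
    inoculum-proportion vector per experiment) are sampled jointly with an
    emcee ensemble in unconstrained coordinates.  The MAP point is the best
    of ``n_starts`` seeded L-BFGS-B runs on the transformed-space
    log-posterior; intervals are the 16th–84th percentile of the marginal
    posterior samples.  Fully reproducible given ``sampler_config.seed``.

    With an empty dataset list the posterior equals the prior (useful for
    prior predictive checks); ``type_labels`` must then be given.
    """
    spec = spec or PriorSpec()
    cfg = sampler_config or SamplerConfig()
    if datasets:
        labels = list(datasets[0].type_labels)
        for ds in datasets:
            if list(ds.type_labels) != labels:
                raise ValueError("all datasets must share the same type labels")
    elif type_labels is not None:
        labels = list(type_labels)
    else:
        raise ValueError("type_labels is required when no datasets are given")
    n = len(labels)
    space = _ParamSpace(n, list(datasets), spec, reference_pair, labels)
    posterior = _Posterior(space)

    ss = np.random.SeedSequence(cfg.seed)
    s_opt, s_walk, s_mc = ss.generate_state(3) >> np.uint32(1)  # keep < 2**31

    x_map = _find_map(space, posterior, int(s_opt), cfg.n_starts)

    ndim = space.ndim
    n_walkers = cfg.n_walkers or max(2 * ndim + 2, 24)
    if n_walkers % 2:
        n_walkers += 1
    if n_walkers < 2 * ndim + 2:
        n_walkers = 2 * ndim + 2 + (ndim % 2) * 0
        n_walkers += n_walkers % 2
    rng = np.random.default_rng(int(s_walk))
    lob = np.array([b[0] for b in space.bounds()])
    upb = np.array([b[1] for b in space.bounds()])
    p0 = x_map[None, :] + 0.05 * rng.standard_normal((n_walkers, ndim))
    p0 = np.clip(p0, lob + 1e-6, upb - 1e-6)

    import emcee

    sampler = emcee.EnsembleSampler(n_walkers, ndim, posterior, vectorize=True)
    sampler.random_state = np.random.RandomState(int(s_mc)).get_state()
    sampler.run_mcmc(p0, cfg.n_steps, progress=False)
    burn = cfg.n_burnin if cfg.n_burnin is not None else cfg.n_steps // 2
    chain = sampler.get_chain(discard=burn)  # (steps, walkers, ndim)
    flat = chain.reshape(-1, ndim)

    warnings_list: list[str] = []
    rhat = _split_rhat(chain)
    max_rhat = float(np.nanmax(rhat)) if rhat.size else 1.0
    if max_rhat > cfg.rhat_threshold:
        warnings_list.append(
            f"non-converged chains: max split-Rhat {max_rhat:.3f} > {cfg.rhat_threshold}"
        )
    if np.any(flat.std(axis=0) < 1e-12):
        warnings_list.append("degenerate posterior: zero-variance parameter detected")
    for w in warnings_list:
        warnings.warn(w, RuntimeWarning, stacklevel=2)

    # prefer the best point ever seen by the sampler if it beats the optimiser
    lp_flat = sampler.get_log_prob(discard=burn).reshape(-1)
    best = int(np.argmax(lp_flat))
    if lp_flat[best] > posterior(x_map[None, :])[0]:
        x_map = flat[best]

    nat = space.natural_samples(flat)
    map_params, map_latents = space.params_at(x_map)
    map_nat = space.natural_samples(x_map[None, :])
    estimates = {
        name: ParamEstimate(
            float(map_nat[name][0]),
            float(np.percentile(s, 16)),
            float(np.percentile(s, 84)),
        )
        for name, s in nat.items()
    }
    diagnostics = {
        "n_samples": int(flat.shape[0]),
        "n_walkers": int(n_walkers),
        "n_steps": int(cfg.n_steps),
        "acceptance_rate": float(np.mean(sampler.acceptance_fraction)),
        "seed": int(cfg.seed),
        "max_rhat": max_rhat,
        "warnings": warnings_list,
    }
    return PosteriorSummary(
        type_labels=labels,
        estimates=estimates,
        map_params=map_params.normalized() if datasets else map_params,
        map_initial_proportions=map_latents,
        diagnostics=diagnostics,
        samples=nat if keep_samples else None,
    )


def _find_map(
    space: _ParamSpace, posterior: _Posterior, seed: int, n_starts: int
) -> np.ndarray:
    """Best of ``n_starts`` seeded L-BFGS-B maximisations of the transformed
    log-posterior; gradients by batched central differences (ties broken by
    first-found)."""
    rng = np.random.default_rng(seed)
    bounds = space.bounds()
    lob = np.array([b[0] for b in bounds])
    upb = np.array([b[1] for b in bounds])
    centre = np.clip(space.heuristic_start(), lob + 1e-6, upb - 1e-6)
    ndim = space.ndim
    scale = np.ones(ndim)
    scale[space.sl_single] = 2.0
    scale[space.sl_pair] = 2.0
    scale[space.sl_frac] = 1.0
    scale[space.sl_alr] = 0.3

    h = 1e-5
    eye = np.eye(ndim)

    def neg_logpost_and_grad(x: np.ndarray):
        X = np.vstack([x[None, :], x[None, :] + h * eye, x[None, :] - h * eye])
        lp = posterior(X)
        f = lp[0]
        if not np.isfinite(f):
            return 1e12, np.zeros(ndim)
        grad = (lp[1 : 1 + ndim] - lp[1 + ndim :]) / (2 * h)
        grad[~np.isfinite(grad)] = 0.0
        return -f, -grad

    best_x, best_f = None, np.inf
    for s in range(n_starts):
        x0 = centre if s == 0 else np.clip(
            centre + scale * rng.standard_normal(ndim), lob + 1e-6, upb - 1e-6
        )
        res = optimize.minimize(
            neg_logpost_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300},
        )
        if res.fun < best_f:  # strict: ties keep the first-found optimum
            best_f, best_x = res.fun, res.x
    return np.asarray(best_x)
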