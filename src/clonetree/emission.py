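"""Allele-count emission densities on a discrete cellular-prevalence grid.

The emission corrects the variant allele frequency for copy number and
tumour content by mixing three cell populations: normal cells,
cancer cells without the mutation, and cancer cells carrying the
mutation.  Uncertainty over the number of mutated copies in the mutant
population is handled with a parsimony prior placing equal weight on
1..major_cn variant alleles, marginalized inside the density.

All likelihoods are cached on a shared prevalence grid; the grid is
also the quadrature rule used for the tree marginalization and the
uniform outlier marginal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import betabinom, binom

from .io_formats import SnvTable, ValidationError

logger = logging.getLogger("clonetree")

NORMAL = "normal"
REFERENCE_CANCER = "reference-cancer"
VARIANT_CANCER = "variant-cancer"


@dataclass(frozen=True)
class PrevalenceGrid:
    """Equally spaced grid of G points spanning [0, 1] inclusive."""

    size: int = 101
    values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValidationError("grid size must be >= 2")
        object.__setattr__(self, "values", np.linspace(0.0, 1.0, self.size))

    @property
    def step(self) -> float:
        return 1.0 / (self.size - 1)

    def trapezoid_logweights(self) -> np.ndarray:
        w = np.zeros(self.size)
        w[0] = w[-1] = np.log(0.5)
        return w


@dataclass(frozen=True)
class GenotypeState:
    """One population configuration entering the VAF mixture."""

    population: str
    total_cn: int
    variant_alleles: int
    prior_weight: float

    def __post_init__(self) -> None:
        if self.variant_alleles > self.total_cn:
            raise ValidationError("variant_alleles exceeds total_cn")


def enumerate_genotype_states(
    major_cn: int, minor_cn: int, normal_cn: int = 2
) -> List[GenotypeState]:
    """Enumerate the population states for one copy-number configuration.

    Returns the normal and non-mutated cancer populations plus one
    variant-cancer state per candidate variant-allele count in
    ``1..major_cn``, each with equal prior weight (the major copy
    number parsimony prior).  Prior weights sum to one within the
    variant-cancer states; the normal and reference-cancer populations
    are deterministic components of the mixture and carry weight 1.
    """
    if minor_cn > major_cn:
        raise ValidationError("minor_cn > major_cn")
    if major_cn < 1:
        raise ValidationError("major_cn must be >= 1")
    total = major_cn + minor_cn
    states = [
        GenotypeState(NORMAL, normal_cn, 0, 1.0),
        GenotypeState(REFERENCE_CANCER, total, 0, 1.0),
    ]
    w = 1.0 / major_cn
    for m in range(1, major_cn + 1):
        states.append(GenotypeState(VARIANT_CANCER, total, m, w))
    return states


def _variant_states(states: Sequence[GenotypeState]) -> List[GenotypeState]:
    return [s for s in states if s.population == VARIANT_CANCER]


def _population(states: Sequence[GenotypeState], name: str) -> GenotypeState:
    for s in states:
        if s.population == name:
            return s
    raise ValidationError(f"state set lacks a {name!r} population")


def expected_vaf(
    cellular_prevalence: float,
    tumour_content: float,
    states: Sequence[GenotypeState],
    error_rate: float = 0.0,
) -> float:
    """Expected variant allele frequency under the population mixture.

    Allele counts from the three populations are pooled with weights
    ``(1-t)*c_N : t*(1-p)*c_R : t*p*c_V`` where ``p`` is the cellular
    prevalence, ``t`` the tumour content, and ``c`` the population
    copy numbers.  With several candidate variant-allele states the
    prior-weighted mean VAF is returned.
    """
    xis = _expected_vaf_per_state(
        np.asarray([cellular_prevalence], float), tumour_content, states, error_rate
    )
    weights = np.array([s.prior_weight for s in _variant_states(states)])
    return float(np.dot(weights / weights.sum(), xis[:, 0]))


def _expected_vaf_per_state(
    prevalences: np.ndarray,
    tumour_content: float,
    states: Sequence[GenotypeState],
    error_rate: float,
) -> np.ndarray:
    """VAF per variant state; shape (n_variant_states, len(prevalences))."""
    t = tumour_content
    eps = error_rate
    p = prevalences
    normal = _population(states, NORMAL)
    ref = _population(states, REFERENCE_CANCER)
    variants = _variant_states(states)
    if not variants:
        raise ValidationError("state set lacks a variant-cancer population")
    c_n, c_r = normal.total_cn, ref.total_cn
    out = np.empty((len(variants), p.shape[0]))
    for i, st in enumerate(variants):
        c_v = st.total_cn
        mu_v = np.clip(st.variant_alleles / c_v, eps, 1.0 - eps)
        num = (1 - t) * c_n * eps + t * (1 - p) * c_r * eps + t * p * c_v * mu_v
        den = (1 - t) * c_n + t * (1 - p) * c_r + t * p * c_v
        out[i] = num / den
    return out


@dataclass
class GridLikelihood:
    """Per-item, per-sample log emission density on the prevalence grid.

    ``loglik`` has shape (items, samples, grid).  Items are mutations,
    or pre-clustered blocks when rows have been summed over members.
    """

    loglik: np.ndarray
    grid: PrevalenceGrid
    density_kind: str = "binomial"
    precision: Optional[float] = None
    _outlier_cache: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def num_items(self) -> int:
        return self.loglik.shape[0]

    @property
    def num_samples(self) -> int:
        return self.loglik.shape[1]

    def outlier_marginals(self) -> np.ndarray:
        """Multi-sample uniform-prevalence marginal per item (summed over samples)."""
        if self._outlier_cache is None:
            vals = np.array(
                [
                    sum(
                        outlier_marginal_loglik(self.loglik[i, s], self.grid)
                        for s in range(self.num_samples)
                    )
                    for i in range(self.num_items)
                ]
            )
            self._outlier_cache = vals
        return self._outlier_cache

    def subset_sum(self, items: Sequence[int]) -> "GridLikelihood":
        """Collapse the given item rows into a single-item likelihood."""
        rows = self.loglik[list(items)].sum(axis=0, keepdims=True)
        return GridLikelihood(rows, self.grid, self.density_kind, self.precision)


def _density_loglik(
    alt: int, depth: int, xi: np.ndarray, density_kind: str, precision: Optional[float]
) -> np.ndarray:
    xi = np.clip(xi, 1e-12, 1.0 - 1e-12)
    if density_kind == "binomial":
        return binom.logpmf(alt, depth, xi)
    if density_kind == "beta-binomial":
        if precision is None or precision <= 0:
            raise ValidationError("beta-binomial density requires a positive precision")
        return betabinom.logpmf(alt, depth, xi * precision, (1.0 - xi) * precision)
    raise ValidationError(f"unknown density kind {density_kind!r}")


def loglik_at(
    obs,
    cellular_prevalence: float,
    density_kind: str = "binomial",
    precision: Optional[float] = None,
) -> float:
    """Log emission density of one observation at an arbitrary prevalence."""
    states = enumerate_genotype_states(obs.major_cn, obs.minor_cn, obs.normal_cn)
    if obs.depth == 0:
        return 0.0
    xis = _expected_vaf_per_state(
        np.asarray([cellular_prevalence], float),
        obs.tumour_content,
        states,
        obs.error_rate,
    )[:, 0]
    weights = np.array([s.prior_weight for s in _variant_states(states)])
    weights = weights / weights.sum()
    lls = _density_loglik(obs.alt_counts, obs.depth, xis, density_kind, precision)
    return float(logsumexp(lls, b=weights))


def compute_grid_likelihood(
    table: SnvTable,
    grid: Optional[PrevalenceGrid] = None,
    density_kind: str = "binomial",
    precision: Optional[float] = None,
) -> GridLikelihood:
    """Evaluate the emission log density of every (mutation, sample) row
    at every grid point, marginalizing the genotype-state mixture.

    Depth-zero rows contribute a flat zero log likelihood (no
    information) and trigger a warning.
    """
    grid = grid or PrevalenceGrid()
    N, S, G = table.num_mutations, table.num_samples, grid.size
    loglik = np.zeros((N, S, G))
    n_zero = 0
    for i, mut in enumerate(table.mutations):
        for j, samp in enumerate(table.samples):
            obs = table.get(mut, samp)
            if obs.depth == 0:
                n_zero += 1
                continue
            states = enumerate_genotype_states(
                obs.major_cn, obs.minor_cn, obs.normal_cn
            )
            xis = _expected_vaf_per_state(
                grid.values, obs.tumour_content, states, obs.error_rate
            )
            weights = np.array([s.prior_weight for s in _variant_states(states)])
            weights = weights / weights.sum()
            lls = _density_loglik(
                obs.alt_counts, obs.depth, xis, density_kind, precision
            )
            loglik[i, j] = logsumexp(lls, axis=0, b=weights[:, None])
    if n_zero:
        logger.warning("%d rows have zero depth; treated as uninformative", n_zero)
    return GridLikelihood(loglik, grid, density_kind, precision)


def outlier_marginal_loglik(loglik_row: np.ndarray, grid: PrevalenceGrid) -> float:
    """Trapezoidal log integral of the emission over a uniform prevalence.

    Returns ``log ∫_0^1 f(x | p) dp`` computed on the grid in log
    space.  A constant row integrates to itself; an all ``-inf`` row
    returns ``-inf``.
    """
    row = np.asarray(loglik_row, float)
    if row.shape[0] != grid.size:
        raise ValidationError("row length does not match grid size")
    if np.all(np.isneginf(row)):
        return -np.inf
    return float(
        logsumexp(row + grid.trapezoid_logweights()) - np.log(grid.size - 1)
    )
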