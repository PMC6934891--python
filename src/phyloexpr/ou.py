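"""Stationary Ornstein-Uhlenbeck model of expression evolution.

A gene's expression level x evolves under random mutational drift pulled
back toward an optimal level mu by stabilizing selection with Gaussian
fitness exp(-w (x - mu)^2 / 2).  Population-scaled, the process is an OU
diffusion with reversion rate beta = W sigma^2 and stationary variance 1/W,
where W = 2 Ne w is the strength of expression conservation.  Conditional
on a starting value x0, after time t

    E[x | x0]   = x0 e^{-beta t} + mu (1 - e^{-beta t})
    Var[x | x0] = (1 - e^{-2 beta t}) / W.

The *stationary* regime assumes the tissue originated long before the root
of the species tree, so the root value is already drawn from the stationary
law N(mu, 1/W).  Every node of the phylogeny then has mean mu and variance
1/W, and the covariance between two nodes separated by path time d is
e^{-beta d} / W -- for two extant species that diverged t ago, e^{-2 beta t}/W.
This covariance is root independent, which is what makes the distance and
ancestral-inference machinery tractable.

Among genes, the optimum mu may vary (variance V_mu) and so may W (gamma
distributed); the simulator reproduces both, which is how the pi parameter
(pi = V_mu / (1/W + V_mu)) arises in the data it generates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .expression import LOG2P1, ExpressionProfileSet, SampleLabel
from .timetree import TimeTree


@dataclass(frozen=True)
class OUParameters:
    """Parameters of the stationary OU expression model.

    Attributes
    ----------
    mu:
        Optimal expression level (analysis scale, typically log2).
    W:
        Strength of expression conservation, 2*Ne*w; stationary variance
        of a gene's expression is 1/W.
    beta:
        Rate of expression evolution per time unit (W * sigma^2);
        expression distance is 2*beta*t.
    V_mu:
        Among-gene variance of the optimum mu.
    """

    W: float
    beta: float
    mu: float = 0.0
    V_mu: float = 0.0

    def __post_init__(self):
        if not self.W > 0:
            raise ValidationError(f"W must be positive, got {self.W}")
        if self.beta < 0:
            raise ValidationError(f"beta must be non-negative, got {self.beta}")
        if self.V_mu < 0:
            raise ValidationError(f"V_mu must be non-negative, got {self.V_mu}")

    @property
    def stationary_variance(self) -> float:
        return 1.0 / self.W

    @property
    def total_variance(self) -> float:
        """V_T = 1/W + V_mu: stationary variance across genes and lineages."""
        return 1.0 / self.W + self.V_mu

    @property
    def pi(self) -> float:
        """Fraction of total variance due to among-gene optimum variation."""
        return self.V_mu / self.total_variance


def ou_conditional_moments(
    x0: float, params: OUParameters, t: float
) -> tuple[float, float]:
    """Mean and variance of expression after time t, starting from x0."""
    if t < 0:
        raise ValidationError(f"elapsed time must be non-negative, got {t}")
    decay = np.exp(-params.beta * t)
    mean = x0 * decay + params.mu * (1.0 - decay)
    variance = (1.0 - decay * decay) / params.W
    return float(mean), float(variance)


def stationary_pair_covariance(params: OUParameters, t: float) -> float:
    """Covariance between two lineages that diverged t time units ago."""
    if t < 0:
        raise ValidationError(f"divergence time must be non-negative, got {t}")
    return float(np.exp(-2.0 * params.beta * t) / params.W)


def stationary_cov_matrix(
    tree: TimeTree,
    params: OUParameters,
    labels: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Stationary covariance over named tree nodes (default: leaves).

    Entry (i, j) is e^{-beta * d_ij} / W with d_ij the path time between the
    nodes; the diagonal is the common stationary variance 1/W.  The result is
    symmetric positive semi-definite and independent of the root placement.
    """
    d, labels = tree.distance_matrix(labels)
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite path distance in tree")
    return np.exp(-params.beta * d) / params.W, labels


def correlation_matrix(tree: TimeTree, beta: float, labels=None):
    """W-free part of the stationary covariance: corr_ij = e^{-beta d_ij}."""
    d, labels = tree.distance_matrix(labels)
    return np.exp(-beta * d), labels


def simulate_expression(
    tree: TimeTree,
    params: OUParameters,
    n_genes: int,
    seed: int | np.random.Generator,
    w_distribution: tuple[float, float] | None = None,
    tissue: str = "tissue",
    replicate: str = "1",
    return_internal: bool = False,
):
    """Simulate a gene x species expression table on a time tree.

    Per gene: draw an optimum mu_g ~ N(mu, V_mu); draw W_g ~ Gamma(shape,
    rate) if ``w_distribution`` is given, else W_g = W; draw the root value
    from the stationary law N(mu_g, 1/W_g); then recurse down every edge
    sampling from the exact OU transition kernel (no time discretization).
    Deterministic given the seed.

    Values are generated on the analysis (log2-like, Gaussian) scale, so the
    returned profiles carry ``transform_tag = "log2p1"``.

    Returns the :class:`ExpressionProfileSet`; with ``return_internal=True``
    also a dict of internal-node label -> per-gene true ancestral values.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mu_g = params.mu + np.sqrt(params.V_mu) * rng.standard_normal(n_genes)
    if w_distribution is not None:
        shape, rate = w_distribution
        if not (shape > 0 and rate > 0):
            raise ValidationError(
                f"gamma(shape, rate) must be positive, got {w_distribution}"
            )
        w_g = rng.gamma(shape, 1.0 / rate, size=n_genes)
    else:
        w_g = np.full(n_genes, params.W)
    sd_stat = 1.0 / np.sqrt(w_g)

    dtree = tree.dendropy_tree
    values: dict = {}
    internal: dict[str, np.ndarray] = {}
    leaf_order: list[str] = []
    leaf_cols: list[np.ndarray] = []
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            x = mu_g + sd_stat * rng.standard_normal(n_genes)
        else:
            t = float(nd.edge.length)
            decay = np.exp(-params.beta * t)
            mean = values[nd.parent_node] * decay + mu_g * (1.0 - decay)
            sd = np.sqrt((1.0 - decay * decay) / w_g)
            x = mean + sd * rng.standard_normal(n_genes)
        values[nd] = x
        if nd.is_leaf():
            leaf_order.append(nd.taxon.label)
            leaf_cols.append(x)
        else:
            internal[nd.label] = x

    expr = ExpressionProfileSet(
        [f"g{i + 1}" for i in range(n_genes)],
        [SampleLabel(taxon, tissue, replicate) for taxon in leaf_order],
        np.column_stack(leaf_cols),
        transform_tag=LOG2P1,
    )
    if return_internal:
        return expr, internal
    return expr
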