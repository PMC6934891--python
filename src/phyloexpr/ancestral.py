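"""Empirical-Bayes ancestral transcriptome inference.

Under the stationary OU model, the ancestral value y at an internal node
and the tip profile x = (x1, ..., xn) of a gene are jointly multivariate
normal with common mean mu, common variance 1/W, and covariances
e^{-beta d}/W for path time d.  The posterior mean of y is therefore a
phylogeny-dependent linear combination of the tips,

    E[y | x] = b0 + sum_i b_i x_i,

with b = Cov(y, x) Cov(x, x)^{-1} and b0 = mu (1 - sum_i b_i), and a
posterior variance Var(y) - b Cov(x, y) that is the same for every gene
sharing (beta, W).  The Brownian-motion ancestral estimate is recovered in
the limit beta -> 0 with beta/W (the mutational variance rate) held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conservation import ConservationEstimates, conservation_analysis
from .distance import PiFit, estimate_pi
from .errors import TreeError, ValidationError
from .expression import ExpressionProfileSet
from .ou import OUParameters, stationary_cov_matrix
from .timetree import TimeTree


@dataclass(frozen=True)
class AncestralWeights:
    """Linear posterior-mean coefficients for one internal node.

    ``b`` is ordered like ``taxa``; ``b0 = mu (1 - sum b)`` so that a
    profile constant at the optimum is reconstructed as the optimum.  The
    coefficients depend only on the tree and (beta, W), not on expression.
    """

    node: str
    b0: float
    b: np.ndarray
    taxa: tuple[str, ...]
    posterior_variance: float


def ancestral_weights(
    tree: TimeTree, node: str, params: OUParameters
) -> AncestralWeights:
    """Posterior-mean coefficients (b0, b) for a named internal node."""
    if params.beta <= 0:
        raise ValidationError("ancestral weights require beta > 0")
    nd = tree.find_node(node)
    if nd.is_leaf():
        raise TreeError(f"{node!r} is a leaf; ancestral nodes are internal")
    taxa = tree.leaf_labels
    cov, _ = stationary_cov_matrix(tree, params, labels=taxa + [node])
    n = len(taxa)
    c_xx = cov[:n, :n]
    c_xy = cov[:n, n]
    try:
        b = np.linalg.solve(c_xx, c_xy)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular tip covariance (coincident zero-length tips?); "
            "jitter the offending branch lengths"
        ) from exc
    b0 = params.mu * (1.0 - float(b.sum()))
    post_var = float(cov[n, n] - b @ c_xy)
    return AncestralWeights(
        node=node,
        b0=b0,
        b=b,
        taxa=tuple(taxa),
        posterior_variance=max(post_var, 0.0),
    )


def infer_ancestral_expression(
    expr: ExpressionProfileSet,
    tree: TimeTree,
    node: str,
    params: OUParameters,
    tissue: str | None = None,
    mu_per_gene: np.ndarray | str = "tip_mean",
) -> tuple[np.ndarray, float, AncestralWeights]:
    """Per-gene posterior-mean ancestral expression at one internal node.

    ``mu_per_gene`` selects the empirical-Bayes plug-in for each gene's
    optimum: ``"tip_mean"`` (that gene's across-species mean, the default),
    ``"grand_mean"`` (one shared mean), or an explicit per-gene array.
    Since the weights satisfy b0 = mu (1 - sum b), the per-gene estimate is
    mu_g (1 - sum b) + sum_i b_i x_gi.

    Returns ``(estimates, posterior_variance, weights)``.
    """
    x, taxa = expr.taxon_matrix(tissue=tissue)
    tree_taxa = set(tree.leaf_labels)
    unmatched = [t for t in taxa if t not in tree_taxa]
    if unmatched or set(taxa) != tree_taxa:
        missing = sorted(tree_taxa - set(taxa))
        raise TreeError(
            f"taxon mismatch between profiles and tree; "
            f"profiles-only: {unmatched}, tree-only: {missing}"
        )
    w = ancestral_weights(tree, node, params)
    order = [taxa.index(t) for t in w.taxa]
    x = x[:, order]
    if isinstance(mu_per_gene, str):
        if mu_per_gene == "tip_mean":
            mu_g = x.mean(axis=1)
        elif mu_per_gene == "grand_mean":
            mu_g = np.full(x.shape[0], float(x.mean()))
        else:
            raise ValidationError(f"unknown mu_per_gene mode {mu_per_gene!r}")
    else:
        mu_g = np.asarray(mu_per_gene, dtype=float)
        if mu_g.shape != (x.shape[0],):
            raise ValidationError("mu_per_gene array must have one value per gene")
    shrink = 1.0 - float(w.b.sum())
    y_hat = mu_g * shrink + x @ w.b
    return y_hat, w.posterior_variance, w


@dataclass(frozen=True)
class NodeParamEstimates:
    """Plug-in OU parameter estimates for ancestral inference.

    ``beta`` and ``pi`` are shared per tissue (from the correlation-decay
    fit); ``mu`` is the per-gene across-species mean; ``W_post`` is the
    per-gene posterior conservation strength from the gamma empirical-Bayes
    fit.
    """

    genes: tuple[str, ...]
    beta: float
    pi: float
    mu: np.ndarray
    W_post: np.ndarray
    pi_fit: PiFit
    conservation: ConservationEstimates


def estimate_node_params(
    expr: ExpressionProfileSet,
    tree: TimeTree,
    tissue: str | None = None,
) -> NodeParamEstimates:
    """Estimate (mu_g, beta, W_g) from data, for plug-in ancestral inference.

    Requires the tissue in >= 3 species.  beta comes from the pi fit
    (correlation decay over species pairs); per-gene W from the conservation
    module's empirical-Bayes posterior; per-gene mu is the tip mean.
    """
    x, taxa = expr.taxon_matrix(tissue=tissue)
    if len(taxa) < 3:
        raise ValidationError(
            f"parameter estimation requires n >= 3 species; got {len(taxa)}"
        )
    fit = estimate_pi(expr, tree, tissue=tissue)
    cons = conservation_analysis(expr, tree, beta=fit.beta, tissue=tissue)
    return NodeParamEstimates(
        genes=tuple(expr.genes),
        beta=fit.beta,
        pi=fit.pi,
        mu=x.mean(axis=1),
        W_post=cons.W_post,
        pi_fit=fit,
        conservation=cons,
    )
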