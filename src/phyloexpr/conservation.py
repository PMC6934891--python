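"""Empirical-Bayes estimation of the strength of expression conservation W.

Gene k's tip profile x_k is modelled as multivariate normal with mean
mu_k * 1 and covariance corr / W_k, where corr_ij = e^{-beta d_ij} is the
W-free stationary-OU correlation over the species tree and W_k is the
gene-specific conservation strength.  W varies among genes with a
Gamma(alpha, lambda) prior.  Writing

    Q(x_k) = (x_k - mu_k 1)' corr^{-1} (x_k - mu_k 1)

(the phylogeny-corrected expression variability of the gene; it reduces to
the plain sum of squared deviations on a star tree), conjugacy gives the
posterior W | x_k ~ Gamma(alpha + m/2, lambda + Q/2) and the posterior mean

    E[W | x_k] = a / (c + Q(x_k)),     a = 2 alpha + m,  c = 2 lambda,

where m is the degrees of freedom of Q.  Because mu_k is plugged in as the
tip mean, one degree of freedom is consumed and m = n - 1 by default (the
``df_correction`` flag restores m = n).  The hyperparameters (alpha,
lambda) are fitted by maximizing the marginal likelihood of the observed
Q values, a closed-form compound (beta-prime-type) density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import gammaln

from .errors import ValidationError
from .expression import ExpressionProfileSet
from .timetree import TimeTree


def phylo_quadratic_Q(x_k, mu_k: float, corr: np.ndarray) -> float:
    """Phylogeny-corrected quadratic variability of one gene.

    Q = (x_k - mu_k 1)' corr^{-1} (x_k - mu_k 1); with corr = I (star tree,
    long branches) this is the plain sum of squared deviations from mu_k.
    """
    x_k = np.asarray(x_k, dtype=float)
    corr = np.asarray(corr, dtype=float)
    resid = x_k - mu_k
    try:
        cf = cho_factor(corr)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "species correlation matrix is not positive definite"
        ) from exc
    return float(resid @ cho_solve(cf, resid))


def _q_matrix(x: np.ndarray, mu: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Vectorized Q for a genes x species matrix."""
    resid = x - mu[:, None]
    cf = cho_factor(corr)
    return np.einsum("gi,gi->g", resid, cho_solve(cf, resid.T).T)


@dataclass(frozen=True)
class ConservationHyperFit:
    """Fitted gamma hyperparameters for among-gene variation in W.

    ``a = 2 alpha + m`` and ``c = 2 lambda`` are the constants of the
    posterior-mean formula W = a / (c + Q); ``m`` is the chi-square degrees
    of freedom used for Q.
    """

    alpha: float
    lam: float
    a: float
    c: float
    m: int
    n_species: int
    loglik: float
    converged: bool
    near_degenerate: bool


def _neg_loglik(theta: np.ndarray, q: np.ndarray, m: int) -> float:
    alpha, lam = np.exp(theta)
    half_m = 0.5 * m
    ll = (
        (half_m - 1.0) * np.log(q)
        + alpha * np.log(lam)
        + gammaln(half_m + alpha)
        - half_m * np.log(2.0)
        - gammaln(half_m)
        - gammaln(alpha)
        - (half_m + alpha) * np.log(lam + 0.5 * q)
    )
    return -float(ll.sum())


def fit_conservation_hyperparams(
    q_values,
    n: int,
    df_correction: bool = True,
) -> ConservationHyperFit:
    """Maximum marginal likelihood fit of the Gamma(alpha, lambda) prior.

    ``q_values`` are per-gene Q statistics over ``n`` species.  Marginally,
    Q * W ~ chi-square with m = n - 1 (or n) degrees of freedom and
    W ~ Gamma(alpha, lambda); integrating W out gives the closed-form
    density maximized here.  Starting values come from moment matching.
    A near-flat W distribution (constant W across genes) drives alpha to
    its upper bound; the fit is then flagged ``near_degenerate``.
    """
    q = np.asarray(q_values, dtype=float)
    q = q[np.isfinite(q)]
    if q.size < 50:
        raise ValidationError(
            f"hyperparameter fitting needs >= 50 genes with finite Q; got {q.size}"
        )
    if np.any(q < 0):
        raise ValidationError("Q values must be non-negative")
    q = np.maximum(q, 1e-12)
    m = n - 1 if df_correction else n
    if m < 1:
        raise ValidationError("need at least 2 species")

    # moment matching: E[Q] = m lam/(alpha-1), E[Q^2] = m(m+2) lam^2/((alpha-1)(alpha-2))
    mean_q = float(q.mean())
    ratio = float((q**2).mean()) / mean_q**2
    denom = ratio * m - m - 2.0
    starts = []
    if denom > 0:
        alpha0 = (2.0 * ratio * m - m - 2.0) / denom
        if alpha0 > 1.0:
            starts.append((alpha0, mean_q * (alpha0 - 1.0) / m))
    starts += [(2.0, mean_q / m), (1.0, 0.5 * mean_q / m), (10.0, 9.0 * mean_q / m)]

    bounds = [(np.log(1e-3), np.log(1e6)), (np.log(1e-8), np.log(1e8))]
    best = None
    for alpha0, lam0 in starts:
        res = minimize(
            _neg_loglik,
            x0=np.log([alpha0, max(lam0, 1e-8)]),
            args=(q, m),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha_hat, lam_hat = np.exp(best.x)
    near_degenerate = bool(alpha_hat >= 1e3)
    if near_degenerate:
        warnings.warn(
            "alpha estimate at/near its upper bound: among-gene variance of W "
            "is indistinguishable from zero (constant-W regime)",
            stacklevel=2,
        )
    if not best.success and not near_degenerate:
        raise ValidationError(
            "hyperparameter optimization did not converge "
            f"(moment-matched fallback: alpha={starts[0][0]:.3g}); {best.message}"
        )
    return ConservationHyperFit(
        alpha=float(alpha_hat),
        lam=float(lam_hat),
        a=float(2.0 * alpha_hat + m),
        c=float(2.0 * lam_hat),
        m=m,
        n_species=n,
        loglik=-float(best.fun),
        converged=bool(best.success),
        near_degenerate=near_degenerate,
    )


def posterior_W(q, a: float, c: float):
    """Posterior mean conservation strength W = a / (c + Q)."""
    if not (a > 0 and c > 0):
        raise ValidationError(f"a and c must be positive, got a={a}, c={c}")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValidationError("Q must be non-negative")
    out = a / (c + q)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ConservationEstimates:
    """Per-gene conservation estimates plus the fitted hyperparameters."""

    genes: tuple[str, ...]
    Q: np.ndarray
    W_post: np.ndarray
    hyper: ConservationHyperFit


def conservation_analysis(
    expr: ExpressionProfileSet,
    tree: TimeTree,
    beta: float,
    tissue: str | None = None,
    mu_method: str = "tip_mean",
    df_correction: bool = True,
) -> ConservationEstimates:
    """Full conservation pipeline for one tissue.

    Builds corr_ij = e^{-beta d_ij} from the tree, computes per-gene Q with
    the plug-in optimum (``tip_mean`` arithmetic mean, or ``gls`` the
    correlation-weighted generalized-least-squares mean), fits the gamma
    hyperparameters, and returns posterior W per gene.
    """
    x, taxa = expr.taxon_matrix(tissue=tissue)
    d, _ = tree.distance_matrix(taxa)
    corr = np.exp(-beta * d)
    if mu_method == "tip_mean":
        mu = x.mean(axis=1)
    elif mu_method == "gls":
        cf = cho_factor(corr)
        w = cho_solve(cf, np.ones(len(taxa)))
        mu = (x @ w) / w.sum()
    else:
        raise ValidationError(f"unknown mu_method {mu_method!r}")
    q = _q_matrix(x, mu, corr)
    hyper = fit_conservation_hyperparams(
        q, n=len(taxa), df_correction=df_correction
    )
    return ConservationEstimates(
        genes=tuple(expr.genes),
        Q=q,
        W_post=posterior_W(q, hyper.a, hyper.c),
        hyper=hyper,
    )
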