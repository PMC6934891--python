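"""Expression distances linear in evolutionary time.

Under the stationary OU model, the between-species correlation of a gene's
expression decays as r12 = pi + (1 - pi) e^{-2 beta t}, where pi = V_mu/V_T
is the fraction of stationary variance due to among-gene variation of the
optimum.  Three successively better estimators of the linear-to-time
distance D12 = 2 beta t follow:

* Pearson distance        P12 = 1 - r12
* constant-mu distance    D12 = -ln(r12)                (assumes pi = 0)
* variable-mu distance    D12 = -ln[(r12 - pi)/(1 - pi)]

The constant-mu estimator underestimates D12 when optima genuinely vary
among genes, which becomes non-trivial once D12 exceeds about 0.5.  pi can
itself be estimated whenever the same tissue is sampled in at least three
species, by fitting the correlation-decay curve over all species pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from scipy.optimize import least_squares

from .errors import UndefinedDistanceError, ValidationError
from .expression import ExpressionProfileSet
from .timetree import TimeTree

PEARSON = "pearson"
CONST_MU = "const_mu"
VAR_MU = "var_mu"
METHODS = (PEARSON, CONST_MU, VAR_MU)

#: CLI-facing aliases: Pearson / stationary-OU / variable-optimum-OU.
METHOD_ALIASES = {"pea": PEARSON, "sou": CONST_MU, "vou": VAR_MU}


# ---------------------------------------------------------------------- #
# per-pair estimators


def pearson_correlation(x1, x2, labels=("sample 1", "sample 2")) -> float:
    """Pearson correlation between two per-gene expression vectors."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValidationError("expression vectors must share one length")
    if x1.size < 3:
        raise ValidationError("need at least 3 genes for a correlation")
    for x, lab in ((x1, labels[0]), (x2, labels[1])):
        if np.std(x) == 0:
            raise ValidationError(f"zero expression variance in {lab}")
    r = float(np.corrcoef(x1, x2)[0, 1])
    return min(1.0, max(-1.0, r))


def pearson_distance(r12: float) -> float:
    """P12 = 1 - r12."""
    if not -1.0 <= r12 <= 1.0:
        raise ValidationError(f"correlation {r12} outside [-1, 1]")
    return 1.0 - r12


def constant_mu_distance(r12: float) -> float:
    """D12 = -ln(r12), the constant-optimum stationary-OU distance."""
    if not -1.0 <= r12 <= 1.0:
        raise ValidationError(f"correlation {r12} outside [-1, 1]")
    if r12 <= 0:
        raise UndefinedDistanceError(
            f"constant-mu distance undefined for r12 = {r12} <= 0 "
            "(distance saturates)"
        )
    return float(-np.log(r12))


def variable_mu_distance(r12: float, pi: float) -> float:
    """D12 = -ln[(r12 - pi)/(1 - pi)], correcting for optimum variation."""
    if not 0.0 <= pi < 1.0:
        raise ValidationError(f"pi must lie in [0, 1), got {pi}")
    if not -1.0 <= r12 <= 1.0:
        raise ValidationError(f"correlation {r12} outside [-1, 1]")
    if r12 <= pi:
        raise UndefinedDistanceError(
            f"variable-mu distance undefined for r12 = {r12} <= pi = {pi} "
            "(divergence beyond resolvable range)"
        )
    return float(-np.log((r12 - pi) / (1.0 - pi)))


def evolution_rate(d12: float, t: float) -> float:
    """Rate of transcriptome evolution beta = D12 / (2 t)."""
    if t <= 0:
        raise ValidationError(f"divergence time must be positive, got {t}")
    return d12 / (2.0 * t)


def _apply_method(r: float, method: str, pi: float | None) -> float:
    if method == PEARSON:
        return pearson_distance(r)
    if method == CONST_MU:
        return constant_mu_distance(r)
    if method == VAR_MU:
        if pi is None:
            raise ValidationError("variable-mu distance requires pi")
        return variable_mu_distance(r, pi)
    raise ValidationError(f"unknown method {method!r}; use one of {METHODS}")


# ---------------------------------------------------------------------- #
# pi estimation


@dataclass(frozen=True)
class PiFit:
    """Result of fitting r_ij = pi + (1 - pi) e^{-beta d_ij} over species
    pairs of one tissue.  ``d_ij`` is the tree path distance (= 2 t for an
    ultrametric tree)."""

    pi: float
    beta: float
    rss: float
    n_species: int
    n_pairs: int
    at_boundary: bool
    r_values: tuple = field(default=(), repr=False)
    d_values: tuple = field(default=(), repr=False)


def estimate_pi(
    expr: ExpressionProfileSet,
    tree: TimeTree,
    tissue: str | None = None,
) -> PiFit:
    """Estimate pi (and a shared beta) from one tissue over >= 3 species.

    All pairwise Pearson correlations are regressed on the decay curve
    pi + (1 - pi) e^{-beta d} by bounded nonlinear least squares, with
    0 <= pi < min(r_ij) and beta >= 0.
    """
    x, taxa = expr.taxon_matrix(tissue=tissue)
    n = len(taxa)
    if n < 3:
        raise ValidationError(
            f"pi estimation requires the tissue in n >= 3 species; got n = {n}"
        )
    d_full, _ = tree.distance_matrix(taxa)
    corr = np.corrcoef(x.T)
    iu = np.triu_indices(n, k=1)
    r = corr[iu]
    d = d_full[iu]
    r_min = float(r.min())
    if r_min <= 0:
        raise ValidationError(
            "non-positive between-species correlation; pi not estimable"
        )
    pi_hi = max(r_min - 1e-9, 1e-9)

    def resid(theta):
        pi_, beta_ = theta
        return pi_ + (1.0 - pi_) * np.exp(-beta_ * d) - r

    d_scale = float(np.mean(d)) or 1.0
    best = None
    for pi0, beta0 in [
        (min(0.5 * r_min, pi_hi), 1.0 / d_scale),
        (min(0.9 * r_min, pi_hi), 0.2 / d_scale),
        (1e-6, 2.0 / d_scale),
    ]:
        fit = least_squares(
            resid, x0=[pi0, beta0], bounds=([0.0, 0.0], [pi_hi, np.inf])
        )
        if best is None or fit.cost < best.cost:
            best = fit
    pi_hat, beta_hat = best.x
    at_boundary = bool(
        pi_hat <= 1e-8 or pi_hat >= pi_hi - 1e-8 or beta_hat <= 1e-12
    )
    if at_boundary:
        warnings.warn(
            "pi estimate at a bound of its feasible region; interpret with care",
            stacklevel=2,
        )
    return PiFit(
        pi=float(pi_hat),
        beta=float(beta_hat),
        rss=float(2.0 * best.cost),
        n_species=n,
        n_pairs=len(r),
        at_boundary=at_boundary,
        r_values=tuple(r),
        d_values=tuple(d),
    )


# ---------------------------------------------------------------------- #
# distance matrices


@dataclass
class ExpressionDistanceMatrix:
    """Symmetric matrix of pairwise expression distances.

    ``labels`` are (taxon, tissue) pairs; undefined entries (correlation at
    or below the estimator's domain boundary) are stored as NaN rather than
    clipped.  ``se`` holds gene-bootstrap standard errors when computed.
    """

    labels: list[tuple[str, str]]
    D: np.ndarray
    method: str
    se: np.ndarray | None = None
    pi_used: float | None = None

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != (n, n):
                raise ValidationError("se matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def has_undefined(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return bool(np.isnan(self.D[off]).any())

    def label_strings(self) -> list[str]:
        taxa = [t for t, _ in self.labels]
        if len(set(taxa)) == len(taxa):
            return taxa
        return [f"{t}.{ti}" for t, ti in self.labels]

    def value(self, a: str, b: str) -> float:
        names = self.label_strings()
        return float(self.D[names.index(a), names.index(b)])

    def to_phylip(self) -> str:
        """PHYLIP square distance-matrix format (NaN written as -1)."""
        names = self.label_strings()
        out = [f"{self.n}"]
        for i, name in enumerate(names):
            row = " ".join(
                f"{(-1.0 if np.isnan(v) else v):.6f}" for v in self.D[i]
            )
            out.append(f"{name:<12s}{row}")
        return "\n".join(out) + "\n"


def read_phylip(text: str) -> tuple[np.ndarray, list[str]]:
    """Parse a PHYLIP square distance matrix (entries of -1 become NaN)."""
    lines = [ln for ln in StringIO(text).read().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    names, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        names.append(parts[0])
        rows.append([float(v) for v in parts[1 : n + 1]])
    d = np.array(rows)
    d[d == -1.0] = np.nan
    return d, names


def _corr_matrix(values: np.ndarray) -> np.ndarray:
    stds = values.std(axis=0)
    if np.any(stds == 0):
        raise ValidationError(
            f"zero expression variance in sample column(s) "
            f"{list(np.flatnonzero(stds == 0))}"
        )
    return np.clip(np.corrcoef(values.T), -1.0, 1.0)


def _distances_from_corr(
    corr: np.ndarray, method: str, pi: float | None
) -> tuple[np.ndarray, int]:
    n = corr.shape[0]
    d = np.zeros((n, n))
    n_undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                v = _apply_method(corr[i, j], method, pi)
            except UndefinedDistanceError:
                v = np.nan
                n_undefined += 1
            d[i, j] = d[j, i] = v
    return d, n_undefined


def expression_distance_matrix(
    expr: ExpressionProfileSet,
    method: str = PEARSON,
    pi: float | None = None,
    tree: TimeTree | None = None,
    tissue: str | None = None,
) -> ExpressionDistanceMatrix:
    """All pairwise expression distances between (taxon, tissue) samples.

    Replicates are mean-collapsed first.  For the variable-mu method, pass
    ``pi`` directly or a ``tree`` (single-tissue data) from which it is
    estimated via :func:`estimate_pi`.  Undefined pairs are flagged NaN with
    a summary warning, never silently clipped.
    """
    method = METHOD_ALIASES.get(method, method)
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; use one of {METHODS}")
    sub = expr if tissue is None else expr.subset(tissue=tissue)
    sub = sub.collapse_replicates("mean")
    if method == VAR_MU and pi is None:
        if tree is None:
            raise ValidationError(
                "variable-mu distances need pi (given, or estimated from a tree)"
            )
        if len(sub.tissues) != 1:
            raise ValidationError(
                "automatic pi estimation is per tissue; subset to one tissue "
                "or pass pi explicitly"
            )
        pi = estimate_pi(sub, tree).pi
    corr = _corr_matrix(sub.values)
    d, n_undefined = _distances_from_corr(
        corr, method, pi if method == VAR_MU else None
    )
    if n_undefined:
        warnings.warn(
            f"{n_undefined} pairwise distance(s) undefined "
            f"(correlation outside the {method} domain); flagged as NaN",
            stacklevel=2,
        )
    return ExpressionDistanceMatrix(
        labels=[(s.taxon, s.tissue) for s in sub.samples],
        D=d,
        method=method,
        pi_used=pi if method == VAR_MU else None,
    )


def bootstrap_distance_se(
    expr: ExpressionProfileSet,
    method: str = PEARSON,
    pi: float | None = None,
    B: int = 100,
    seed: int | np.random.Generator = 0,
    tissue: str | None = None,
) -> np.ndarray:
    """Gene-bootstrap standard errors for every pairwise distance.

    Genes are resampled with replacement B times; the SE is the sample SD of
    each entry over replicates (NaN replicates excluded per entry).
    """
    if B < 2:
        raise ValidationError("need at least B = 2 bootstrap replicates")
    method = METHOD_ALIASES.get(method, method)
    sub = expr if tissue is None else expr.subset(tissue=tissue)
    sub = sub.collapse_replicates("mean")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    g = sub.n_genes
    reps = np.empty((B, sub.n_samples, sub.n_samples))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(B):
            idx = rng.integers(0, g, size=g)
            corr = _corr_matrix(sub.values[idx])
            reps[b], _ = _distances_from_corr(
                corr, method, pi if method == VAR_MU else None
            )
        se = np.nanstd(reps, axis=0, ddof=1)
    return se
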