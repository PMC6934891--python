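"""Expression-tree inference and phylogeny-dependent tests.

* Neighbor-Joining expression trees from a pairwise distance matrix, with
  gene-resampling bootstrap support on bipartitions.
* Ordinary-least-squares mapping of expression distances onto a fixed
  topology (non-negative branch lengths via NNLS on the path-incidence
  system).
* The relative expression rate test: Delta_AB = D_AC - D_BC with outgroup
  C; both lineages span the same time, so Delta != 0 indicates
  lineage-specific acceleration.  Significance comes from a paired gene
  bootstrap (genes resampled jointly so the two distances stay correlated)
  and a normal approximation.
* The two-species/two-tissue quartet decomposition into internal split
  lengths gamma_D (developmental similarity: same-tissue pairs) and
  gamma_E (evolutionary relatedness: same-species pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import nnls
from scipy.stats import norm
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj as skbio_nj

from .distance import (
    METHOD_ALIASES,
    METHODS,
    VAR_MU,
    ExpressionDistanceMatrix,
    _apply_method,
    _corr_matrix,
    _distances_from_corr,
)
from .errors import TreeError, ValidationError
from .expression import ExpressionProfileSet
from .timetree import TimeTree

# ---------------------------------------------------------------------- #
# neighbor joining


def nj_tree(dm: ExpressionDistanceMatrix) -> dendropy.Tree:
    """Neighbor-Joining (Saitou-Nei) tree from an expression distance matrix.

    On an additive (tree-metric) input, NJ recovers the generating topology
    and branch lengths exactly.  Flagged-undefined (NaN) entries are
    refused; clip or re-estimate upstream.  Negative branch lengths, which
    NJ can produce on noisy input, are kept and warned about.
    """
    if dm.n < 3:
        raise ValidationError("NJ needs at least 3 labels")
    if dm.has_undefined:
        raise ValidationError(
            "distance matrix contains undefined (NaN) entries; "
            "NJ refuses them (re-estimate or clip explicitly)"
        )
    names = dm.label_strings()
    sk_dm = SkbioDistanceMatrix(dm.D, ids=names)
    sk_tree = skbio_nj(sk_dm)
    newick = str(sk_tree).strip()
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    if any(
        e.length is not None and e.length < 0
        for e in tree.preorder_edge_iter()
    ):
        warnings.warn(
            "NJ produced negative branch length(s); kept unclamped",
            stacklevel=2,
        )
    return tree


def leaf_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as canonical frozensets of labels.

    Each split is represented by the side that does *not* contain the
    alphabetically smallest leaf label.
    """
    all_leaves = frozenset(
        lf.taxon.label for lf in tree.leaf_node_iter()
    )
    anchor = min(all_leaves)
    splits: set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(
            lf.taxon.label for lf in nd.leaf_iter()
        )
        side = all_leaves - below if anchor in below else below
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    newick_with_support: str
    supports: dict[frozenset, float]
    B: int


def bootstrap_support(
    expr: ExpressionProfileSet,
    method: str = "pearson",
    pi: float | None = None,
    B: int = 100,
    seed: int | np.random.Generator = 0,
    tissue: str | None = None,
) -> BootstrapResult:
    """NJ tree with gene-resampling bootstrap support per bipartition.

    Support is the percentage of B replicates (genes resampled with
    replacement, distances and NJ recomputed) whose tree contains each
    non-trivial bipartition of the point-estimate tree.  Replicates whose
    resampled matrix has undefined entries are skipped and the support
    denominator reduced accordingly.
    """
    if B < 1:
        raise ValidationError("need B >= 1 bootstrap replicates")
    method = METHOD_ALIASES.get(method, method)
    sub = expr if tissue is None else expr.subset(tissue=tissue)
    sub = sub.collapse_replicates("mean")
    labels = [(s.taxon, s.tissue) for s in sub.samples]
    point_D, _ = _distances_from_corr(
        _corr_matrix(sub.values), method, pi if method == VAR_MU else None
    )
    point_dm = ExpressionDistanceMatrix(labels, point_D, method, pi_used=pi)
    point_tree = nj_tree(point_dm)
    target_splits = leaf_splits(point_tree)

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = {s: 0 for s in target_splits}
    n_ok = 0
    g = sub.n_genes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(B):
            idx = rng.integers(0, g, size=g)
            rep_D, n_undef = _distances_from_corr(
                _corr_matrix(sub.values[idx]),
                method,
                pi if method == VAR_MU else None,
            )
            if n_undef:
                continue
            rep_tree = nj_tree(
                ExpressionDistanceMatrix(labels, rep_D, method)
            )
            rep_splits = leaf_splits(rep_tree)
            n_ok += 1
            for s in target_splits:
                if s in rep_splits:
                    counts[s] += 1
    if n_ok == 0:
        raise ValidationError("all bootstrap replicates had undefined distances")
    supports = {s: 100.0 * c / n_ok for s, c in counts.items()}

    # annotate internal nodes of the point tree with their support
    all_leaves = frozenset(lf.taxon.label for lf in point_tree.leaf_node_iter())
    anchor = min(all_leaves)
    for nd in point_tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = all_leaves - below if anchor in below else below
        if side in supports:
            nd.label = f"{supports[side]:.0f}"
    newick = point_tree.as_string(schema="newick", suppress_rooting=True).strip()
    return BootstrapResult(
        tree=point_tree, newick_with_support=newick, supports=supports, B=n_ok
    )


# ---------------------------------------------------------------------- #
# least-squares branch lengths on a fixed topology


@dataclass
class LSBranchFit:
    tree: dendropy.Tree
    newick: str
    edge_lengths: dict[frozenset, float]
    residual: float


def ls_branch_lengths(
    topology: TimeTree | dendropy.Tree,
    dm: ExpressionDistanceMatrix,
) -> LSBranchFit:
    """Map expression distances onto a fixed topology by least squares.

    Branch lengths minimize sum_{i<j} (D_ij - path_ij)^2 subject to
    non-negativity (NNLS on the path-incidence system); the summed squared
    residual is reported.  The topology is derooted first, since only the
    unrooted shape is identifiable from pairwise distances.
    """
    dtree = (
        topology.dendropy_tree if isinstance(topology, TimeTree) else topology
    )
    work = dendropy.Tree(dtree)
    work.deroot()
    leaves = [lf.taxon.label for lf in work.leaf_node_iter()]
    names = dm.label_strings()
    if set(leaves) != set(names):
        raise TreeError(
            f"topology leaves {sorted(leaves)} do not match distance labels "
            f"{sorted(names)}"
        )
    if dm.has_undefined:
        raise ValidationError("distance matrix contains undefined entries")

    edges = [
        nd.edge
        for nd in work.preorder_node_iter()
        if nd.parent_node is not None
    ]
    below: list[frozenset] = []
    for e in edges:
        below.append(
            frozenset(lf.taxon.label for lf in e.head_node.leaf_iter())
        )
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    A = np.zeros((len(pairs), len(edges)))
    for p, (i, j) in enumerate(pairs):
        for e_idx, bl in enumerate(below):
            if (names[i] in bl) != (names[j] in bl):
                A[p, e_idx] = 1.0
    if np.linalg.matrix_rank(A) < len(edges):
        raise ValidationError(
            "branch lengths are not identifiable on this topology "
            "(rank-deficient path-incidence system)"
        )
    d_vec = np.array([dm.D[i, j] for i, j in pairs])
    lengths, rnorm = nnls(A, d_vec)
    for e, ln in zip(edges, lengths):
        e.length = float(ln)
    newick = work.as_string(schema="newick", suppress_rooting=True).strip()
    return LSBranchFit(
        tree=work,
        newick=newick,
        edge_lengths={bl: float(ln) for bl, ln in zip(below, lengths)},
        residual=float(rnorm**2),
    )


# ---------------------------------------------------------------------- #
# relative expression rate test


@dataclass(frozen=True)
class RateTestResult:
    """Relative rate test of lineages A vs B with outgroup C."""

    lineages: tuple[str, str, str]
    d_ac: float
    d_bc: float
    delta: float
    se: float
    z: float
    p: float
    n_boot: int
    method: str
    pi_used: float | None


def _pair_distance(x1, x2, method, pi):
    r = float(np.corrcoef(x1, x2)[0, 1])
    return _apply_method(min(1.0, max(-1.0, r)), method, pi)


def _bootstrap_corr(u, v, idx):
    """Row-wise Pearson correlation of u[idx] vs v[idx] for an index matrix."""
    ub = u[idx]
    vb = v[idx]
    ub = ub - ub.mean(axis=1, keepdims=True)
    vb = vb - vb.mean(axis=1, keepdims=True)
    num = (ub * vb).sum(axis=1)
    den = np.sqrt((ub**2).sum(axis=1) * (vb**2).sum(axis=1))
    return np.clip(num / den, -1.0, 1.0)


def relative_rate_test(
    expr: ExpressionProfileSet,
    a: str,
    b: str,
    outgroup: str,
    method: str = "pearson",
    pi: float | None = None,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    tissue: str | None = None,
) -> RateTestResult:
    """Test Delta_AB = D_AC - D_BC = 0 (equal expression rates in A and B).

    Genes are bootstrapped jointly, so the replicate D_AC and D_BC stay
    correlated; z = Delta/SE(Delta) is referred to a standard normal
    (two-sided).
    """
    method = METHOD_ALIASES.get(method, method)
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    x, taxa = expr.taxon_matrix(tissue=tissue, taxa=[a, b, outgroup])
    xa, xb, xc = x.T
    pi_arg = pi if method == VAR_MU else None
    d_ac = _pair_distance(xa, xc, method, pi_arg)
    d_bc = _pair_distance(xb, xc, method, pi_arg)
    delta = d_ac - d_bc

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    g = x.shape[0]
    idx = rng.integers(0, g, size=(n_boot, g))
    r_ac = _bootstrap_corr(xa, xc, idx)
    r_bc = _bootstrap_corr(xb, xc, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "pearson":
            deltas = (1.0 - r_ac) - (1.0 - r_bc)
        elif method == "const_mu":
            deltas = -np.log(r_ac) + np.log(r_bc)
        else:
            deltas = -np.log(r_ac - pi_arg) + np.log(r_bc - pi_arg)
    deltas = deltas[np.isfinite(deltas)]
    if deltas.size < 2:
        raise ValidationError(
            "bootstrap distances undefined in (almost) all replicates"
        )
    se = float(np.std(deltas, ddof=1))
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = delta / se
        p = float(2.0 * norm.sf(abs(z)))
    return RateTestResult(
        lineages=(a, b, outgroup),
        d_ac=float(d_ac),
        d_bc=float(d_bc),
        delta=float(delta),
        se=se,
        z=float(z),
        p=p,
        n_boot=int(deltas.size),
        method=method,
        pi_used=pi_arg,
    )


# ---------------------------------------------------------------------- #
# two-species / two-tissue quartet


@dataclass(frozen=True)
class QuartetNetwork:
    """Split decomposition of a two-species x two-tissue quartet.

    ``gamma_D`` is the internal split length separating the tissues
    (developmental similarity); ``gamma_E`` the one separating the species
    (evolutionary relatedness).  Pendant edges are keyed by quartet label.
    Negative estimates are reported unclipped and flagged.
    """

    gamma_D: float
    gamma_E: float
    pendant: dict[str, float]
    residual: float
    negative_flag: bool


def quartet_gamma_from_distances(
    d_a1a2: float,
    d_b1b2: float,
    d_a1b1: float,
    d_a2b2: float,
    d_a1b2: float,
    d_a2b1: float,
) -> QuartetNetwork:
    """gamma decomposition from the six pairwise quartet distances.

    Labels: A/B are species, 1/2 tissues; e.g. ``d_a1b2`` is the distance
    between species A tissue 1 and species B tissue 2.  The system of six
    split-path equations in six unknowns (four pendants + two internal
    splits) is exactly determined:

        gamma_E = [d(A1,B2) + d(A2,B1) - d(A1,A2) - d(B1,B2)] / 2
        gamma_D = [d(A1,B2) + d(A2,B1) - d(A1,B1) - d(A2,B2)] / 2
    """
    d = np.array([d_a1a2, d_b1b2, d_a1b1, d_a2b2, d_a1b2, d_a2b1], float)
    if not np.all(np.isfinite(d)):
        raise ValidationError("all six quartet distances must be defined")
    gamma_e = 0.5 * (d_a1b2 + d_a2b1 - d_a1a2 - d_b1b2)
    gamma_d = 0.5 * (d_a1b2 + d_a2b1 - d_a1b1 - d_a2b2)
    # unknowns: [p_A1, p_A2, p_B1, p_B2, gamma_D, gamma_E]
    system = np.array(
        [
            [1, 1, 0, 0, 1, 0],  # d(A1,A2)
            [0, 0, 1, 1, 1, 0],  # d(B1,B2)
            [1, 0, 1, 0, 0, 1],  # d(A1,B1)
            [0, 1, 0, 1, 0, 1],  # d(A2,B2)
            [1, 0, 0, 1, 1, 1],  # d(A1,B2)
            [0, 1, 1, 0, 1, 1],  # d(A2,B1)
        ],
        dtype=float,
    )
    sol = np.linalg.solve(system, d)
    residual = float(((system @ sol - d) ** 2).sum())
    pendant = dict(zip(("A1", "A2", "B1", "B2"), map(float, sol[:4])))
    negative = bool(min(gamma_d, gamma_e, *pendant.values()) < 0)
    if negative:
        warnings.warn(
            "negative quartet split/pendant length estimated; "
            "reported unclipped",
            stacklevel=2,
        )
    return QuartetNetwork(
        gamma_D=float(gamma_d),
        gamma_E=float(gamma_e),
        pendant=pendant,
        residual=residual,
        negative_flag=negative,
    )


def quartet_gamma(
    dm: ExpressionDistanceMatrix,
    species_a: str,
    species_b: str,
    tissue_1: str,
    tissue_2: str,
) -> QuartetNetwork:
    """gamma decomposition reading the six distances from a matrix whose
    labels cover species {A, B} x tissues {1, 2}."""
    index = {lab: k for k, lab in enumerate(dm.labels)}

    def at(sp, ti):
        key = (sp, ti)
        if key not in index:
            raise ValidationError(f"quartet member {key} absent from matrix")
        return index[key]

    a1, a2 = at(species_a, tissue_1), at(species_a, tissue_2)
    b1, b2 = at(species_b, tissue_1), at(species_b, tissue_2)
    D = dm.D
    return quartet_gamma_from_distances(
        d_a1a2=D[a1, a2],
        d_b1b2=D[b1, b2],
        d_a1b1=D[a1, b1],
        d_a2b2=D[a2, b2],
        d_a1b2=D[a1, b2],
        d_a2b1=D[a2, b1],
    )
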