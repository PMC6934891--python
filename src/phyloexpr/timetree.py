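"""Rooted time trees (branch lengths in time units) backed by dendropy.

:class:`TimeTree` wraps a :class:`dendropy.Tree` and exposes the pieces the
OU machinery needs: leaf labels, path distances between *any* two nodes
(leaf or internal), ultrametricity checking, and Newick round-tripping.
Internal nodes without labels are assigned stable preorder names
``N1, N2, ...`` so they can be addressed from the command line.
"""

from __future__ import annotations

import math
from typing import Sequence

import dendropy
import numpy as np

from .errors import TreeError


class TimeTree:
    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_nodes()
        self._validate()
        self._depths = self._compute_depths()

    # -- construction ---------------------------------------------------- #

    @classmethod
    def from_newick(cls, newick_text: str) -> "TimeTree":
        try:
            tree = dendropy.Tree.get(
                data=newick_text,
                schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "TimeTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- bookkeeping ------------------------------------------------------ #

    def _label_nodes(self) -> None:
        used = {
            nd.taxon.label if nd.taxon else nd.label
            for nd in self._tree
            if (nd.taxon and nd.taxon.label) or nd.label
        }
        counter = 0
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if not nd.label:
                counter += 1
                while f"N{counter}" in used:
                    counter += 1
                nd.label = f"N{counter}"
                used.add(nd.label)

    def _validate(self) -> None:
        leaves = self.leaf_labels
        if len(leaves) < 2:
            raise TreeError("tree needs at least two leaves")
        if len(set(leaves)) != len(leaves):
            raise TreeError("duplicate leaf labels")
        root = self._tree.seed_node
        for nd in self._tree.preorder_node_iter():
            if nd is root:
                continue
            ln = nd.edge.length
            if ln is None:
                raise TreeError(
                    f"missing branch length on the edge above {self._name(nd)!r}"
                )
            if not math.isfinite(ln) or ln < 0:
                raise TreeError(
                    f"invalid branch length {ln!r} above {self._name(nd)!r}"
                )

    @staticmethod
    def _name(nd: dendropy.Node) -> str:
        return nd.taxon.label if nd.taxon else (nd.label or "<unnamed>")

    def _compute_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + float(nd.edge.length)
        return depths

    # -- queries ----------------------------------------------------------- #

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def internal_labels(self) -> list[str]:
        return [
            nd.label
            for nd in self._tree.preorder_node_iter()
            if not nd.is_leaf()
        ]

    def find_node(self, label: str) -> dendropy.Node:
        for nd in self._tree.preorder_node_iter():
            if self._name(nd) == label:
                return nd
        raise TreeError(f"no node labelled {label!r}")

    def depth(self, label: str) -> float:
        return self._depths[self.find_node(label)]

    def path_distance(self, a: str, b: str) -> float:
        """Patristic distance between any two named nodes."""
        na, nb = self.find_node(a), self.find_node(b)
        return self._node_distance(na, nb)

    def _node_distance(self, na: dendropy.Node, nb: dendropy.Node) -> float:
        if na is nb:
            return 0.0
        ancestors = set()
        nd = na
        while nd is not None:
            ancestors.add(nd)
            nd = nd.parent_node
        mrca = nb
        while mrca not in ancestors:
            mrca = mrca.parent_node
        return self._depths[na] + self._depths[nb] - 2.0 * self._depths[mrca]

    def distance_matrix(
        self, labels: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[str]]:
        """Pairwise path-distance matrix over ``labels`` (default: leaves)."""
        labels = list(labels) if labels is not None else self.leaf_labels
        nodes = [self.find_node(lb) for lb in labels]
        n = len(nodes)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self._node_distance(nodes[i], nodes[j])
        return d, labels

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        depths = [self._depths[lf] for lf in self._tree.leaf_node_iter()]
        dmax = max(depths)
        if dmax == 0:
            return True
        return (dmax - min(depths)) <= rtol * dmax

    def rerooted_at(self, label: str) -> "TimeTree":
        """A copy rerooted at the named node (for stationarity checks)."""
        clone = dendropy.Tree(self._tree)
        target = None
        for nd in clone.preorder_node_iter():
            if self._name(nd) == label:
                target = nd
                break
        if target is None:
            raise TreeError(f"no node labelled {label!r}")
        clone.reroot_at_node(target, update_bipartitions=False)
        return TimeTree(clone)


def read_time_tree(newick_text: str) -> TimeTree:
    """Parse a rooted Newick time tree (branch lengths required)."""
    return TimeTree.from_newick(newick_text)


def write_time_tree(tree: TimeTree) -> str:
    return tree.to_newick()
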