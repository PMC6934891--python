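"""Shared fixtures and tree generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phyloexpr as px

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_binary_tree_newick(
    rng: np.random.Generator, n_leaves: int, ultrametric: bool = False
) -> str:
    """Random rooted binary tree with positive branch lengths.

    With ``ultrametric=True``, leaf depths are equalized (a clock-like time
    tree); otherwise branch lengths are i.i.d. uniform.
    """
    labels = [f"T{i + 1}" for i in range(n_leaves)]
    if not ultrametric:
        nodes = [(lb, 0.0) for lb in labels]  # (newick, unused)
        items = [lb for lb in labels]
        while len(items) > 1:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
            b1, b2 = rng.uniform(0.05, 1.0, size=2)
            merged = f"({items[i]}:{b1:.6f},{items[j]}:{b2:.6f})"
            items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
        return items[0] + ";"
    # coalescent-style: merge subtrees upward at increasing heights
    items = [(lb, 0.0) for lb in labels]
    height = 0.0
    while len(items) > 1:
        height += rng.uniform(0.05, 0.5)
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (s1, h1), (s2, h2) = items[i], items[j]
        merged = (
            f"({s1}:{height - h1:.12g},{s2}:{height - h2:.12g})",
            height,
        )
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return items[0][0] + ";"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def three_leaf_tree() -> px.TimeTree:
    return px.read_time_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_leaf_tree() -> px.TimeTree:
    return px.read_time_tree(
        "(((A:0.2,B:0.2):0.3,(C:0.3,D:0.2):0.2):0.5,(E:0.6,F:0.6):0.4);"
    )


@pytest.fixture
def toy_tsv(tmp_path):
    """3-gene x 4-sample expression table (2 taxa x 1 tissue x 2 reps)."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "gene\thuman.liver.1\thuman.liver.2\tmacaque.liver.1\tmacaque.liver.2\n"
        "g1\t1.0\t2.0\t1.5\t1.5\n"
        "g2\t0.0\t0.0\t0.5\t0.5\n"
        "g3\t3.0\t5.0\t4.0\t4.0\n"
    )
    return path
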