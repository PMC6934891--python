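"""Expression trees, branch mapping, rate test, quartet decomposition."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import lsq_linear

import phyloexpr as px
from phyloexpr.phylo import leaf_splits
from tests.conftest import random_binary_tree_newick


def _dm_from_tree(tree: px.TimeTree) -> px.ExpressionDistanceMatrix:
    d, labels = tree.distance_matrix()
    return px.ExpressionDistanceMatrix([(l, "t") for l in labels], d, "pearson")


def _rf(newick_a: str, newick_b: str) -> int:
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    return treecompare.symmetric_difference(ta, tb)


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        dm = px.ExpressionDistanceMatrix(
            [("A", "t"), ("B", "t"), ("C", "t")], d, "pearson"
        )
        tree = px.nj_tree(dm)
        # three-point formulas: a = (dAB + dAC - dBC)/2 etc.
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_additive_matrix_exact_recovery(self, rng):
        gen = px.read_time_tree(random_binary_tree_newick(rng, 5))
        dm = _dm_from_tree(gen)
        tree = px.nj_tree(dm)
        nwk = tree.as_string(schema="newick")
        assert _rf(nwk, gen.to_newick()) == 0
        # branch lengths: path distances reproduce the input matrix
        rec = px.read_time_tree(nwk)
        d_rec, _ = rec.distance_matrix([l for l, _ in dm.labels])
        np.testing.assert_allclose(d_rec, dm.D, atol=1e-10)

    def test_matches_independent_nj_implementation(self, rng):
        # dendropy's NJ as an independent oracle on a noisy matrix
        gen = px.read_time_tree(random_binary_tree_newick(rng, 6))
        d, labels = gen.distance_matrix()
        noisy = d + rng.uniform(0, 0.01, size=d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm = px.ExpressionDistanceMatrix([(l, "t") for l in labels], noisy, "pearson")
        mine = px.nj_tree(dm).as_string(schema="newick")

        import csv
        import io

        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow([""] + labels)
        for i, lb in enumerate(labels):
            writer.writerow([lb] + list(noisy[i]))
        buf.seek(0)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
        oracle = pdm.nj_tree().as_string(schema="newick")
        assert _rf(mine, oracle) == 0

    def test_undefined_entries_refused(self):
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        dm = px.ExpressionDistanceMatrix(
            [("A", "t"), ("B", "t"), ("C", "t")], d, "const_mu"
        )
        with pytest.raises(px.ValidationError, match="undefined"):
            px.nj_tree(dm)

    def test_deterministic_on_ties(self):
        # fully tied star distances: identical tree across repeated runs
        d = np.ones((4, 4)) - np.eye(4)
        dm = px.ExpressionDistanceMatrix(
            [(c, "t") for c in "ABCD"], d, "pearson"
        )
        t1 = px.nj_tree(dm).as_string(schema="newick")
        t2 = px.nj_tree(dm).as_string(schema="newick")
        assert t1 == t2


class TestBootstrapSupport:
    def test_clear_split_gets_high_support(self):
        gen = px.read_time_tree(
            "(((A:0.1,B:0.12):0.08,C:0.25):0.05,(D:0.2,E:0.18):0.1);"
        )
        expr = px.simulate_expression(
            gen, px.OUParameters(W=1.0, beta=1.0), 5000, seed=42
        )
        res = px.bootstrap_support(expr, method="const_mu", B=100, seed=7)
        assert min(res.supports.values()) >= 95

    def test_star_like_simulation_gives_low_support(self):
        starlike = px.read_time_tree(
            "((A:0.3,B:0.3):0.0,(C:0.3,(D:0.3,E:0.3):0.0):0.0);"
        )
        expr = px.simulate_expression(
            starlike, px.OUParameters(W=1.0, beta=1.0), 5000, seed=43
        )
        res = px.bootstrap_support(expr, method="const_mu", B=100, seed=8)
        assert min(res.supports.values()) < 95

    def test_fixed_seed_reproducible(self, six_leaf_tree):
        expr = px.simulate_expression(
            six_leaf_tree, px.OUParameters(W=1.0, beta=1.0), 800, seed=3
        )
        r1 = px.bootstrap_support(expr, B=30, seed=11)
        r2 = px.bootstrap_support(expr, B=30, seed=11)
        assert r1.supports == r2.supports
        assert r1.newick_with_support == r2.newick_with_support


class TestLSBranchLengths:
    def test_additive_input_recovers_lengths_exactly(self, rng):
        gen = px.read_time_tree(random_binary_tree_newick(rng, 6))
        dm = _dm_from_tree(gen)
        fit = px.ls_branch_lengths(gen, dm)
        assert fit.residual == pytest.approx(0.0, abs=1e-18)
        rec = px.read_time_tree(fit.newick)
        d_rec, _ = rec.distance_matrix([l for l, _ in dm.labels])
        np.testing.assert_allclose(d_rec, dm.D, atol=1e-8)

    def test_wrong_topology_leaves_residual(self, rng):
        gen = px.read_time_tree("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        dm = _dm_from_tree(gen)
        wrong = px.read_time_tree("(((A:1,D:1):1,C:2):1,(B:1.5,E:1.5):1.5);")
        fit = px.ls_branch_lengths(wrong, dm)
        assert fit.residual > 1e-3

    def test_negative_edge_pinned_at_zero_matches_qp_oracle(self):
        # craft a matrix whose unconstrained LS optimum has a negative edge:
        # star-like distances on a resolved 4-leaf topology
        topo = px.read_time_tree("((A:1,B:1):1,(C:1,D:1):1);")
        d = np.array(
            [
                [0.0, 2.0, 1.0, 1.0],
                [2.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 2.0],
                [1.0, 1.0, 2.0, 0.0],
            ]
        )
        dm = px.ExpressionDistanceMatrix(
            [("A", "t"), ("B", "t"), ("C", "t"), ("D", "t")], d, "pearson"
        )
        fit = px.ls_branch_lengths(topo, dm)
        internal = [s for s, ln in fit.edge_lengths.items() if len(s) == 2]
        assert len(internal) == 1
        assert fit.edge_lengths[internal[0]] == pytest.approx(0.0, abs=1e-12)
        # independent bounded-least-squares oracle on the same system
        labels = dm.label_strings()
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges = list(fit.edge_lengths.keys())
        A = np.array(
            [
                [1.0 if (labels[i] in e) != (labels[j] in e) else 0.0 for e in edges]
                for i, j in pairs
            ]
        )
        target = np.array([d[i, j] for i, j in pairs])
        oracle = lsq_linear(A, target, bounds=(0, np.inf))
        np.testing.assert_allclose(
            [fit.edge_lengths[e] for e in edges], oracle.x, atol=1e-8
        )

    def test_leaf_set_mismatch_rejected(self, rng):
        gen = px.read_time_tree(random_binary_tree_newick(rng, 5))
        dm = _dm_from_tree(gen)
        other = px.read_time_tree("((X:1,Y:1):1,Z:2);")
        with pytest.raises(px.TreeError, match="match"):
            px.ls_branch_lengths(other, dm)


class TestRelativeRateTest:
    def _expr_null(self, n_genes=1500, seed=5):
        tree = px.read_time_tree("((A:1,B:1):1,C:2);")
        return px.simulate_expression(
            tree, px.OUParameters(W=1.0, beta=0.3), n_genes, seed=seed
        )

    def test_duplicate_lineages_give_null(self):
        expr = self._expr_null()
        x, taxa = expr.taxon_matrix()
        vals = x.copy()
        vals[:, taxa.index("B")] = vals[:, taxa.index("A")]
        dup = px.ExpressionProfileSet(
            expr.genes,
            [(t, "t", "1") for t in taxa],
            vals,
            transform_tag="log2p1",
        )
        res = px.relative_rate_test(dup, "A", "B", "C", n_boot=200, seed=1)
        assert res.delta == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry_under_lineage_swap(self):
        expr = self._expr_null()
        r_ab = px.relative_rate_test(
            expr, "A", "B", "C", method="const_mu", n_boot=500, seed=9
        )
        r_ba = px.relative_rate_test(
            expr, "B", "A", "C", method="const_mu", n_boot=500, seed=9
        )
        assert r_ba.delta == pytest.approx(-r_ab.delta)
        assert r_ba.p == pytest.approx(r_ab.p)

    def test_power_increases_with_rate_asymmetry(self):
        # lengthen A's expression branch: more OU divergence along A
        zs = []
        for ta in (1.0, 1.6, 2.4):
            tree = px.read_time_tree(f"((A:{ta},B:1):1,C:2);")
            expr = px.simulate_expression(
                tree, px.OUParameters(W=1.0, beta=0.3), 4000, seed=70
            )
            res = px.relative_rate_test(
                expr, "A", "B", "C", method="const_mu", n_boot=400, seed=2
            )
            zs.append(abs(res.z))
        assert zs[0] < zs[1] < zs[2]
        assert zs[2] > 3.0


class TestQuartetGamma:
    def test_pure_species_split(self):
        # distances from a tree with only the species split (gamma_D = 0)
        g_e, p = 0.4, {"A1": 0.1, "A2": 0.2, "B1": 0.3, "B2": 0.15}
        q = px.quartet_gamma_from_distances(
            d_a1a2=p["A1"] + p["A2"],
            d_b1b2=p["B1"] + p["B2"],
            d_a1b1=p["A1"] + p["B1"] + g_e,
            d_a2b2=p["A2"] + p["B2"] + g_e,
            d_a1b2=p["A1"] + p["B2"] + g_e,
            d_a2b1=p["A2"] + p["B1"] + g_e,
        )
        assert q.gamma_D == pytest.approx(0.0, abs=1e-12)
        assert q.gamma_E == pytest.approx(g_e)
        assert q.residual == pytest.approx(0.0, abs=1e-20)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.tuples(*[st.floats(min_value=0.01, max_value=1.0)] * 4),
    )
    def test_forward_construction_recovered_exactly(self, g_d, g_e, pendants):
        p1, p2, p3, p4 = pendants
        q = px.quartet_gamma_from_distances(
            d_a1a2=p1 + p2 + g_d,
            d_b1b2=p3 + p4 + g_d,
            d_a1b1=p1 + p3 + g_e,
            d_a2b2=p2 + p4 + g_e,
            d_a1b2=p1 + p4 + g_d + g_e,
            d_a2b1=p2 + p3 + g_d + g_e,
        )
        assert q.gamma_D == pytest.approx(g_d, abs=1e-9)
        assert q.gamma_E == pytest.approx(g_e, abs=1e-9)
        assert q.pendant["A1"] == pytest.approx(p1, abs=1e-9)
        assert q.pendant["B2"] == pytest.approx(p4, abs=1e-9)

    def test_tissue_relabelling_swaps_gamma_pairs(self, rng):
        d = {k: rng.uniform(0.2, 1.0) for k in
             ("a1a2", "b1b2", "a1b1", "a2b2", "a1b2", "a2b1")}
        q = px.quartet_gamma_from_distances(
            d["a1a2"], d["b1b2"], d["a1b1"], d["a2b2"], d["a1b2"], d["a2b1"]
        )
        # swapping tissue labels 1 <-> 2 in both species
        q_swap = px.quartet_gamma_from_distances(
            d["a1a2"], d["b1b2"], d["a2b2"], d["a1b1"], d["a2b1"], d["a1b2"]
        )
        assert q_swap.gamma_E == pytest.approx(q.gamma_E)
        assert q_swap.gamma_D == pytest.approx(q.gamma_D)
        assert q_swap.pendant["A1"] == pytest.approx(q.pendant["A2"])

    def test_matrix_interface(self):
        labels = [("A", "1"), ("A", "2"), ("B", "1"), ("B", "2")]
        d = np.array(
            [
                [0.0, 0.3, 0.7, 0.75],
                [0.3, 0.0, 0.75, 0.7],
                [0.7, 0.75, 0.0, 0.45],
                [0.75, 0.7, 0.45, 0.0],
            ]
        )
        dm = px.ExpressionDistanceMatrix(labels, d, "const_mu")
        q = px.quartet_gamma(dm, "A", "B", "1", "2")
        manual = px.quartet_gamma_from_distances(0.3, 0.45, 0.7, 0.7, 0.75, 0.75)
        assert q.gamma_D == pytest.approx(manual.gamma_D)
        assert q.gamma_E == pytest.approx(manual.gamma_E)


class TestSplits:
    def test_leaf_splits_canonical(self):
        tree = dendropy.Tree.get(
            data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick"
        )
        splits = leaf_splits(tree)
        assert splits == {frozenset({"C", "D"})}
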