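"""Newick handling, Felsenstein contrasts and contrast regression."""

import math

import numpy as np
import pytest

from sterome.phylo import (
    PhyloError,
    compute_contrasts,
    contrast_regression,
    drop_tips,
    parse_newick,
    write_newick,
)
from sterome.synthetic import random_tree, simulate_brownian


def gls_slope(tree, x: dict, y: dict) -> float:
    """Independent oracle: the phylogenetic GLS slope by direct inversion of
    the Brownian covariance (shared root-to-MRCA path lengths)."""
    tips = tree.tip_labels
    n = len(tips)
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
    depth = {
        leaf.taxon.label: leaf.distance_from_root()
        for leaf in tree.dendropy_tree.leaf_node_iter()
    }
    C = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i == j:
                C[i, j] = depth[a]
            else:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                C[i, j] = 0.5 * (depth[a] + depth[b] - d)
    Ci = np.linalg.inv(C)
    X = np.column_stack([np.ones(n), [x[t] for t in tips]])
    Y = np.array([y[t] for t in tips])
    return float(np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ Y)[1])


class TestNewickIO:
    def test_parse_small_tree(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert set(t.tip_labels) == {"A", "B", "C"}
        internal = sum(
            1 for nd in t.dendropy_tree.preorder_node_iter() if not nd.is_leaf()
        )
        assert internal == 2

    def test_round_trip_preserves_distances(self):
        for seed in range(100):
            t = random_tree(6, seed=seed)
            t2 = parse_newick(write_newick(t))
            assert set(t2.tip_labels) == set(t.tip_labels)
            pdm1 = t.dendropy_tree.phylogenetic_distance_matrix().as_data_table()
            pdm2 = t2.dendropy_tree.phylogenetic_distance_matrix().as_data_table()
            for a in t.tip_labels:
                for b in t.tip_labels:
                    assert pdm1[a, b] == pytest.approx(pdm2[a, b], abs=1e-9)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(PhyloError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(PhyloError):
            parse_newick("((A:1,B:1:1,C:2);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(PhyloError, match="branch length"):
            parse_newick("((A:1,B):1,C:2);")


class TestDropTips:
    def test_prune_one_tip(self):
        t = drop_tips(parse_newick("((A:1,B:1):1,C:2);"), ["C"])
        assert set(t.tip_labels) == {"A", "B"}

    def test_degree_two_node_suppressed_lengths_summed(self):
        t = drop_tips(parse_newick("(((A:1,B:1):2,C:1):1,D:4);"), ["C"])
        # A's root-to-tip distance: 1 + 2 + 1 (suppressed node absorbed)
        leaf = {
            nd.taxon.label: nd.distance_from_root()
            for nd in t.dendropy_tree.leaf_node_iter()
        }
        assert leaf["A"] == pytest.approx(4.0)

    def test_drop_nothing_is_identity(self):
        t0 = parse_newick("((A:1,B:1):1,C:2);")
        t1 = drop_tips(t0, [])
        assert write_newick(t1) == write_newick(t0)

    def test_unknown_tip_rejected(self):
        with pytest.raises(PhyloError, match="unknown"):
            drop_tips(parse_newick("(A:1,B:1);"), ["Z"])

    def test_cannot_drop_to_single_tip(self):
        with pytest.raises(PhyloError, match="fewer than two"):
            drop_tips(parse_newick("((A:1,B:1):1,C:2);"), ["A", "B"])


class TestContrasts:
    def test_two_taxon_closed_form(self):
        cs = compute_contrasts(parse_newick("(A:1,B:1);"), {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(math.sqrt(2.0))

    def test_three_taxon_hand_recursion(self):
        cs = compute_contrasts(
            parse_newick("((A:1,B:1):1,C:2);"), {"A": 4.0, "B": 2.0, "C": 1.0}
        )
        got = sorted(np.abs(cs.contrasts))
        assert got[0] == pytest.approx(2.0 / math.sqrt(3.5), abs=1e-9)  # extended branch 1.5
        assert got[1] == pytest.approx(math.sqrt(2.0), abs=1e-9)

    def test_translation_invariance(self):
        t = random_tree(12, seed=2)
        x = simulate_brownian(t, 1.0, seed=7)
        c0 = compute_contrasts(t, x)
        c1 = compute_contrasts(t, {k: v + 100.0 for k, v in x.items()})
        assert np.allclose(c0.contrasts, c1.contrasts)

    def test_contrast_count_is_tips_minus_one(self):
        for n in (2, 5, 16, 33):
            t = random_tree(n, seed=n)
            cs = compute_contrasts(t, simulate_brownian(t, 1.0, seed=n + 1))
            assert len(cs) == n - 1

    def test_child_order_flips_sign_only(self):
        a = parse_newick("(A:1,B:2);")
        b = parse_newick("(B:2,A:1);")
        trait = {"A": 5.0, "B": 1.0}
        ca = compute_contrasts(a, trait)
        cb = compute_contrasts(b, trait)
        assert ca.contrasts[0] == pytest.approx(-cb.contrasts[0])

    def test_missing_tip_values_listed(self):
        with pytest.raises(PhyloError, match="B"):
            compute_contrasts(parse_newick("(A:1,B:1);"), {"A": 1.0})

    def test_matches_dendropy_pic(self):
        # independent implementation cross-check
        import dendropy
        from dendropy.model.continuous import PhylogeneticIndependentContrasts

        t = random_tree(10, seed=5)
        trait = simulate_brownian(t, 2.0, seed=6)
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree.get(
            data=write_newick(t), schema="newick", taxon_namespace=taxa
        )
        cm = dendropy.ContinuousCharacterMatrix.from_dict(
            {label: [value] for label, value in trait.items()}, taxon_namespace=taxa
        )
        pic = PhylogeneticIndependentContrasts(tree=tree, char_matrix=cm)
        ref = sorted(
            abs(nd.pic[0]["pic_contrast_standardized"])
            for nd in pic.contrasts_tree(0).postorder_internal_node_iter()
        )
        ours = sorted(np.abs(compute_contrasts(t, trait).contrasts))
        assert np.allclose(ours, ref, atol=1e-9)


class TestContrastRegression:
    def test_exact_proportionality(self):
        t = random_tree(8, seed=1)
        x = simulate_brownian(t, 1.0, seed=2)
        cx = compute_contrasts(t, x)
        cy = compute_contrasts(t, {k: 2.0 * v for k, v in x.items()})
        reg = contrast_regression(cx, cy)
        assert reg.slope == pytest.approx(2.0, rel=1e-9)
        assert reg.r2 == pytest.approx(1.0)

    def test_self_regression(self):
        t = random_tree(8, seed=3)
        cx = compute_contrasts(t, simulate_brownian(t, 1.0, seed=4))
        reg = contrast_regression(cx, cx)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.pvalue < 1e-10

    def test_mismatched_trees_rejected(self):
        ta, tb = random_tree(8, seed=1), random_tree(8, seed=99)
        ca = compute_contrasts(ta, simulate_brownian(ta, 1.0, seed=2))
        cb = compute_contrasts(tb, simulate_brownian(tb, 1.0, seed=2))
        with pytest.raises(PhyloError, match="different trees"):
            contrast_regression(ca, cb)

    @pytest.mark.parametrize("n_tips", [3, 4, 5, 6])
    def test_equals_gls_slope(self, n_tips):
        for seed in range(5):
            t = random_tree(n_tips, seed=seed)
            x = simulate_brownian(t, 1.0, seed=100 + seed)
            y = simulate_brownian(t, 1.0, seed=200 + seed)
            reg = contrast_regression(compute_contrasts(t, x), compute_contrasts(t, y))
            assert reg.slope == pytest.approx(gls_slope(t, x, y), abs=1e-9)

    def test_recovers_proportional_evolution(self):
        # traits co-evolved with true slope 2 plus small independent noise
        t = random_tree(64, seed=17)
        x = simulate_brownian(t, 1.0, seed=18)
        e = simulate_brownian(t, 0.01, seed=19)
        y = {k: 2.0 * x[k] + e[k] for k in x}
        reg = contrast_regression(compute_contrasts(t, x), compute_contrasts(t, y))
        assert reg.slope == pytest.approx(2.0, abs=0.1)
        assert reg.r2 > 0.98

    def test_polytomy_resolved(self):
        t = parse_newick("(A:1,B:1,C:1);")
        cs = compute_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert len(cs) == 2
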