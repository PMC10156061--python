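import itertools
import math

import numpy as np
import pytest

from pebpmine.phylogeny import (Alignment, DistanceMatrix, bootstrap_support,
                                check_clades, nj_tree, pairwise_distance,
                                progressive_align)
from pebpmine.synthetic_data import clade_taxa


class TestPairwiseDistance:
    def test_identical_rows_zero_for_all_models(self):
        row = "ACDEFGHIKL" * 10
        for model in ("p", "poisson", "gamma"):
            p, d = pairwise_distance(row, row, model)
            assert p == 0 and d == 0

    def test_poisson_closed_form(self):
        # 10 differing sites out of 100 -> p = 0.1, d = -ln(0.9)
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        p, d = pairwise_distance(a, b, "poisson")
        assert p == 0.1
        assert d == pytest.approx(0.105361, abs=1e-6)

    def test_gamma_alpha_one_closed_form(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        p, d = pairwise_distance(a, b, "gamma", alpha=1.0)
        assert d == pytest.approx(1 / 0.9 - 1, abs=1e-9)

    def test_pairwise_gap_deletion(self):
        p, d = pairwise_distance("A-CA", "AG-A", "p")
        assert p == 0.0   # only 2 comparable columns, both identical

    def test_saturated_distance_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            pairwise_distance("AAAA", "CCCC", "poisson")

    def test_no_comparable_columns(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance("--AA", "AA--", "p")

    def test_poisson_dominates_p_and_gamma_limits_to_poisson(self):
        a = "A" * 100
        for k in (5, 20, 50):
            b = "C" * k + "A" * (100 - k)
            p, dp = pairwise_distance(a, b, "p")
            _, dpois = pairwise_distance(a, b, "poisson")
            _, dgam = pairwise_distance(a, b, "gamma", alpha=1e6)
            assert dpois >= dp
            assert abs(dgam - dpois) < 1e-6


def _ls_fit_4taxon(D, names):
    """Brute-force least-squares branch lengths over all 3 unrooted 4-taxon
    topologies; returns (best split frozenset, lengths dict, internal)."""
    a, b, c, d = names
    idx = {n: i for i, n in enumerate(names)}
    observed = {pair: D[idx[pair[0]], idx[pair[1]]]
                for pair in itertools.combinations(names, 2)}
    best = None
    for split in ((a, b), (a, c), (a, d)):
        other = tuple(n for n in names if n not in split)
        # unknowns: la, lb, lc, ld (leaf edges in 'names' order), m (internal)
        rows, rhs = [], []
        for (x, y), dist in observed.items():
            row = [0.0] * 5
            row[idx[x]] = 1
            row[idx[y]] = 1
            same_side = ({x, y} == set(split)) or ({x, y} == set(other))
            if not same_side:
                row[4] = 1
            rows.append(row)
            rhs.append(dist)
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        rss = float(np.sum((np.array(rows) @ sol - np.array(rhs)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, frozenset(split), sol)
    _, split, sol = best
    return split, {n: sol[idx[n]] for n in names}, sol[4]


class TestNJTree:
    def test_four_taxon_additive_matrix_recovered(self):
        """NJ agrees with the brute-force least-squares oracle on a known tree:
        leaf branches 0.1/0.2/0.3/0.4, internal 0.05."""
        names = ["a", "b", "c", "d"]
        D = np.zeros((4, 4))
        dd = {("a", "b"): 0.3, ("c", "d"): 0.7, ("a", "c"): 0.45,
              ("a", "d"): 0.55, ("b", "c"): 0.55, ("b", "d"): 0.65}
        for (x, y), v in dd.items():
            i, j = names.index(x), names.index(y)
            D[i, j] = D[j, i] = v
        split, lengths, internal = _ls_fit_4taxon(D, names)
        assert split == frozenset({"a", "b"})
        assert lengths["a"] == pytest.approx(0.1, abs=1e-9)
        assert internal == pytest.approx(0.05, abs=1e-9)

        tree = nj_tree(DistanceMatrix(names, D, D * 0, "p"))
        assert tree.bipartitions() == {frozenset({"a", "b"})}
        taxa, mat = tree.leaf_distances()
        for (x, y), v in dd.items():
            assert mat[taxa.index(x), taxa.index(y)] == pytest.approx(v, abs=1e-9)

    def test_three_taxa_three_point_formula(self):
        names = ["a", "b", "c"]
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(DistanceMatrix(names, D, D * 0, "p"))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_zero_matrix_yields_zero_tree_with_flag(self):
        D = np.zeros((4, 4))
        tree = nj_tree(DistanceMatrix(list("abcd"), D, D, "p"))
        assert "zero_distance_matrix" in tree.flags
        _, mat = tree.leaf_distances()
        assert np.allclose(mat, 0)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0, 2], [1.1, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(list("abc"), D, D, "p"))

    @pytest.mark.parametrize("seed", range(50))
    def test_additive_matrices_recovered_exactly(self, seed):
        """On additive matrices (random trees, 5-9 taxa) NJ returns the unique
        additive tree: patristic distances equal the input exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 10))
        names = [f"t{i}" for i in range(n)]
        D = _random_additive_matrix(names, rng)
        tree = nj_tree(DistanceMatrix(names, D, D * 0, "p"))
        taxa, mat = tree.leaf_distances()
        order = [taxa.index(nm) for nm in names]
        assert np.allclose(mat[np.ix_(order, order)], D, atol=1e-8)

    def test_matches_independent_nj_implementation(self):
        """Topology cross-check against scikit-bio's neighbour joining."""
        import skbio
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(99)
        names = [f"t{i}" for i in range(7)]
        D = _random_additive_matrix(names, rng)
        D += rng.uniform(0, 0.01, D.shape)    # mild non-additive noise
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)

        mine = nj_tree(DistanceMatrix(names, D, D * 0, "p")).bipartitions()
        sk_tree = skbio_nj(skbio.DistanceMatrix(D, ids=names))
        ref = min(names)
        full = set(names)
        theirs = set()
        for node in sk_tree.non_tips():
            below = {t.name for t in node.tips()}
            if 2 <= len(below) <= len(full) - 2:
                theirs.add(frozenset(below if ref in below else full - below))
        assert mine == theirs


def _random_additive_matrix(names, rng):
    """Distance matrix of a random binary tree with branch lengths in
    [0.05, 1.0] (tree metrics are additive by construction)."""
    n = len(names)
    D = np.zeros((n, n))

    def recurse(taxa):
        if len(taxa) == 1:
            return {taxa[0]: 0.0}
        k = int(rng.integers(1, len(taxa)))
        left, right = recurse(taxa[:k]), recurse(taxa[k:])
        el, er = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        for x, dx in left.items():
            for y, dy in right.items():
                i, j = names.index(x), names.index(y)
                D[i, j] = D[j, i] = dx + el + dy + er
        out = {x: dx + el for x, dx in left.items()}
        out.update({y: dy + er for y, dy in right.items()})
        return out

    recurse(list(names))
    return D


class TestBootstrap:
    def _two_clade_alignment(self):
        base = "DEFGHIKLMN" * 7
        row_a = "A" * 30 + base
        row_b = "C" * 30 + base
        taxa = ["a1", "a2", "a3", "b1", "b2", "b3"]
        rows = [row_a, row_a, row_a, row_b, row_b, row_b]
        return Alignment(taxa, rows)

    def test_clear_split_has_full_support(self):
        tree = bootstrap_support(self._two_clade_alignment(), "p", replicates=100, seed=1)
        split = frozenset({"a1", "a2", "a3"})
        assert tree.support.get(split) == 1.0

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(self._two_clade_alignment(), "p", replicates=1, seed=3)
        assert set(tree.support.values()) <= {0.0, 1.0}

    def test_seeded_determinism(self):
        t1 = bootstrap_support(self._two_clade_alignment(), "p", 50, seed=7)
        t2 = bootstrap_support(self._two_clade_alignment(), "p", 50, seed=7)
        assert t1.support == t2.support
        assert t1.to_newick() == t2.to_newick()


class TestCheckClades:
    def _tree(self):
        taxa, groups = clade_taxa(n_per_clade=3)
        aln = progressive_align(taxa)
        return nj_tree(DistanceMatrix.from_alignment(aln, "poisson")), groups

    def test_planted_subfamilies_monophyletic(self):
        tree, groups = self._tree()
        result = check_clades(tree, groups)
        assert all(result.values())

    def test_mixed_group_not_monophyletic(self):
        tree, groups = self._tree()
        bad = {"mixed": [groups["FT"][0], groups["MFT"][0], groups["FT"][1]]}
        assert check_clades(tree, bad) == {"mixed": False}

    def test_all_leaves_true_by_convention(self):
        tree, _ = self._tree()
        assert check_clades(tree, {"all": list(tree.taxa)}) == {"all": True}

    def test_single_leaf_group_rejected(self):
        tree, groups = self._tree()
        with pytest.raises(ValueError):
            check_clades(tree, {"solo": [groups["FT"][0]]})


class TestProgressiveAlign:
    def test_rows_reconstruct_inputs(self):
        taxa, _ = clade_taxa(n_per_clade=2)
        aln = progressive_align(taxa)
        for name, row in zip(aln.taxa, aln.rows):
            assert row.replace("-", "") == taxa[name]

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        taxa, _ = clade_taxa(n_per_clade=2)
        aln = progressive_align(taxa)
        tree = bootstrap_support(aln, "poisson", replicates=10, seed=5)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                                   preserve_underscores=True)
        assert {t.label for t in parsed.taxon_namespace} == set(aln.taxa)
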