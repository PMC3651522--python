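"""Tree handling and independent contrasts against the GLS oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from phyloblot import phylo
from phyloblot.phylo import (
    ContrastSet,
    NewickParseError,
    TreeError,
    contrast_regression,
    independent_contrasts,
    leaf_labels,
    parse_newick,
    prune_to_taxa,
    resolve_polytomies,
    set_equal_branch_lengths,
)
from phyloblot.simulate import random_binary_tree

from conftest import gls_slope


class TestParseNewick:
    def test_two_leaf_tree_with_lengths(self):
        t = parse_newick("(A:1,B:1);")
        assert sorted(leaf_labels(t)) == ["A", "B"]
        lengths = [n.edge.length for n in t.leaf_node_iter()]
        assert lengths == [1.0, 1.0]

    def test_four_leaf_tree_without_lengths(self):
        t = parse_newick("((A,B),(C,D));")
        assert sorted(leaf_labels(t)) == ["A", "B", "C", "D"]
        assert all(n.edge.length is None for n in t.leaf_node_iter())

    @pytest.mark.parametrize("bad", ["(A,B", "", "   ", "(A:1,A:1);"])
    def test_malformed_or_duplicate_input_rejected(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)


class TestBranchLengthsAndTopology:
    def test_equal_branch_lengths_set_everywhere(self):
        t = set_equal_branch_lengths(parse_newick("((A:5,B:0.1):2,C:9);"), 1.0)
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.edge.length == 1.0
        assert sorted(leaf_labels(t)) == ["A", "B", "C"]

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_length_rejected(self, bad):
        with pytest.raises(TreeError):
            set_equal_branch_lengths(parse_newick("(A:1,B:1);"), bad)

    def test_resolve_polytomies_is_binary_and_seeded(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        r1 = resolve_polytomies(t, seed=5)
        r2 = resolve_polytomies(t, seed=5)
        for nd in r1.preorder_internal_node_iter():
            assert len(nd.child_nodes()) == 2
        assert phylo.as_newick(r1) == phylo.as_newick(r2)
        new_lengths = [
            nd.edge.length
            for nd in r1.preorder_node_iter()
            if nd.parent_node is not None
        ]
        assert 0.0 in new_lengths  # inserted branches are zero length

    def test_resolve_binary_tree_is_identity(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        assert phylo.as_newick(resolve_polytomies(t, 0)) == phylo.as_newick(t)

    def test_prune_sums_suppressed_branch_lengths(self):
        t = prune_to_taxa(parse_newick("((A:1,B:1):1,C:1);"), ["A", "C"])
        lengths = {n.taxon.label: n.edge.length for n in t.leaf_node_iter()}
        assert lengths == {"A": 2.0, "C": 1.0}

    def test_prune_to_full_leaf_set_is_identity(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        assert phylo.as_newick(prune_to_taxa(t, ["A", "B", "C"])) == phylo.as_newick(t)

    def test_prune_errors(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(TreeError, match="Z"):
            prune_to_taxa(t, ["A", "Z"])
        with pytest.raises(TreeError):
            prune_to_taxa(t, ["A"])


class TestIndependentContrasts:
    def test_single_cherry_formula(self):
        cs = independent_contrasts(parse_newick("(A:1,B:1);"), {"A": 3, "B": 1})
        assert cs.n_contrasts == 1
        assert cs.standardized[0] == pytest.approx(2 / np.sqrt(2), abs=1e-5)

    def test_constant_trait_gives_zero_contrasts(self):
        t = random_binary_tree(12, seed=4)
        cs = independent_contrasts(t, {l: 7.7 for l in leaf_labels(t)})
        assert np.allclose(cs.standardized, 0.0)

    def test_balanced_four_taxon_worked_example(self):
        # Cherries (1-2)/sqrt 2 and (4-8)/sqrt 2; ancestral values 1.5 and 6
        # on branches extended to 1.5 give (1.5-6)/sqrt 3. Cross-checked
        # against the BM-covariance GLS oracle.
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cs = independent_contrasts(t, {"A": 1, "B": 2, "C": 4, "D": 8})
        assert np.allclose(
            cs.standardized, [-0.70711, -2.82843, -2.59808], atol=1e-5
        )
        assert np.allclose(cs.variance, [2.0, 2.0, 3.0])

    def test_contrast_count_is_leaves_minus_one(self):
        rng = np.random.default_rng(11)
        for n in (4, 9, 17, 33, 64):
            t = random_binary_tree(n, seed=int(rng.integers(2**31)))
            trait = {l: float(rng.normal()) for l in leaf_labels(t)}
            assert independent_contrasts(t, trait).n_contrasts == n - 1

    def test_missing_trait_value_names_the_leaf(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(TreeError, match="C"):
            independent_contrasts(t, {"A": 1, "B": 2})

    def test_polytomy_rejected_with_guidance(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="resolve_polytomies"):
            independent_contrasts(t, {"A": 1, "B": 2, "C": 3})

    def test_matches_gls_oracle_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            t = random_binary_tree(int(rng.integers(4, 11)), seed=int(rng.integers(2**31)))
            labels = leaf_labels(t)
            x = {l: float(rng.normal()) for l in labels}
            y = {l: float(rng.normal()) for l in labels}
            cx = independent_contrasts(t, x, "x")
            cy = independent_contrasts(t, y, "y")
            pic = contrast_regression(cx, cy).slope
            gls = gls_slope(t, x, y)
            assert pic == pytest.approx(gls, rel=1e-8, abs=1e-12)

    @given(
        shift=hst.floats(min_value=-50, max_value=50),
        scale=hst.floats(min_value=0.01, max_value=50),
    )
    def test_affine_equivariance(self, shift, scale):
        t = random_binary_tree(8, seed=99)
        rng = np.random.default_rng(1)
        base = {l: float(rng.normal()) for l in leaf_labels(t)}
        c0 = independent_contrasts(t, base)
        c_shift = independent_contrasts(t, {k: v + shift for k, v in base.items()})
        c_scale = independent_contrasts(t, {k: v * scale for k, v in base.items()})
        assert np.allclose(c0.standardized, c_shift.standardized, atol=1e-9)
        assert np.allclose(c0.standardized * scale, c_scale.standardized, rtol=1e-9)

    def test_child_order_flips_signs_but_not_regression(self):
        rng = np.random.default_rng(5)
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((D:1,C:1):1,(B:1,A:1):1);")
        x = {l: float(rng.normal()) for l in "ABCD"}
        y = {l: float(rng.normal()) for l in "ABCD"}
        r1 = contrast_regression(
            independent_contrasts(t1, x), independent_contrasts(t1, y)
        )
        r2 = contrast_regression(
            independent_contrasts(t2, x), independent_contrasts(t2, y)
        )
        s1 = np.sort(np.abs(independent_contrasts(t1, x).standardized))
        s2 = np.sort(np.abs(independent_contrasts(t2, x).standardized))
        assert np.allclose(s1, s2)
        assert r1.slope == pytest.approx(r2.slope)
        assert r1.p == pytest.approx(r2.p)

    def test_bm_simulated_contrasts_are_calibrated(self, analysis_subtree):
        # Under BM with rate sigma^2 the standardized contrasts are
        # N(0, sigma^2); a reduced-size calibration check (the acceptance
        # suite runs the full-size version).
        from phyloblot.simulate import BMParameters, simulate_bm_traits

        rate = 0.06
        sq = []
        for seed in range(200):
            params = BMParameters.from_correlation(0.0, rate_1=rate, seed=seed)
            traits = simulate_bm_traits(analysis_subtree, params)
            cs = independent_contrasts(analysis_subtree, traits["log_level"].to_dict())
            sq.extend(cs.standardized**2)
        assert np.mean(sq) == pytest.approx(rate, rel=0.10)


class TestContrastRegression:
    def _pair(self, u, w):
        ids = tuple(range(len(u)))
        u = np.asarray(u, float)
        w = np.asarray(w, float)
        mk = lambda name, s: ContrastSet(name, ids, s, np.ones_like(s), s)
        return mk("u", u), mk("w", w)

    def test_perfect_proportionality(self):
        cu, cw = self._pair([1, 2, 3], [2, 4, 6])
        r = contrast_regression(cu, cw)
        assert r.slope == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.intercept is None and r.df_residual == 2

    def test_orthogonal_contrasts_give_zero_slope(self):
        cu, cw = self._pair([1, -1, 0], [1, 1, 0])
        assert contrast_regression(cu, cw).slope == pytest.approx(0.0)

    def test_positivize_changes_nothing(self):
        rng = np.random.default_rng(8)
        cu, cw = self._pair(rng.normal(size=9), rng.normal(size=9))
        a = contrast_regression(cu, cw, positivize=False)
        b = contrast_regression(cu, cw, positivize=True)
        assert (a.slope, a.r_squared, a.p) == pytest.approx((b.slope, b.r_squared, b.p))

    def test_mismatched_node_sets_rejected(self):
        cu, _ = self._pair([1, 2, 3], [1, 2, 3])
        cw = ContrastSet("w", (5, 6, 7), np.ones(3), np.ones(3), np.ones(3))
        with pytest.raises(TreeError):
            contrast_regression(cu, cw)

    def test_all_zero_predictor_rejected(self):
        cu, cw = self._pair([0, 0, 0], [1, 2, 3])
        with pytest.raises(ValueError):
            contrast_regression(cu, cw)
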