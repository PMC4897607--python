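"""Phylogeny handling: parsing, calibration, distances, Faith's PD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import commphylo as cp
from commphylo.tree import (AgeConstraints, CalibrationError, NewickParseError,
                            TreeValidationError, bladj_calibrate)
from oracles import (bladj_chain_oracle, brute_cophenetic, brute_faith_pd,
                     path_walk_distance)


class TestParseWrite:
    def test_basic_topology(self, three_tip_tree):
        assert sorted(three_tip_tree.tip_labels) == ["A", "B", "C"]
        assert len(three_tip_tree.dendropy_tree.seed_node.child_nodes()) == 2

    def test_single_tip(self):
        t = cp.parse_newick("(A);")
        assert t.tip_labels == ["A"]

    def test_quoted_labels_and_polytomy(self):
        t = cp.parse_newick("('sp one':1,B:1,C:1,'D_x':1);")
        assert "sp one" in t.tip_labels and "D_x" in t.tip_labels
        assert len(t.dendropy_tree.seed_node.child_nodes()) == 4

    def test_unbalanced_parentheses_reports_offset(self):
        with pytest.raises(NewickParseError, match="offset|open"):
            cp.parse_newick("((A:1,B:1:1,C:2);")
        with pytest.raises(NewickParseError, match="offset"):
            cp.parse_newick("(A:1,B:1)):1;")

    def test_duplicate_tip_label_rejected(self):
        with pytest.raises((TreeValidationError, NewickParseError)):
            cp.parse_newick("((A:1,A:1):1,C:2);")

    def test_round_trip_preserves_cophenetic(self, three_tip_tree):
        re = cp.parse_newick(three_tip_tree.to_newick())
        assert sorted(re.tip_labels) == sorted(three_tip_tree.tip_labels)
        d1 = cp.cophenetic(three_tip_tree).to_dataframe()
        d2 = cp.cophenetic(re).to_dataframe()
        assert (d1 == d2.loc[d1.index, d1.columns]).all().all()

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10 ** 6), n=st.integers(2, 20))
    def test_round_trip_random_trees(self, seed, n):
        t = cp.simulate_yule_tree(n, seed=seed, root_age=73.0)
        re = cp.parse_newick(t.to_newick())
        d1 = cp.cophenetic(t).to_dataframe()
        d2 = cp.cophenetic(re).to_dataframe()
        assert np.array_equal(d1.values, d2.loc[d1.index, d1.columns].values)


class TestCophenetic:
    def test_star_tree_all_two(self, star_tree):
        d = cp.cophenetic(star_tree)
        assert d.get("A", "B") == d.get("A", "C") == d.get("B", "C") == 2.0

    def test_hand_values(self, three_tip_tree):
        d = cp.cophenetic(three_tip_tree)
        assert d.get("A", "B") == 2.0
        assert d.get("A", "C") == 4.0
        assert np.all(np.diag(d.values) == 0)
        assert np.array_equal(d.values, d.values.T)

    def test_missing_branch_length_named(self):
        t = cp.parse_newick("((A:1,B):1,C:2);")
        with pytest.raises(TreeValidationError, match="B"):
            cp.cophenetic(t)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_walk_oracle(self, seed):
        t = cp.simulate_yule_tree(np.random.default_rng(seed).integers(3, 21),
                                  seed=seed, root_age=100.0)
        d = cp.cophenetic(t)
        for (a, b), expected in brute_cophenetic(t).items():
            assert d.get(a, b) == pytest.approx(expected, rel=1e-12)

    def test_ultrametric_distance_is_twice_mrca_age(self):
        t = cp.simulate_yule_tree(12, seed=5, root_age=80.0)
        d = cp.cophenetic(t)
        dt = t.dendropy_tree
        pdm_nodes = {leaf.taxon.label: leaf for leaf in dt.leaf_node_iter()}
        for a in t.tip_labels[:6]:
            for b in t.tip_labels[6:]:
                mrca = dt.mrca(taxa=[pdm_nodes[a].taxon, pdm_nodes[b].taxon])
                assert d.get(a, b) == pytest.approx(2 * mrca.age, rel=1e-9)


class TestBladj:
    def test_even_interpolation_on_chain(self):
        t = cp.parse_newick("(((A:1)n2:1)n1:1)r;")
        c = bladj_calibrate(t, AgeConstraints({"r": 30.0}))
        assert c.age_of("n1") == pytest.approx(20.0)
        assert c.age_of("n2") == pytest.approx(10.0)
        assert c.age_of("A") == 0.0
        assert c.is_ultrametric()

    def test_all_dated_identity(self):
        t = cp.parse_newick("(((A:5,B:5)n2:5,C:9)n1:5,D:20)r;")
        c = bladj_calibrate(t, AgeConstraints({"r": 20.0, "n1": 15.0, "n2": 5.0}))
        assert c.age_of("n1") == 15.0 and c.age_of("n2") == 5.0
        # branch lengths recomputed from ages
        d = cp.cophenetic(c)
        assert d.get("A", "B") == pytest.approx(10.0)
        assert d.get("A", "D") == pytest.approx(40.0)

    def test_caterpillar_matches_path_enumeration_oracle(self):
        # root(40) - i1 - i2(20) - i3 - i4 - tips(0)
        nwk = "((((A:1,B:1)i4:1,C:1)i3:1,D:1)i2:1,(E:1)i1:1)r;"
        c = bladj_calibrate(cp.parse_newick(nwk),
                            AgeConstraints({"r": 40.0, "i2": 20.0}))
        # i1 sits alone between root(40) and tip E(0): one node, even spacing
        assert c.age_of("i1") == pytest.approx(bladj_chain_oracle((40, 0), 1)[0])
        # i3's governing path runs to its nearest dated descendant, tip C,
        # one step below: even spacing between i2(20) and 0 gives 10.  Fixed
        # top-down, i3 then anchors i4's path to the A/B tips.
        expect_i3 = bladj_chain_oracle((20, 0), 1)[0]
        assert c.age_of("i3") == pytest.approx(expect_i3)
        assert c.age_of("i4") == pytest.approx(
            bladj_chain_oracle((expect_i3, 0), 1)[0])

    def test_pure_chain_spacing_between_dated_anchors(self):
        # unambiguous dated-to-dated chain: r(40) - x1 - x2 - x3 - tip(0)
        c = bladj_calibrate(cp.parse_newick("((((A:1)x3:1)x2:1)x1:1)r;"),
                            AgeConstraints({"r": 40.0}))
        for got, want in zip([c.age_of(f"x{i}") for i in (1, 2, 3)],
                             bladj_chain_oracle((40, 0), 3)):
            assert got == pytest.approx(want)

    def test_idempotent(self):
        t = cp.simulate_yule_tree(16, seed=3, root_age=50.0)
        cons = AgeConstraints({})
        c1 = bladj_calibrate(t, cons, root_age=50.0)
        c2 = bladj_calibrate(c1, cons, root_age=50.0)
        for node1, node2 in zip(c1.dendropy_tree.preorder_node_iter(),
                                c2.dendropy_tree.preorder_node_iter()):
            assert node2.age == pytest.approx(node1.age, rel=1e-9)

    def test_constraint_violating_ancestry_names_both(self):
        t = cp.parse_newick("(((A:1)n2:1)n1:1)r;")
        with pytest.raises(CalibrationError, match="n2.*n1|n1.*n2"):
            bladj_calibrate(t, AgeConstraints({"r": 30.0, "n1": 5.0, "n2": 10.0}))

    def test_unknown_constraint_label(self):
        t = cp.parse_newick("((A:1,B:1)n1:1)r;")
        with pytest.raises(CalibrationError, match="nope"):
            bladj_calibrate(t, AgeConstraints({"nope": 3.0}), root_age=10.0)

    def test_root_age_required(self):
        t = cp.parse_newick("((A:1,B:1)n1:1);")
        with pytest.raises(CalibrationError, match="root"):
            bladj_calibrate(t, AgeConstraints({}))

    def test_age_constraint_file_round_trip(self, tmp_path):
        p = tmp_path / "ages.txt"
        p.write_text("# calibration\nr 30\nn1, 12.5\n")
        cons = AgeConstraints.read(p)
        assert cons["r"] == 30.0 and cons["n1"] == 12.5


class TestFaithPD:
    def test_single_species_zero(self, star_tree):
        assert cp.faith_pd(star_tree, {"A"}) == 0.0

    def test_star_tree_values(self, star_tree):
        assert cp.faith_pd(star_tree, {"A", "B"}) == 2.0
        assert cp.faith_pd(star_tree, {"A", "B", "C"}) == 3.0

    def test_full_tip_set_is_total_branch_length(self):
        t = cp.simulate_yule_tree(10, seed=4, root_age=60.0)
        total = sum(n.edge.length for n in t.dendropy_tree.preorder_node_iter()
                    if n.parent_node is not None)
        assert cp.faith_pd(t, set(t.tip_labels)) == pytest.approx(total)

    def test_unknown_species_listed(self, star_tree):
        with pytest.raises(TreeValidationError, match="Z"):
            cp.faith_pd(star_tree, {"A", "Z"})
        with pytest.raises(ValueError):
            cp.faith_pd(star_tree, set())

    def test_rooting_conventions(self, three_tip_tree):
        # {A,B}: MRCA-rooted spans the cherry (2); root-rooted adds the stem (1)
        assert cp.faith_pd(three_tip_tree, {"A", "B"}, rooted="mrca") == 2.0
        assert cp.faith_pd(three_tip_tree, {"A", "B"}, rooted="root") == 3.0
        assert cp.faith_pd(three_tip_tree, {"C"}, rooted="root") == 2.0

    @pytest.mark.parametrize("rooted", ["mrca", "root"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed, rooted):
        rng = np.random.default_rng(seed)
        t = cp.simulate_yule_tree(int(rng.integers(4, 13)), seed=seed + 50,
                                  root_age=90.0)
        tips = t.tip_labels
        for _ in range(5):
            k = int(rng.integers(1, len(tips) + 1))
            sub = set(rng.choice(tips, size=k, replace=False))
            assert cp.faith_pd(t, sub, rooted=rooted) == pytest.approx(
                brute_faith_pd(t, sub, rooted=rooted), rel=1e-12)

    def test_monotone_in_species(self):
        t = cp.simulate_yule_tree(12, seed=9, root_age=70.0)
        tips = t.tip_labels
        rng = np.random.default_rng(0)
        order = list(rng.permutation(tips))
        prev = 0.0
        for k in range(1, len(order) + 1):
            val = cp.faith_pd(t, set(order[:k]))
            assert val >= prev - 1e-12
            prev = val
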