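"""Synthetic generator: Yule trees, Brownian traits, assembly modes."""

import numpy as np
import pandas as pd
import pytest

import commphylo as cp
from commphylo.synthetic import AssemblySpec, SuccessionDesign, neutral_dataset


class TestYule:
    def test_tip_count_labels_ultrametric(self):
        t = cp.simulate_yule_tree(5, seed=1)
        assert t.n_tips == 5
        assert all(l.startswith("s") for l in t.tip_labels)
        assert t.is_ultrametric(rtol=1e-9)
        assert t.root_age == pytest.approx(100.0)

    def test_deterministic(self):
        a = cp.simulate_yule_tree(16, seed=42).to_newick()
        b = cp.simulate_yule_tree(16, seed=42).to_newick()
        assert a == b

    def test_binary_internal_node_count(self):
        for seed in range(20):
            t = cp.simulate_yule_tree(16, seed=seed)
            internal = sum(1 for n in t.dendropy_tree.preorder_node_iter()
                           if not n.is_leaf())
            assert internal == 15  # a binary tree with n tips has n-1 internal nodes

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            cp.simulate_yule_tree(1)


class TestBrownianTrait:
    def test_variance_matches_closed_form(self):
        # on a fixed tree, across replicates, Var(tip) = sigma2 * depth
        t = cp.simulate_yule_tree(6, seed=11, root_age=50.0)
        sigma2 = 2.0
        tips = t.tip_labels
        vals = np.array([cp.evolve_trait(t, sigma2, seed=s)[tips].values
                         for s in range(1000)])
        var = vals.var(axis=0, ddof=1)
        expected = sigma2 * 50.0
        se = expected * np.sqrt(2.0 / 999)  # sampling sd of a variance estimate
        assert np.all(np.abs(var - expected) < 4 * se)

    def test_sisters_correlate_more_than_distant_tips(self):
        t = cp.parse_newick("((A:1,B:1):9,C:10);")
        vals = np.array([[cp.evolve_trait(t, 1.0, seed=s)[x] for x in "ABC"]
                         for s in range(800)])
        corr = np.corrcoef(vals.T)
        assert corr[0, 1] > corr[0, 2] + 0.3  # shared path 9/10 vs 0

    def test_invalid_rate(self):
        t = cp.simulate_yule_tree(4, seed=0)
        with pytest.raises(ValueError):
            cp.evolve_trait(t, 0.0)


@pytest.fixture(scope="module")
def pool():
    tree = cp.simulate_yule_tree(32, seed=3)
    return tree, cp.evolve_trait(tree, 1.0, seed=4), cp.cophenetic(tree)


class TestAssembly:
    def test_neutral_full_richness_contains_everyone(self, pool):
        tree, traits, dist = pool
        spec = AssemblySpec(mode="neutral", richness=32, seed=1)
        cm = cp.assemble_plots(tree, traits, spec, 3)
        assert (cm.richness == 32).all()

    def test_richness_exceeding_pool_rejected(self, pool):
        tree, traits, dist = pool
        spec = AssemblySpec(mode="neutral", richness=33, seed=1)
        with pytest.raises(ValueError, match="pool"):
            cp.assemble_plots(tree, traits, spec, 1)

    def test_limiting_similarity_respects_delta(self, pool):
        tree, traits, dist = pool
        spec = AssemblySpec(mode="limiting_similarity", richness=4, delta=60.0,
                            seed=5)
        cm = cp.assemble_plots(tree, traits, spec, 10, dist=dist)
        for plot in cm.plots:
            sp = sorted(cm.species_set(plot))
            sub = dist.submatrix(sp).values
            np.fill_diagonal(sub, np.inf)
            assert sub.min() >= 60.0 - 1e-9  # delta never had to relax here

    def test_filtering_concentrates_near_optimum(self, pool):
        tree, traits, dist = pool
        opt = float(traits.max())
        spec = AssemblySpec(mode="filtering", richness=6, sigma=1.0,
                            optimum=opt, seed=6)
        cm = cp.assemble_plots(tree, traits, spec, 20)
        chosen = [traits[s] for p in cm.plots for s in cm.species_set(p)]
        neutral = cp.assemble_plots(
            tree, traits, AssemblySpec(mode="neutral", richness=6, seed=7), 20)
        base = [traits[s] for p in neutral.plots for s in neutral.species_set(p)]
        assert abs(np.mean(chosen) - opt) < abs(np.mean(base) - opt)

    def test_generated_data_validates_untouched(self, pool):
        tree, traits, dist = pool
        spec = AssemblySpec(mode="neutral", richness=5, seed=8)
        cm = cp.assemble_plots(tree, traits, spec, 4)
        # rebuild through the validating constructor: no exception, sums to 1
        again = cp.CommunityMatrix(cm.wide, cm.plot_meta, cm.species_meta)
        assert np.allclose(again.wide.sum(axis=1), 1.0)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            AssemblySpec(mode="magic")
        with pytest.raises(ValueError):
            AssemblySpec(mode="filtering", sigma=0.0)


class TestSuccessionDataset:
    def test_default_design_dimensions(self, tmp_path):
        tree, cm = cp.simulate_succession_dataset(seed=0)
        assert len(cm.plots) == 90
        counts = cm.stages.value_counts().sort_index()
        assert counts.tolist() == [9, 9, 9, 37, 16, 10]
        assert tree.n_tips == 356
        assert (cm.life_forms == "woody").sum() == 129
        # round-trips through the CSV reader untouched
        paths = cm.write(tmp_path)
        back = cp.read_community(paths["community"], paths["plots"], paths["species"])
        assert len(back.plots) == 90 and len(back.species) == 356

    def test_pure_function_of_seed(self):
        _, a = cp.simulate_succession_dataset(seed=12)
        _, b = cp.simulate_succession_dataset(seed=12)
        pd.testing.assert_frame_equal(a.wide, b.wide)
        _, c = cp.simulate_succession_dataset(seed=13)
        assert not a.wide.equals(c.wide)

    def test_richness_rises_along_succession(self):
        _, cm = cp.simulate_succession_dataset(seed=1)
        med = cm.richness.groupby(cm.stages).median()
        assert (med.diff().dropna() >= 0).all()

    def test_woody_fraction_rises_with_stage(self):
        _, cm = cp.simulate_succession_dataset(seed=2)
        woody = set(cm.species_meta.index[cm.life_forms == "woody"])
        frac = {}
        for stage in range(1, 7):
            sub = cm.subset(stage=stage)
            occ = sub.wide.gt(0)
            frac[stage] = (occ[list(woody & set(sub.species))].sum().sum()
                           / occ.sum().sum())
        assert frac[6] > frac[1]

    def test_invalid_design(self):
        with pytest.raises(ValueError):
            SuccessionDesign(plot_counts=(1, 2, 3))

    def test_fixture_dataset_shape(self, fixture_data):
        tree, cm = fixture_data
        assert len(cm.plots) == 12 and tree.n_tips == 24
        assert sorted(cm.stages.unique()) == [1, 2, 3]

    def test_neutral_dataset_shape(self):
        tree, cm = neutral_dataset(16, 10, (3, 6), seed=0)
        assert len(cm.plots) == 10
        assert cm.richness.between(3, 6).all()
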