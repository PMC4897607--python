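"""Trial-swap randomization and standardized effect sizes."""

import numpy as np
import pandas as pd
import pytest

import commphylo as cp
from commphylo.nulls import SwapChain, ses_alpha, ses_beta
from conftest import toy_community


class TestIndependentSwap:
    def test_full_matrix_has_no_checkerboard(self):
        m = np.ones((2, 2), dtype=int)
        assert np.array_equal(cp.independent_swap(m, 500, seed=1), m)

    def test_margins_preserved(self):
        rng = np.random.default_rng(0)
        m = (rng.random((12, 30)) < 0.3).astype(int)
        m[m.sum(axis=1) == 0, 0] = 1
        out = cp.independent_swap(m, 5000, seed=3)
        assert np.array_equal(out.sum(axis=0), m.sum(axis=0))
        assert np.array_equal(out.sum(axis=1), m.sum(axis=1))
        assert not np.array_equal(out, m)  # enough trials to actually move

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            cp.independent_swap(np.array([[0.5, 1], [1, 0]]), 10)

    def test_checkerboard_sampled_evenly(self):
        # only two matrices share these margins; over 10,000 chains the
        # frequency of each should be 50% within 3 sigma
        start = np.array([[1, 0], [0, 1]])
        hits = 0
        for i in range(10_000):
            out = cp.independent_swap(start, 20, seed=i)
            hits += int(out[0, 0] == 1)
        p = hits / 10_000
        sigma = np.sqrt(0.25 / 10_000)
        assert abs(p - 0.5) < 3 * sigma

    def test_abundances_travel_within_plots(self):
        pres = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        abund = np.array([[0.7, 0.0], [0.0, 1.0]])
        chain = SwapChain(pres, abund, seed=4)
        chain.advance(50)
        # row sums and per-row value multisets are invariant
        assert chain.abund.sum(axis=1) == pytest.approx([0.7, 1.0])
        for r in range(2):
            assert sorted(chain.abund[r][chain.abund[r] > 0]) == \
                sorted(abund[r][abund[r] > 0])

    def test_deterministic(self):
        m = (np.random.default_rng(1).random((8, 20)) < 0.4).astype(int)
        m[m.sum(axis=1) == 0, 0] = 1
        a = cp.independent_swap(m, 1000, seed=11)
        b = cp.independent_swap(m, 1000, seed=11)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def neutral_case():
    tree, cm = cp.synthetic.neutral_dataset(32, 30, (4, 10), seed=5)
    return tree, cm, cp.cophenetic(tree)


class TestSes:
    def test_reproducible_bit_for_bit(self, neutral_case):
        tree, cm, dist = neutral_case
        a = ses_alpha(cm, dist, n_rand=49, seed=9)
        b = ses_alpha(cm, dist, n_rand=49, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_null_margins_hold_inside_ensemble(self, neutral_case):
        tree, cm, dist = neutral_case
        chain = SwapChain(cm.presence, cm.abundance, seed=2)
        r0, c0 = chain.pres.sum(axis=1), chain.pres.sum(axis=0)
        for _ in range(5):
            chain.advance(chain.fill)
            assert np.array_equal(chain.pres.sum(axis=1), r0)
            assert np.array_equal(chain.pres.sum(axis=0), c0)

    def test_observed_equal_null_mean_gives_zero_index(self):
        from commphylo.nulls import _ses
        out = _ses(np.array([3.0]), np.array([3.0]), np.array([1.0]))
        assert out[0] == 0.0

    def test_sign_convention(self):
        from commphylo.nulls import _ses
        # observed below the null mean -> positive index (clustering)
        assert _ses(np.array([1.0]), np.array([2.0]), np.array([0.5]))[0] == 2.0

    def test_degenerate_null_warns_and_zeroes(self):
        from commphylo.nulls import _ses
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = _ses(np.array([1.0]), np.array([1.5]), np.array([0.0]))
        assert out[0] == 0.0

    def test_identical_pair_beta_nti_positive(self, three_tip_tree):
        # comdistnt of an identical pair is 0; any null with sd > 0 gives
        # a positive betaNTI (lower turnover than expected)
        cm = toy_community({"p1": {"A": 1.0, "C": 1.0},
                            "p2": {"A": 1.0, "C": 1.0},
                            "p3": {"B": 1.0, "C": 1.0},
                            "p4": {"A": 1.0, "B": 1.0}})
        dist = cp.cophenetic(three_tip_tree)
        table = ses_beta(cm, dist, pairs=[("p1", "p2")], n_rand=199, seed=21)
        assert table.loc[0, "comdistnt_obs"] == 0.0
        assert table.loc[0, "comdistnt_null_mean"] > 0
        assert table.loc[0, "beta_nti"] > 0

    def test_single_target_wrappers_match_tables(self, neutral_case):
        tree, cm, dist = neutral_case
        plot = cm.plots[0]
        nri, nti = cp.nri_nti(plot, cm, dist, n_rand=49, seed=3)
        assert nri.index_name == "NRI" and nti.metric == "MNTD"
        # same substream seed -> identical numbers on re-evaluation
        nri2, _ = cp.nri_nti(plot, cm, dist, n_rand=49, seed=3)
        assert nri.index == nri2.index
        a, b = cm.plots[0], cm.plots[1]
        bnri, bnti = cp.beta_nri_nti((a, b), cm, dist, n_rand=49, seed=3)
        assert bnri.index_name == "betaNRI"
        assert np.isfinite(bnri.index)

    def test_richness_one_plot_rejected_by_wrapper(self, three_tip_tree):
        cm = toy_community({"p1": {"A": 1.0}, "p2": {"A": 1.0, "B": 1.0}})
        dist = cp.cophenetic(three_tip_tree)
        with pytest.raises(ValueError, match="richness"):
            cp.nri_nti("p1", cm, dist, n_rand=9)

    def test_n_rand_validated(self, neutral_case):
        tree, cm, dist = neutral_case
        with pytest.raises(ValueError):
            ses_alpha(cm, dist, n_rand=0)
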