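import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import commphylo as cp


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    return cp.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """Three tips on unit branches from the root: all distances 2."""
    return cp.parse_newick("(A:1,B:1,C:1);")


@pytest.fixture(scope="session")
def fixture_data():
    """The small 3-stage / 12-plot / 24-species synthetic dataset."""
    return cp.fixture_dataset(seed=7)


@pytest.fixture(scope="session")
def random_cases():
    """200 (tree <= 8 tips, two random communities) cases for oracle checks."""
    rng = np.random.default_rng(2024)
    cases = []
    for rep in range(200):
        n = int(rng.integers(3, 9))
        tree = cp.simulate_yule_tree(n, seed=int(rng.integers(2 ** 31)),
                                     root_age=float(rng.uniform(10, 200)))
        species = tree.tip_labels
        dist = cp.cophenetic(tree)

        def community():
            k = int(rng.integers(1, n + 1))
            chosen = rng.choice(species, size=k, replace=False)
            return {s: float(rng.lognormal(0, 1)) for s in chosen}

        cases.append((tree, dist, community(), community()))
    return cases


def toy_community(wide_dict, stages=None, life_forms=None, renormalize=True):
    """Build a CommunityMatrix from {plot: {species: abundance}}."""
    wide = pd.DataFrame(wide_dict).T.fillna(0.0)
    stages = stages or {p: 1 for p in wide.index}
    plot_meta = pd.DataFrame({"stage": pd.Series(stages), "plot_size": "10x10"})
    life_forms = life_forms or {s: "herbaceous" for s in wide.columns}
    species_meta = pd.DataFrame({"life_form": pd.Series(life_forms)})
    return cp.CommunityMatrix(wide, plot_meta, species_meta,
                              renormalize=renormalize)
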