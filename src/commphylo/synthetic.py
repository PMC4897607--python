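"""Synthetic phylogenies and succession-structured communities.

This module generates datasets with *known* assembly mechanisms so the whole
pipeline — tree handling, diversity metrics, null models, stage statistics —
can be exercised and validated without field data.  Three assembly modes are
implemented on top of a simulated regional pool:

``neutral``
    Species are drawn uniformly at random (without replacement) to the target
    richness.  Communities assembled this way should look random to the null
    models: standardized effect sizes near 0.

``filtering``
    A Brownian trait evolved on the tree carries the niche signal; species
    are sampled with probability proportional to a Gaussian kernel
    exp(-(trait - optimum)^2 / (2 sigma^2)).  Because the trait is
    phylogenetically conserved, strong filtering concentrates communities in
    a clade neighbourhood and produces phylogenetic clustering (NRI > 0).

``limiting_similarity``
    Candidates (in shuffled order) are accepted only if their cophenetic
    distance to every already-accepted species is at least ``delta`` Myr;
    whenever the candidate pool is exhausted before the target richness is
    reached, delta relaxes by a factor 0.9 and scanning restarts over the
    remaining pool.  This produces phylogenetic overdispersion (NRI < 0).

A succession chronosequence is emulated by varying the assembly mode and its
strength per stage rather than by explicit temporal dynamics — the
space-for-time logic of chronosequence designs.  The default
:class:`SuccessionDesign` mirrors the structure of a six-stage old-field to
climax-forest series: plot counts (9, 9, 9, 37, 16, 10), a regional pool of
356 species of which 129 are woody, per-plot richness rising along the
series, and assembly shifting from limiting similarity (stages 1-3, with
weakening strength) through neutral (stage 4, the transitional shrub stage)
to increasingly strong environmental filtering (stages 5-6).  Woody species
are the high-trait (clade-biased) part of the pool and the late-stage filter
optimum sits in that region, so the woody fraction rises along succession.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .seeding import derive_seed
from .tree import DistanceMatrix, PhyloTree, cophenetic

logger = logging.getLogger(__name__)

ASSEMBLY_MODES = ("neutral", "filtering", "limiting_similarity")


@dataclass(frozen=True)
class AssemblySpec:
    """Parameters of one community-assembly process.

    richness: species per plot.  sigma/optimum: Gaussian filter width and
    centre in trait units (filtering mode).  delta: minimum cophenetic
    distance in Myr (limiting-similarity mode).  Abundances are lognormal
    (meanlog, sdlog) and renormalized to relative coverage.
    """

    mode: str = "neutral"
    richness: int = 12
    sigma: float = 1.5
    optimum: float = 0.0
    delta: float = 120.0
    abund_meanlog: float = 0.0
    abund_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ASSEMBLY_MODES:
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if self.richness < 1:
            raise ValueError("richness must be >= 1")
        if self.mode == "filtering" and self.sigma <= 0:
            raise ValueError("filtering requires sigma > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass(frozen=True)
class SuccessionDesign:
    """A six-stage chronosequence layout.

    Defaults echo the dimensions of a semi-arid temperate succession survey
    (90 plots over six stages, 356-species pool with 129 woody species); all
    values are configurable.
    """

    plot_counts: tuple = (9, 9, 9, 37, 16, 10)
    pool_size: int = 356
    n_woody: int = 129
    root_age: float = 100.0
    trait_sigma2: float = 1.0
    stage_richness: tuple = (8, 10, 12, 16, 18, 20)
    stage_modes: tuple = ("limiting_similarity", "limiting_similarity",
                          "limiting_similarity", "neutral",
                          "filtering", "filtering")
    stage_delta: tuple = (150.0, 110.0, 75.0, 0.0, 0.0, 0.0)
    stage_sigma: tuple = (1.0, 1.0, 1.0, 1.0, 2.0, 1.0)

    def __post_init__(self):
        if len(self.plot_counts) != 6:
            raise ValueError("a succession design has six stages")
        if any(c < 1 for c in self.plot_counts):
            raise ValueError("every stage needs at least one plot")
        if not 0 < self.n_woody < self.pool_size:
            raise ValueError("n_woody must be between 0 and pool_size")
        for name in ("stage_richness", "stage_modes", "stage_delta", "stage_sigma"):
            if len(getattr(self, name)) != 6:
                raise ValueError(f"{name} needs six entries")


# ---------------------------------------------------------------------------
# tree and trait simulation
# ---------------------------------------------------------------------------

def simulate_yule_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0,
                       root_age: float | None = 100.0) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` tips, ultrametric by construction.

    Waiting times between speciation events are exponential with rate
    ``birth_rate x k`` (k = current lineage count) and the splitting lineage
    is chosen uniformly; after the last split an extra exponential interval
    separates the final speciation from the present.  If ``root_age`` is
    given, branch lengths are rescaled so the root sits at that age (Myr) and
    node ages are attached (tips at 0).  Tips are labelled s0001, s0002, ...
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    rng = np.random.default_rng(seed)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    birth_time = {root: 0.0}
    active = [root]
    t = 0.0
    # root splits at t = 0 (the stem is dropped)
    while len(active) < n_tips:
        if len(active) > 1:
            t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        children = []
        for _ in range(2):
            ch = dendropy.Node()
            node.add_child(ch)
            birth_time[ch] = t
            children.append(ch)
        active.extend(children)
    present = t + rng.exponential(1.0 / (birth_rate * n_tips))

    scale = 1.0 if root_age is None else root_age / present
    for node in tree.preorder_node_iter():
        end = birth_time[node.child_nodes()[0]] if node.child_nodes() else present
        node.age = (present - end) * scale
        if node.parent_node is not None:
            node.edge.length = (end - birth_time[node]) * scale
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_namespace.new_taxon(label=f"s{i:04d}")
    return PhyloTree(tree, calibrated=True)


def evolve_trait(tree: PhyloTree, sigma2: float, seed: int = 0,
                 root_value: float = 0.0) -> pd.Series:
    """Brownian-motion trait on the tree; returns a Series indexed by tip.

    Each branch adds an independent normal increment with mean 0 and variance
    ``sigma2 x branch_length``, so tip variance across replicates equals
    sigma2 times root-to-tip depth and tips covary by sigma2 times shared
    path length.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    value = {}
    out = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            value[node] = float(root_value)
        else:
            bl = node.edge.length
            if bl is None:
                raise ValueError("evolve_trait requires branch lengths everywhere")
            value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(sigma2 * bl))
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return pd.Series(out, name="trait")


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def _sample_one_plot(spec: AssemblySpec, species: np.ndarray, traits: np.ndarray,
                     dvals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pool = len(species)
    if spec.richness > pool:
        raise ValueError(f"richness {spec.richness} exceeds pool size {pool}")
    if spec.mode == "neutral":
        return rng.choice(pool, size=spec.richness, replace=False)
    if spec.mode == "filtering":
        w = np.exp(-((traits - spec.optimum) ** 2) / (2 * spec.sigma ** 2))
        if w.sum() <= 0:
            w = np.ones(pool)
        return rng.choice(pool, size=spec.richness, replace=False, p=w / w.sum())
    # limiting similarity: sequential accept/reject with relaxing threshold
    delta = spec.delta
    accepted: list[int] = []
    remaining = list(rng.permutation(pool))
    while len(accepted) < spec.richness:
        progressed = False
        still = []
        for cand in remaining:
            if len(accepted) >= spec.richness:
                still.append(cand)
                continue
            if not accepted or dvals[np.ix_([cand], accepted)].min() >= delta:
                accepted.append(cand)
                progressed = True
            else:
                still.append(cand)
        remaining = still
        if len(accepted) < spec.richness and not progressed:
            delta *= 0.9
    return np.array(accepted)


def assemble_plots(tree: PhyloTree, traits: pd.Series, spec: AssemblySpec,
                   n_plots: int, stage: int = 1, plot_size: str = "10x10",
                   plot_prefix: str = "plot", life_forms: pd.Series | None = None,
                   dist: DistanceMatrix | None = None) -> CommunityMatrix:
    """Assemble ``n_plots`` communities from the tree's tip pool under ``spec``.

    Abundances are lognormal draws renormalized to relative coverage.  If
    ``life_forms`` is omitted every species is labelled herbaceous (life form
    only matters for subset analyses).
    """
    species = np.array(tree.tip_labels)
    tvals = traits.reindex(species).values.astype(float)
    if np.isnan(tvals).any():
        raise ValueError("traits missing for some tips")
    dvals = None
    if spec.mode == "limiting_similarity":
        dvals = (dist or cophenetic(tree)).submatrix(list(species)).values
    rng = np.random.default_rng(spec.seed)

    wide = pd.DataFrame(0.0, index=[f"{plot_prefix}{i + 1:03d}" for i in range(n_plots)],
                        columns=species)
    for plot in wide.index:
        idx = _sample_one_plot(spec, species, tvals, dvals, rng)
        ab = rng.lognormal(spec.abund_meanlog, spec.abund_sdlog, size=len(idx))
        wide.loc[plot, species[idx]] = ab
    plot_meta = pd.DataFrame({"stage": stage, "plot_size": plot_size}, index=wide.index)
    if life_forms is None:
        life_forms = pd.Series("herbaceous", index=species)
    species_meta = pd.DataFrame({"life_form": life_forms.reindex(species)})
    return CommunityMatrix(wide, plot_meta, species_meta)


def neutral_dataset(n_tips: int = 64, n_plots: int = 100,
                    richness_range: tuple = (5, 15), seed: int = 0):
    """A neutral benchmark: one Yule pool plus uniformly assembled plots.

    Per-plot richness is drawn uniformly from ``richness_range`` (inclusive)
    and species are sampled uniformly without replacement, i.e. the same
    process the independent-swap null conditions on.  Used to calibrate the
    standardized indices (their SES should be ~N(0, 1) on this input).
    Returns ``(PhyloTree, CommunityMatrix)``.
    """
    tree = simulate_yule_tree(n_tips, seed=derive_seed(seed, "neutral-tree"),
                              root_age=100.0)
    species = np.array(tree.tip_labels)
    rng = np.random.default_rng(derive_seed(seed, "neutral-plots"))
    lo, hi = richness_range
    wide = pd.DataFrame(0.0, index=[f"p{i + 1:04d}" for i in range(n_plots)],
                        columns=species)
    for plot in wide.index:
        r = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(species), size=r, replace=False)
        wide.loc[plot, species[idx]] = rng.lognormal(0.0, 1.0, size=r)
    plot_meta = pd.DataFrame({"stage": 1, "plot_size": "10x10"}, index=wide.index)
    species_meta = pd.DataFrame({"life_form": "herbaceous"}, index=species)
    return tree, CommunityMatrix(wide, plot_meta, species_meta)


def focal_clade(tree: PhyloTree, traits: pd.Series,
                size_range: tuple = (15, 40)) -> list:
    """Tips of the mid-sized clade whose trait mean is most distinctive.

    Scans internal nodes with a clade size inside ``size_range`` and returns
    the tip labels of the clade with the highest trait discriminability: the
    offset of the clade's mean from the pool mean divided by the clade's own
    trait standard deviation.  A high score means a Gaussian filter centred
    on the clade mean captures the clade and little else — the clade a
    habitat filter would most cleanly single out.  Deterministic given
    (tree, traits).
    """
    overall_mean = float(traits.mean())
    best, best_score = None, -np.inf
    for node in tree.dendropy_tree.preorder_internal_node_iter():
        tips = [l.taxon.label for l in node.leaf_iter()]
        if not size_range[0] <= len(tips) <= size_range[1]:
            continue
        vals = traits.loc[tips]
        score = abs(float(vals.mean()) - overall_mean) / max(float(vals.std()), 1e-9)
        if score > best_score:
            best, best_score = tips, score
    if best is None:
        raise ValueError("no clade within the requested size range")
    return best


def mechanism_recovery_dataset(mode: str, seed: int = 0, n_mech: int = 50,
                               n_context: int = 50, pool_size: int = 128,
                               spec: AssemblySpec | None = None):
    """Mechanism plots embedded in a neutral regional matrix.

    Assembles ``n_mech`` plots under ``mode`` (stage 2) alongside
    ``n_context`` neutral plots (stage 1) from one Yule pool.  The context
    plots matter: the margin-preserving swap null randomizes the supplied
    matrix, so a matrix consisting solely of, say, filtered plots has
    occurrence frequencies that already encode the filter and the indices
    lose their reference point — just as a field survey restricted to one
    habitat would.  Filtering targets a clade: the optimum is the mean trait
    of the focal clade returned by :func:`focal_clade` (the mid-sized clade
    with the most distinctive trait mean), so filtered plots concentrate in
    that clade's neighbourhood.  Other parameters come from ``spec`` or the
    :class:`AssemblySpec` defaults.

    Returns ``(PhyloTree, CommunityMatrix)``; mechanism plots are stage 2.
    """
    tree = simulate_yule_tree(pool_size, seed=derive_seed(seed, "mech-tree"),
                              root_age=100.0)
    traits = evolve_trait(tree, 1.0, seed=derive_seed(seed, "mech-traits"))
    dist = cophenetic(tree) if mode == "limiting_similarity" else None
    if spec is None:
        optimum = 0.0
        if mode == "filtering":
            optimum = float(traits.loc[focal_clade(tree, traits)].mean())
        spec = AssemblySpec(mode=mode, optimum=optimum,
                            seed=derive_seed(seed, "mech-plots"))
    mech = assemble_plots(tree, traits, spec, n_mech, stage=2,
                          plot_prefix="mech_p", dist=dist)
    ctx_spec = AssemblySpec(mode="neutral", richness=spec.richness,
                            seed=derive_seed(seed, "mech-context"))
    ctx = assemble_plots(tree, traits, ctx_spec, n_context, stage=1,
                         plot_prefix="ctx_p")
    cm = CommunityMatrix(pd.concat([mech.wide, ctx.wide]),
                         pd.concat([mech.plot_meta, ctx.plot_meta]),
                         mech.species_meta)
    return tree, cm


# ---------------------------------------------------------------------------
# succession dataset
# ---------------------------------------------------------------------------

def _stage_specs(design: SuccessionDesign, traits: pd.Series,
                 woody: pd.Index, seed: int) -> list[AssemblySpec]:
    optimum = float(traits.loc[woody].mean())
    specs = []
    for s in range(6):
        specs.append(AssemblySpec(
            mode=design.stage_modes[s],
            richness=design.stage_richness[s],
            sigma=design.stage_sigma[s],
            optimum=optimum,
            delta=design.stage_delta[s],
            seed=derive_seed(seed, "stage", s + 1),
        ))
    return specs


def simulate_succession_dataset(design: SuccessionDesign | None = None,
                                seed: int = 0):
    """Simulate one regional tree plus a six-stage community dataset.

    Returns ``(PhyloTree, CommunityMatrix)``.  The generator is a pure
    function of (design, seed): identical inputs give identical datasets.
    Woody species are the ``n_woody`` tips with the largest trait values
    (clade-biased because the trait is Brownian); stages 1-3 plots are
    labelled 10x10 and stages 4-6 plots 20x20, mirroring a field design in
    which woody-dominated stages use larger plots.
    """
    design = design or SuccessionDesign()
    tree = simulate_yule_tree(design.pool_size, seed=derive_seed(seed, "tree"),
                              root_age=design.root_age)
    traits = evolve_trait(tree, design.trait_sigma2, seed=derive_seed(seed, "traits"))
    woody = traits.sort_values(ascending=False).index[:design.n_woody]
    life_forms = pd.Series("herbaceous", index=traits.index)
    life_forms.loc[woody] = "woody"
    dist = cophenetic(tree)

    specs = _stage_specs(design, traits, woody, seed)
    frames, metas = [], []
    plot_counter = 0
    for s, (spec, count) in enumerate(zip(specs, design.plot_counts), start=1):
        cm = assemble_plots(
            tree, traits, spec, count, stage=s,
            plot_size="10x10" if s <= 3 else "20x20",
            plot_prefix=f"st{s}_p", life_forms=life_forms, dist=dist)
        frames.append(cm.wide)
        metas.append(cm.plot_meta)
        plot_counter += count
    wide = pd.concat(frames)
    plot_meta = pd.concat(metas)
    species_meta = pd.DataFrame({"life_form": life_forms})
    cm = CommunityMatrix(wide, plot_meta, species_meta)
    logger.info("simulated succession dataset: %d plots, %d species pool",
                plot_counter, design.pool_size)
    return tree, cm


def fixture_dataset(seed: int = 7):
    """A small 3-stage, 12-plot, 24-species dataset for quick tests/CI.

    Stage 1 is overdispersed (limiting similarity), stage 2 neutral and
    stage 3 clustered (filtering) — the same mechanism gradient as the full
    design at toy scale.
    """
    tree = simulate_yule_tree(24, seed=derive_seed(seed, "fixture-tree"),
                              root_age=100.0)
    traits = evolve_trait(tree, 1.0, seed=derive_seed(seed, "fixture-traits"))
    dist = cophenetic(tree)
    woody = traits.sort_values(ascending=False).index[:8]
    life_forms = pd.Series("herbaceous", index=traits.index)
    life_forms.loc[woody] = "woody"
    modes = [("limiting_similarity", dict(delta=80.0)),
             ("neutral", {}),
             ("filtering", dict(sigma=3.0, optimum=float(traits.loc[woody].mean())))]
    frames, metas = [], []
    for s, (mode, kw) in enumerate(modes, start=1):
        spec = AssemblySpec(mode=mode, richness=6,
                            seed=derive_seed(seed, "fixture-stage", s), **kw)
        cm = assemble_plots(tree, traits, spec, 4, stage=s,
                            plot_prefix=f"st{s}_p", life_forms=life_forms,
                            dist=dist)
        frames.append(cm.wide)
        metas.append(cm.plot_meta)
    cm = CommunityMatrix(pd.concat(frames), pd.concat(metas),
                         pd.DataFrame({"life_form": life_forms}))
    return tree, cm
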