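"""Per-plot (alpha) diversity: Simpson, MPD, MNTD, Faith's PD.

MPD is the mean patristic distance over all distinct pairs of co-occurring
species; MNTD is the mean distance from each species to its nearest
co-occurring relative.  Both come in an occurrence flavour (every present
species counts equally) and an abundance-weighted flavour in which pairwise
distances are weighted by relative coverage.  Plots with a single species
have no pairwise structure; MPD/MNTD are reported as missing (NaN) there and
dropped from stage-level summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .tree import DistanceMatrix, PhyloTree, cophenetic, faith_pd

logger = logging.getLogger(__name__)


def simpson(abundances) -> float:
    """Gini-Simpson diversity, 1 - sum(p_i^2).

    Input abundances are renormalized internally, so any nonnegative vector
    with a positive total is accepted.  The inverse form 1/sum(p_i^2) is
    available via :func:`simpson_inverse`.
    """
    p = np.asarray(abundances, dtype=float)
    if p.size == 0 or np.any(p < 0):
        raise ValueError("abundances must be a nonempty, nonnegative vector")
    tot = p.sum()
    if tot <= 0:
        raise ValueError("all-zero abundance vector")
    p = p / tot
    return float(1.0 - np.sum(p ** 2))


def simpson_inverse(abundances) -> float:
    """Inverse Simpson diversity, 1 / sum(p_i^2)."""
    return 1.0 / (1.0 - simpson(abundances))


def _aligned(abund, dist: DistanceMatrix):
    """Map a {species: abundance} mapping / Series onto dist's index."""
    if isinstance(abund, pd.Series):
        items = abund[abund > 0]
    else:
        items = pd.Series({k: v for k, v in dict(abund).items() if v > 0})
    missing = [s for s in items.index if s not in dist._index]
    if missing:
        raise KeyError(f"species absent from distance matrix: {sorted(missing)}")
    idx = np.array([dist._index[s] for s in items.index])
    return idx, items.values.astype(float)


def mpd(abund, dist: DistanceMatrix, abundance_weighted: bool = False) -> float:
    """Mean pairwise phylogenetic distance of one plot (Myr).

    ``abund`` maps species to relative coverage (zeros ignored).  Unweighted:
    mean of d(i, j) over unordered distinct pairs.  Weighted: sum of
    p_i p_j d(i, j) over ordered pairs i != j divided by sum of p_i p_j over
    the same pairs (conspecific self-pairs are excluded so the weighted form
    is a proper mean of between-species distances).  Returns NaN for plots
    with fewer than two species.
    """
    idx, w = _aligned(abund, dist)
    if len(idx) < 2:
        return float("nan")
    D = dist.values[np.ix_(idx, idx)]
    if abundance_weighted:
        p = w / w.sum()
        num = p @ D @ p
        den = 1.0 - np.sum(p ** 2)
        return float(num / den)
    k = len(idx)
    return float(D.sum() / (k * (k - 1)))


def mntd(abund, dist: DistanceMatrix, abundance_weighted: bool = False) -> float:
    """Mean nearest-taxon distance of one plot (Myr); NaN below richness 2."""
    idx, w = _aligned(abund, dist)
    if len(idx) < 2:
        return float("nan")
    D = dist.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(D, np.inf)
    mins = D.min(axis=1)
    if abundance_weighted:
        p = w / w.sum()
        return float(np.sum(p * mins))
    return float(mins.mean())


def alpha_table(cm: CommunityMatrix, tree: PhyloTree,
                dist: DistanceMatrix | None = None,
                abundance_weighted: bool = False,
                pd_rooted: str = "mrca") -> pd.DataFrame:
    """Per-plot alpha diversity table.

    Columns: stage, richness, simpson, faith_pd, mpd, mntd, weighting.
    """
    if dist is None:
        dist = cophenetic(tree)
    rows = []
    n_singletons = 0
    for plot in cm.plots:
        row = cm.wide.loc[plot]
        present = row[row > 0]
        sp_set = set(present.index)
        rich = len(sp_set)
        if rich < 2:
            n_singletons += 1
        rows.append({
            "plot": plot,
            "stage": int(cm.stages.loc[plot]),
            "richness": rich,
            "simpson": simpson(present.values),
            "faith_pd": faith_pd(tree, sp_set, rooted=pd_rooted),
            "mpd": mpd(present, dist, abundance_weighted=abundance_weighted),
            "mntd": mntd(present, dist, abundance_weighted=abundance_weighted),
            "weighting": "abundance" if abundance_weighted else "occurrence",
        })
    if n_singletons:
        logger.info("%d plot(s) with richness 1: MPD/MNTD reported as missing",
                    n_singletons)
    return pd.DataFrame(rows).set_index("plot")
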