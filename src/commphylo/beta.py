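"""Between-plot (beta) diversity within succession stages.

Taxonomic turnover is 1 - Jaccard on species sets.  Phylogenetic turnover
uses the two classic inter-community distances: COMDIST (mean patristic
distance over all cross-community species pairs) and COMDISTNT (mean
distance from each species to its nearest relative in the other community).
Species shared by both plots contribute zero distances, so identical plots
have COMDISTNT 0.  Pairs are enumerated within a succession stage only,
mirroring a chronosequence design in which turnover is compared among plots
of the same age class.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .tree import DistanceMatrix

logger = logging.getLogger(__name__)


def jaccard_dissimilarity(a, b) -> float:
    """1 - |a n b| / |a u b| on species sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("jaccard_dissimilarity requires two non-empty sets")
    return 1.0 - len(a & b) / len(a | b)


def _plot_vec(abund, dist: DistanceMatrix):
    if isinstance(abund, pd.Series):
        items = abund[abund > 0]
    else:
        items = pd.Series({k: v for k, v in dict(abund).items() if v > 0})
    if items.empty:
        raise ValueError("empty plot")
    missing = [s for s in items.index if s not in dist._index]
    if missing:
        raise KeyError(f"species absent from distance matrix: {sorted(missing)}")
    idx = np.array([dist._index[s] for s in items.index])
    return idx, items.values.astype(float)


def comdist(abund_a, abund_b, dist: DistanceMatrix,
            abundance_weighted: bool = False,
            exclude_conspecifics: bool = False) -> float:
    """Mean inter-community pairwise distance (Myr).

    Unweighted: mean of d(i, j) over all cross pairs i in a, j in b,
    conspecific pairs included at distance 0 (the classic convention;
    ``exclude_conspecifics=True`` drops them instead).  Weighted: sum of
    p_i q_j d(i, j) with p, q the plots' relative coverages; since each
    plot's coverages sum to 1 no further normalization is needed.
    """
    ia, wa = _plot_vec(abund_a, dist)
    ib, wb = _plot_vec(abund_b, dist)
    D = dist.values[np.ix_(ia, ib)]
    if exclude_conspecifics:
        mask = ia[:, None] != ib[None, :]
        if abundance_weighted:
            pa, pb = wa / wa.sum(), wb / wb.sum()
            W = np.outer(pa, pb) * mask
            if W.sum() == 0:
                return float("nan")
            return float((W * D).sum() / W.sum())
        if mask.sum() == 0:
            return float("nan")
        return float(D[mask].mean())
    if abundance_weighted:
        pa, pb = wa / wa.sum(), wb / wb.sum()
        return float(pa @ D @ pb)
    return float(D.mean())


def comdistnt(abund_a, abund_b, dist: DistanceMatrix,
              abundance_weighted: bool = False,
              exclude_conspecifics: bool = False) -> float:
    """Mean inter-community nearest-taxon distance (Myr).

    For each species in plot a, take the minimum distance to any species in
    plot b, and vice versa.  Unweighted: mean over the pooled per-species
    minima of both directions.  Weighted: each direction's minima are
    averaged with that plot's relative coverages (weights summing to 1) and
    the two directional means are averaged, which keeps the metric symmetric
    under unequal richness.
    """
    ia, wa = _plot_vec(abund_a, dist)
    ib, wb = _plot_vec(abund_b, dist)
    D = dist.values[np.ix_(ia, ib)].copy()
    if exclude_conspecifics:
        D[ia[:, None] == ib[None, :]] = np.inf
    min_ab = D.min(axis=1)
    min_ba = D.min(axis=0)
    if np.isinf(min_ab).any() or np.isinf(min_ba).any():
        return float("nan")
    if abundance_weighted:
        pa, pb = wa / wa.sum(), wb / wb.sum()
        return float(0.5 * (np.sum(pa * min_ab) + np.sum(pb * min_ba)))
    return float((min_ab.sum() + min_ba.sum()) / (len(min_ab) + len(min_ba)))


def within_stage_pairs(cm: CommunityMatrix):
    """All unordered plot pairs sharing a succession stage.

    Returns a list of (plot_a, plot_b, stage); stages with fewer than two
    plots yield no pairs (logged).
    """
    pairs = []
    for stage, group in cm.plot_meta.groupby("stage"):
        plots = list(group.index)
        if len(plots) < 2:
            logger.warning("stage %d has %d plot(s); no within-stage pairs",
                           stage, len(plots))
            continue
        for a, b in itertools.combinations(plots, 2):
            pairs.append((a, b, int(stage)))
    return pairs


def beta_table(cm: CommunityMatrix, dist: DistanceMatrix,
               abundance_weighted: bool = False,
               exclude_conspecifics: bool = False) -> pd.DataFrame:
    """Pairwise within-stage beta metrics.

    Columns: plot_a, plot_b, stage, jaccard, comdist, comdistnt, weighting.
    """
    rows = []
    for a, b, stage in within_stage_pairs(cm):
        ra, rb = cm.wide.loc[a], cm.wide.loc[b]
        sa, sb = ra[ra > 0], rb[rb > 0]
        rows.append({
            "plot_a": a, "plot_b": b, "stage": stage,
            "jaccard": jaccard_dissimilarity(sa.index, sb.index),
            "comdist": comdist(sa, sb, dist, abundance_weighted,
                               exclude_conspecifics),
            "comdistnt": comdistnt(sa, sb, dist, abundance_weighted,
                                   exclude_conspecifics),
            "weighting": "abundance" if abundance_weighted else "occurrence",
        })
    return pd.DataFrame(rows)
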