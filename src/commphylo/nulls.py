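"""Independent-swap null models and standardized effect sizes.

The null model randomizes the plot x species occurrence matrix while holding
both margins fixed: each plot keeps its species richness and each species
keeps its occurrence frequency across plots.  That constraint is realized by
the trial-swap (independent swap) algorithm: repeatedly pick two plots and
two species at random and, whenever the 2x2 submatrix is a checkerboard
([[1,0],[0,1]] or [[0,1],[1,0]]), flip it.  A chain of such trials mixes over
the set of matrices sharing the observed margins; successive null samples are
taken from one chain after a burn-in of ``burnin_factor x fill`` trials and
separated by ``thin_factor x fill`` trials, where fill is the number of
occupied cells (a standard mixing heuristic, configurable).

Abundances ride along with the presence structure: when a checkerboard flips,
each affected plot's coverage value is reattached to the species that moved
in, so per-plot richness, species occurrence frequencies and every plot's
multiset of coverage values (hence its unit sum) are all preserved.  No
separate abundance null is needed.

Standardized indices follow the community-phylogenetics sign convention:

    NRI  = -(MPD_obs  - mean MPD_null)  / sd MPD_null
    NTI  = -(MNTD_obs - mean MNTD_null) / sd MNTD_null

so positive values mean co-occurring species are more closely related than
expected (phylogenetic clustering) and negative values mean overdispersion.
betaNRI / betaNTI apply the same construction to COMDIST / COMDISTNT for
plot pairs; negative values indicate higher-than-expected phylogenetic
turnover.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .seeding import derive_seed
from .tree import DistanceMatrix

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn
        return wrap

DEFAULT_N_RAND = 999
DEFAULT_BURNIN_FACTOR = 10
DEFAULT_THIN_FACTOR = 1


@dataclass(frozen=True)
class NullModelResult:
    """Observed metric, null distribution moments and standardized index."""

    target: object            # plot id or (plot_a, plot_b) pair
    metric: str               # MPD | MNTD | COMDIST | COMDISTNT
    index_name: str           # NRI | NTI | betaNRI | betaNTI
    observed: float
    null_mean: float
    null_sd: float
    index: float
    n_randomizations: int
    abundance_weighted: bool
    seed: int


# ---------------------------------------------------------------------------
# trial-swap kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _apply_trials(pres, abund, p1, p2, s1, s2):  # pragma: no cover - jitted
    n_swaps = 0
    for t in range(p1.shape[0]):
        a = p1[t]
        b = p2[t]
        c = s1[t]
        d = s2[t]
        if a == b or c == d:
            continue
        if pres[a, c] == 1 and pres[b, d] == 1 and pres[a, d] == 0 and pres[b, c] == 0:
            pres[a, c] = 0
            pres[b, d] = 0
            pres[a, d] = 1
            pres[b, c] = 1
            abund[a, d] = abund[a, c]
            abund[a, c] = 0.0
            abund[b, c] = abund[b, d]
            abund[b, d] = 0.0
            n_swaps += 1
        elif pres[a, d] == 1 and pres[b, c] == 1 and pres[a, c] == 0 and pres[b, d] == 0:
            pres[a, d] = 0
            pres[b, c] = 0
            pres[a, c] = 1
            pres[b, d] = 1
            abund[a, c] = abund[a, d]
            abund[a, d] = 0.0
            abund[b, d] = abund[b, c]
            abund[b, c] = 0.0
            n_swaps += 1
    return n_swaps


class SwapChain:
    """A running trial-swap chain over a presence (+ abundance) matrix."""

    def __init__(self, presence: np.ndarray, abundance: np.ndarray | None, seed: int):
        presence = np.asarray(presence)
        if not np.isin(presence, (0, 1)).all():
            raise ValueError("independent swap requires a binary presence matrix")
        self.pres = presence.astype(np.uint8).copy()
        if abundance is None:
            abundance = self.pres.astype(float)
        self.abund = np.asarray(abundance, dtype=float).copy()
        if self.abund.shape != self.pres.shape:
            raise ValueError("abundance and presence shapes differ")
        self.rng = np.random.default_rng(seed)
        self.fill = int(self.pres.sum())
        self.n_swaps = 0

    def advance(self, n_trials: int) -> None:
        if n_trials <= 0:
            return
        P, S = self.pres.shape
        p = self.rng.integers(0, P, size=(2, n_trials))
        s = self.rng.integers(0, S, size=(2, n_trials))
        self.n_swaps += _apply_trials(self.pres, self.abund, p[0], p[1], s[0], s[1])


def independent_swap(matrix, n_trials: int, seed: int = 0):
    """Return a margin-preserving randomization of a binary matrix.

    Performs ``n_trials`` trial swaps (random 2x2 checkerboard flips) on a
    copy of ``matrix``.  Row sums (plot richness) and column sums (species
    occurrence frequency) are preserved exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    chain = SwapChain(np.asarray(matrix), None, seed)
    chain.advance(int(n_trials))
    return chain.pres.copy()


# ---------------------------------------------------------------------------
# vectorized metric engines (used for observed values and every null sample)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mntd_all(pres, abund, D):  # pragma: no cover - jitted
    P, S = pres.shape
    out_u = np.full(P, np.nan)
    out_w = np.full(P, np.nan)
    for p in range(P):
        idx = np.flatnonzero(pres[p])
        k = idx.shape[0]
        if k < 2:
            continue
        su = 0.0
        sw = 0.0
        wtot = 0.0
        for ii in range(k):
            i = idx[ii]
            best = np.inf
            for jj in range(k):
                if jj == ii:
                    continue
                d = D[i, idx[jj]]
                if d < best:
                    best = d
            su += best
            sw += abund[p, i] * best
            wtot += abund[p, i]
        out_u[p] = su / k
        out_w[p] = sw / wtot
    return out_u, out_w


@njit(cache=True)
def _nearest_to_plots(pres, D):  # pragma: no cover - jitted
    """md[i, p] = min over species j present in plot p of D[i, j]."""
    P, S = pres.shape
    md = np.full((S, P), np.inf)
    for p in range(P):
        idx = np.flatnonzero(pres[p])
        for i in range(S):
            best = np.inf
            for jj in range(idx.shape[0]):
                d = D[i, idx[jj]]
                if d < best:
                    best = d
            md[i, p] = best
    return md


def _row_normalized(abund):
    tot = abund.sum(axis=1, keepdims=True)
    return np.divide(abund, tot, out=np.zeros_like(abund, dtype=float),
                     where=tot > 0)


def _mpd_all(pres, abund, D, abundance_weighted):
    Pf = pres.astype(float)
    k = Pf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if abundance_weighted:
            W = _row_normalized(abund)
            num = ((W @ D) * W).sum(axis=1)
            den = 1.0 - (W ** 2).sum(axis=1)
        else:
            num = ((Pf @ D) * Pf).sum(axis=1)
            den = k * (k - 1)
        out = num / den
    out[k < 2] = np.nan
    return out


def _alpha_metrics(pres, abund, D, abundance_weighted):
    mpd_vals = _mpd_all(pres, abund, D, abundance_weighted)
    mntd_u, mntd_w = _mntd_all(pres, abund, D)
    return mpd_vals, (mntd_w if abundance_weighted else mntd_u)


def _beta_metrics(pres, abund, D, ia, ib, abundance_weighted):
    """COMDIST and COMDISTNT for the plot-index pairs (ia, ib)."""
    Pf = pres.astype(float)
    k = Pf.sum(axis=1)
    W = _row_normalized(abund) if abundance_weighted else Pf / k[:, None]
    X = W @ D
    cd = (X[ia] * W[ib]).sum(axis=1)

    md = _nearest_to_plots(pres, D)
    if abundance_weighted:
        g_ab = (W[ia] * md[:, ib].T).sum(axis=1)   # sum_i in a w_i * min(i -> b)
        g_ba = (W[ib] * md[:, ia].T).sum(axis=1)
        cdnt = 0.5 * (g_ab + g_ba)
    else:
        g_ab = (Pf[ia] * md[:, ib].T).sum(axis=1)
        g_ba = (Pf[ib] * md[:, ia].T).sum(axis=1)
        cdnt = (g_ab + g_ba) / (k[ia] + k[ib])
    return cd, cdnt


# ---------------------------------------------------------------------------
# SES machinery
# ---------------------------------------------------------------------------

def _ses(obs, null_mean, null_sd):
    """Signed index -(obs - mean)/sd; 0 (with a warning) when sd degenerates."""
    out = np.full_like(np.asarray(obs, dtype=float), np.nan)
    obs = np.asarray(obs, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(null_mean)
    degenerate = ok & (null_sd <= 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} target(s) had a degenerate null (sd = 0); "
            "their index is reported as 0 and should be excluded from t-tests",
            RuntimeWarning, stacklevel=2)
    good = ok & (null_sd > 0)
    out[good] = -(obs[good] - null_mean[good]) / null_sd[good]
    out[degenerate] = 0.0
    return out


def _null_moments(sample_iter, obs_shape, n_rand):
    total = np.zeros(obs_shape)
    total_sq = np.zeros(obs_shape)
    count = np.zeros(obs_shape)
    for vals in sample_iter:
        finite = np.isfinite(vals)
        v = np.where(finite, vals, 0.0)
        total += v
        total_sq += v ** 2
        count += finite
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
        var = (total_sq - count * mean ** 2) / (count - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    sd[count < 2] = np.nan
    return mean, sd


def _prepare(cm: CommunityMatrix, dist: DistanceMatrix):
    D = dist.submatrix(list(cm.species)).values
    pres = cm.presence
    abund = cm.abundance
    return pres, abund, D


def ses_alpha(cm: CommunityMatrix, dist: DistanceMatrix,
              abundance_weighted: bool = False,
              n_rand: int = DEFAULT_N_RAND, seed: int = 0,
              burnin_factor: int = DEFAULT_BURNIN_FACTOR,
              thin_factor: int = DEFAULT_THIN_FACTOR) -> pd.DataFrame:
    """NRI and NTI for every plot against one shared swap-null ensemble.

    The randomized pool is the full supplied matrix (all plots, all species
    of the regional pool), as in the regional-pool convention: every null
    sample preserves plot richness and species occurrence frequencies.

    Returns a DataFrame indexed by plot with observed MPD/MNTD, null moments,
    NRI/NTI, and bookkeeping columns.  Identical seeds give bit-identical
    results.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    pres, abund, D = _prepare(cm, dist)
    obs_mpd, obs_mntd = _alpha_metrics(pres, abund, D, abundance_weighted)

    chain = SwapChain(pres, abund, seed)
    chain.advance(burnin_factor * chain.fill)

    def samples():
        for _ in range(n_rand):
            chain.advance(max(thin_factor * chain.fill, 1))
            yield np.stack(_alpha_metrics(chain.pres, chain.abund, D,
                                          abundance_weighted))

    mean, sd = _null_moments(samples(), (2, len(cm.plots)), n_rand)
    nri = _ses(obs_mpd, mean[0], sd[0])
    nti = _ses(obs_mntd, mean[1], sd[1])
    return pd.DataFrame({
        "stage": cm.stages.values,
        "mpd_obs": obs_mpd, "mpd_null_mean": mean[0], "mpd_null_sd": sd[0],
        "nri": nri,
        "mntd_obs": obs_mntd, "mntd_null_mean": mean[1], "mntd_null_sd": sd[1],
        "nti": nti,
        "n_rand": n_rand,
        "weighting": "abundance" if abundance_weighted else "occurrence",
        "seed": seed,
    }, index=cm.plots.rename("plot"))


def ses_beta(cm: CommunityMatrix, dist: DistanceMatrix, pairs=None,
             abundance_weighted: bool = False,
             n_rand: int = DEFAULT_N_RAND, seed: int = 0,
             burnin_factor: int = DEFAULT_BURNIN_FACTOR,
             thin_factor: int = DEFAULT_THIN_FACTOR) -> pd.DataFrame:
    """betaNRI and betaNTI for plot pairs against one shared null ensemble.

    ``pairs`` is a list of (plot_a, plot_b) or (plot_a, plot_b, stage)
    tuples; by default all within-stage pairs are used.
    """
    from .beta import within_stage_pairs
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if pairs is None:
        pairs = within_stage_pairs(cm)
    pairs = [tuple(p) for p in pairs]
    if not pairs:
        raise ValueError("no plot pairs to evaluate")
    pos = {p: i for i, p in enumerate(cm.plots)}
    ia = np.array([pos[p[0]] for p in pairs])
    ib = np.array([pos[p[1]] for p in pairs])
    stages = [p[2] if len(p) > 2 else None for p in pairs]

    pres, abund, D = _prepare(cm, dist)
    obs_cd, obs_cdnt = _beta_metrics(pres, abund, D, ia, ib, abundance_weighted)

    chain = SwapChain(pres, abund, seed)
    chain.advance(burnin_factor * chain.fill)

    def samples():
        for _ in range(n_rand):
            chain.advance(max(thin_factor * chain.fill, 1))
            yield np.stack(_beta_metrics(chain.pres, chain.abund, D, ia, ib,
                                         abundance_weighted))

    mean, sd = _null_moments(samples(), (2, len(pairs)), n_rand)
    beta_nri = _ses(obs_cd, mean[0], sd[0])
    beta_nti = _ses(obs_cdnt, mean[1], sd[1])
    return pd.DataFrame({
        "plot_a": [p[0] for p in pairs],
        "plot_b": [p[1] for p in pairs],
        "stage": stages,
        "comdist_obs": obs_cd,
        "comdist_null_mean": mean[0], "comdist_null_sd": sd[0],
        "beta_nri": beta_nri,
        "comdistnt_obs": obs_cdnt,
        "comdistnt_null_mean": mean[1], "comdistnt_null_sd": sd[1],
        "beta_nti": beta_nti,
        "n_rand": n_rand,
        "weighting": "abundance" if abundance_weighted else "occurrence",
        "seed": seed,
    })


# ---------------------------------------------------------------------------
# single-target convenience wrappers
# ---------------------------------------------------------------------------

def nri_nti(plot, cm: CommunityMatrix, dist: DistanceMatrix,
            n_rand: int = DEFAULT_N_RAND, abundance_weighted: bool = False,
            seed: int = 0, **kwargs):
    """(NRI, NTI) :class:`NullModelResult` pair for one plot.

    The null still randomizes the full regional matrix; the seed is a
    substream derived from ``seed`` and the plot id, so evaluating plots in
    any order (or in parallel) reproduces the same numbers.
    """
    if cm.richness.loc[plot] < 2:
        raise ValueError(f"plot {plot!r} has richness < 2; NRI/NTI undefined")
    sub = derive_seed(seed, "nri_nti", plot, int(abundance_weighted))
    table = ses_alpha(cm, dist, abundance_weighted=abundance_weighted,
                      n_rand=n_rand, seed=sub, **kwargs)
    row = table.loc[plot]
    mk = dict(target=plot, n_randomizations=n_rand,
              abundance_weighted=abundance_weighted, seed=sub)
    return (
        NullModelResult(metric="MPD", index_name="NRI", observed=row["mpd_obs"],
                        null_mean=row["mpd_null_mean"], null_sd=row["mpd_null_sd"],
                        index=row["nri"], **mk),
        NullModelResult(metric="MNTD", index_name="NTI", observed=row["mntd_obs"],
                        null_mean=row["mntd_null_mean"], null_sd=row["mntd_null_sd"],
                        index=row["nti"], **mk),
    )


def beta_nri_nti(pair, cm: CommunityMatrix, dist: DistanceMatrix,
                 n_rand: int = DEFAULT_N_RAND, abundance_weighted: bool = False,
                 seed: int = 0, **kwargs):
    """(betaNRI, betaNTI) :class:`NullModelResult` pair for one plot pair."""
    a, b = pair[0], pair[1]
    sub = derive_seed(seed, "beta_nri_nti", a, b, int(abundance_weighted))
    table = ses_beta(cm, dist, pairs=[(a, b)],
                     abundance_weighted=abundance_weighted,
                     n_rand=n_rand, seed=sub, **kwargs)
    row = table.iloc[0]
    mk = dict(target=(a, b), n_randomizations=n_rand,
              abundance_weighted=abundance_weighted, seed=sub)
    return (
        NullModelResult(metric="COMDIST", index_name="betaNRI",
                        observed=row["comdist_obs"],
                        null_mean=row["comdist_null_mean"],
                        null_sd=row["comdist_null_sd"],
                        index=row["beta_nri"], **mk),
        NullModelResult(metric="COMDISTNT", index_name="betaNTI",
                        observed=row["comdistnt_obs"],
                        null_mean=row["comdistnt_null_mean"],
                        null_sd=row["comdistnt_null_sd"],
                        index=row["beta_nti"], **mk),
    )
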