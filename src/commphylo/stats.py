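"""Stage-level inference: one-sample t-tests, one-way ANOVA and SNK letters.

Diversity metrics are compared across succession stages with one-way ANOVA
followed by the Student-Newman-Keuls (SNK) stepwise multiple-range procedure,
summarized as a compact letter display (stages sharing a letter are not
significantly different).  Standardized indices (NRI/NTI/betaNRI/betaNTI) are
tested against zero with two-tailed one-sample t-tests per stage.

SNK tests the range of every rank-ordered subset of group means against the
studentized-range distribution with range parameter r (the number of means
spanned) and the ANOVA error degrees of freedom; a non-significant range
closes all of its sub-ranges (the classic step-down protection).  Unbalanced
group sizes are handled with the harmonic mean of all group sizes, the usual
convention for range tests on unequal n.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Raised when a test is requested on data with no variance."""


def one_sample_t(values, mu: float = 0.0):
    """Two-tailed one-sample t-test; returns (t, df, p).

    NaNs are dropped.  Requires n >= 2 and positive variance (a constant
    vector is untestable and raises :class:`ZeroVarianceError`).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError(f"one_sample_t requires n >= 2 (got {len(x)})")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("zero variance: one-sample t-test is untestable")
    res = sps.ttest_1samp(x, popmean=mu)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


@dataclass
class SNKResult:
    """One-way ANOVA with Student-Newman-Keuls letter groups."""

    F: float
    p: float
    df_between: int
    df_error: int
    means: np.ndarray
    ns: np.ndarray
    letters: list = field(default_factory=list)
    degenerate: bool = False


def _letter_display(k: int, homogeneous: list) -> list:
    """Compact letters from homogeneous index ranges (i, j) over sorted groups."""
    # drop ranges contained in others
    maximal = [r for r in homogeneous
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in homogeneous)]
    maximal.sort()
    letters = [""] * k
    for letter, (i, j) in zip(itertools.cycle(string.ascii_lowercase), maximal):
        for g in range(i, j + 1):
            letters[g] += letter
    return letters


def anova_snk(groups, alpha: float = 0.05) -> SNKResult:
    """One-way ANOVA F-test plus SNK compact letter display.

    ``groups`` is a list of 1-D value vectors (NaNs dropped); letters are
    returned in the input group order, assigned from 'a' at the largest mean.
    When the pooled error variance is zero the ANOVA is degenerate: F and p
    are undefined and all groups share the letter 'a', with the
    ``degenerate`` flag set.
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    cleaned = [g[np.isfinite(g)] for g in cleaned]
    if len(cleaned) < 2:
        raise ValueError("anova_snk requires at least two groups")
    if any(len(g) < 2 for g in cleaned):
        raise ValueError("every group needs n >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    k = len(cleaned)
    ns = np.array([len(g) for g in cleaned])
    means = np.array([g.mean() for g in cleaned])
    n_total = int(ns.sum())
    df_between = k - 1
    df_error = n_total - k
    sse = float(sum(((g - g.mean()) ** 2).sum() for g in cleaned))
    mse = sse / df_error

    if mse <= 0:
        return SNKResult(F=float("nan"), p=float("nan"),
                         df_between=df_between, df_error=df_error,
                         means=means, ns=ns, letters=["a"] * k, degenerate=True)

    F, p = sps.f_oneway(*cleaned)

    # SNK on rank-ordered means, descending so 'a' labels the largest
    order = np.argsort(-means, kind="stable")
    sorted_means = means[order]
    n_h = k / np.sum(1.0 / ns)           # harmonic mean group size
    se = np.sqrt(mse / n_h)

    homogeneous = []

    def step(i, j):
        if i >= j:
            homogeneous.append((i, j))
            return
        r = j - i + 1
        q_obs = (sorted_means[i] - sorted_means[j]) / se
        q_crit = sps.studentized_range.ppf(1 - alpha, r, df_error)
        if q_obs > q_crit:
            step(i, j - 1)
            step(i + 1, j)
        else:
            homogeneous.append((i, j))

    step(0, k - 1)
    letters_sorted = _letter_display(k, list(set(homogeneous)))
    letters = [""] * k
    for rank, gi in enumerate(order):
        letters[gi] = letters_sorted[rank]
    return SNKResult(F=float(F), p=float(p), df_between=df_between,
                     df_error=df_error, means=means, ns=ns, letters=letters)


# ---------------------------------------------------------------------------
# stage-level summary tables
# ---------------------------------------------------------------------------

def _stage_groups(df: pd.DataFrame, value_col: str, stage_col: str = "stage"):
    groups = {}
    for stage, sub in df.groupby(stage_col):
        vals = pd.to_numeric(sub[value_col], errors="coerce").dropna().values
        groups[int(stage)] = vals
    return dict(sorted(groups.items()))


def summarize_stages_anova(df: pd.DataFrame, value_col: str,
                           stage_col: str = "stage",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-stage mean +/- SD with SNK letters for one diversity metric.

    Rows: one per stage (n, mean, sd, letter); the ANOVA F, p and dfs are
    repeated on every row for convenience.  Stages with fewer than two
    non-missing values are excluded from the ANOVA (logged) and reported
    without a letter.
    """
    groups = _stage_groups(df, value_col, stage_col)
    usable = {s: v for s, v in groups.items() if len(v) >= 2}
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        logger.warning("stages %s have < 2 values for %s; excluded from ANOVA",
                       skipped, value_col)
    res = anova_snk(list(usable.values()), alpha=alpha) if len(usable) >= 2 else None
    rows = []
    for stage, vals in groups.items():
        row = {"stage": stage, "metric": value_col, "n": len(vals),
               "mean": np.mean(vals) if len(vals) else np.nan,
               "sd": np.std(vals, ddof=1) if len(vals) > 1 else np.nan,
               "letter": "", "F": np.nan, "p": np.nan, "degenerate": False}
        if res is not None and stage in usable:
            row["letter"] = res.letters[list(usable).index(stage)]
            row["F"], row["p"], row["degenerate"] = res.F, res.p, res.degenerate
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_stages_ttest(df: pd.DataFrame, value_col: str,
                           stage_col: str = "stage", mu: float = 0.0,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-stage two-tailed one-sample t-tests of an index against ``mu``.

    Stages with fewer than two values, or zero variance, are flagged
    untestable (t and p reported as NaN).
    """
    rows = []
    for stage, vals in _stage_groups(df, value_col, stage_col).items():
        row = {"stage": stage, "metric": value_col, "n": len(vals),
               "mean": np.mean(vals) if len(vals) else np.nan,
               "sd": np.std(vals, ddof=1) if len(vals) > 1 else np.nan,
               "t": np.nan, "df": np.nan, "p": np.nan,
               "significant": False, "untestable": False}
        try:
            t, dfree, p = one_sample_t(vals, mu=mu)
            row.update(t=t, df=dfree, p=p, significant=bool(p < alpha))
        except (ValueError, ZeroVarianceError):
            row["untestable"] = True
        rows.append(row)
    return pd.DataFrame(rows)
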