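"""Group summaries and factorial comparisons for clamp cohorts.

Endpoints are summarized as mean +/- SEM per diet-by-consciousness group and
compared with pooled-variance Student t tests or a two-way ANOVA (diet x
anesthesia, with interaction) followed by Tukey HSD pairwise comparisons of
the four cell means.  Sums of squares default to Type II, the standard
choice for an unbalanced factorial (e.g. 16/16/16/8) when main effects are
of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupSummary",
    "AnovaTable",
    "TTestResult",
    "summarize_groups",
    "two_way_anova",
    "unpaired_t_test",
    "paired_t_test",
]

#: endpoints summarized by default when present
DEFAULT_ENDPOINTS = ("Rd_basal", "Rd_SS", "EGP_basal", "EGP_SS",
                     "SI_P", "SI_H", "MCR")


@dataclass
class GroupSummary:
    """Per-group n and mean/SEM for each endpoint.

    ``stats`` maps endpoint name to ``(mean, sem)``; SEM is NaN (undefined)
    for a single-animal group, never reported as 0.
    """

    label: str
    n: int
    stats: dict[str, tuple[float, float]]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float

    def __iter__(self):
        yield from (self.t, self.df, self.p)


@dataclass
class AnovaTable:
    """Two-way ANOVA decomposition plus Tukey pairwise comparisons.

    ``table`` has rows diet / anesthesia / interaction / residual with
    columns sum_sq, df, F, p; ``tukey`` lists the pairwise cell contrasts
    with Tukey-adjusted p values.
    """

    table: pd.DataFrame
    tukey: pd.DataFrame
    ss_type: int

    def to_json_dict(self) -> dict:
        return {
            "ss_type": self.ss_type,
            "anova": self.table.reset_index()
                     .rename(columns={"index": "term"}).to_dict(orient="records"),
            "tukey": self.tukey.to_dict(orient="records"),
        }


def summarize_groups(results: pd.DataFrame,
                     endpoints: tuple[str, ...] | None = None,
                     group_col: str = "group") -> list[GroupSummary]:
    """Per-group mean and SEM (SD/sqrt(n)) for each endpoint column.

    ``results`` is a tidy frame with one row per animal.  If ``group_col``
    is absent but ``diet`` and ``state`` are present, groups are their
    combination.
    """
    df = results.copy()
    if group_col not in df.columns:
        if {"diet", "state"} <= set(df.columns):
            df[group_col] = df["diet"].astype(str) + ":" + df["state"].astype(str)
        else:
            raise ValueError(f"no '{group_col}' column and no diet/state columns")
    if endpoints is None:
        endpoints = tuple(c for c in DEFAULT_ENDPOINTS if c in df.columns)
        if not endpoints:
            raise ValueError("no known endpoint columns found")
    out = []
    for label, sub in df.groupby(group_col, sort=True):
        n = len(sub)
        stats_d = {}
        for ep in endpoints:
            vals = sub[ep].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            stats_d[ep] = (mean, sem)
        out.append(GroupSummary(label=str(label), n=n, stats=stats_d))
    return out


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Sum-coded (effects) contrast columns; last level as reference.

    Sum coding leaves Type II sums of squares unchanged relative to any
    full-rank coding and is the coding under which Type III tests the
    conventional main-effect hypotheses.
    """
    levels = np.unique(labels)
    cols = []
    for lv in levels[:-1]:
        col = np.where(labels == lv, 1.0, 0.0)
        col[labels == levels[-1]] = -1.0
        cols.append(col)
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of an OLS fit and the model's rank."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def two_way_anova(values, diet, anesthesia, ss_type: int = 2,
                  tukey: bool = True) -> AnovaTable:
    """Diet x anesthesia ANOVA with interaction and Tukey HSD on cell means.

    Sums of squares come from explicit model comparisons on sum-coded
    design matrices: Type II tests each main effect adjusted for the other
    (ignoring the interaction), the standard choice for unbalanced factorial
    main effects; Type III adjusts for all other terms.  The interaction
    term is dropped (with a warning) when a design cell is empty.  Tukey
    comparisons use the one-way residual mean square across the cells,
    which equals the full factorial model's residual.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(diet).astype(str)
    a = np.asarray(anesthesia).astype(str)
    if np.isnan(y).any():
        raise ValueError("values contain NaN")
    if not (len(y) == len(d) == len(a)):
        raise ValueError("values and factor labels must have equal length")
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    cells = np.char.add(np.char.add(d, ":"), a)
    n_cells = len(np.unique(cells))
    if n_cells < 2:
        raise ValueError("need at least 2 populated design cells")
    full_grid = len(np.unique(d)) * len(np.unique(a))
    with_interaction = n_cells == full_grid
    if not with_interaction:
        warnings.warn("empty design cell: interaction term dropped",
                      RuntimeWarning, stacklevel=2)

    n = len(y)
    ones = np.ones((n, 1))
    A = _dummies(d)
    B = _dummies(a)
    AB = (np.repeat(A, B.shape[1], axis=1) * np.tile(B, (1, A.shape[1]))
          if with_interaction else np.empty((n, 0)))
    X_full = np.hstack([ones, A, B, AB])
    rss_full, rank_full = _rss(X_full, y)
    df_resid = n - rank_full
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom; add observations per cell")
    ms_resid = rss_full / df_resid

    rss_ab, _ = _rss(np.hstack([ones, A, B]), y)
    if ss_type == 2:
        # each main effect adjusted for the other, ignoring the interaction
        ss_A = _rss(np.hstack([ones, B]), y)[0] - rss_ab
        ss_B = _rss(np.hstack([ones, A]), y)[0] - rss_ab
    else:
        ss_A = _rss(np.hstack([ones, B, AB]), y)[0] - rss_full
        ss_B = _rss(np.hstack([ones, A, AB]), y)[0] - rss_full
    ss_AB = rss_ab - rss_full if with_interaction else np.nan

    rows = {"diet": (ss_A, A.shape[1]), "anesthesia": (ss_B, B.shape[1])}
    if with_interaction:
        rows["interaction"] = (ss_AB, AB.shape[1])
    table = pd.DataFrame(
        [{"sum_sq": max(ss, 0.0), "df": float(dfq),
          "F": (max(ss, 0.0) / dfq) / ms_resid if ms_resid > 0 else np.inf,
          "p": float(sps.f.sf((max(ss, 0.0) / dfq) / ms_resid, dfq, df_resid))
          if ms_resid > 0 else 0.0}
         for ss, dfq in rows.values()],
        index=list(rows),
    )
    table.loc["residual"] = [rss_full, float(df_resid), np.nan, np.nan]

    if tukey:
        tk = pairwise_tukeyhsd(y, cells)
        tukey_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        tukey_df = tukey_df.rename(columns={"p-adj": "p_adj"})
    else:
        tukey_df = pd.DataFrame()
    return AnovaTable(table=table, tukey=tukey_df, ss_type=ss_type)


def unpaired_t_test(group_a, group_b) -> TTestResult:
    """Two-sided pooled-variance (Student) t test.

    Degenerate zero-variance data follow the documented convention:
    equal means give p = 1, unequal means give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    diff = np.mean(a) - np.mean(b)
    if pooled == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=float(np.sign(diff)) * float("inf"), df=df, p=0.0)
    t = diff / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def paired_t_test(before, after) -> TTestResult:
    """Two-sided paired t test on within-animal differences."""
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = np.std(d, ddof=1)
    df = n - 1
    if sd == 0:
        return TTestResult(t=0.0, df=df, p=1.0) if np.mean(d) == 0 else \
            TTestResult(t=float(np.sign(np.mean(d))) * float("inf"), df=df, p=0.0)
    t = np.mean(d) / (sd / np.sqrt(n))
    return TTestResult(t=float(t), df=df, p=float(2.0 * sps.t.sf(abs(t), df)))
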