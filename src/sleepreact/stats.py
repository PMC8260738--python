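"""Repeated-measures ANOVA, planned contrasts, and correlation utilities.

The ANOVA is the classical univariate sums-of-squares decomposition for
balanced within-subject (optionally split-plot, with one between-subjects
factor) designs, with the subject strata as error terms: each
within-subject effect is tested against its interaction with subjects
(nested in groups when a between factor is present). No sphericity
correction is applied by default; a Greenhouse-Geisser option is provided.
All p-values are two-sided.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    table: pd.DataFrame     # effect, SS, df1, df2, MS, F, p [, eps_gg, p_gg]

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


class DesignMatrixError(ValueError):
    pass


def _u(df: pd.DataFrame, cols: tuple[str, ...], dv: str) -> float:
    """Sum over cells of (cell total)^2 / (cell size) for a balanced design."""
    if not cols:
        return df[dv].sum() ** 2 / len(df)
    g = df.groupby(list(cols), observed=True)[dv]
    return float((g.sum() ** 2 / g.size()).sum())


def _check_balance(df, dv, subject, within, between):
    cells = df.groupby([subject] + within, observed=True)[dv].size()
    full = df[subject].nunique() * int(np.prod([df[w].nunique() for w in within]))
    if len(cells) != full or cells.nunique() != 1 or cells.iloc[0] != 1:
        bad = cells[cells != cells.mode().iloc[0]]
        which = bad.index[0] if len(bad) else "missing subject x within cell"
        raise DesignMatrixError(f"unbalanced design at cell {which}")
    if between is not None:
        per_subj = df.groupby(subject, observed=True)[between].nunique()
        if (per_subj != 1).any():
            raise DesignMatrixError("between-subjects factor varies within a subject")
        sizes = df.drop_duplicates(subject).groupby(between, observed=True)[subject].size()
        if sizes.nunique() != 1:
            raise DesignMatrixError("between-subjects groups are not equally sized")


def _gg_epsilon(df, dv, subject, effect_cols):
    """Greenhouse-Geisser epsilon for one within effect, from the covariance
    of the subject x cell score matrix (cells = level combinations of the
    effect, averaged over any other factors)."""
    wide = df.pivot_table(index=subject, columns=effect_cols, values=dv, observed=True)
    k = wide.shape[1]
    if k < 3:
        return 1.0
    s = np.cov(wide.to_numpy(), rowvar=False)
    h = np.eye(k) - np.ones((k, k)) / k
    dsc = h @ s @ h
    num = np.trace(dsc) ** 2
    den = (k - 1) * np.sum(dsc * dsc)
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: list[str] | None = None,
    between: str | None = None,
    gg_correction: bool = False,
) -> AnovaResult:
    """Balanced repeated-measures (optionally split-plot) ANOVA.

    ``within`` lists within-subject factor columns; ``between`` names at
    most one between-subjects factor (subjects nested in its groups). Each
    subject must contribute exactly one value per within-cell.
    """
    within = list(within or [])
    if not within and between is None:
        raise DesignMatrixError("at least one factor is required")
    df = data.copy()
    _check_balance(df, dv, subject, within, between)

    n = df[subject].nunique()
    g = df[between].nunique() if between else 1
    levels = {w: df[w].nunique() for w in within}

    def U(*cols):
        return _u(df, tuple(cols), dv)

    rows = []

    if between is not None:
        ss_b = U(between) - U()
        ss_sb = U(subject) - U(between)
        df_b, df_sb = g - 1, n - g
        f = (ss_b / df_b) / (ss_sb / df_sb) if ss_sb > 0 else 0.0
        rows.append((between, ss_b, df_b, df_sb, f, sps.f.sf(f, df_b, df_sb) if f > 0 else 1.0, None))

    for r in range(1, len(within) + 1):
        for eff in itertools.combinations(within, r):
            sub = list(eff)

            def ie(term):  # inclusion-exclusion over subsets of the effect
                tot = 0.0
                for rr in range(len(sub) + 1):
                    for a in itertools.combinations(sub, rr):
                        tot += (-1) ** (len(sub) - len(a)) * term(a)
                return tot

            ss_e = ie(lambda a: U(*a))
            base = (lambda a: U(*a, between)) if between else (lambda a: U(*a))
            ss_err = ie(lambda a: U(*a, subject) - base(a))
            df_e = int(np.prod([levels[w] - 1 for w in eff]))
            df_err = df_e * (n - g)
            ms_err = ss_err / df_err if df_err > 0 else np.nan
            f = (ss_e / df_e) / ms_err if ms_err and ms_err > 0 else 0.0
            p = sps.f.sf(f, df_e, df_err) if f > 0 else 1.0
            eps = _gg_epsilon(df, dv, subject, sub) if gg_correction else None
            rows.append((" x ".join(eff), ss_e, df_e, df_err, f, p, eps))

            if between is not None:
                ss_i = ie(lambda a: U(*a, between) - U(*a))
                df_i = df_e * (g - 1)
                f_i = (ss_i / df_i) / ms_err if ms_err and ms_err > 0 else 0.0
                p_i = sps.f.sf(f_i, df_i, df_err) if f_i > 0 else 1.0
                rows.append((" x ".join(eff) + f" x {between}", ss_i, df_i, df_err, f_i, p_i, eps))

    table = pd.DataFrame(rows, columns=["effect", "SS", "df1", "df2", "F", "p", "eps_gg"])
    table["MS"] = table["SS"] / table["df1"]
    if gg_correction:
        corr = table["eps_gg"].fillna(1.0)
        table["p_gg"] = sps.f.sf(table["F"], corr * table["df1"], corr * table["df2"])
    else:
        table = table.drop(columns=["eps_gg"])
    return AnovaResult(table=table[[c for c in ["effect", "SS", "df1", "df2", "MS", "F", "p", "eps_gg", "p_gg"] if c in table]])


def planned_comparison(
    data: pd.DataFrame,
    factor: str,
    levels: tuple[str, str],
    dv: str = "value",
    subject: str = "subject",
    at: dict | None = None,
) -> tuple[float, int, float]:
    """Paired two-level contrast at fixed levels of other factors.

    Returns ``(F, df2, p)`` with F(1, n-1) equal to the squared paired-t
    statistic and a two-sided p.
    """
    df = data.copy()
    for col, lev in (at or {}).items():
        df = df[df[col] == lev]
    a = df[df[factor] == levels[0]].groupby(subject, observed=True)[dv].mean()
    b = df[df[factor] == levels[1]].groupby(subject, observed=True)[dv].mean()
    common = a.index.intersection(b.index)
    if len(common) < len(a.index.union(b.index)):
        missing = sorted(set(a.index.union(b.index)) - set(common))
        raise DesignMatrixError(f"subject(s) missing a level: {missing}")
    if len(common) < 2:
        raise DesignMatrixError("need at least 2 subjects")
    d = a.loc[common].to_numpy() - b.loc[common].to_numpy()
    n = len(d)
    if np.isclose(d.std(ddof=1), 0):
        # degenerate paired differences: no effect if the constant is zero,
        # a perfectly reliable one otherwise
        if np.isclose(d.mean(), 0):
            return 0.0, n - 1, 1.0
        return float("inf"), n - 1, 0.0
    t, p = sps.ttest_rel(a.loc[common], b.loc[common])
    return float(t**2), n - 1, float(p)


from functools import lru_cache


@lru_cache(maxsize=4)
def _perm_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (midranks, n <= 10)."""
    n = len(xr)
    xc = xr - xr.mean()
    sy = yr.std()
    sx = xc.std()
    thresh = abs(rho) - 1e-12
    count = 0
    total = 0
    if n <= 8:
        yp = yr[_perm_indices(n)]
        r = ((yp - yr.mean()) @ xc / n) / (sx * sy)
        return float(np.mean(np.abs(r) >= thresh))
    batch: list[tuple] = []

    def flush(rows):
        nonlocal count, total
        yp = np.asarray(rows)
        r = ((yp - yr.mean()) @ xc / n) / (sx * sy)
        count += int(np.sum(np.abs(r) >= thresh))
        total += len(rows)

    for perm in itertools.permutations(yr):
        batch.append(perm)
        if len(batch) >= 200_000:
            flush(batch)
            batch = []
    if batch:
        flush(batch)
    return count / total


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p is an exact two-sided permutation p when n <= ``exact_max_n``, else
    the usual t-approximation. Returns ``(nan, nan)`` with a warning for
    zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance input: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p_t = sps.spearmanr(x, y)
    if n <= exact_max_n:
        xr = sps.rankdata(x)
        yr = sps.rankdata(y)
        return float(rho), float(_exact_spearman_p(xr, yr, rho))
    return float(rho), float(p_t)


def fisher_z(rho: float) -> float:
    """Variance-stabilizing atanh transform; |rho| clamped to 1 - 1e-7."""
    r = np.clip(rho, -(1 - 1e-7), 1 - 1e-7)
    return float(np.arctanh(r))
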