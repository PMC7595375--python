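"""Balanced within-subject (repeated-measures) ANOVA and simple contrasts.

Implements the univariate decomposition for a fully balanced two-way
within-subject design with one observation per subject x cell: each effect
(factor A, factor B, A x B) is tested against its own subject-by-effect
error stratum.  Effect size is eta squared (effect SS over total SS).
Simple contrasts compare each level of a factor against a fixed reference
level, with the standard error taken from that factor's error stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnbalancedDesignError",
    "AnovaResult",
    "ContrastResult",
    "check_balanced",
    "rm_anova_2way",
    "rm_anova_1way",
    "simple_contrasts",
    "single_level_posthoc",
    "normalize_outcomes",
]


class UnbalancedDesignError(ValueError):
    """Design is not balanced/complete; no imputation is attempted."""


@dataclass(frozen=True)
class AnovaResult:
    """Within-subject ANOVA table: one row per effect or residual stratum."""

    table: pd.DataFrame  # columns: effect, ss, df, ms, F, p, eta_sq
    n_subjects: int
    factor_levels: dict  # factor name -> ordered levels
    gg_epsilon: Optional[dict] = None  # effect -> Greenhouse-Geisser epsilon

    def row(self, effect: str) -> pd.Series:
        match = self.table[self.table["effect"] == effect]
        if match.empty:
            raise KeyError(f"no effect {effect!r} in ANOVA table")
        return match.iloc[0]


@dataclass(frozen=True)
class ContrastResult:
    """Simple contrasts of factor levels versus a reference level."""

    table: pd.DataFrame  # columns: comparison, level, reference, estimate, se, t, df, p
    factor: str
    reference: str
    error_ms: float
    error_df: int

    def row(self, level: str) -> pd.Series:
        match = self.table[self.table["level"] == level]
        if match.empty:
            raise KeyError(f"no contrast for level {level!r}")
        return match.iloc[0]


def _levels(series: pd.Series) -> List:
    """Levels in order of first appearance (stable across subjects)."""
    return list(pd.unique(series))


def check_balanced(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
) -> None:
    """Raise :class:`UnbalancedDesignError` unless every subject x cell
    combination has exactly one observation."""
    for col in (dv, subject, *within):
        if col not in data.columns:
            raise KeyError(f"column {col!r} missing from outcome table")
    counts = data.groupby([subject, *within], observed=True, sort=False).size()
    expected = len(_levels(data[subject]))
    for f in within:
        expected *= len(_levels(data[f]))
    if len(counts) != expected or (counts != 1).any():
        bad = counts[counts != 1]
        detail = (
            f"cells with counts != 1: {bad.to_dict()}"
            if len(bad)
            else f"{expected - len(counts)} missing cells"
        )
        raise UnbalancedDesignError(
            f"design is not balanced/complete ({detail}); refusing to impute"
        )
    if data[dv].isna().any():
        raise UnbalancedDesignError("outcome column contains missing values")


def _gg_epsilon(cell_matrix: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an n_subjects x k matrix of cell values."""
    k = cell_matrix.shape[1]
    s = np.cov(cell_matrix, rowvar=False, ddof=1)
    # double-centered covariance
    s = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(s) ** 2
    den = (k - 1) * np.sum(s * s)
    return float(num / den) if den > 0 else 1.0


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: Tuple[str, str] = ("visual", "platform"),
    greenhouse_geisser: bool = False,
) -> AnovaResult:
    """Two-way fully within-subject ANOVA on a balanced outcome table.

    Each of the effects A, B and A x B is tested with an F ratio against its
    subject-by-effect interaction mean square; in the balanced complete case
    this univariate decomposition coincides with the Type III analysis.
    """
    fa, fb = within
    check_balanced(data, dv, subject, within)
    subjects = _levels(data[subject])
    la, lb = _levels(data[fa]), _levels(data[fb])
    n, a, b = len(subjects), len(la), len(lb)
    if n < 2:
        raise UnbalancedDesignError(f"need >= 2 subjects, got {n}")
    if a < 2 or b < 2:
        raise ValueError("each within-subject factor needs >= 2 levels")

    # y[s, i, j]
    wide = data.pivot_table(
        index=subject, columns=[fa, fb], values=dv, observed=True, sort=False
    )
    y = np.empty((n, a, b))
    for i, va in enumerate(la):
        for j, vb in enumerate(lb):
            y[:, i, j] = wide[(va, vb)].loc[subjects].to_numpy()

    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_total = float(np.sum((y - g) ** 2))
    ss_subj = a * b * float(np.sum((m_s - g) ** 2))
    ss_a = n * b * float(np.sum((m_a - g) ** 2))
    ss_b = n * a * float(np.sum((m_b - g) ** 2))
    ss_ab = n * float(
        np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    )
    ss_as = b * float(
        np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
    )
    ss_bs = a * float(
        np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
    )
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    effects = [
        (fa, ss_a, a - 1, ss_as, (n - 1) * (a - 1)),
        (fb, ss_b, b - 1, ss_bs, (n - 1) * (b - 1)),
        (f"{fa} * {fb}", ss_ab, (a - 1) * (b - 1), ss_abs, (n - 1) * (a - 1) * (b - 1)),
    ]

    gg = None
    if greenhouse_geisser:
        cells = {
            fa: m_sa,
            fb: m_sb,
            f"{fa} * {fb}": y.reshape(n, a * b),
        }
        gg = {name: _gg_epsilon(cells[name]) for name, *_ in effects}

    rows = []
    for name, ss_e, df_e, ss_r, df_r in effects:
        ms_e, ms_r = ss_e / df_e, ss_r / df_r
        if ms_r > 0:
            fval = ms_e / ms_r
        else:
            fval = np.nan if ms_e == 0 else np.inf
        df_num, df_den = df_e, df_r
        if gg is not None:
            eps = gg[name]
            df_num, df_den = eps * df_e, eps * df_r
        if np.isnan(fval):
            p = np.nan
        elif np.isinf(fval):
            p = 0.0
        else:
            p = float(stats.f.sf(fval, df_num, df_den))
        rows.append(
            {"effect": name, "ss": ss_e, "df": df_e, "ms": ms_e,
             "F": fval, "p": p, "eta_sq": ss_e / ss_total if ss_total > 0 else 0.0}
        )
        rows.append(
            {"effect": f"Residual ({name})", "ss": ss_r, "df": df_r,
             "ms": ms_r, "F": np.nan, "p": np.nan, "eta_sq": np.nan}
        )
    rows.append(
        {"effect": "subject", "ss": ss_subj, "df": n - 1,
         "ms": ss_subj / (n - 1), "F": np.nan, "p": np.nan, "eta_sq": np.nan}
    )
    return AnovaResult(
        table=pd.DataFrame(rows),
        n_subjects=n,
        factor_levels={fa: la, fb: lb},
        gg_epsilon=gg,
    )


def rm_anova_1way(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "visual",
    greenhouse_geisser: bool = False,
) -> AnovaResult:
    """One-way within-subject ANOVA on a balanced outcome table."""
    check_balanced(data, dv, subject, [within])
    subjects = _levels(data[subject])
    la = _levels(data[within])
    n, a = len(subjects), len(la)
    if n < 2:
        raise UnbalancedDesignError(f"need >= 2 subjects, got {n}")
    if a < 2:
        raise ValueError("within-subject factor needs >= 2 levels")

    wide = data.pivot_table(
        index=subject, columns=within, values=dv, observed=True, sort=False
    )
    y = wide[la].loc[subjects].to_numpy()  # n x a

    g = y.mean()
    m_s = y.mean(axis=1)
    m_a = y.mean(axis=0)
    ss_total = float(np.sum((y - g) ** 2))
    ss_subj = a * float(np.sum((m_s - g) ** 2))
    ss_a = n * float(np.sum((m_a - g) ** 2))
    ss_as = ss_total - ss_subj - ss_a
    ss_as = max(ss_as, 0.0)
    df_a, df_r = a - 1, (n - 1) * (a - 1)
    ms_a, ms_r = ss_a / df_a, ss_as / df_r
    if ms_r > 0:
        fval = ms_a / ms_r
    else:
        fval = np.nan if ms_a == 0 else np.inf

    gg = None
    df_num, df_den = df_a, df_r
    if greenhouse_geisser:
        eps = _gg_epsilon(y)
        gg = {within: eps}
        df_num, df_den = eps * df_a, eps * df_r
    if np.isnan(fval):
        p = np.nan
    elif np.isinf(fval):
        p = 0.0
    else:
        p = float(stats.f.sf(fval, df_num, df_den))

    rows = [
        {"effect": within, "ss": ss_a, "df": df_a, "ms": ms_a, "F": fval,
         "p": p, "eta_sq": ss_a / ss_total if ss_total > 0 else 0.0},
        {"effect": f"Residual ({within})", "ss": ss_as, "df": df_r, "ms": ms_r,
         "F": np.nan, "p": np.nan, "eta_sq": np.nan},
        {"effect": "subject", "ss": ss_subj, "df": n - 1,
         "ms": ss_subj / (n - 1), "F": np.nan, "p": np.nan, "eta_sq": np.nan},
    ]
    return AnovaResult(
        table=pd.DataFrame(rows),
        n_subjects=n,
        factor_levels={within: la},
        gg_epsilon=gg,
    )


def simple_contrasts(
    data: pd.DataFrame,
    factor: str = "visual",
    reference: str = "EO",
    dv: str = "value",
    subject: str = "subject",
    other: Optional[str] = None,
) -> ContrastResult:
    """Simple contrasts of each level of ``factor`` against ``reference``.

    The estimate is the mean over subjects of the per-subject (level -
    reference) difference, averaging over the other within-subject factor if
    present.  The SE uses the subject-by-factor error stratum:
    ``SE = sqrt(2 * MS_err / (n * b))`` with ``b`` levels of the other factor
    and error df ``(n - 1) * (a - 1)``.
    """
    within = [factor] if other is None else [factor, other]
    check_balanced(data, dv, subject, within)
    levels = _levels(data[factor])
    if reference not in levels:
        raise ValueError(
            f"reference level {reference!r} not among factor levels {levels}"
        )
    if other is None:
        res = rm_anova_1way(data, dv=dv, subject=subject, within=factor)
        b = 1
    else:
        res = rm_anova_2way(data, dv=dv, subject=subject, within=(factor, other))
        b = len(res.factor_levels[other])
    err = res.row(f"Residual ({factor})")
    ms_err, df_err = float(err["ms"]), int(err["df"])
    n = res.n_subjects

    # per-subject level means averaged over the other factor
    subj_means = data.groupby([subject, factor], observed=True, sort=False)[dv].mean()
    se = float(np.sqrt(2.0 * ms_err / (n * b)))
    rows = []
    for level in levels:
        if level == reference:
            continue
        diffs = (
            subj_means.xs(level, level=factor) - subj_means.xs(reference, level=factor)
        )
        est = float(diffs.mean())
        t = est / se if se > 0 else (0.0 if est == 0 else np.inf)
        p = float(2 * stats.t.sf(abs(t), df_err)) if np.isfinite(t) else 0.0
        rows.append(
            {"comparison": f"{level} - {reference}", "level": level,
             "reference": reference, "estimate": est, "se": se, "t": t,
             "df": df_err, "p": p}
        )
    return ContrastResult(
        table=pd.DataFrame(rows),
        factor=factor,
        reference=reference,
        error_ms=ms_err,
        error_df=df_err,
    )


def single_level_posthoc(
    data: pd.DataFrame,
    platform_level,
    platform: str = "platform",
    factor: str = "visual",
    reference: str = "EO",
    dv: str = "value",
    subject: str = "subject",
) -> Tuple[AnovaResult, ContrastResult]:
    """One-way RM-ANOVA over ``factor`` restricted to one level of the other
    factor, plus simple contrasts versus ``reference``."""
    if platform_level not in set(data[platform]):
        raise ValueError(
            f"platform level {platform_level!r} not present in column {platform!r}"
        )
    sub = data[data[platform] == platform_level]
    res = rm_anova_1way(sub, dv=dv, subject=subject, within=factor)
    con = simple_contrasts(
        sub, factor=factor, reference=reference, dv=dv, subject=subject
    )
    return res, con


def normalize_outcomes(
    data: pd.DataFrame,
    by: str = "platform",
    dv: str = "value",
    method: str = "zscore",
) -> pd.DataFrame:
    """Make outcome columns of different units commensurable before a
    combined ANOVA: per level of ``by``, z-score (default), log-transform,
    or pass through raw values."""
    out = data.copy()
    if method == "raw":
        return out
    if method == "log":
        if (out[dv] <= 0).any():
            raise ValueError("log normalization requires strictly positive outcomes")
        out[dv] = np.log(out[dv])
        return out
    if method == "zscore":
        def _z(x):
            sd = x.std(ddof=1)
            return (x - x.mean()) / sd if sd > 0 else x - x.mean()

        out[dv] = out.groupby(by, observed=True, sort=False)[dv].transform(_z)
        return out
    raise ValueError(f"unknown normalization method {method!r}")
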