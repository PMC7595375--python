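"""Independent brute-force oracles used by the tests.

Deliberately written with plain Python loops and textbook definitions,
independent of the implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_rm2(y: np.ndarray) -> dict:
    """Within-subject two-way decomposition of y[subject, a, b] by loops."""
    n, a, b = y.shape
    grand = sum(y[s, i, j] for s in range(n) for i in range(a) for j in range(b)) / (
        n * a * b
    )
    ms = [sum(y[s, i, j] for i in range(a) for j in range(b)) / (a * b) for s in range(n)]
    ma = [sum(y[s, i, j] for s in range(n) for j in range(b)) / (n * b) for i in range(a)]
    mb = [sum(y[s, i, j] for s in range(n) for i in range(a)) / (n * a) for j in range(b)]
    mab = [[sum(y[s, i, j] for s in range(n)) / n for j in range(b)] for i in range(a)]
    msa = [[sum(y[s, i, j] for j in range(b)) / b for i in range(a)] for s in range(n)]
    msb = [[sum(y[s, i, j] for i in range(a)) / a for j in range(b)] for s in range(n)]

    ss_total = sum(
        (y[s, i, j] - grand) ** 2 for s in range(n) for i in range(a) for j in range(b)
    )
    ss_subj = a * b * sum((m - grand) ** 2 for m in ms)
    ss_a = n * b * sum((m - grand) ** 2 for m in ma)
    ss_b = n * a * sum((m - grand) ** 2 for m in mb)
    ss_ab = n * sum(
        (mab[i][j] - ma[i] - mb[j] + grand) ** 2 for i in range(a) for j in range(b)
    )
    ss_as = b * sum(
        (msa[s][i] - ms[s] - ma[i] + grand) ** 2 for s in range(n) for i in range(a)
    )
    ss_bs = a * sum(
        (msb[s][j] - ms[s] - mb[j] + grand) ** 2 for s in range(n) for j in range(b)
    )
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    out = {"ss_total": ss_total, "ss_subject": ss_subj}
    for name, ss_e, df_e, ss_r, df_r in [
        ("A", ss_a, a - 1, ss_as, (n - 1) * (a - 1)),
        ("B", ss_b, b - 1, ss_bs, (n - 1) * (b - 1)),
        ("AB", ss_ab, (a - 1) * (b - 1), ss_abs, (n - 1) * (a - 1) * (b - 1)),
    ]:
        f = (ss_e / df_e) / (ss_r / df_r)
        out[name] = {
            "ss": ss_e,
            "df": df_e,
            "ss_err": ss_r,
            "df_err": df_r,
            "F": f,
            "p": float(stats.f.sf(f, df_e, df_r)),
        }
    return out


def brute_force_rm1(y: np.ndarray) -> dict:
    """One-way within-subject decomposition of y[subject, level] by loops."""
    n, a = y.shape
    grand = sum(y[s, i] for s in range(n) for i in range(a)) / (n * a)
    ms = [sum(y[s, i] for i in range(a)) / a for s in range(n)]
    ma = [sum(y[s, i] for s in range(n)) / n for i in range(a)]
    ss_total = sum((y[s, i] - grand) ** 2 for s in range(n) for i in range(a))
    ss_subj = a * sum((m - grand) ** 2 for m in ms)
    ss_a = n * sum((m - grand) ** 2 for m in ma)
    ss_err = ss_total - ss_subj - ss_a
    df_a, df_err = a - 1, (n - 1) * (a - 1)
    f = (ss_a / df_a) / (ss_err / df_err)
    return {
        "ss": ss_a,
        "df": df_a,
        "ss_err": ss_err,
        "df_err": df_err,
        "F": f,
        "p": float(stats.f.sf(f, df_a, df_err)),
    }


def long_table(y: np.ndarray, subjects=None, la=None, lb=None):
    """y[subject, a, b] -> long DataFrame (subject, visual, platform, value)."""
    import pandas as pd

    n, a, b = y.shape
    subjects = subjects or [f"S{s}" for s in range(n)]
    la = la or [f"A{i}" for i in range(a)]
    lb = lb or [f"B{j}" for j in range(b)]
    rows = [
        {"subject": subjects[s], "visual": la[i], "platform": lb[j], "value": y[s, i, j]}
        for s in range(n)
        for i in range(a)
        for j in range(b)
    ]
    return pd.DataFrame(rows)
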