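"""Independent brute-force / formula-level oracles used by the tests.

Everything here deliberately avoids the code paths of the package:
interval operations are all-pairs loops, the moderated test is a
step-by-step reimplementation on top of statsmodels OLS with a
bracketing trigamma inversion, and correlations use the textbook
formula.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from cardiosplice.intervals import GenomicInterval


def brute_force_intersect(query, subject):
    """All overlapping (q, s, span) triples by O(n^2) scanning."""
    out = []
    for q in query:
        hits = []
        for s in subject:
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                hits.append(s)
        for s in sorted(hits, key=lambda s: (s.start, s.end)):
            out.append(
                (q, s, (q.chrom, max(q.start, s.start), min(q.end, s.end)))
            )
    return out


def brute_force_merge(intervals, window=0):
    """Merge by repeated pairwise unioning until a fixed point."""
    items = [[iv.chrom, iv.strand, iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0] or a[1] != b[1]:
                    continue
                gap = max(a[2], b[2]) - min(a[3], b[3])
                if gap <= window:
                    a[2], a[3] = min(a[2], b[2]), max(a[3], b[3])
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, st, s, e) for c, st, s, e in items)


def pearson_textbook(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def moderated_ttest_oracle(psi: pd.DataFrame, design: pd.DataFrame, contrast: dict):
    """Step-by-step moderated t: OLS per event, then empirical Bayes.

    Returns (table DataFrame indexed like psi, d0, s0_squared).
    """
    contrast = pd.Series(contrast, dtype=float)
    samples = [s for s in psi.columns if s in contrast.index]
    meta = design.set_index("sample_id").loc[samples]
    base = pd.DataFrame({"c": contrast.loc[samples]})
    base = pd.concat(
        [base, pd.get_dummies(meta["batch"], drop_first=True, dtype=float)], axis=1
    )

    rows = []
    for ev in psi.index:
        y = psi.loc[ev, samples].astype(float)
        m = y.notna()
        X = base.loc[m.values]
        X = X.loc[:, [c for c in X.columns if c == "c" or X[c].nunique() > 1]]
        X = sm.add_constant(X, prepend=True)
        res = sm.OLS(y[m.values].values, X.values).fit()
        d = res.df_resid
        s2 = res.ssr / d if d > 0 else np.nan
        se_unit = res.bse[1] / math.sqrt(res.scale)
        rows.append({"event_id": ev, "beta": res.params[1], "s2": s2, "d": d,
                     "se_unit": se_unit})
    tab = pd.DataFrame(rows).set_index("event_id")

    ok = (tab["s2"] > 0) & (tab["d"] > 0)
    z = np.log(tab.loc[ok, "s2"].values)
    dfv = tab.loc[ok, "d"].values
    e = z - special.digamma(dfv / 2) + np.log(dfv / 2)
    evar = e.var(ddof=1) - special.polygamma(1, dfv / 2).mean()
    if evar > 0:
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - evar, 1e-8, 1e10, xtol=1e-14, rtol=1e-15
        )
        d0 = 2 * half_d0
        s02 = float(np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0)))
    else:
        # zero excess spread: prior collapses onto the geometric mean
        d0 = 1e6
        s02 = float(np.exp(z.mean()))

    s2_post = (d0 * s02 + tab["d"] * tab["s2"]) / (d0 + tab["d"])
    t = tab["beta"] / (tab["se_unit"] * np.sqrt(s2_post))
    df_total = np.minimum(d0 + tab["d"], 1e6)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"effect": tab["beta"], "t": t, "p_raw": p, "s2_post": s2_post}, index=tab.index
    )
    return out, d0, s02


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up, written from the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj
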