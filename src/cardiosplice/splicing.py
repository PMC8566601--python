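"""PSI quantification and genotype-pattern splicing inference.

PSI (percent spliced-in) for a cassette exon is estimated per sample as
inclusion-junction reads over total junction reads. Differential events
are retained when detected in at least 75% of the samples of each
compared group and the group-mean difference exceeds dPSI 0.1.
Moderated testing follows the empirical-Bayes variance shrinkage of
the limma lineage: per-event residual variances s^2 with d residual
degrees of freedom are shrunk toward a prior (d0, s0^2) estimated by
method of moments on log residual variances, giving

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t~   = beta / (se_unit * s~),   p from t with d0 + d df.

Four genotype models rank each event: (1) HTZ-specific, (2)
HMZ-specific, (3) equivalent in HTZ and HMZ vs WT, (4) additive allele
dose 0/1/2 over WT/HTZ/HMZ. Pattern assignment correlates each event's
PSI vector with idealized group-indicator templates over several sample
groupings and picks the best-correlated significant template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .synthetic import JunctionCounts

#: Cap on the prior degrees of freedom: beyond this the moderated test
#: is numerically the fully pooled-variance test.
D0_CAP = 1e6


# ---------------------------------------------------------------------------
# PSI and filtering


def compute_psi(jc: JunctionCounts, min_total_reads: int = 10) -> pd.DataFrame:
    """PSI = inclusion / (inclusion + exclusion); missing below depth.

    Samples with fewer than ``min_total_reads`` total junction reads for
    an event yield NaN (the event is not reliably detected there).
    """
    if min_total_reads < 1:
        raise ValueError("min_total_reads must be >= 1")
    total = jc.inclusion + jc.exclusion
    psi = jc.inclusion / total.where(total > 0)
    return psi.where(total >= min_total_reads)


def filter_events(
    psi: pd.DataFrame,
    design: pd.DataFrame,
    groups: tuple[str, str],
    min_detect_frac: float = 0.75,
    min_dpsi: float = 0.1,
) -> list[str]:
    """Events detected in >= ``min_detect_frac`` of each group's samples
    with |group-mean dPSI| > ``min_dpsi``."""
    sample_sets = []
    for g in groups:
        ids = design.loc[design["genotype"] == g, "sample_id"].tolist()
        if not ids:
            raise ValueError(f"group {g!r} has zero samples in the design")
        sample_sets.append(ids)
    a, b = (psi[ids] for ids in sample_sets)
    detect_ok = (a.notna().mean(axis=1) >= min_detect_frac) & (
        b.notna().mean(axis=1) >= min_detect_frac
    )
    dpsi = (a.mean(axis=1) - b.mean(axis=1)).abs()
    keep = detect_ok & (dpsi > min_dpsi)
    return psi.index[keep].tolist()


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t-test


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log residual variances.

    Matches the mean and excess variance of z = log(s^2) against the
    scaled-F model: z - digamma(d/2) + log(d/2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) and extra variance
    trigamma(d0/2) beyond trigamma(d/2). Events with zero residual
    variance or df are excluded from estimation.

    When the log-variances show no excess spread (evar <= 0) the prior
    is effectively infinite-df and collapses onto the observed
    variances' geometric mean, so that identical residual variances
    shrink to themselves and the moderated t reduces to the ordinary t.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return D0_CAP, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar <= 0:
        return D0_CAP, float(np.exp(z.mean()))
    d0 = 2.0 * trigamma_inverse(evar)
    d0 = min(d0, D0_CAP)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s02


@dataclass
class ModeratedResult:
    """Per-event moderated test results plus the shared prior."""

    table: pd.DataFrame  # effect, t, p_raw, p_fdr, s2, df, s2_post
    d0: float
    s0_squared: float


def moderated_ttest(
    psi: pd.DataFrame,
    design: pd.DataFrame,
    contrast: Mapping[str, float] | pd.Series,
    batch_covariate: bool = True,
) -> ModeratedResult:
    """Empirical-Bayes moderated t-test of PSI on a per-sample contrast.

    ``contrast`` maps sample_id -> numeric contrast value (e.g. a 0/1
    group indicator or a 0/1/2 allele dose); samples absent from the
    contrast are excluded. Batch enters as fixed-effect indicator
    columns. Events with missing PSI are fit on their non-missing
    samples. BH-adjusted p-values are computed across events.
    """
    contrast = pd.Series(dict(contrast), dtype=float)
    samples = [s for s in psi.columns if s in contrast.index]
    if len(samples) < 3:
        raise ValueError("need >= 3 samples covered by the contrast")
    design = design.set_index("sample_id").loc[samples]
    cvec = contrast.loc[samples].to_numpy()
    cols = [np.ones(len(samples)), cvec]
    if batch_covariate:
        batches = pd.get_dummies(design["batch"], drop_first=True, dtype=float)
        cols.extend(batches[c].to_numpy() for c in batches.columns)
    X_full = np.column_stack(cols)

    Y = psi[samples].to_numpy(dtype=float)
    n_events = Y.shape[0]
    effect = np.full(n_events, np.nan)
    s2 = np.full(n_events, np.nan)
    dfs = np.zeros(n_events)
    se_unit = np.full(n_events, np.nan)  # unscaled SE of the contrast coef

    for i in range(n_events):
        y = Y[i]
        m = np.isfinite(y)
        X = X_full[m]
        # drop constant non-contrast columns (e.g. batch absent in subset)
        keep = [0, 1] + [j for j in range(2, X.shape[1]) if np.ptp(X[:, j]) > 0]
        X = X[:, keep]
        n, p = X.shape
        d = n - p
        if d <= 0 or np.ptp(X[:, 1]) == 0:
            continue
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = XtX_inv @ X.T @ y[m]
        resid = y[m] - X @ beta
        effect[i] = beta[1]
        s2[i] = float(resid @ resid / d) if d > 0 else np.nan
        dfs[i] = d
        se_unit[i] = np.sqrt(XtX_inv[1, 1])

    fit_ok = np.isfinite(s2) & (dfs > 0)
    if not fit_ok.any():
        raise ValueError("zero residual degrees of freedom for all events; use larger groups")
    d0, s02 = estimate_prior(s2[fit_ok], dfs[fit_ok])
    s2_post = np.where(
        fit_ok, (d0 * s02 + dfs * np.nan_to_num(s2)) / (d0 + dfs), np.nan
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = effect / (se_unit * np.sqrt(s2_post))
        df_total = np.where(fit_ok, np.minimum(d0 + dfs, D0_CAP), np.nan)
        p_raw = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    p_fdr = np.full(n_events, np.nan)
    finite = np.isfinite(p_raw)
    if finite.any():
        p_fdr[finite] = multipletests(p_raw[finite], method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "effect": effect,
            "t": tstat,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "s2": s2,
            "df": dfs,
            "s2_post": s2_post,
            "df_total": df_total,
        },
        index=psi.index,
    )
    return ModeratedResult(table, d0, s02)


# ---------------------------------------------------------------------------
# genotype models


MODEL_NAMES = ("htz_specific", "hmz_specific", "shared_r636s", "dosage_additive")


def _model_contrasts(design: pd.DataFrame) -> dict[str, pd.Series]:
    d = design.set_index("sample_id")["genotype"]
    missing = set(("WT", "HTZ", "HMZ", "KO")) - set(d)
    if missing:
        raise ValueError(f"design lacks genotypes {sorted(missing)}")
    contrasts = {
        # (1) HTZ vs all others
        "htz_specific": (d == "HTZ").astype(float),
        # (2) HMZ vs all others
        "hmz_specific": (d == "HMZ").astype(float),
        # (3) equivalent differential splicing in HTZ and HMZ vs WT
        "shared_r636s": d[d.isin(["WT", "HTZ", "HMZ"])].isin(["HTZ", "HMZ"]).astype(float),
        # (4) additive allele dose over WT/HTZ/HMZ
        "dosage_additive": d[d.isin(["WT", "HTZ", "HMZ"])].map(
            {"WT": 0.0, "HTZ": 1.0, "HMZ": 2.0}
        ),
    }
    return contrasts


def fit_genotype_models(
    psi: pd.DataFrame,
    design: pd.DataFrame,
    fdr_cutoff: float = 0.1,
    min_dpsi: float = 0.1,
) -> pd.DataFrame:
    """Fit the four genotype models per event and pick the best.

    Best model = smallest raw p; ties broken toward the more
    constrained dosage interpretation (4 > 3 > 2 > 1). The event is
    called significant when the best model's BH-adjusted p is below
    ``fdr_cutoff`` and its |dPSI| exceeds ``min_dpsi``. dPSI is the
    fitted extreme group difference (twice the per-allele slope for
    the dosage model).
    """
    fits = {
        name: moderated_ttest(psi, design, contrast)
        for name, contrast in _model_contrasts(design).items()
    }
    pref = {name: i for i, name in enumerate(reversed(MODEL_NAMES))}
    rows = []
    for ev in psi.index:
        pvals = {}
        for name, fit in fits.items():
            p = fit.table.loc[ev, "p_raw"]
            if np.isfinite(p):
                pvals[name] = float(p)
        if not pvals:
            rows.append(
                {"event_id": ev, "best_model": None, "p_raw": np.nan,
                 "p_fdr": np.nan, "dpsi": np.nan, "significant": False}
            )
            continue
        best = min(pvals, key=lambda m: (pvals[m], pref[m]))
        fit = fits[best]
        eff = float(fit.table.loc[ev, "effect"])
        dpsi = 2.0 * eff if best == "dosage_additive" else eff
        p_fdr = float(fit.table.loc[ev, "p_fdr"])
        rows.append(
            {
                "event_id": ev,
                "best_model": best,
                "p_raw": pvals[best],
                "p_fdr": p_fdr,
                "dpsi": dpsi,
                "significant": bool(p_fdr < fdr_cutoff and abs(dpsi) > min_dpsi),
            }
        )
    return pd.DataFrame(rows).set_index("event_id")


# ---------------------------------------------------------------------------
# pattern assignment (MarkerFinder-style)


def default_groupings(design: pd.DataFrame) -> dict[str, dict[str, list[str]]]:
    """Primary genotypes plus aggregated mutation groups."""
    d = design.set_index("sample_id")["genotype"]

    def ids(genos: Sequence[str]) -> list[str]:
        return d[d.isin(genos)].index.tolist()

    return {
        "primary": {g: ids([g]) for g in ("WT", "HTZ", "HMZ", "KO")},
        "r636s_aggregate": {
            "WT": ids(["WT"]),
            "R636S": ids(["HTZ", "HMZ"]),
            "KO": ids(["KO"]),
        },
        "any_mutation": {"WT": ids(["WT"]), "MUT": ids(["HTZ", "HMZ", "KO"])},
    }


def assign_patterns(
    psi: pd.DataFrame,
    design: pd.DataFrame,
    groupings: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Assign each event to its best-correlated idealized group template.

    For every grouping and group, the template is the 0/1 indicator of
    group membership over samples; the event's PSI vector is Pearson-
    correlated with each template and assigned to the (grouping, group)
    with the maximal correlation among templates with correlation-test
    p < ``p_cutoff``. Events with zero PSI variance are unassigned.
    Groups with fewer than 2 samples are skipped.
    """
    if groupings is None:
        groupings = default_groupings(design)
    samples = list(psi.columns)
    templates = []
    for gname, groups in groupings.items():
        covered = set()
        for members in groups.values():
            covered.update(members)
        if not set(samples) <= covered:
            raise ValueError(f"grouping {gname!r} does not cover all samples")
        for group, members in groups.items():
            if len(members) < 2:
                continue  # single-sample group: skipped
            vec = np.array([1.0 if s in set(members) else 0.0 for s in samples])
            if np.ptp(vec) == 0:
                continue
            templates.append((gname, group, vec))

    rows = []
    for ev in psi.index:
        y = psi.loc[ev, samples].to_numpy(dtype=float)
        m = np.isfinite(y)
        best = None
        if m.sum() >= 3 and np.ptp(y[m]) > 0:
            for gname, group, vec in templates:
                v = vec[m]
                if np.ptp(v) == 0:
                    continue
                r, p = stats.pearsonr(y[m], v)
                if p < p_cutoff and (best is None or r > best[2]):
                    best = (gname, group, float(r), float(p))
        if best is None:
            rows.append({"event_id": ev, "grouping": None, "group": None,
                         "correlation": np.nan, "p_value": np.nan})
        else:
            rows.append({"event_id": ev, "grouping": best[0], "group": best[1],
                         "correlation": best[2], "p_value": best[3]})
    return pd.DataFrame(rows).set_index("event_id")


# ---------------------------------------------------------------------------
# APA and circRNA


def apa_ratio(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-sample 3'UTR isoform ratios, normalized to the gene total.

    ``abundance`` must carry 'gene_id' and 'utr_isoform_id' columns and
    one numeric column per sample. Genes with zero total in a sample
    get missing ratios.
    """
    meta_cols = ["gene_id", "utr_isoform_id"]
    value_cols = [c for c in abundance.columns if c not in meta_cols]
    vals = abundance[value_cols]
    if (vals.to_numpy(dtype=float) < 0).any():
        raise ValueError("abundances must be >= 0")
    totals = abundance.groupby("gene_id")[value_cols].transform("sum")
    ratios = vals / totals.where(totals > 0)
    out = abundance[meta_cols].copy()
    for c in value_cols:
        out[c] = ratios[c]
    return out


def filter_circrna(circs: pd.DataFrame, min_reads: int = 2) -> pd.DataFrame:
    """Retain circRNAs with at least ``min_reads`` total back-splice
    reads across samples."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    meta_cols = [c for c in ("circ_id", "gene_id", "chrom", "start", "end", "strand")
                 if c in circs.columns]
    value_cols = [c for c in circs.columns if c not in meta_cols]
    totals = circs[value_cols].sum(axis=1)
    return circs[totals >= min_reads].copy()


def upper_quartile_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Upper-quartile normalization of a count matrix (features x samples).

    The per-sample factor is the 75th percentile of its nonzero counts;
    normalized counts are scaled by geometric-mean(factors)/factor so
    the overall scale is preserved. Returns (normalized, factors).
    """
    factors = {}
    for c in counts.columns:
        col = counts[c].to_numpy(dtype=float)
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {c!r} has no nonzero counts")
        factors[c] = float(np.percentile(nz, 75))
    factors = pd.Series(factors)
    gmean = float(np.exp(np.mean(np.log(factors))))
    normalized = counts * (gmean / factors)
    return normalized, factors
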