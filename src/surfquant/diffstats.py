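"""Biotin-vs-mock screening statistics.

The core test is an empirical-Bayes moderated two-sample t-test: each
protein's pooled variance is shrunk toward a prior variance s0² with
prior degrees of freedom d0, both estimated by closed-form moment
matching on the log residual variances (the scaled-F hierarchical
model). P-values use a t reference with d + d0 degrees of freedom and
are corrected across proteins by Benjamini-Hochberg step-up.

Also here: the CV-based replicate precision report, Pearson correlation
of method-level fold changes, and the Kruskal-Wallis comparison of
ontology-level abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .quant import ProteinQuantMatrix

DEFAULT_LFC_MIN = 0.5
DEFAULT_PADJ_MAX = 0.1


@dataclass(frozen=True)
class ModeratedFitParams:
    """Variance-moderation hyper-parameters.

    d0 is the prior degrees of freedom (``math.inf`` when the residual
    variances are essentially constant); s0_sq the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection.

    trigamma is strictly decreasing on (0, inf), from +inf to 0.
    """
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, hi) > y:
        return hi
    if special.polygamma(1, lo) < y:
        return lo
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> ModeratedFitParams:
    """Moment-matching fit of (d0, s0²) on per-protein log variances.

    With s² | σ² ~ σ² χ²_d / d and σ² ~ s0² d0 / χ²_{d0}, the statistic
    e = log s² − ψ(d/2) + log(d/2) has mean log s0² + ψ(d0/2) − log(d0/2)
    and variance ψ'(d/2) + ψ'(d0/2); solving the second equation for d0
    (trigamma inversion) and substituting gives s0². When the observed
    spread of log variances does not exceed its sampling expectation,
    d0 is infinite and s0² = exp(mean(e)).
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return ModeratedFitParams(d0=math.inf, s0_sq=float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0)
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        x = _trigamma_inverse(evar)
        if math.isfinite(x):
            d0 = 2.0 * x
            s0 = math.exp(emean + float(special.digamma(x)) - math.log(x))
            return ModeratedFitParams(d0=d0, s0_sq=s0)
    return ModeratedFitParams(d0=math.inf, s0_sq=math.exp(emean))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def moderated_ttest(
    matrix: ProteinQuantMatrix | pd.DataFrame,
    design: pd.DataFrame,
    params: ModeratedFitParams | str = "estimate",
    groups: tuple[str, str] = ("biotin", "mock"),
    min_obs: int = 2,
) -> pd.DataFrame:
    """Moderated two-group comparison on the log2-centred layer.

    log2fc = mean(first group) − mean(second group). Proteins with fewer
    than ``min_obs`` observed values in either group are skipped and
    reported with NaN statistics (``tested`` False). Pass a fitted
    :class:`ModeratedFitParams` to fix the prior, or ``"estimate"`` for
    moment-matching estimation; ``ModeratedFitParams`` with d0 = 0
    reduces to the ordinary pooled two-sample t-test.

    Returns a protein-indexed frame with log2fc, t_mod, df, p, p_adj,
    significant, reportable and per-group observation counts.
    """
    if isinstance(matrix, ProteinQuantMatrix):
        if matrix.log2 is None:
            raise ValueError("matrix has no log2 layer; call normalize() first")
        data = matrix.log2
        reportable = matrix.meta["has_unique_peptide"].reindex(data.index)
    else:
        data = matrix
        reportable = pd.Series(True, index=data.index)

    g1, g2 = groups
    s1 = design.loc[design["group"] == g1, "sample_id"]
    s2cols = design.loc[design["group"] == g2, "sample_id"]
    x1 = data[list(s1)].to_numpy(dtype=float)
    x2 = data[list(s2cols)].to_numpy(dtype=float)

    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    tested = (n1 >= min_obs) & (n2 >= min_obs)

    m1 = np.nansum(x1, axis=1) / np.maximum(n1, 1)
    m2 = np.nansum(x2, axis=1) / np.maximum(n2, 1)
    ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
    ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    d = n1 + n2 - 2
    lfc = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (ss1 + ss2) / d

    if isinstance(params, str):
        if params != "estimate":
            raise ValueError("params must be ModeratedFitParams or 'estimate'")
        fit = estimate_prior(s2[tested], d[tested].astype(float))
    else:
        fit = params

    d0, s0 = fit.d0, fit.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_post * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), np.maximum(df_total, 1e-300))
    )
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "s2_pooled": s2,
            "t_mod": t,
            "df": df_total,
            "p": p,
            "n_obs_1": n1,
            "n_obs_2": n2,
            "tested": tested,
        },
        index=data.index,
    )
    for col in ("log2fc", "s2_pooled", "t_mod", "df", "p"):
        out.loc[~tested, col] = np.nan
    padj = np.full(len(out), np.nan)
    padj[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["p_adj"] = padj
    out["reportable"] = reportable.fillna(False).to_numpy(dtype=bool)
    out["significant"] = (
        (out["log2fc"] > DEFAULT_LFC_MIN)
        & (out["p_adj"] < DEFAULT_PADJ_MAX)
        & out["reportable"]
    ).fillna(False)
    out.attrs["fit"] = fit
    out.attrs["n_skipped"] = int((~tested).sum())
    return out


def significant_proteins(
    results: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    padj_max: float = DEFAULT_PADJ_MAX,
) -> set[str]:
    """Proteins with log2fc > lfc_min, adjusted p < padj_max and a
    unique peptide (the reporting gate)."""
    mask = (
        (results["log2fc"] > lfc_min)
        & (results["p_adj"] < padj_max)
        & results["reportable"].astype(bool)
    ).fillna(False)
    return set(results.index[mask])


def cv(values) -> float:
    """Coefficient of variation in percent: sd (n−1) / mean × 100."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("cv requires at least two values")
    m = x.mean()
    if m <= 0:
        raise ValueError("cv requires a positive mean")
    return float(np.std(x, ddof=1) / m * 100.0)


def precision_report(
    linear: pd.DataFrame,
    design: pd.DataFrame,
    by: tuple[str, ...] = ("cell_line", "group"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein CVs across replicates of the same condition.

    Returns ``(cv_table, summary)``: the protein x condition CV table
    (percent, NaN when fewer than two observations) and a summary with
    median, minimum and maximum CV per condition.
    """
    cv_cols = {}
    for key, sub in design.groupby(list(by)):
        name = key if isinstance(key, str) else "/".join(map(str, key))
        cols = [c for c in sub["sample_id"] if c in linear.columns]
        if len(cols) < 2:
            continue
        x = linear[cols].to_numpy(dtype=float)
        n = np.sum(~np.isnan(x), axis=1)
        mean = np.nansum(x, axis=1) / np.maximum(n, 1)
        ss = np.nansum((x - mean[:, None]) ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.sqrt(ss / np.maximum(n - 1, 1))
            vals = np.where((n >= 2) & (mean > 0), sd / mean * 100.0, np.nan)
        cv_cols[name] = vals
    cv_table = pd.DataFrame(cv_cols, index=linear.index)
    summary = pd.DataFrame(
        {
            "median_cv": cv_table.median(axis=0),
            "min_cv": cv_table.min(axis=0),
            "max_cv": cv_table.max(axis=0),
            "n_proteins": cv_table.notna().sum(axis=0),
        }
    )
    return cv_table, summary


def pearson_method_correlation(
    lfc_table: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation between methods.

    Returns (r matrix, two-sided p matrix); p comes from the exact
    t transform with n − 2 degrees of freedom.
    """
    cols = list(lfc_table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(
        np.where(np.eye(len(cols)), 0.0, np.nan), index=cols, columns=cols
    )
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = lfc_table[[a, b]].dropna()
            if len(sub) < min_pairs:
                raise ValueError(
                    f"fewer than {min_pairs} complete pairs for ({a}, {b})"
                )
            for col in (a, b):
                if np.isclose(sub[col].std(ddof=1), 0.0):
                    raise ValueError(f"zero variance in column {col!r}")
            res = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All values identical across all groups (H undefined after tie
    correction) gives (0.0, 1.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if flat.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
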