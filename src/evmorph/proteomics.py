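"""Cellular-proteome statistics.

Covers the downstream protein-matrix analyses: per-protein z-scoring,
Ward.D2 hierarchical clustering for heatmaps, empirical-Bayes moderated
differential abundance with the joint |FC| >= 2 and p < 0.05 rule, volcano
classification, and per-gene-set ANOVA with Tukey HSD and Benjamini–Hochberg
adjustment over sets.

The moderated statistic shrinks per-protein residual variances s_g^2 toward
a pooled prior s_0^2 with prior degrees of freedom d_0, both estimated by
moment matching of log s_g^2 against the scaled-F prior (digamma/trigamma
equations solved by Newton iterations).  The posterior variance is

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

and the moderated t uses d_0 + d_g degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "zscore_by_row",
    "ward_hclust",
    "moderated_de",
    "volcano_classify",
    "gene_set_anova",
    "trigamma_inverse",
    "WardResult",
]


def zscore_by_row(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row across samples (n-1 sd); constant rows are dropped."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = matrix.std(axis=1, ddof=1)
    constant = sd <= 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant row(s)", stacklevel=2)
        matrix = matrix.loc[~constant]
        sd = sd.loc[~constant]
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


@dataclass
class WardResult:
    linkage: np.ndarray      # scipy linkage matrix (merge tree with heights)
    order: np.ndarray        # leaf ordering
    labels: list


def ward_hclust(matrix: pd.DataFrame, axis: int = 0) -> WardResult:
    """Ward.D2 agglomerative clustering on Euclidean distances.

    ``axis=0`` clusters rows, ``axis=1`` columns.  Merge heights follow the
    Lance–Williams update for Ward linkage on squared Euclidean distances
    (the ".D2" convention: heights are on the distance scale).
    """
    X = matrix.to_numpy(dtype=float)
    labels = list(matrix.index if axis == 0 else matrix.columns)
    if axis == 1:
        X = X.T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values produce NaN distances")
    Z = linkage(X, method="ward")
    return WardResult(linkage=Z, order=leaves_list(Z), labels=labels)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iterations."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) from residual variances.

    Matches mean/variance of log s^2 to the scaled-F prior: with
    z = log s^2, var(z) - trigamma(df/2) = trigamma(d0/2), and the mean
    determines s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.clip(s2, 1e-300, None)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    s02 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def moderated_de(
    matrix: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated differential abundance (log2 input).

    Per protein: a linear model on group indicators (group means); residual
    variance pooled across all groups with d_g = n - k df; the contrast is
    ``contrast[0] - contrast[1]`` on the log2 scale.  ``prior_df`` overrides
    the estimated d_0 (0 disables shrinkage, np.inf forces s~^2 = s0^2).
    Significance is the joint rule p < alpha AND |fold change| >= fc_threshold.
    """
    test_g, ref_g = contrast
    for g in contrast:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    X = matrix[groups.index].to_numpy(dtype=float)
    glabels = groups.to_numpy()
    uniq = pd.unique(glabels)
    n, k = X.shape[1], len(uniq)
    d_g = n - k
    if d_g < 1:
        raise ValueError("no residual degrees of freedom")
    means = {g: X[:, glabels == g].mean(axis=1) for g in uniq}
    rss = np.zeros(X.shape[0])
    for g in uniq:
        sub = X[:, glabels == g]
        rss += ((sub - means[g][:, None]) ** 2).sum(axis=1)
    s2 = rss / d_g

    if prior_df is None:
        d0, s02 = _fit_f_dist(s2, d_g)
        if np.isinf(d0):
            warnings.warn(
                "residual variances look homogeneous; prior df set to infinity",
                stacklevel=2,
            )
    else:
        d0 = float(prior_df)
        _, s02 = _fit_f_dist(s2, d_g)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    na = int((glabels == test_g).sum())
    nb = int((glabels == ref_g).sum())
    c = 1.0 / na + 1.0 / nb
    log2_fc = means[test_g] - means[ref_g]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = log2_fc / np.sqrt(s2 * c)
        t_mod = log2_fc / np.sqrt(s2_post * c)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "residual_df": float(d_g),
            "prior_df": d0,
            "prior_var": s02,
            "posterior_var": s2_post,
            "p_value": p,
            "significant": (p < alpha) & (2.0 ** np.abs(log2_fc) >= fc_threshold),
        },
        index=matrix.index,
    )
    return out


def volcano_classify(results: pd.DataFrame) -> dict:
    """Partition DE results into up / down / not-significant counts."""
    sig = results["significant"]
    n_up = int((sig & (results["log2_fc"] > 0)).sum())
    n_down = int((sig & (results["log2_fc"] < 0)).sum())
    return {"n_up": n_up, "n_down": n_down, "n_ns": int(len(results) - n_up - n_down)}


def gene_set_anova(
    es: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA per gene set on enrichment scores, Tukey HSD pairs, BH.

    ``es`` is sets x samples.  BH adjusts the ANOVA p-values across sets;
    ``significant`` means q <= alpha.  Zero within-group variance with
    distinct means yields F = inf handled as p = 0 with a flag.
    """
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    cols = {f"tukey_p_{a}_vs_{b}": (a, b)
            for i, a in enumerate(uniq) for b in uniq[i + 1:]}
    rows = []
    for set_name, row in es.iterrows():
        samples = [row[groups.index[groups == g]].to_numpy(dtype=float) for g in uniq]
        degenerate = all(np.ptp(s) == 0 for s in samples)
        if degenerate and np.ptp([s.mean() for s in samples]) > 0:
            f_stat, p = np.inf, 0.0
        elif degenerate:
            f_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p = stats.f_oneway(*samples)
        rec = {"set": set_name, "anova_F": float(f_stat), "anova_p": float(p),
               "degenerate": bool(degenerate)}
        if degenerate:
            for name in cols:
                rec[name] = 0.0 if p == 0.0 else 1.0
        else:
            tk = stats.tukey_hsd(*samples)
            for name, (a, b) in cols.items():
                rec[name] = float(tk.pvalue[uniq.index(a), uniq.index(b)])
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("set")
    out["bh_q"] = multipletests(out["anova_p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["bh_q"] <= alpha
    return out
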