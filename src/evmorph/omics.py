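"""Differential analysis of secretion panels and lipid class tables.

The statistics follow screening-panel practice: per-analyte Welch t-tests
between two groups (raw p < alpha by default, Benjamini–Hochberg optionally),
log2 fold changes on raw abundance means with a pseudo-count, PCA
sub-profiles on significant analytes, interaction-degree ranking over a
user-supplied edge list, and per-class lipid totals split by ionization
mode.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import LIPID_CLASSES

__all__ = [
    "welch_test",
    "differential_panel",
    "pca_on_significant",
    "lipid_feature_pca",
    "degree_ranking",
    "lipid_class_totals",
]


def welch_test(values_a, values_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, p) two-sided.

    Degenerate inputs: zero variance in both groups gives p = 1 when the
    means agree and p = 0 (with a warning) when they differ.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        warnings.warn("zero variance in both groups with unequal means", stacklevel=2)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def differential_panel(
    matrix: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    correct: bool = False,
    pseudo_count: float | None = None,
) -> pd.DataFrame:
    """Per-analyte Welch test of ``group_b`` against ``group_a``.

    ``matrix`` is analytes x samples on the raw abundance scale.  Direction
    ("increased"/"decreased") describes group_b relative to group_a.  The
    log2 fold change uses a pseudo-count (default: half the smallest positive
    value in the matrix) so zero abundances stay finite.  Analytes constant
    across every sample are flagged untestable.  ``significant`` is raw
    p < alpha, or BH q < alpha when ``correct=True``.
    """
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    if pseudo_count is None:
        pos = matrix.to_numpy()
        pos = pos[pos > 0]
        pseudo_count = 0.5 * pos.min() if pos.size else 1.0
    rows = []
    for analyte, row in matrix.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        untestable = np.ptp(np.concatenate([a, b])) == 0
        if untestable:
            t, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, df, p = welch_test(a, b)
        ma, mb = a.mean(), b.mean()
        rows.append(
            {
                "analyte": analyte,
                "mean_a": ma,
                "mean_b": mb,
                "log2_fold_change": np.log2((mb + pseudo_count) / (ma + pseudo_count)),
                "t_statistic": t,
                "degrees_freedom": df,
                "p_value": p,
                "untestable": bool(untestable),
                "direction": "increased" if mb >= ma else "decreased",
            }
        )
    out = pd.DataFrame(rows).set_index("analyte")
    out["bh_q"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    crit = out["bh_q"] if correct else out["p_value"]
    out["significant"] = (crit < alpha) & ~out["untestable"]
    return out


def _pca_samples(X: np.ndarray, index) -> dict:
    """PCA with samples as observations on z-scored analyte rows."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((X - mu) / sd).T  # samples x analytes
    Zc = Z - Z.mean(axis=0)
    _, s, vt = np.linalg.svd(Zc, full_matrices=False)
    var = s**2 / max(Zc.shape[0] - 1, 1)
    pct = 100.0 * var / var.sum()
    comp = [f"PC{i + 1}" for i in range(vt.shape[0])]
    return {
        "scores": pd.DataFrame(Zc @ vt.T, index=index, columns=comp),
        "variance_explained": pct,
        "loadings": vt.T,
    }


def pca_on_significant(matrix: pd.DataFrame, significant_ids) -> dict:
    """PCA of samples on the z-scored significant analyte sub-profile.

    Returns sample scores on PC1/PC2..., loadings and % variance explained.
    """
    ids = [i for i in significant_ids if i in matrix.index]
    if len(ids) < 2:
        raise ValueError("need at least 2 significant analytes for PCA")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    X = matrix.loc[ids].to_numpy(dtype=float)
    return _pca_samples(X, matrix.columns)


def lipid_feature_pca(matrix: pd.DataFrame) -> dict:
    """Sample PCA on all (unannotated) lipid feature intensities."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    return _pca_samples(matrix.to_numpy(dtype=float), matrix.columns)


def degree_ranking(edges, node_subset) -> pd.DataFrame:
    """Rank nodes of a subset by degree in the subset-induced subgraph.

    ``edges`` is an iterable of unordered id pairs.  Degree counts distinct
    neighbors inside the subset; duplicate edges and self-loops are ignored;
    subset nodes absent from the edge list get degree 0.  Ties are broken
    alphabetically.
    """
    subset = list(dict.fromkeys(node_subset))
    if not subset:
        raise ValueError("node subset is empty")
    sset = set(subset)
    neighbors: dict[str, set] = {n: set() for n in subset}
    for u, v in edges:
        if u == v or u not in sset or v not in sset:
            continue
        neighbors[u].add(v)
        neighbors[v].add(u)
    out = pd.DataFrame(
        {"node": subset, "degree": [len(neighbors[n]) for n in subset]}
    )
    return out.sort_values(
        ["degree", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def lipid_class_totals(
    lipids: pd.DataFrame,
    sample_columns: list[str] | None = None,
    class_col: str = "class",
    mode_col: str = "mode",
) -> dict[str, pd.DataFrame]:
    """Total abundance per lipid class per sample, split by ionization mode.

    Classes outside the 9 annotated ones are binned to "other" with a
    warning.  Returns {mode: class x sample DataFrame}.  Class totals
    conserve mass: summing totals over classes reproduces the per-sample
    column sums.
    """
    if class_col not in lipids.columns or mode_col not in lipids.columns:
        raise ValueError("lipid table needs class and mode annotations")
    if sample_columns is None:
        sample_columns = [
            c for c in lipids.columns
            if c not in (class_col, mode_col, "species")
            and pd.api.types.is_numeric_dtype(lipids[c])
        ]
    cls = lipids[class_col].where(lipids[class_col].isin(LIPID_CLASSES), "other")
    n_other = int((cls == "other").sum())
    if n_other:
        warnings.warn(f"{n_other} species with unknown class binned to 'other'",
                      stacklevel=2)
    out = {}
    for mode, sub in lipids.groupby(mode_col):
        totals = sub[sample_columns].groupby(cls.loc[sub.index]).sum()
        totals.index.name = "class"
        out[str(mode)] = totals
    return out
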