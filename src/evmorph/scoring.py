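"""Well-level composite morphology scoring and assay-quality metrics.

The scoring chain is: per-well medians of QC-passed single-cell features →
control-anchored min-max normalization (unstimulated wells ↦ 0, stimulated
wells ↦ 1 per feature) → PCA across wells → the first principal component
(PC1) as a composite morphological score, oriented so stimulated controls
score higher.  Assay quality is summarized by the Z′ factor

    Z' = 1 - (3·σ₊ + 3·σ₋) / |μ₊ - μ₋|

with sample (n-1) standard deviations; Z' > 0.5 is the conventional
"optimized assay" band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CANONICAL_FEATURES, NEG_CTL, POS_CTL

__all__ = [
    "aggregate_well_medians",
    "minmax_normalize",
    "composite_pca_score",
    "normalize_scores",
    "delta_score",
    "z_factor",
    "dose_response_summary",
    "CompositeScoreResult",
    "ZFactorResult",
]

MIN_CELLS_PER_WELL = 50

ID_COLUMNS = ("experiment", "operator", "well_id", "image_id", "cell_id")


@dataclass
class CompositeScoreResult:
    """PCA loadings, per-well scores, % variance and orientation sign."""

    loadings: pd.DataFrame        # features x components
    scores: pd.DataFrame          # wells x components (PC1, PC2, ...)
    variance_explained: np.ndarray  # percent per component, sums to 100
    orientation_sign: int

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


@dataclass
class ZFactorResult:
    mu_pos: float
    mu_neg: float
    sigma_pos: float
    sigma_neg: float
    z_factor: float
    quality_label: str


def aggregate_well_medians(
    records: pd.DataFrame,
    layout: pd.DataFrame,
    min_cells: int = MIN_CELLS_PER_WELL,
    features: tuple[str, ...] | list[str] | None = None,
) -> pd.DataFrame:
    """Median each feature over the cells of a well.

    Medians of ~700–1000 cells make the well profile robust to residual
    single-cell outliers.  Wells with fewer than ``min_cells`` cells are
    dropped with a warning.  Returns one row per well, indexed by well_id,
    with layout condition columns attached plus ``n_cells``.
    """
    if records.empty:
        raise ValueError("no cell records to aggregate")
    unknown = set(records["well_id"]) - set(layout["well_id"])
    if unknown:
        raise ValueError(f"records reference wells missing from layout: {sorted(unknown)[:5]}")
    if features is None:
        features = [
            c for c in records.columns
            if c not in ID_COLUMNS and pd.api.types.is_numeric_dtype(records[c])
        ]
    grouped = records.groupby("well_id", sort=False)
    med = grouped[list(features)].median()
    med["n_cells"] = grouped.size()
    small = med.index[med["n_cells"] < min_cells]
    if len(small):
        warnings.warn(
            f"dropping {len(small)} well(s) with fewer than {min_cells} cells",
            stacklevel=2,
        )
        med = med.drop(index=small)
    if med.empty:
        raise ValueError("all wells fell below min_cells")
    lay = layout.set_index("well_id")
    out = lay.loc[med.index].join(med)
    out.index.name = "well_id"
    return out


def minmax_normalize(
    profiles: pd.DataFrame,
    features: list[str] | tuple[str, ...] | None = None,
    group_col: str = "group",
    neg_group: str = NEG_CTL,
    pos_group: str = POS_CTL,
) -> pd.DataFrame:
    """Control-anchored min-max normalization of well profiles.

    Per feature, x ↦ (x − μ₋)/(μ₊ − μ₋) with μ₋/μ₊ the means over
    unstimulated / stimulated control wells.  Treatment wells are mapped by
    the same affine transform (values outside [0, 1] are allowed).
    """
    if features is None:
        features = [f for f in CANONICAL_FEATURES if f in profiles.columns]
    groups = profiles[group_col]
    neg = profiles.loc[groups == neg_group, features]
    pos = profiles.loc[groups == pos_group, features]
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("need at least 2 wells in each control group")
    mu_neg = neg.mean()
    mu_pos = pos.mean()
    span = mu_pos - mu_neg
    degenerate = span.abs() <= 1e-12
    if degenerate.any():
        bad = list(span.index[degenerate])
        raise ValueError(f"degenerate feature(s) with equal control means: {bad}")
    out = profiles.copy()
    out[features] = (profiles[features] - mu_neg) / span
    return out


def composite_pca_score(
    profiles: pd.DataFrame,
    features: list[str] | tuple[str, ...] | None = None,
    standardize: bool = False,
    group_col: str = "group",
    orient_groups: tuple[str, str] = (POS_CTL, NEG_CTL),
    fit_groups: list[str] | None = None,
) -> CompositeScoreResult:
    """PCA across wells; PC1 is the composite morphology score.

    ``standardize=True`` z-scores each feature first (correlation-matrix
    PCA) — the choice for raw well medians; min-max-normalized profiles are
    used as-is.  By default the PCA is fit on every well of the analysis
    (controls and treatment share one PC space); pass ``fit_groups`` to fit
    on a subset (e.g. controls only) and project the rest.  PC1 is oriented
    so the first group of ``orient_groups`` scores at least as high as the
    second (stimulated controls high).
    """
    if features is None:
        features = [f for f in CANONICAL_FEATURES if f in profiles.columns]
    X = profiles[list(features)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 wells for PCA")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    fit_mask = np.ones(X.shape[0], dtype=bool)
    if fit_groups is not None:
        fit_mask = profiles[group_col].isin(fit_groups).to_numpy()
        if fit_mask.sum() < 3:
            raise ValueError("need at least 3 wells in fit_groups")
    center = X[fit_mask].mean(axis=0)
    Xc = X - center
    if standardize:
        sd = X[fit_mask].std(axis=0, ddof=1)
        zero = sd <= 0
        if zero.any():
            bad = [features[i] for i in np.nonzero(zero)[0]]
            raise ValueError(f"zero-variance feature(s) under standardize=True: {bad}")
        Xc = Xc / sd
    _, s, vt = np.linalg.svd(Xc[fit_mask], full_matrices=False)
    n_fit = fit_mask.sum()
    var = s**2 / (n_fit - 1)
    pct = 100.0 * var / var.sum()
    scores = Xc @ vt.T
    comp_names = [f"PC{i + 1}" for i in range(vt.shape[0])]
    scores_df = pd.DataFrame(scores, index=profiles.index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=list(features), columns=comp_names)

    sign = 1
    if group_col in profiles.columns:
        g = profiles[group_col]
        hi, lo = orient_groups
        if (g == hi).any() and (g == lo).any():
            if scores_df.loc[g == hi, "PC1"].mean() < scores_df.loc[g == lo, "PC1"].mean():
                sign = -1
    else:
        # fall back: largest-magnitude loading positive
        if loadings["PC1"].iloc[np.argmax(np.abs(loadings["PC1"]))] < 0:
            sign = -1
    scores_df["PC1"] *= sign
    loadings["PC1"] *= sign
    return CompositeScoreResult(
        loadings=loadings,
        scores=scores_df,
        variance_explained=pct,
        orientation_sign=sign,
    )


def normalize_scores(
    scores: pd.Series,
    groups: pd.Series,
    neg_group: str = NEG_CTL,
    pos_group: str = POS_CTL,
) -> pd.Series:
    """Anchor a score so the NEG_CTL mean is 0 and the POS_CTL mean is 1."""
    mu_neg = scores[groups == neg_group].mean()
    mu_pos = scores[groups == pos_group].mean()
    if abs(mu_pos - mu_neg) <= 1e-12:
        raise ValueError("no dynamic range between control groups")
    return (scores - mu_neg) / (mu_pos - mu_neg)


def delta_score(
    scores: pd.Series,
    layout: pd.DataFrame,
    group_a: str,
    group_b: str,
    strata: tuple[str, ...] = ("experiment", "operator"),
) -> pd.DataFrame:
    """Δ = mean score(group_a) − mean score(group_b) per stratum, with SE.

    Strata missing either group are skipped with a warning.  Because both
    groups share any additive batch offset within a stratum, Δ is invariant
    to operator/experiment level shifts.
    """
    lay = layout.set_index("well_id").loc[scores.index]
    rows = []
    for key, sub in lay.groupby(list(strata)):
        key = key if isinstance(key, tuple) else (key,)
        sa = scores[sub.index[sub["group"] == group_a]]
        sb = scores[sub.index[sub["group"] == group_b]]
        if len(sa) == 0 or len(sb) == 0:
            warnings.warn(f"stratum {key}: group missing, skipped", stacklevel=2)
            continue
        delta = sa.mean() - sb.mean()
        se = float(np.sqrt(sa.var(ddof=1) / len(sa) + sb.var(ddof=1) / len(sb)))
        rows.append(dict(zip(strata, key)) | {
            "delta": float(delta), "se": se, "n_a": len(sa), "n_b": len(sb),
        })
    return pd.DataFrame(rows)


def z_factor(
    scores: pd.Series,
    groups: pd.Series,
    pos_group: str = POS_CTL,
    neg_group: str = NEG_CTL,
) -> ZFactorResult:
    """Z′ assay-quality statistic from per-well scores of the two controls."""
    pos = scores[groups == pos_group].to_numpy(dtype=float)
    neg = scores[groups == neg_group].to_numpy(dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 wells per control group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p == mu_n:
        raise ValueError("no dynamic range: control means are equal")
    s_p, s_n = float(pos.std(ddof=1)), float(neg.std(ddof=1))
    z = 1.0 - (3.0 * s_p + 3.0 * s_n) / abs(mu_p - mu_n)
    if z > 0.5:
        label = "optimized"
    elif z > 0.0:
        label = "marginal"
    else:
        label = "unusable"
    return ZFactorResult(
        mu_pos=mu_p, mu_neg=mu_n, sigma_pos=s_p, sigma_neg=s_n,
        z_factor=float(z), quality_label=label,
    )


def dose_response_summary(
    scores: pd.Series,
    doses: pd.Series,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Per-dose mean ± sd plus a permutation test of monotone trend.

    The trend statistic is the Spearman rank correlation between score and
    dose; its p-value is two-sided from ``n_permutations`` seeded label
    permutations.
    """
    doses = doses.loc[scores.index]
    levels = np.sort(doses.unique())
    if len(levels) < 3:
        raise ValueError("need at least 3 distinct dose levels")
    table = (
        pd.DataFrame({"dose": doses, "score": scores})
        .groupby("dose")["score"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    rho = stats.spearmanr(doses.to_numpy(), scores.to_numpy()).statistic
    rng = np.random.default_rng(seed)
    d_rank = stats.rankdata(doses.to_numpy())
    s_rank = stats.rankdata(scores.to_numpy())
    d_c = d_rank - d_rank.mean()
    s_c = s_rank - s_rank.mean()
    denom = np.sqrt((d_c**2).sum() * (s_c**2).sum())
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = (d_c[rng.permutation(len(d_c))] * s_c).sum() / denom
    p = float((np.sum(np.abs(null) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1))
    return {"per_dose": table, "spearman_rho": float(rho), "p_value": p}
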