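"""Gene Set Variation Analysis: per-sample gene-set enrichment scores.

The algorithm estimates, for each gene, a kernel cumulative-density statistic
of its expression across samples (Gaussian kernel, bandwidth s_i/4), ranks
genes within each sample by that statistic, symmetrizes the ranks around the
middle of the list (r = |p/2 - rank|), and walks the ranked list: in-set
genes push the walk up by |r|^tau normalized over the set, out-of-set genes
pull it down by 1/(p - |set|).  The enrichment score of a set in a sample is
the sum of the largest positive and largest negative deviations of the walk
(``mx_diff=True``, the default) or the single maximum-magnitude deviation.

Scores are bounded in [-1, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["gsva_scores", "filter_gene_sets"]


def filter_gene_sets(
    gene_sets: dict[str, list[str]],
    universe,
    min_size: int = 5,
    max_size: int = 500,
) -> dict[str, list[str]]:
    """Intersect sets with the measured universe and apply size bounds."""
    uni = set(universe)
    out = {}
    for name, members in gene_sets.items():
        kept = [g for g in dict.fromkeys(members) if g in uni]
        if min_size <= len(kept) <= max_size:
            out[name] = kept
        else:
            warnings.warn(
                f"gene set {name!r} skipped ({len(kept)} measured genes)",
                stacklevel=2,
            )
    return out


def _kcdf_gaussian(X: np.ndarray) -> np.ndarray:
    """Kernel-ECDF statistic per gene/sample: mean Phi((x_ij - x_ik)/h_i)."""
    p, n = X.shape
    sd = X.std(axis=1, ddof=1)
    h = sd / 4.0
    h[h <= 0] = 1e-6  # constant genes: degenerate kernel, ties broken later
    Z = np.empty_like(X)
    for i in range(p):
        diff = (X[i][:, None] - X[i][None, :]) / h[i]
        Z[i] = norm.cdf(diff).mean(axis=1)
    return Z


def gsva_scores(
    matrix: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    tau: float = 1.0,
    mx_diff: bool = True,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Enrichment score per (gene set, sample); returns sets x samples.

    ``matrix`` is genes x samples of continuous values; sets smaller than
    ``min_size`` (after intersection with the matrix) or larger than
    ``max_size`` are skipped with a warning.
    """
    sets = filter_gene_sets(gene_sets, matrix.index, min_size, max_size)
    if not sets:
        raise ValueError("no gene set survived the size filter")
    largest = max(len(v) for v in sets.values())
    p, n = matrix.shape
    if p < 2 * largest:
        raise ValueError(
            f"matrix has {p} genes; need at least twice the largest set ({largest})"
        )
    X = matrix.to_numpy(dtype=float)
    Z = _kcdf_gaussian(X)
    genes = list(matrix.index)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # per sample: order genes by decreasing statistic; symmetrized ranks
    order = np.argsort(-Z, axis=0, kind="stable")      # p x n, walk order
    ranks = np.empty_like(order)
    rows = np.arange(p)[:, None]
    cols = np.arange(n)[None, :]
    ranks[order, cols] = rows + 1                       # rank 1 = highest
    r_sym = np.abs(p / 2.0 - ranks)                     # p x n

    es = np.zeros((len(sets), n))
    for si, (name, members) in enumerate(sets.items()):
        in_set = np.zeros(p, dtype=bool)
        in_set[[gene_pos[g] for g in members]] = True
        m = in_set.sum()
        dec = 1.0 / (p - m)
        for j in range(n):
            ordered = order[:, j]
            walk_in = in_set[ordered]
            w = np.abs(r_sym[ordered, j]) ** tau
            inc = np.where(walk_in, w, 0.0)
            tot = inc.sum()
            step = inc / tot - np.where(walk_in, 0.0, dec)
            nu = np.cumsum(step)
            if mx_diff:
                es[si, j] = nu.max(initial=0.0) + nu.min(initial=0.0)
            else:
                es[si, j] = nu[np.argmax(np.abs(nu))]
    return pd.DataFrame(es, index=list(sets.keys()), columns=matrix.columns)
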