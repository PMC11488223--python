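"""Per-cell morphological and mitochondrial feature extraction.

Masks come in as labeled images (cells and nuclei share label ids); features
come out as one row per cell with a fixed, documented column order.  The
descriptor set is 7 descriptors x 3 compartments (Cell, Nucleus, Cytoplasm):
Area, Perimeter, MajorAxisLength, MinorAxisLength, FormFactor, AspectRatio,
PerimeterAreaRatio — 21 features in total — plus Solidity, Eccentricity and
the nucleus:cell area ratio used by QC.

Conventions: coordinates are pixel-centered, origin top-left, row-major.
Axis lengths are moment based (4*sqrt of the pixel-coordinate covariance
eigenvalues, the normalized-second-central-moments ellipse).  The perimeter
is the Crofton estimate with 4 directions, which converges to the true
boundary length for smooth shapes (chain-code style estimators overshoot a
circle's perimeter by ~4%, which would bias the form factor of round cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.feature import graycomatrix, graycoprops
from skimage.morphology import convex_hull_image

from .synthetic import AUX_FEATURES, BASE_DESCRIPTORS, CANONICAL_FEATURES, COMPARTMENTS

__all__ = [
    "compute_shape_descriptors",
    "form_factor",
    "extract_single_cell_features",
    "compute_mito_features",
    "qc_filter",
    "MITO_FEATURES",
]

MITO_FEATURES = (
    "Mito_MeanIntensity",
    "Mito_IntegratedIntensity",
    "Mito_StdIntensity",
    "Mito_MADIntensity",
    "Mito_MassDisplacement",
    "Mito_FracAtD_1",
    "Mito_FracAtD_2",
    "Mito_FracAtD_3",
    "Mito_FracAtD_4",
    "Mito_Texture_Contrast_1",
    "Mito_Texture_Homogeneity_1",
    "Mito_Texture_Entropy_1",
    "Mito_Texture_Correlation_1",
    "Mito_Texture_Contrast_3",
    "Mito_Texture_Homogeneity_3",
    "Mito_Texture_Entropy_3",
    "Mito_Texture_Correlation_3",
)

QC_SOLIDITY_EPS = 1e-6
QC_NUCLEUS_RATIO = 0.85


def form_factor(area: float, perimeter: float) -> float:
    """4*pi*Area/Perimeter^2 — 1 for a circle, smaller for complex outlines."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def _moment_axes(mask: np.ndarray):
    """Eigenvalues of the pixel-coordinate covariance -> axis lengths."""
    ys, xs = np.nonzero(mask)
    coords = np.column_stack([ys, xs]).astype(float)
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / coords.shape[0]
    lam = np.linalg.eigvalsh(cov)  # ascending
    lam = np.clip(lam, 0.0, None)
    major = 4.0 * np.sqrt(lam[1])
    minor = 4.0 * np.sqrt(lam[0])
    ecc = float(np.sqrt(1.0 - lam[0] / lam[1])) if lam[1] > 0 else 0.0
    return major, minor, ecc


def _compartment_descriptors(mask: np.ndarray) -> dict:
    """Descriptors for an arbitrary nonempty mask (no topology checks)."""
    area = float(mask.sum())
    perim = float(measure.perimeter_crofton(mask, directions=4))
    major, minor, _ = _moment_axes(mask)
    if perim <= 0:  # single isolated pixel
        perim = 4.0
    return {
        "Area": area,
        "Perimeter": perim,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "FormFactor": form_factor(area, perim),
        "AspectRatio": major / minor if minor > 0 else np.inf,
        "PerimeterAreaRatio": perim / area,
    }


def compute_shape_descriptors(mask: np.ndarray) -> dict:
    """Shape descriptors of a single binary object.

    Raises ``ValueError`` on an empty mask and on masks with more than one
    connected component (call per label instead).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    _, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(
            f"mask has {n} connected components; compute descriptors label-wise"
        )
    out = _compartment_descriptors(mask)
    hull = convex_hull_image(mask)
    out["Solidity"] = out["Area"] / float(hull.sum())
    *_, ecc = _moment_axes(mask)
    out["Eccentricity"] = ecc
    return out


# ---------------------------------------------------------------------------
# mitochondrial features
# ---------------------------------------------------------------------------


def compute_mito_features(mito: np.ndarray, cell_mask: np.ndarray) -> dict:
    """Intensity, radial-distribution and texture features inside one cell.

    FracAtD_k are intensity fractions over 4 equal-width rings of normalized
    distance-to-edge (ring 1 = outermost shell, ring 4 = object core), and
    sum to 1.  Texture is from a symmetric, normalized gray-level
    co-occurrence matrix (8 levels, offsets 1 and 3 px, averaged over the 4
    principal directions); on an all-zero channel texture features are NaN.
    """
    cell_mask = np.asarray(cell_mask).astype(bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    mito = np.asarray(mito, dtype=float)
    if mito.shape != cell_mask.shape:
        raise ValueError("image and mask dimensions differ")
    vals = mito[cell_mask]
    if not np.all(np.isfinite(vals)) or (vals < 0).any():
        raise ValueError("intensities must be finite and non-negative")
    out = {}
    total = float(vals.sum())
    out["Mito_MeanIntensity"] = float(vals.mean())
    out["Mito_IntegratedIntensity"] = total
    out["Mito_StdIntensity"] = float(vals.std())
    out["Mito_MADIntensity"] = float(np.median(np.abs(vals - np.median(vals))))

    ys, xs = np.nonzero(cell_mask)
    bc = np.array([ys.mean(), xs.mean()])
    if total > 0:
        wc = np.array(
            [np.average(ys, weights=mito[cell_mask]),
             np.average(xs, weights=mito[cell_mask])]
        )
        out["Mito_MassDisplacement"] = float(np.linalg.norm(wc - bc))
    else:
        out["Mito_MassDisplacement"] = 0.0

    # radial rings on normalized distance-to-edge
    dist = ndimage.distance_transform_edt(cell_mask)
    dmax = dist[cell_mask].max()
    frac = np.zeros(4)
    if total > 0 and dmax > 0:
        norm = dist[cell_mask] / dmax
        ring = np.minimum((norm * 4).astype(int), 3)
        for k in range(4):
            frac[k] = mito[cell_mask][ring == k].sum() / total
    elif total > 0:
        frac[0] = 1.0
    for k in range(4):
        out[f"Mito_FracAtD_{k + 1}"] = float(frac[k])

    # texture: quantize inside-mask intensities to 8 levels
    if total > 0 and vals.max() > vals.min():
        q = np.zeros_like(mito, dtype=np.uint8)
        lev = np.clip(
            ((mito - vals.min()) / (vals.max() - vals.min()) * 8).astype(int), 0, 7
        )
        q[cell_mask] = lev[cell_mask] + 1  # reserve 0 for outside
        for off in (1, 3):
            glcm = graycomatrix(
                q, distances=[off], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                levels=9, symmetric=True, normed=False,
            )[1:, 1:, :, :].astype(float)  # drop outside-mask level
            s = glcm.sum(axis=(0, 1), keepdims=True)
            s[s == 0] = 1.0
            glcm = glcm / s
            glcm_m = glcm.mean(axis=3, keepdims=True)
            out[f"Mito_Texture_Contrast_{off}"] = float(
                graycoprops_from(glcm_m, "contrast")
            )
            out[f"Mito_Texture_Homogeneity_{off}"] = float(
                graycoprops_from(glcm_m, "homogeneity")
            )
            p = glcm_m[:, :, 0, 0]
            nz = p[p > 0]
            out[f"Mito_Texture_Entropy_{off}"] = float(-(nz * np.log2(nz)).sum())
            out[f"Mito_Texture_Correlation_{off}"] = float(
                graycoprops_from(glcm_m, "correlation")
            )
    else:
        for off in (1, 3):
            for prop in ("Contrast", "Homogeneity", "Entropy", "Correlation"):
                out[f"Mito_Texture_{prop}_{off}"] = np.nan
    return out


def graycoprops_from(glcm: np.ndarray, prop: str) -> float:
    return float(graycoprops(glcm, prop)[0, 0])


# ---------------------------------------------------------------------------
# single-cell extraction
# ---------------------------------------------------------------------------


def extract_single_cell_features(
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    mito: np.ndarray | None = None,
    layout_row: pd.Series | dict | None = None,
    image_id: str = "img0",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One feature record per cell label.

    Returns ``(records, dropped)``: border-touching cells are dropped with
    reason ``"border"``; nucleus labels without a matching cell are reported
    with reason ``"orphan_nucleus"``.  Cytoplasm = cell mask minus nucleus
    mask.  When ``mito`` is given, Mito_* features are appended.
    """
    cell_labels = np.asarray(cell_labels)
    nucleus_labels = np.asarray(nucleus_labels)
    if cell_labels.shape != nucleus_labels.shape:
        raise ValueError("cell and nucleus label images have different dimensions")
    if mito is not None and np.asarray(mito).shape != cell_labels.shape:
        raise ValueError("mitochondria channel dimensions differ from masks")

    meta = {
        "experiment": "", "operator": "", "well_id": "",
    }
    if layout_row is not None:
        lr = dict(layout_row)
        for k in meta:
            meta[k] = lr.get(k, "")

    records, dropped = [], []
    cell_ids = np.unique(cell_labels)
    cell_ids = cell_ids[cell_ids > 0]
    nuc_ids = set(np.unique(nucleus_labels)) - {0}
    orphan = sorted(nuc_ids - set(cell_ids.tolist()))
    for lab in orphan:
        dropped.append({"cell_id": int(lab), "reason": "orphan_nucleus"})

    h, w = cell_labels.shape
    slices = ndimage.find_objects(cell_labels)
    for lab in cell_ids:
        sl = slices[int(lab) - 1]
        if sl is None:
            continue
        touches = (
            sl[0].start == 0 or sl[1].start == 0
            or sl[0].stop == h or sl[1].stop == w
        )
        if touches:
            dropped.append({"cell_id": int(lab), "reason": "border"})
            continue
        # pad by 1 so boundary estimates see background on all sides
        sl = (
            slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, h)),
            slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, w)),
        )
        cmask = cell_labels[sl] == lab
        nmask = (nucleus_labels[sl] == lab) & cmask
        if not nmask.any():
            dropped.append({"cell_id": int(lab), "reason": "no_nucleus"})
            continue
        cyto = cmask & ~nmask
        if not cyto.any():
            dropped.append({"cell_id": int(lab), "reason": "no_cytoplasm"})
            continue
        rec = dict(meta)
        rec["image_id"] = image_id
        rec["cell_id"] = int(lab)
        cell_d = _compartment_descriptors(cmask)
        nuc_d = _compartment_descriptors(nmask)
        cyto_d = _compartment_descriptors(cyto)
        for comp, d in (("Cell", cell_d), ("Nucleus", nuc_d), ("Cytoplasm", cyto_d)):
            for name in BASE_DESCRIPTORS:
                rec[f"{comp}_{name}"] = d[name]
        hull = convex_hull_image(cmask)
        rec["Cell_Solidity"] = cell_d["Area"] / float(hull.sum())
        *_, ecc = _moment_axes(cmask)
        rec["Cell_Eccentricity"] = ecc
        rec["NucleusCellAreaRatio"] = nuc_d["Area"] / cell_d["Area"]
        if mito is not None:
            rec.update(compute_mito_features(np.asarray(mito)[sl], cmask))
        records.append(rec)

    cols = (
        ["experiment", "operator", "well_id", "image_id", "cell_id"]
        + list(CANONICAL_FEATURES) + list(AUX_FEATURES)
        + (list(MITO_FEATURES) if mito is not None else [])
    )
    rec_df = pd.DataFrame(records, columns=cols)
    drop_df = pd.DataFrame(dropped, columns=["cell_id", "reason"])
    return rec_df, drop_df


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    records: pd.DataFrame,
    solidity_rule: bool = True,
    nucleus_ratio_rule: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reject debris and poorly segmented cells.

    A record is rejected when Solidity >= 1 - 1e-6 (perfectly convex blobs
    are debris or segmentation failures) or when the nucleus:cell area ratio
    is >= 0.85 (inclusive bound).  Each rule can be toggled off.  Returns
    ``(kept, rejected)``; rejected rows carry a ``qc_reason`` column.
    """
    for col, rule in (
        ("Cell_Solidity", solidity_rule),
        ("NucleusCellAreaRatio", nucleus_ratio_rule),
    ):
        if rule and col not in records.columns:
            raise ValueError(f"records lack required feature {col!r}")
    reasons = pd.Series("", index=records.index, dtype=object)
    reject = pd.Series(False, index=records.index)
    if solidity_rule:
        bad = records["Cell_Solidity"] >= 1.0 - QC_SOLIDITY_EPS
        reasons[bad] = "solidity"
        reject |= bad
    if nucleus_ratio_rule:
        bad = records["NucleusCellAreaRatio"] >= QC_NUCLEUS_RATIO
        reasons[bad & ~reject] = "nucleus_ratio"
        reasons[bad & reject] = "solidity+nucleus_ratio"
        reject |= bad
    kept = records.loc[~reject].copy()
    rejected = records.loc[reject].copy()
    rejected["qc_reason"] = reasons[reject]
    return kept, rejected
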