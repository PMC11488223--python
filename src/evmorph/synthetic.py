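"""Synthetic plates, wells and omics tables with known ground truth.

The generator emulates the structure of a microglia morphology bioactivity
assay: unstimulated cells (``NEG_CTL``) are small and round, cytokine-
stimulated cells (``POS_CTL``) are large, elongated and ramified, and
EV-treated stimulated cells (``POS_EV``) sit between the two control
phenotypes.  The fraction of the stimulated-to-unstimulated gap recovered by
treatment is the single ground-truth bioactivity parameter ``ev_effect``
(0 = indistinguishable from POS_CTL, 1 = fully restored to NEG_CTL).

Two generation routes are provided:

* :func:`render_synthetic_well` rasterizes labeled cell/nucleus masks plus a
  mitochondria intensity channel, so the full image-analysis path can be
  exercised.  Cell silhouettes are star-shaped polygons: an ellipse body with
  Gaussian radial protrusion bumps, which reproduces the ramified-vs-amoeboid
  contrast with four latent parameters (body radius, elongation, protrusion
  count, protrusion length).
* :func:`gen_feature_table` draws per-cell feature vectors directly from
  group-conditional distributions whose means are the deterministic
  latent-to-feature map evaluated at the group latents.  For ``POS_EV`` the
  mean vector is interpolated between the two control means on the feature
  scale, so treatment effects are exactly linear in ``ev_effect`` by design.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so identical configurations produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

NEG_CTL = "NEG_CTL"
POS_CTL = "POS_CTL"
POS_EV = "POS_EV"
KNOWN_GROUPS = (NEG_CTL, POS_CTL, POS_EV)

COMPARTMENTS = ("Cell", "Nucleus", "Cytoplasm")
BASE_DESCRIPTORS = (
    "Area",
    "Perimeter",
    "MajorAxisLength",
    "MinorAxisLength",
    "FormFactor",
    "AspectRatio",
    "PerimeterAreaRatio",
)

#: the 21 canonical cellular/nuclear descriptors used for composite scoring
CANONICAL_FEATURES = tuple(
    f"{comp}_{desc}" for comp in COMPARTMENTS for desc in BASE_DESCRIPTORS
)

#: QC and auxiliary descriptors carried alongside the canonical set
AUX_FEATURES = ("Cell_Solidity", "Cell_Eccentricity", "NucleusCellAreaRatio")

LIPID_CLASSES = ("PC", "PE", "PG", "PE-P", "SM", "Cer", "HexCer", "TG", "LPC")

_PROTRUSION_WIDTH_PX = 4.0  # base width of a protrusion at the cell body


class SyntheticConfigError(ValueError):
    """Raised for invalid generator configurations."""


class SyntheticGenerationError(RuntimeError):
    """Raised when a well cannot be rendered under the configuration."""


@dataclass(frozen=True)
class MorphParams:
    """Latent shape-parameter distribution for one group (mean, sd pairs)."""

    body_radius: tuple[float, float]
    elongation: tuple[float, float]
    protrusion_count: tuple[float, float]
    protrusion_length: tuple[float, float]

    def means(self) -> np.ndarray:
        return np.array(
            [
                self.body_radius[0],
                self.elongation[0],
                self.protrusion_count[0],
                self.protrusion_length[0],
            ]
        )


DEFAULT_MORPH_PARAMS: dict[str, MorphParams] = {
    # unstimulated: small, round, few short processes
    NEG_CTL: MorphParams(
        body_radius=(18.0, 2.5),
        elongation=(1.3, 0.12),
        protrusion_count=(2.0, 0.8),
        protrusion_length=(8.0, 2.5),
    ),
    # cytokine stimulated: large, elongated, ramified
    POS_CTL: MorphParams(
        body_radius=(28.0, 3.5),
        elongation=(2.2, 0.25),
        protrusion_count=(5.0, 1.2),
        protrusion_length=(25.0, 5.0),
    ),
}


@dataclass(frozen=True)
class SyntheticPlateConfig:
    """Configuration of a synthetic assay plate.

    ``ev_effect`` is the fraction of the POS_CTL→NEG_CTL morphology gap
    recovered under EV treatment; ``operator_shift``/``experiment_shift`` are
    additive perturbations of the latent body radius (px) applied per
    operator/experiment index, identically to every group.
    """

    n_wells_per_group: int = 8
    groups: tuple[str, ...] = KNOWN_GROUPS
    cells_per_well_range: tuple[int, int] = (700, 1000)
    morph_params_per_group: dict[str, MorphParams] = field(
        default_factory=lambda: dict(DEFAULT_MORPH_PARAMS)
    )
    ev_effect: float = 0.5
    operator_shift: float = 0.0
    experiment_shift: float = 0.0
    n_operators: int = 1
    n_experiments: int = 1
    image_size: int = 1024
    noise_sd: float = 0.02
    cell_noise_frac: float = 0.35
    well_noise_frac: float = 0.05
    debris_frac: float = 0.02
    large_nucleus_frac: float = 0.01
    cytokine_dose_ng_ml: float = 5.0
    ev_dose: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells_per_group < 2:
            raise SyntheticConfigError("n_wells_per_group must be >= 2")
        unknown = set(self.groups) - set(KNOWN_GROUPS)
        if unknown:
            raise SyntheticConfigError(f"unknown group label(s): {sorted(unknown)}")
        lo, hi = self.cells_per_well_range
        if not (0 < lo <= hi):
            raise SyntheticConfigError(
                "cells_per_well_range must be positive and ordered"
            )
        if not 0.0 <= self.ev_effect <= 1.0:
            raise SyntheticConfigError("ev_effect must lie in [0, 1]")
        if self.n_operators < 1 or self.n_experiments < 1:
            raise SyntheticConfigError("need at least one operator and experiment")

    def replace(self, **kw) -> "SyntheticPlateConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# latent -> feature map
# ---------------------------------------------------------------------------


def _ellipse_perimeter(a, b):
    # Ramanujan's approximation
    return np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))


def latent_to_features(radius, elongation, protrusion_count, protrusion_length,
                       nucleus_ratio=0.4):
    """Deterministic map from latent shape parameters to the canonical
    feature vector (plus auxiliary descriptors), vectorized over arrays.

    The map is a smooth geometric idealization of the rendered silhouettes:
    an ellipse of area pi*R^2 with ``protrusion_count`` tapered protrusions of
    length ``protrusion_length`` and base width ~4 px.
    """
    R = np.asarray(radius, dtype=float)
    E = np.maximum(np.asarray(elongation, dtype=float), 1.0)
    P = np.maximum(np.asarray(protrusion_count, dtype=float), 0.0)
    L = np.maximum(np.asarray(protrusion_length, dtype=float), 0.0)
    w = _PROTRUSION_WIDTH_PX

    a = R * np.sqrt(E)  # semi-major
    b = R / np.sqrt(E)  # semi-minor
    body_area = np.pi * R**2
    body_perim = _ellipse_perimeter(a, b)

    cell_area = body_area + P * 0.5 * w * L
    cell_perim = body_perim + P * (2 * np.sqrt(L**2 + (w / 2) ** 2) - w)
    reach = L * np.tanh(P / 2.0)
    cell_major = 2 * a + 0.6 * reach
    cell_minor = 2 * b + 0.15 * reach

    nuc_area = np.clip(nucleus_ratio, 0.0, 1.0) * cell_area
    nuc_elong = 1.0 + 0.3 * (E - 1.0)
    nuc_r = np.sqrt(nuc_area / np.pi)
    na = nuc_r * np.sqrt(nuc_elong)
    nb = nuc_r / np.sqrt(nuc_elong)
    nuc_perim = _ellipse_perimeter(na, nb)

    cyto_area = cell_area - nuc_area
    cyto_perim = cell_perim + nuc_perim  # annulus: outer + inner boundary

    def pack(area, perim, major, minor):
        return {
            "Area": area,
            "Perimeter": perim,
            "MajorAxisLength": major,
            "MinorAxisLength": minor,
            "FormFactor": 4 * np.pi * area / perim**2,
            "AspectRatio": major / minor,
            "PerimeterAreaRatio": perim / area,
        }

    feats = {}
    for comp, d in (
        ("Cell", pack(cell_area, cell_perim, cell_major, cell_minor)),
        ("Nucleus", pack(nuc_area, nuc_perim, 2 * na, 2 * nb)),
        ("Cytoplasm", pack(cyto_area, cyto_perim, cell_major, cell_minor)),
    ):
        for name, val in d.items():
            feats[f"{comp}_{name}"] = val

    hull_extra = 0.5 * P * L**2  # protrusions open concavities vs the hull
    feats["Cell_Solidity"] = cell_area / (cell_area + hull_extra)
    feats["Cell_Eccentricity"] = np.sqrt(1.0 - 1.0 / E**2)
    feats["NucleusCellAreaRatio"] = np.broadcast_to(
        np.asarray(nucleus_ratio, dtype=float), np.shape(cell_area)
    ).copy() if np.ndim(cell_area) else float(nucleus_ratio)
    return feats


def group_feature_means(config: SyntheticPlateConfig) -> pd.DataFrame:
    """Expected (noise-free) feature vector per group.

    POS_EV means interpolate POS_CTL toward NEG_CTL by ``ev_effect`` on the
    feature scale, which makes treatment effects exactly linear in the
    bioactivity parameter.
    """
    mp = config.morph_params_per_group
    rows = {}
    for grp in (NEG_CTL, POS_CTL):
        th = mp[grp].means()
        rows[grp] = {
            k: float(v) for k, v in latent_to_features(*th).items()
        }
    means = pd.DataFrame(rows).T
    if POS_EV in config.groups or True:
        delta = config.ev_effect
        means.loc[POS_EV] = (
            means.loc[POS_CTL] + delta * (means.loc[NEG_CTL] - means.loc[POS_CTL])
        )
    return means


def _batch_shift_vector(config: SyntheticPlateConfig, operator_idx: int,
                        experiment_idx: int) -> pd.Series:
    """Feature-space offset for an operator/experiment stratum.

    Derived from the latent body-radius shift at the NEG_CTL reference point
    and applied identically to every group, so between-group differences are
    invariant to batch.
    """
    s = config.operator_shift * operator_idx + config.experiment_shift * experiment_idx
    if s == 0:
        zero = {k: 0.0 for k in list(CANONICAL_FEATURES) + list(AUX_FEATURES)}
        return pd.Series(zero)
    th = config.morph_params_per_group[NEG_CTL].means()
    base = latent_to_features(*th)
    shifted = latent_to_features(th[0] + s, th[1], th[2], th[3])
    return pd.Series({k: float(shifted[k]) - float(base[k]) for k in base})


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = (
    "well_id", "row", "col", "group", "cytokine_dose_ng_ml", "ev_dose",
    "operator", "experiment",
)


def gen_plate_layout(config: SyntheticPlateConfig) -> pd.DataFrame:
    """Assign wells to groups/doses/operators/experiments.

    One plate block (all groups x ``n_wells_per_group``) is laid out per
    operator x experiment combination; well ids are unique across blocks.
    """
    rows = []
    row_letters = "ABCDEFGHIJKLMNOP"
    for e in range(config.n_experiments):
        for o in range(config.n_operators):
            idx = 0
            for grp in config.groups:
                for _ in range(config.n_wells_per_group):
                    r, c = divmod(idx, 12)
                    well = f"E{e + 1}_O{o + 1}_{row_letters[r]}{c + 1:02d}"
                    rows.append(
                        {
                            "well_id": well,
                            "row": row_letters[r],
                            "col": c + 1,
                            "group": grp,
                            "cytokine_dose_ng_ml": (
                                0.0 if grp == NEG_CTL else config.cytokine_dose_ng_ml
                            ),
                            "ev_dose": config.ev_dose if grp == POS_EV else 0.0,
                            "operator": f"O{o + 1}",
                            "experiment": f"E{e + 1}",
                        }
                    )
                    idx += 1
    return pd.DataFrame(rows, columns=list(LAYOUT_COLUMNS))


# ---------------------------------------------------------------------------
# image-free fast path
# ---------------------------------------------------------------------------


def gen_feature_table(
    config: SyntheticPlateConfig, layout: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Draw per-cell feature vectors directly (no rendering).

    Per-cell noise and a per-well random offset are scaled by each feature's
    control gap |POS_CTL - NEG_CTL| (see docs/methods.md for the calibration).
    A small ``debris_frac`` of cells gets Solidity == 1 and a
    ``large_nucleus_frac`` gets NucleusCellAreaRatio >= 0.85 so the QC rules
    have work to do.
    """
    if layout is None:
        layout = gen_plate_layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    means = group_feature_means(config)
    cols = list(CANONICAL_FEATURES) + list(AUX_FEATURES)
    gap = (means.loc[POS_CTL, cols] - means.loc[NEG_CTL, cols]).abs()
    # floor keeps zero-gap features (none by default) from collapsing to 0 sd
    scale = np.maximum(gap.to_numpy(), 1e-3 * means.loc[NEG_CTL, cols].abs().to_numpy())
    lo, hi = config.cells_per_well_range

    frames = []
    for _, wrow in layout.iterrows():
        n_cells = int(rng.integers(lo, hi + 1))
        op_idx = int(wrow["operator"][1:]) - 1
        ex_idx = int(wrow["experiment"][1:]) - 1
        shift = _batch_shift_vector(config, op_idx, ex_idx)[cols].to_numpy()
        mu = means.loc[wrow["group"], cols].to_numpy() + shift
        well_offset = rng.normal(0.0, config.well_noise_frac) * scale
        x = (
            mu
            + well_offset
            + rng.normal(size=(n_cells, len(cols))) * (config.cell_noise_frac * scale)
        )
        df = pd.DataFrame(x, columns=cols)
        # bounded auxiliary descriptors get small fixed noise so the QC
        # rules see a realistic (few-percent) debris rate, not a gap-scaled one
        df["Cell_Solidity"] = mu[cols.index("Cell_Solidity")] + rng.normal(
            0.0, 0.02, size=n_cells
        )
        df["Cell_Eccentricity"] = mu[cols.index("Cell_Eccentricity")] + rng.normal(
            0.0, 0.03, size=n_cells
        )
        # nucleus:cell area ratio has its own biology: Beta(8,12) clipped
        df["NucleusCellAreaRatio"] = np.clip(
            rng.beta(8, 12, size=n_cells), 0.1, 0.8
        )
        n_debris = int(round(config.debris_frac * n_cells))
        n_bignuc = int(round(config.large_nucleus_frac * n_cells))
        if n_debris:
            df.iloc[:n_debris, df.columns.get_loc("Cell_Solidity")] = 1.0
        if n_bignuc:
            sl = slice(n_debris, n_debris + n_bignuc)
            df.iloc[sl, df.columns.get_loc("NucleusCellAreaRatio")] = rng.uniform(
                0.85, 0.95, size=n_bignuc
            )
        _clip_feature_frame(df)
        df.insert(0, "experiment", wrow["experiment"])
        df.insert(1, "operator", wrow["operator"])
        df.insert(2, "well_id", wrow["well_id"])
        df.insert(3, "image_id", wrow["well_id"] + "_f00")
        df.insert(4, "cell_id", np.arange(1, n_cells + 1))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _clip_feature_frame(df: pd.DataFrame) -> None:
    for comp in COMPARTMENTS:
        df[f"{comp}_Area"] = df[f"{comp}_Area"].clip(lower=1.0)
        df[f"{comp}_Perimeter"] = df[f"{comp}_Perimeter"].clip(lower=1.0)
        df[f"{comp}_MajorAxisLength"] = df[f"{comp}_MajorAxisLength"].clip(lower=1.0)
        df[f"{comp}_MinorAxisLength"] = df[f"{comp}_MinorAxisLength"].clip(lower=1.0)
        df[f"{comp}_FormFactor"] = df[f"{comp}_FormFactor"].clip(0.01, 1.02)
        df[f"{comp}_AspectRatio"] = df[f"{comp}_AspectRatio"].clip(lower=1.0)
        df[f"{comp}_PerimeterAreaRatio"] = df[f"{comp}_PerimeterAreaRatio"].clip(
            lower=1e-4
        )
    df["Cell_Solidity"] = df["Cell_Solidity"].clip(0.01, 1.0)
    df["Cell_Eccentricity"] = df["Cell_Eccentricity"].clip(0.0, 0.999)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _sample_latents(group: str, config: SyntheticPlateConfig, rng, n: int):
    mp = config.morph_params_per_group
    if group == POS_EV:
        d = config.ev_effect
        mu = mp[POS_CTL].means() + d * (mp[NEG_CTL].means() - mp[POS_CTL].means())
        sd = (1 - d) * np.array(
            [mp[POS_CTL].body_radius[1], mp[POS_CTL].elongation[1],
             mp[POS_CTL].protrusion_count[1], mp[POS_CTL].protrusion_length[1]]
        ) + d * np.array(
            [mp[NEG_CTL].body_radius[1], mp[NEG_CTL].elongation[1],
             mp[NEG_CTL].protrusion_count[1], mp[NEG_CTL].protrusion_length[1]]
        )
    else:
        p = mp[group]
        mu = p.means()
        sd = np.array(
            [p.body_radius[1], p.elongation[1], p.protrusion_count[1],
             p.protrusion_length[1]]
        )
    lat = rng.normal(mu, sd, size=(n, 4))
    lat[:, 0] = np.clip(lat[:, 0], 4.0, None)       # radius
    lat[:, 1] = np.clip(lat[:, 1], 1.0, None)       # elongation
    lat[:, 2] = np.clip(np.round(lat[:, 2]), 0, None)  # protrusion count
    lat[:, 3] = np.clip(lat[:, 3], 0.0, None)       # protrusion length
    return lat


def _cell_polygon(radius, elong, n_prot, prot_len, phi, rng, n_theta=180):
    """Star-shaped silhouette: rotated ellipse + Gaussian radial bumps."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    a = radius * np.sqrt(elong)
    b = radius / np.sqrt(elong)
    r = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if n_prot >= 1:
        centers = rng.uniform(0, 2 * np.pi, size=int(n_prot))
        width = _PROTRUSION_WIDTH_PX / (2.0 * max(radius, 1.0))
        for c in centers:
            d = np.angle(np.exp(1j * (theta - c)))
            r = r + prot_len * np.exp(-0.5 * (d / max(width, 0.05)) ** 2)
    y = r * np.sin(theta + phi)
    x = r * np.cos(theta + phi)
    return y, x


def render_synthetic_well(
    well: pd.Series | dict,
    config: SyntheticPlateConfig,
    n_cells: int | None = None,
    well_index: int = 0,
):
    """Rasterize one well: labeled cell/nucleus masks + mitochondria channel.

    Returns ``(cell_labels, nucleus_labels, mito_image, ground_truth)`` where
    ``ground_truth`` is a per-cell table of the latent parameters actually
    rendered.  Raises :class:`SyntheticGenerationError` when more than 20% of
    placements fail (overcrowding).
    """
    well = dict(well)
    size = int(config.image_size)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 202, well_index])
    )
    if n_cells is None:
        lo, hi = config.cells_per_well_range
        n_cells = int(rng.integers(lo, hi + 1))
    lat = _sample_latents(well["group"], config, rng, n_cells)
    mean_foot = np.pi * np.mean(lat[:, 0]) ** 2 * 2.5
    if n_cells * mean_foot > 0.3 * size * size:
        raise SyntheticGenerationError(
            "expected cell footprint exceeds 30% of the image; "
            "increase image_size or reduce cells per well"
        )

    cells = np.zeros((size, size), dtype=np.uint16)
    nuclei = np.zeros_like(cells)
    mito = np.zeros((size, size), dtype=float)
    gt_rows = []
    occupied = np.zeros((size, size), dtype=bool)
    failures = 0
    label = 0
    for i in range(n_cells):
        R, E, P, L = lat[i]
        reach = R * np.sqrt(E) + L + 2
        placed = False
        for _ in range(30):
            cy, cx = rng.uniform(reach, size - reach, size=2)
            phi = rng.uniform(0, np.pi)
            py, px = _cell_polygon(R, E, P, L, phi, rng)
            rr, cc = draw_polygon(py + cy, px + cx, shape=cells.shape)
            if rr.size == 0 or occupied[rr, cc].any():
                continue
            label += 1
            cells[rr, cc] = label
            occupied[rr, cc] = True
            # nucleus: concentric ellipse, area ratio Beta(8,12) in (0.1, 0.8)
            ratio = float(np.clip(rng.beta(8, 12), 0.1, 0.8))
            cell_area = rr.size
            nr = np.sqrt(ratio * cell_area / np.pi)
            ne = 1.0 + 0.3 * (E - 1.0)
            na, nb = nr * np.sqrt(ne), nr / np.sqrt(ne)
            na = min(na, 0.9 * R * np.sqrt(E))
            nb = min(nb, 0.9 * R / np.sqrt(E))
            th = np.linspace(0, 2 * np.pi, 90, endpoint=False)
            nrad = (na * nb) / np.sqrt(
                (nb * np.cos(th)) ** 2 + (na * np.sin(th)) ** 2
            )
            nrr, ncc = draw_polygon(
                nrad * np.sin(th + phi) + cy, nrad * np.cos(th + phi) + cx,
                shape=cells.shape,
            )
            inside = cells[nrr, ncc] == label
            nuclei[nrr[inside], ncc[inside]] = label
            # mitochondria: puncta confined to this cell's mask; sample spot
            # centers from the eroded interior so Gaussian tails stay inside
            n_spots = max(1, rng.poisson(cell_area / 150.0))
            y0, y1 = rr.min(), rr.max() + 1
            x0, x1 = cc.min(), cc.max() + 1
            local = np.zeros((y1 - y0, x1 - x0), bool)
            local[rr - y0, cc - x0] = True
            interior = ndimage.binary_erosion(local, iterations=2)
            iy, ix = np.nonzero(interior if interior.any() else local)
            pick = rng.integers(0, iy.size, size=n_spots)
            amp = rng.lognormal(0.0, 0.4, size=n_spots)
            for k in range(n_spots):
                _add_spot(mito, iy[pick[k]] + y0, ix[pick[k]] + x0, amp[k])
            gt_rows.append(
                {
                    "well_id": well.get("well_id", "?"),
                    "cell_label": label,
                    "group": well["group"],
                    "body_radius": R,
                    "elongation": E,
                    "protrusion_count": P,
                    "protrusion_length": L,
                    "nucleus_ratio": ratio,
                }
            )
            placed = True
            break
        if not placed:
            failures += 1
    if n_cells and failures > 0.2 * n_cells:
        raise SyntheticGenerationError(
            f"{failures}/{n_cells} placements failed; increase image_size"
        )
    if config.noise_sd > 0:
        mito = mito + rng.normal(0.0, config.noise_sd, size=mito.shape)
    mito = np.clip(mito, 0.0, None)
    gt = pd.DataFrame(
        gt_rows,
        columns=[
            "well_id", "cell_label", "group", "body_radius", "elongation",
            "protrusion_count", "protrusion_length", "nucleus_ratio",
        ],
    )
    return cells, nuclei, mito, gt


def _add_spot(img, cy, cx, amp, sigma=1.5):
    rad = int(3 * sigma)
    y0, y1 = max(cy - rad, 0), min(cy + rad + 1, img.shape[0])
    x0, x1 = max(cx - rad, 0), min(cx + rad + 1, img.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


# ---------------------------------------------------------------------------
# omics tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticOmicsConfig:
    """Secretion panel, lipidome and proteome generator settings.

    Defaults mirror the assay's scale: a 200-analyte secretion panel with 94
    detected analytes and 40 analytes shifted by stimulation (38 up, 2 down)
    plus 24 shifted by EV treatment (10 up, 14 down); a 2662-protein matrix
    with a flagged differential subset; lipid species in 9 annotated classes
    where stimulation raises every class total except LPC.
    """

    n_analytes: int = 200
    n_detected: int = 94
    n_stim_diff: int = 40
    n_stim_down: int = 2
    n_ev_diff: int = 24
    n_ev_up: int = 10
    n_samples_per_group: int = 6
    n_proteins: int = 2662
    n_protein_samples_per_group: int = 3
    n_protein_diff: int = 100
    protein_effect_log2: float = 2.0
    secretion_effect_log2: float = 2.0
    noise_log2: float = 0.3
    lipid_species_per_class: int = 12
    lipid_samples_per_group: int = 5
    lipid_effect_log2: float = 1.0
    n_gene_sets: int = 25
    gene_set_size: tuple[int, int] = (10, 50)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_detected > self.n_analytes:
            raise SyntheticConfigError("detected subset larger than panel")
        if self.n_stim_diff > self.n_detected or self.n_ev_diff > self.n_detected:
            raise SyntheticConfigError("differential set larger than detected panel")
        if self.n_protein_diff > self.n_proteins:
            raise SyntheticConfigError("differential set larger than protein panel")


@dataclass
class OmicsGroundTruth:
    secretion_stim_diff: pd.DataFrame
    secretion_ev_diff: pd.DataFrame
    protein_diff: pd.DataFrame
    lipid_class_effects: pd.DataFrame


def _sample_names(prefix, groups, n_per):
    names, labels = [], {}
    for g in groups:
        for i in range(n_per):
            s = f"{prefix}_{g}_{i + 1}"
            names.append(s)
            labels[s] = g
    return names, labels


def gen_omics_tables(config: SyntheticOmicsConfig):
    """Generate (secretion, lipids, proteins, gene_sets, ground_truth).

    Abundances are log-normal with additive group effects on the log2 scale,
    so fold-change ground truth is exact.  Analytes/proteins outside the
    flagged differential sets have exactly zero effect.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))

    # --- secretion panel -------------------------------------------------
    analytes = [f"CK{i + 1:03d}" for i in range(config.n_analytes)]
    detected = analytes[: config.n_detected]
    samples, sample_groups = _sample_names(
        "S", KNOWN_GROUPS, config.n_samples_per_group
    )
    base = rng.uniform(6, 12, size=config.n_analytes)  # log2 baseline
    stim_eff = np.zeros(config.n_analytes)
    ev_eff = np.zeros(config.n_analytes)
    diff_idx = rng.choice(config.n_detected, size=config.n_stim_diff, replace=False)
    sign = np.ones(config.n_stim_diff)
    sign[: config.n_stim_down] = -1.0
    stim_eff[diff_idx] = sign * config.secretion_effect_log2 * rng.uniform(
        0.8, 1.2, size=config.n_stim_diff
    )
    ev_idx = rng.choice(config.n_detected, size=config.n_ev_diff, replace=False)
    ev_sign = -np.ones(config.n_ev_diff)
    ev_sign[: config.n_ev_up] = 1.0
    ev_eff[ev_idx] = ev_sign * config.secretion_effect_log2 * rng.uniform(
        0.8, 1.2, size=config.n_ev_diff
    )
    log2 = np.empty((config.n_analytes, len(samples)))
    for j, s in enumerate(samples):
        g = sample_groups[s]
        mu = base.copy()
        if g in (POS_CTL, POS_EV):
            mu = mu + stim_eff
        if g == POS_EV:
            mu = mu + ev_eff
        log2[:, j] = mu + rng.normal(0, config.noise_log2, size=config.n_analytes)
    # undetected analytes sit at a low constant floor with tiny noise
    floor = 2.0
    und = np.arange(config.n_detected, config.n_analytes)
    log2[und, :] = floor + rng.normal(0, 0.05, size=(und.size, len(samples)))
    secretion = pd.DataFrame(2.0**log2, index=analytes, columns=samples)
    secretion.index.name = "analyte"
    secretion_groups = pd.Series(sample_groups, name="group")

    # --- lipidome --------------------------------------------------------
    lip_samples, lip_groups = _sample_names(
        "L", KNOWN_GROUPS, config.lipid_samples_per_group
    )
    neg_mode = {"PE", "PG", "PE-P", "Cer", "HexCer"}
    lrows = []
    class_eff = []
    for cls in LIPID_CLASSES:
        eff = 0.0 if cls == "LPC" else config.lipid_effect_log2
        class_eff.append({"class": cls, "stim_log2_effect": eff, "ev_log2_effect": 0.0})
        for i in range(config.lipid_species_per_class):
            b = rng.uniform(8, 14)
            row = {
                "species": f"{cls}({30 + i}:{i % 4})",
                "class": cls,
                "mode": "negative" if cls in neg_mode else "positive",
            }
            for s in lip_samples:
                mu = b + (eff if lip_groups[s] in (POS_CTL, POS_EV) else 0.0)
                row[s] = 2.0 ** (mu + rng.normal(0, config.noise_log2))
            lrows.append(row)
    lipids = pd.DataFrame(lrows)
    lipid_groups = pd.Series(lip_groups, name="group")

    # --- proteome --------------------------------------------------------
    proteins = [f"PROT{i + 1:04d}" for i in range(config.n_proteins)]
    prot_samples, prot_groups = _sample_names(
        "P", KNOWN_GROUPS, config.n_protein_samples_per_group
    )
    pbase = rng.uniform(18, 30, size=config.n_proteins)
    prot_eff = np.zeros(config.n_proteins)  # POS_EV vs POS_CTL
    stim_prot_eff = np.zeros(config.n_proteins)
    pidx = rng.choice(config.n_proteins, size=config.n_protein_diff, replace=False)
    psign = rng.choice([-1.0, 1.0], size=config.n_protein_diff)
    prot_eff[pidx] = psign * config.protein_effect_log2
    sidx = rng.choice(config.n_proteins, size=config.n_protein_diff, replace=False)
    stim_prot_eff[sidx] = rng.choice([-1.0, 1.0], size=config.n_protein_diff) * (
        config.protein_effect_log2
    )
    plog2 = np.empty((config.n_proteins, len(prot_samples)))
    for j, s in enumerate(prot_samples):
        g = prot_groups[s]
        mu = pbase.copy()
        if g in (POS_CTL, POS_EV):
            mu = mu + stim_prot_eff
        if g == POS_EV:
            mu = mu + prot_eff
        plog2[:, j] = mu + rng.normal(0, config.noise_log2, size=config.n_proteins)
    protein_matrix = pd.DataFrame(plog2, index=proteins, columns=prot_samples)
    protein_matrix.index.name = "protein"
    protein_groups = pd.Series(prot_groups, name="group")

    # --- gene sets -------------------------------------------------------
    gene_sets: dict[str, list[str]] = {}
    lo, hi = config.gene_set_size
    for k in range(config.n_gene_sets):
        n = int(rng.integers(lo, hi + 1))
        members = rng.choice(config.n_proteins, size=n, replace=False)
        gene_sets[f"SET_{k + 1:03d}"] = [proteins[m] for m in members]
    # two sets deliberately loaded with EV-responsive proteins
    up_ids = [proteins[i] for i in pidx[prot_eff[pidx] > 0][:30]]
    dn_ids = [proteins[i] for i in pidx[prot_eff[pidx] < 0][:30]]
    if len(up_ids) >= 5:
        gene_sets["SET_EV_UP"] = up_ids
    if len(dn_ids) >= 5:
        gene_sets["SET_EV_DOWN"] = dn_ids

    gt = OmicsGroundTruth(
        secretion_stim_diff=pd.DataFrame(
            {"analyte": [analytes[i] for i in diff_idx],
             "log2_effect": stim_eff[diff_idx]}
        ),
        secretion_ev_diff=pd.DataFrame(
            {"analyte": [analytes[i] for i in ev_idx],
             "log2_effect": ev_eff[ev_idx]}
        ),
        protein_diff=pd.DataFrame(
            {"protein": [proteins[i] for i in pidx],
             "log2_effect": prot_eff[pidx]}
        ),
        lipid_class_effects=pd.DataFrame(class_eff),
    )
    return {
        "secretion": secretion,
        "secretion_groups": secretion_groups,
        "lipids": lipids,
        "lipid_groups": lipid_groups,
        "proteins": protein_matrix,
        "protein_groups": protein_groups,
        "gene_sets": gene_sets,
        "ground_truth": gt,
    }
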