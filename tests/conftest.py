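import numpy as np
import pandas as pd
import pytest

from evmorph.synthetic import (
    SyntheticOmicsConfig,
    SyntheticPlateConfig,
    gen_feature_table,
    gen_omics_tables,
    gen_plate_layout,
)


@pytest.fixture(scope="session")
def small_plate():
    """A light plate: 4 wells/group, ~120 cells/well; fast but realistic."""
    cfg = SyntheticPlateConfig(
        n_wells_per_group=4, cells_per_well_range=(110, 130), seed=11
    )
    layout = gen_plate_layout(cfg)
    features = gen_feature_table(cfg, layout)
    return cfg, layout, features


@pytest.fixture(scope="session")
def omics_tables():
    cfg = SyntheticOmicsConfig(seed=5, n_proteins=600, n_protein_diff=60)
    return cfg, gen_omics_tables(cfg)


@pytest.fixture()
def disk_mask():
    def make(r, pad=5):
        n = 2 * r + 2 * pad + 1
        yy, xx = np.mgrid[:n, :n]
        return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= r**2

    return make


@pytest.fixture()
def ellipse_mask():
    def make(a, b, angle_deg=0.0, pad=6):
        n = 2 * int(max(a, b)) + 2 * pad + 1
        yy, xx = np.mgrid[:n, :n]
        yy = yy - n // 2
        xx = xx - n // 2
        th = np.deg2rad(angle_deg)
        u = xx * np.cos(th) + yy * np.sin(th)
        v = -xx * np.sin(th) + yy * np.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    return make
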