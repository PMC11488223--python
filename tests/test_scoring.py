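"""Well aggregation, control-anchored normalization, composite PCA, Z'."""

import numpy as np
import pandas as pd
import pytest

from evmorph import morphometry, scoring
from evmorph.synthetic import (
    CANONICAL_FEATURES,
    NEG_CTL,
    POS_CTL,
    POS_EV,
    SyntheticPlateConfig,
    gen_feature_table,
    gen_plate_layout,
)


def _profiles(cfg=None):
    cfg = cfg or SyntheticPlateConfig(
        n_wells_per_group=4, cells_per_well_range=(110, 130), seed=11
    )
    lay = gen_plate_layout(cfg)
    kept, _ = morphometry.qc_filter(gen_feature_table(cfg, lay))
    return lay, scoring.aggregate_well_medians(kept, lay)


class TestWellMedians:
    def test_median_is_robust(self):
        lay = pd.DataFrame({
            "well_id": ["w1"], "group": [NEG_CTL], "operator": ["O1"],
            "experiment": ["E1"],
        })
        rec = pd.DataFrame({
            "well_id": ["w1"] * 3, "cell_id": [1, 2, 3], "feat": [1.0, 2.0, 100.0],
        })
        prof = scoring.aggregate_well_medians(rec, lay, min_cells=1)
        assert prof.loc["w1", "feat"] == 2.0
        # an extreme outlier added to a 701-cell well barely moves the median
        many = pd.DataFrame({
            "well_id": ["w1"] * 701, "cell_id": range(701),
            "feat": np.arange(701, dtype=float),
        })
        with_outlier = pd.concat(
            [many, pd.DataFrame({"well_id": ["w1"], "cell_id": [999], "feat": [1e9]})]
        )
        m0 = scoring.aggregate_well_medians(many, lay, min_cells=1).loc["w1", "feat"]
        m1 = scoring.aggregate_well_medians(with_outlier, lay, min_cells=1).loc[
            "w1", "feat"]
        assert abs(m1 - m0) <= 0.5

    def test_one_profile_per_well(self, small_plate):
        cfg, lay, features = small_plate
        prof = scoring.aggregate_well_medians(features, lay)
        assert len(prof) == len(lay)
        assert prof["n_cells"].between(*cfg.cells_per_well_range).all()

    def test_small_wells_dropped_with_warning(self, small_plate):
        _, lay, features = small_plate
        starved = features.groupby("well_id").head(30)
        one_full = features[features["well_id"] == lay["well_id"].iloc[0]]
        mixed = pd.concat([one_full, starved[starved["well_id"] != lay["well_id"].iloc[0]]])
        with pytest.warns(UserWarning, match="fewer than"):
            prof = scoring.aggregate_well_medians(mixed, lay, min_cells=50)
        assert list(prof.index) == [lay["well_id"].iloc[0]]

    def test_unknown_well_rejected(self, small_plate):
        _, lay, features = small_plate
        bad = features.copy()
        bad.loc[bad.index[0], "well_id"] = "GHOST"
        with pytest.raises(ValueError, match="GHOST"):
            scoring.aggregate_well_medians(bad, lay)


class TestMinMaxNormalize:
    def test_anchors(self, small_plate):
        _, lay, _ = small_plate
        _, prof = _profiles()
        norm = scoring.minmax_normalize(prof)
        g = norm["group"]
        feats = list(CANONICAL_FEATURES)
        assert np.allclose(norm.loc[g == NEG_CTL, feats].mean(), 0.0, atol=1e-9)
        assert np.allclose(norm.loc[g == POS_CTL, feats].mean(), 1.0, atol=1e-9)

    def test_midpoint_maps_to_half(self):
        prof = pd.DataFrame({
            "group": [NEG_CTL, NEG_CTL, POS_CTL, POS_CTL, POS_EV],
            "x": [0.0, 0.0, 2.0, 2.0, 1.0],
        })
        norm = scoring.minmax_normalize(prof, ["x"])
        assert norm.loc[norm["group"] == POS_EV, "x"].iloc[0] == pytest.approx(0.5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame({
            "group": [NEG_CTL] * 3 + [POS_CTL] * 3 + [POS_EV] * 3,
            "x": rng.normal(size=9),
        })
        n1 = scoring.minmax_normalize(prof, ["x"])
        prof2 = prof.assign(x=3.0 * prof["x"] + 7.0)
        n2 = scoring.minmax_normalize(prof2, ["x"])
        assert np.allclose(n1["x"], n2["x"], atol=1e-10)

    def test_degenerate_feature_named(self):
        prof = pd.DataFrame({
            "group": [NEG_CTL, NEG_CTL, POS_CTL, POS_CTL],
            "flat": [1.0, 1.0, 1.0, 1.0],
        })
        with pytest.raises(ValueError, match="flat"):
            scoring.minmax_normalize(prof, ["flat"])


class TestCompositePca:
    def test_rank_one_data_gives_pc1_everything(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        prof = pd.DataFrame({"a": x, "b": 2.0 * x})
        res = scoring.composite_pca_score(prof, ["a", "b"])
        assert res.variance_explained[0] == pytest.approx(100.0, abs=1e-9)

    def test_isotropic_cloud_splits_evenly(self):
        rng = np.random.default_rng(7)
        prof = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        res = scoring.composite_pca_score(prof, ["a", "b"])
        assert res.variance_explained[0] == pytest.approx(50.0, abs=2.0)
        assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)

    def test_orientation_stimulated_high(self):
        _, prof = _profiles()
        res = scoring.composite_pca_score(prof, standardize=True)
        g = prof["group"]
        assert res.pc1[g == POS_CTL].mean() > res.pc1[g == NEG_CTL].mean()

    def test_agrees_with_sklearn(self):
        """Independent cross-check of variance split against sklearn PCA."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        res = scoring.composite_pca_score(prof, list("abcde"))
        sk = PCA().fit(prof.to_numpy())
        assert np.allclose(
            res.variance_explained, 100 * sk.explained_variance_ratio_, atol=1e-8
        )
        assert np.allclose(
            np.abs(res.scores.to_numpy()), np.abs(sk.transform(prof.to_numpy())),
            atol=1e-8,
        )

    def test_too_few_wells_or_flat_feature(self):
        prof = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="at least 3"):
            scoring.composite_pca_score(prof, ["a", "b"])
        prof = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            scoring.composite_pca_score(prof, ["a", "b"], standardize=True)

    def test_controls_only_fit_projects_treatment(self):
        """Optional mode: fit the PC space on controls, project POS_EV."""
        _, prof = _profiles()
        res = scoring.composite_pca_score(
            prof, standardize=True, fit_groups=[NEG_CTL, POS_CTL]
        )
        g = prof["group"]
        assert res.pc1[g == POS_CTL].mean() > res.pc1[g == NEG_CTL].mean()
        # treatment wells land between the control means
        ev = res.pc1[g == POS_EV].mean()
        assert res.pc1[g == NEG_CTL].mean() < ev < res.pc1[g == POS_CTL].mean()

    def test_deterministic_rerun(self):
        _, prof = _profiles()
        r1 = scoring.composite_pca_score(prof, standardize=True)
        r2 = scoring.composite_pca_score(prof, standardize=True)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        pd.testing.assert_frame_equal(r1.loadings, r2.loadings)


class TestDeltaScore:
    def test_identical_groups_zero(self):
        lay = pd.DataFrame({
            "well_id": [f"w{i}" for i in range(6)],
            "group": [NEG_CTL, POS_CTL] * 3,
            "experiment": ["E1"] * 6, "operator": ["O1"] * 6,
        })
        scores = pd.Series([1.0] * 6, index=lay["well_id"])
        d = scoring.delta_score(scores, lay, POS_CTL, NEG_CTL)
        assert d["delta"].iloc[0] == pytest.approx(0.0)

    def test_linear_in_group_shift(self):
        rng = np.random.default_rng(0)
        lay = pd.DataFrame({
            "well_id": [f"w{i}" for i in range(8)],
            "group": [NEG_CTL] * 4 + [POS_CTL] * 4,
            "experiment": ["E1"] * 8, "operator": ["O1"] * 8,
        })
        scores = pd.Series(rng.normal(size=8), index=lay["well_id"])
        d0 = scoring.delta_score(scores, lay, POS_CTL, NEG_CTL)["delta"].iloc[0]
        shifted = scores.copy()
        shifted[lay.set_index("well_id")["group"] == POS_CTL] += 2.5
        d1 = scoring.delta_score(shifted, lay, POS_CTL, NEG_CTL)["delta"].iloc[0]
        assert d1 - d0 == pytest.approx(2.5)

    def test_invariant_to_operator_shift(self):
        """A batch shift common to both groups cancels in per-stratum ΔPC1."""
        cfg = SyntheticPlateConfig(
            n_wells_per_group=4, cells_per_well_range=(100, 110),
            n_operators=2, operator_shift=6.0, seed=21,
        )
        lay = gen_plate_layout(cfg)
        kept, _ = morphometry.qc_filter(gen_feature_table(cfg, lay))
        prof = scoring.aggregate_well_medians(kept, lay)
        res = scoring.composite_pca_score(prof, standardize=True)
        # the shift is visible as an operator-level offset of the raw scores
        by_op = res.pc1.groupby(prof["operator"]).mean()
        assert abs(by_op["O1"] - by_op["O2"]) > 0.1
        # ... but cancels in the within-stratum group difference
        d = scoring.delta_score(res.pc1, lay, POS_CTL, NEG_CTL)
        assert len(d) == 2
        assert d["delta"].iloc[0] == pytest.approx(d["delta"].iloc[1], rel=0.10)


class TestZFactor:
    def _mk(self, neg, pos):
        scores = pd.Series(list(neg) + list(pos))
        groups = pd.Series([NEG_CTL] * len(neg) + [POS_CTL] * len(pos))
        return scores, groups

    def test_zero_spread_gives_one(self):
        s, g = self._mk([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert scoring.z_factor(s, g).z_factor == pytest.approx(1.0)

    def test_textbook_half(self):
        # mu-=0, mu+=1, sigma=1/12 each: Z' = 1 - 6/12 = 0.5 exactly
        neg = np.array([-1.0, 1.0]) / (12 * np.sqrt(2)) + 0.0
        pos = np.array([-1.0, 1.0]) / (12 * np.sqrt(2)) + 1.0
        s, g = self._mk(neg, pos)
        res = scoring.z_factor(s, g)
        assert res.sigma_pos == pytest.approx(1 / 12)
        assert res.z_factor == pytest.approx(0.5, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s, g = self._mk(rng.normal(0, 1, 6), rng.normal(4, 1, 6))
            a = rng.uniform(0.2, 5) * rng.choice([-1, 1])
            b = rng.normal()
            z0 = scoring.z_factor(s, g).z_factor
            z1 = scoring.z_factor(a * s + b, g).z_factor
            assert z1 == pytest.approx(z0, rel=1e-9)

    def test_quality_labels_and_errors(self):
        s, g = self._mk([0, 0.01, -0.01], [1, 1.01, 0.99])
        assert scoring.z_factor(s, g).quality_label == "optimized"
        s, g = self._mk([0, 0.2, -0.2], [1, 1.2, 0.8])
        assert scoring.z_factor(s, g).quality_label != "optimized"
        with pytest.raises(ValueError, match="at least 2"):
            scoring.z_factor(pd.Series([0.0, 1.0]), pd.Series([NEG_CTL, POS_CTL]))
        s, g = self._mk([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="dynamic range"):
            scoring.z_factor(s, g)

    def test_z_on_normalized_equals_raw(self):
        """Normalization is affine, so Z' is identical on either scale."""
        _, prof = _profiles()
        res = scoring.composite_pca_score(prof, standardize=True)
        g = prof["group"]
        z_raw = scoring.z_factor(res.pc1, g).z_factor
        z_norm = scoring.z_factor(scoring.normalize_scores(res.pc1, g), g).z_factor
        assert z_norm == pytest.approx(z_raw, rel=1e-9)


class TestDoseResponse:
    def test_strict_monotone_rho(self):
        scores = pd.Series([3.0, 2.0, 1.0, 0.5], index=list("abcd"))
        doses = pd.Series([0.0, 1.0, 2.0, 4.0], index=list("abcd"))
        res = scoring.dose_response_summary(scores, doses, n_permutations=500, seed=1)
        assert res["spearman_rho"] == pytest.approx(-1.0)

    def test_too_few_levels(self):
        scores = pd.Series([1.0, 2.0], index=list("ab"))
        doses = pd.Series([0.0, 1.0], index=list("ab"))
        with pytest.raises(ValueError, match="3 distinct"):
            scoring.dose_response_summary(scores, doses)

    def test_null_p_not_anticonservative(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            idx = [f"w{i}" for i in range(12)]
            scores = pd.Series(rng.normal(size=12), index=idx)
            doses = pd.Series(np.repeat([0, 1, 2, 4], 3), index=idx)
            res = scoring.dose_response_summary(
                scores, doses, n_permutations=400, seed=int(rng.integers(2**31))
            )
            hits += res["p_value"] < 0.05
        assert hits <= 7  # ~5% expected; binomial upper tail at 40 reps

    def test_titration_power(self):
        """EV dose proportional to effect: the trend test fires at n=6."""
        rows = []
        for dose, delta in ((0.5, 0.2), (1.0, 0.45), (2.0, 0.7), (4.0, 0.9)):
            cfg = SyntheticPlateConfig(
                n_wells_per_group=6, cells_per_well_range=(100, 110),
                ev_effect=delta, seed=31,
            )
            lay = gen_plate_layout(cfg)
            kept, _ = morphometry.qc_filter(gen_feature_table(cfg, lay))
            prof = scoring.aggregate_well_medians(kept, lay)
            norm = scoring.minmax_normalize(prof)
            res = scoring.composite_pca_score(norm)
            ns = scoring.normalize_scores(res.pc1, norm["group"])
            ev = ns[norm["group"] == POS_EV]
            rows.append(pd.DataFrame({"score": ev, "dose": dose}))
        tab = pd.concat(rows)
        tab.index = [f"w{i}" for i in range(len(tab))]
        res = scoring.dose_response_summary(
            tab["score"], tab["dose"], n_permutations=5000, seed=2
        )
        assert res["spearman_rho"] < -0.5
        assert res["p_value"] < 0.01


class TestEndToEnd:
    def test_idempotent_scores(self):
        """Scoring its own written output reproduces identical scores."""
        lay, prof = _profiles()
        norm = scoring.minmax_normalize(prof)
        res1 = scoring.composite_pca_score(norm)
        round_trip = pd.read_csv(
            __import__("io").StringIO(norm.reset_index().to_csv(index=False))
        ).set_index("well_id")
        res2 = scoring.composite_pca_score(round_trip)
        assert np.allclose(res1.pc1, res2.pc1, atol=1e-9)
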