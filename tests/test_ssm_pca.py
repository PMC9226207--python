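"""Data-matrix centering, PCA, stepwise selection, scoring and summaries."""

import numpy as np
import pandas as pd
import pytest

import ssmpet as sp
from ssmpet.ssm_pca import (
    _fit_logistic,
    pca_decompose,
    select_variance_prefix,
    stepwise_forward_aic,
)
from ssmpet.types import ImageVolume, Subject


def _toy_cohort(columns, groups, mask_shape=(5, 1, 1)):
    """Cohort whose masked voxel vectors are exactly the given columns."""
    mask = np.ones(mask_shape, dtype=bool)
    subjects = [
        Subject(f"s{i}", g, ImageVolume(np.asarray(c, float).reshape(mask_shape)))
        for i, (c, g) in enumerate(zip(columns, groups))
    ]
    return sp.Cohort(subjects, mask)


def brute_force_double_center(columns, groups):
    """Hand-rolled two-step centering oracle on plain lists."""
    cols = [np.asarray(c, float) for c in columns]
    centred = [c - c.mean() for c in cols]
    hc = [c for c, g in zip(centred, groups) if g == "HC"]
    hc_mean = np.mean(hc, axis=0)
    return np.column_stack([c - hc_mean for c in centred]), hc_mean


class TestBuildDataMatrix:
    def test_identical_subjects_give_null_matrix(self):
        col = [1.0, 2.0, 3.0, 4.0, 5.0]
        cohort = _toy_cohort([col] * 4, ["AD", "AD", "HC", "HC"])
        m = sp.build_data_matrix(cohort)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_matches_brute_force_centering_oracle(self, rng):
        cols = rng.normal(size=(6, 5))
        groups = ["AD", "AD", "HC", "HC", "HC", "MCI+"]
        cohort = _toy_cohort(list(cols), groups)
        m = sp.build_data_matrix(cohort)
        expected, hc_mean = brute_force_double_center(list(cols), groups)
        np.testing.assert_allclose(m.values, expected, atol=1e-12)
        np.testing.assert_allclose(m.hc_mean_profile, hc_mean, atol=1e-12)

    def test_columns_have_zero_mean_after_per_subject_centering(self, static_cohort):
        cohort, _ = static_cohort
        m = sp.build_data_matrix(cohort.select(["AD", "HC"]))
        # HC-profile subtraction shifts all columns identically, so column
        # means equal minus the HC-profile mean, which is itself ~0
        np.testing.assert_allclose(m.values.mean(axis=0), 0.0, atol=1e-10)

    def test_no_hc_subjects_rejected(self):
        cohort = _toy_cohort([[1, 2, 3, 4, 5]] * 2, ["AD", "AD"])
        with pytest.raises(ValueError, match="HC"):
            sp.build_data_matrix(cohort)

    def test_nan_inside_mask_rejected_with_location(self):
        col = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        cohort = _toy_cohort([col, [1, 2, 3, 4, 5]], ["AD", "HC"])
        with pytest.raises(ValueError, match=r"\[1\]"):
            sp.build_data_matrix(cohort)


class TestPCA:
    def test_gram_route_matches_direct_svd(self, rng):
        """Subjects x subjects eigen route equals a full SVD on toys."""
        for _ in range(5):
            n_vox, n_sub = 50, 8
            X = rng.normal(size=(n_vox, n_sub))
            X -= X.mean(axis=0)
            m = sp.DataMatrix(
                X, [f"s{i}" for i in range(n_sub)], ["AD"] * 4 + ["HC"] * 4,
                np.ones((n_vox, 1, 1), bool), (2.0, 2.0, 2.0),
                np.zeros(n_sub), np.zeros(n_vox),
            )
            pca = pca_decompose(m)
            u, s, _ = np.linalg.svd(X, full_matrices=False)
            np.testing.assert_allclose(
                pca.variance_fraction[: len(s)], s**2 / (s**2).sum(), atol=1e-8
            )
            k = pca.component_patterns.shape[1]
            np.testing.assert_allclose(
                np.abs(pca.component_patterns.T @ u[:, :k]), np.eye(k), atol=1e-8
            )

    def test_component_orthonormality_and_ordering(self, trained):
        _, _, _, pca = trained
        k = pca.component_patterns.shape[1]
        gram = pca.component_patterns.T @ pca.component_patterns
        np.testing.assert_allclose(gram, np.eye(k), atol=1e-8)
        assert np.all(np.diff(pca.variance_fraction) <= 1e-12)
        assert pca.variance_fraction.sum() <= 1 + 1e-9

    def test_degenerate_cohort_raises(self):
        cohort = _toy_cohort([[1, 2, 3, 4, 5]] * 4, ["AD", "AD", "HC", "HC"])
        m = sp.build_data_matrix(cohort)
        with pytest.raises(ValueError, match="degenerate"):
            pca_decompose(m)

    def test_variance_prefix_is_minimal(self):
        vf = np.array([0.3, 0.15, 0.1, 0.25, 0.2])
        vf = np.sort(vf)[::-1]  # [0.3, 0.25, 0.2, 0.15, 0.1]
        sel = select_variance_prefix(vf, 0.5)
        assert sel == [0, 1]
        assert vf[sel].sum() >= 0.5
        assert vf[sel[:-1]].sum() < 0.5


class TestStepwiseSelection:
    def test_single_separating_pc_is_selected(self, rng):
        scores = np.zeros((12, 2))
        scores[:, 0] = np.r_[rng.normal(3, 0.3, 6), rng.normal(0, 0.3, 6)]
        scores[:, 1] = rng.normal(0, 1, 12)
        y = np.r_[np.ones(6), np.zeros(6)]
        selected, beta, _ = stepwise_forward_aic(scores, y, [0, 1])
        assert selected[0] == 0

    def test_matches_exhaustive_best_subset_on_two_pc_toys(self, rng):
        """Greedy-forward AIC equals the exhaustive optimum on 2-PC toys."""
        import itertools

        n_match = 0
        for trial in range(20):
            scores = rng.normal(size=(14, 2))
            y = (rng.random(14) < 0.5).astype(float)
            if y.sum() < 2 or y.sum() > 12:
                y[:2] = 1.0
                y[-2:] = 0.0
            selected, _, aic = stepwise_forward_aic(scores, y, [0, 1])
            best_aic = np.inf
            for k in range(3):
                for subset in itertools.combinations([0, 1], k):
                    _, a, _ = _fit_logistic(
                        scores[:, list(subset)] / np.where(
                            scores.std(axis=0, ddof=1)[list(subset)] == 0, 1,
                            scores.std(axis=0, ddof=1)[list(subset)]),
                        y,
                    )
                    best_aic = min(best_aic, a)
            # forward search cannot beat the exhaustive optimum
            assert aic >= best_aic - 1e-8
            if abs(aic - best_aic) < 1e-8:
                n_match += 1
        assert n_match == 20

    def test_ridge_fallback_on_perfect_separation(self):
        x = np.r_[np.full(8, 2.0), np.full(8, -2.0)] + np.r_[
            np.linspace(0, 0.1, 8), np.linspace(0, 0.1, 8)
        ]
        y = np.r_[np.ones(8), np.zeros(8)]
        beta, aic, ridged = _fit_logistic(x[:, None], y)
        assert ridged
        assert np.isfinite(aic)
        assert beta[1] > 0


class TestDerivePattern:
    def test_pattern_is_unit_norm_and_separates_groups(self, trained, static_cohort):
        pattern, table, _, _ = trained
        assert np.linalg.norm(pattern.weights) == pytest.approx(1.0)
        ad = table.loc[table.group == "AD", "z_score"]
        hc = table.loc[table.group == "HC", "z_score"]
        assert ad.mean() > hc.mean()

    def test_recovers_embedded_template(self, trained, template):
        pattern, _, _, _ = trained
        centred = template.values - template.values.mean()
        cos = pattern.weights @ centred / np.linalg.norm(centred)
        assert abs(cos) >= 0.9

    def test_single_selected_pc_gives_that_pc_as_pattern(self, rng):
        """With one candidate PC the stepwise outcome is forced."""
        n_vox = 40
        direction = rng.normal(size=n_vox)
        direction -= direction.mean()
        direction /= np.linalg.norm(direction)
        cols = [direction * v + rng.normal(0, 1e-4, n_vox) for v in
                [3.0, 2.8, 3.2, -3.0, -2.9, -3.1]]
        cohort = _toy_cohort(cols, ["AD"] * 3 + ["HC"] * 3, (n_vox, 1, 1))
        m = sp.build_data_matrix(cohort)
        pattern, pca = sp.derive_pattern(m)
        assert pattern.included_pcs == [0]
        cos = abs(pattern.weights @ pca.component_patterns[:, 0])
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_variance_explained_matches_included_pcs(self, trained):
        pattern, _, _, pca = trained
        expected = 100 * pca.variance_fraction[pattern.included_pcs].sum()
        assert pattern.dp_variance_explained == pytest.approx(expected)

    def test_rejects_non_two_group_labels(self, static_cohort):
        cohort, _ = static_cohort
        m = sp.build_data_matrix(cohort)  # includes MCI groups
        with pytest.raises(ValueError, match="AD/HC"):
            sp.derive_pattern(m)


class TestScoring:
    def test_adding_pattern_raises_score_by_that_amount(self, trained, static_cohort):
        pattern, _, _, _ = trained
        cohort, _ = static_cohort
        img = cohort.subjects[0].image
        base = sp.score_subject(img, pattern)
        for t in (0.5, -1.3, 4.0):
            bumped = img.data.copy()
            bumped[pattern.mask] += t * pattern.weights
            s = sp.score_subject(ImageVolume(bumped, img.voxel_size), pattern)
            assert s - base == pytest.approx(t, abs=1e-8)

    def test_global_additive_shift_leaves_score_unchanged(self, trained, static_cohort):
        pattern, _, _, _ = trained
        cohort, _ = static_cohort
        img = cohort.subjects[3].image
        shifted = ImageVolume(img.data + 17.5, img.voxel_size)
        assert sp.score_subject(shifted, pattern) == pytest.approx(
            sp.score_subject(img, pattern), abs=1e-8
        )

    def test_hc_mean_profile_scores_zero(self, trained):
        pattern, _, _, _ = trained
        vol = np.zeros(pattern.mask.shape)
        vol[pattern.mask] = pattern.training_hc_mean_profile
        assert sp.score_subject(ImageVolume(vol), pattern) == pytest.approx(0.0, abs=1e-8)

    def test_grid_mismatch_rejected(self, trained):
        pattern, _, _, _ = trained
        with pytest.raises(Exception, match="grid"):
            sp.score_subject(ImageVolume(np.ones((4, 4, 4))), pattern)


class TestLoocv:
    def test_duplicate_subject_oracle(self, static_cohort):
        """With a duplicated subject, its LOOCV fold still contains its twin,
        so the LOOCV score equals the twin's in-sample score under that fold."""
        cohort, _ = static_cohort
        train = cohort.select(["AD", "HC"])
        dup = Subject("AD01b", "AD", train.subjects[0].image)
        subjects = train.subjects + [dup]
        cohort2 = sp.Cohort(subjects, train.mask, train.voxel_size)
        full_pattern, _ = sp.derive_pattern(sp.build_data_matrix(cohort2))
        loocv, _ = sp.loocv_scores(cohort2, full_pattern=full_pattern)
        # fold leaving out AD01: derive on the rest (which includes AD01b)
        rest = sp.Cohort(subjects[1:], train.mask, train.voxel_size)
        fold_pattern, _ = sp.derive_pattern(sp.build_data_matrix(rest))
        if fold_pattern.weights @ full_pattern.weights < 0:
            fold_pattern.weights = -fold_pattern.weights
        twin_score = sp.score_subject(dup.image, fold_pattern)
        a01 = loocv.loc[loocv.subject_id == train.subjects[0].subject_id, "raw_score"]
        assert a01.iloc[0] == pytest.approx(twin_score, rel=1e-10)

    def test_identical_images_surface_degeneracy_error(self):
        cohort = _toy_cohort([[1, 2, 3, 4, 5]] * 6, ["AD"] * 3 + ["HC"] * 3)
        with pytest.raises(ValueError, match="degenerate"):
            sp.loocv_scores(cohort)

    def test_subject_order_permutation_only_permutes_rows(self, static_cohort):
        cohort, _ = static_cohort
        train = cohort.select(["AD", "HC"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(train))
        shuffled = sp.Cohort(
            [train.subjects[i] for i in perm], train.mask, train.voxel_size
        )
        t1, _ = sp.loocv_scores(train)
        t2, _ = sp.loocv_scores(shuffled)
        merged = t1.merge(t2, on="subject_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged.raw_score_a, merged.raw_score_b, rtol=1e-10)

    def test_small_fold_rejected(self):
        cols = np.random.default_rng(5).normal(size=(5, 5))
        cohort = _toy_cohort(list(cols), ["AD", "AD", "HC", "HC", "HC"])
        with pytest.raises(ValueError, match="fewer than 2"):
            sp.loocv_scores(cohort)

    def test_fold_patterns_stay_close_to_full_pattern(self, trained):
        _, _, report, _ = trained
        assert report.cosine_to_full_dp.min() >= 0.8


class TestZscore:
    def test_hand_computed_standardisation(self):
        table = pd.DataFrame(
            {"subject_id": ["x"], "group": ["AD"], "raw_score": [4.0], "loocv_flag": [False]}
        )
        out = sp.zscore_standardize(table, [1.0, 2.0, 3.0])
        assert out.z_score.iloc[0] == pytest.approx(2.0)

    def test_score_at_hc_mean_is_zero(self):
        table = pd.DataFrame(
            {"subject_id": ["x"], "group": ["HC"], "raw_score": [2.0], "loocv_flag": [False]}
        )
        assert sp.zscore_standardize(table, [1.0, 2.0, 3.0]).z_score.iloc[0] == 0.0

    def test_single_hc_score_rejected(self):
        table = pd.DataFrame(
            {"subject_id": ["x"], "group": ["AD"], "raw_score": [4.0], "loocv_flag": [False]}
        )
        with pytest.raises(ValueError, match=">= 2"):
            sp.zscore_standardize(table, [1.0])

    def test_hc_loocv_zscores_are_standardised(self, trained):
        _, table, _, _ = trained
        hc = table.loc[table.group == "HC", "z_score"]
        assert hc.mean() == pytest.approx(0.0, abs=1e-10)
        assert hc.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestRegionalSummary:
    def test_constant_region_mean_and_sd(self, atlas, mask, trained):
        pattern, _, _, _ = trained
        flat = pattern.weights.copy()
        region1 = (atlas.labels == 1)[mask]
        flat[region1] = 0.25
        const = sp.DiseasePattern(
            weights=flat, mask=mask, voxel_size=pattern.voxel_size,
            included_pcs=[0], logistic_coefficients=[1.0], intercept=0.0,
            dp_variance_explained=100.0, variance_fractions=np.array([1.0]),
            training_hc_mean_profile=np.zeros(int(mask.sum())),
        )
        table = sp.regional_summary(const, atlas)
        row = table[(table.level == "region") & (table.name == atlas.region_names[1])]
        assert row["mean"].iloc[0] == pytest.approx(0.25)
        assert row["sd"].iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_volume_arithmetic(self, atlas, trained):
        pattern, _, _, _ = trained
        table = sp.regional_summary(pattern, atlas)
        for _, row in table.iterrows():
            # 2 mm voxels: 8 mm^3 each
            assert row.volume_cm3 == pytest.approx(row.n_voxels * 0.008)

    def test_lobe_mean_reaggregates_from_regions(self, atlas, trained):
        pattern, _, _, _ = trained
        table = sp.regional_summary(pattern, atlas)
        regions = table[table.level == "region"]
        for lobe, sub in regions.groupby("lobe"):
            got = table[(table.level == "lobe") & (table.name == lobe)]["mean"].iloc[0]
            expected = np.average(sub["mean"], weights=sub["n_voxels"])
            assert got == pytest.approx(expected, rel=1e-10)

    def test_empty_region_reported_not_dropped(self, atlas, mask, trained):
        pattern, _, _, _ = trained
        names = dict(atlas.region_names)
        label = max(names) + 1
        names[label] = "phantom empty region"
        lobes = dict(atlas.lobe_map)
        lobes["phantom empty region"] = "frontal"
        atlas2 = sp.AtlasDefinition(atlas.labels, names, lobes, atlas.voxel_size)
        table = sp.regional_summary(pattern, atlas2)
        row = table[table.name == "phantom empty region"]
        assert len(row) == 1
        assert row.n_voxels.iloc[0] == 0
        assert np.isnan(row["mean"].iloc[0])
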