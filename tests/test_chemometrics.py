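"""Ratio features, UV scaling, O-PLS-DA, CV and permutation machinery."""

import numpy as np
import pandas as pd
import pytest

from fidcraft import (
    AmplitudeTable,
    FeatureMatrix,
    RatioSpec,
    build_features,
    cross_validate,
    exclude_outliers,
    fit_opls_da,
    permutation_test,
    preprocess,
)
from fidcraft.chemometrics import BUILTIN_RATIOS
from fidcraft.craft_workflow import TABLE_COLUMNS


def _table(amplitudes: dict[str, dict[str, float]]) -> AmplitudeTable:
    """amplitudes: sample_id -> target -> amplitude."""
    rows = []
    for sid, targets in amplitudes.items():
        for name, amp in targets.items():
            rows.append(dict(sample_id=sid, target=name, amplitude=amp,
                             frequency_ppm=2.0, decay=15.0, phase=0.0,
                             n_components_summed=1, residual_rms=0.0))
    return AmplitudeTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))


def _ids(n):
    return [f"s{i}" for i in range(n)]


def _split_feature(n=20, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(0, 1, n), rng.normal(gap, 1, n)])[:, None]
    y = np.array([0] * n + [1] * n, dtype=float)
    return FeatureMatrix(X, ["f"], y, _ids(2 * n))


class TestBuildFeatures:
    BASE = {"SPC": 2.0, "GlycB": 1.0, "GlycA": 1.0, "acetate": 1.0}

    def _labels(self, ids):
        return {i: ("case" if k % 2 else "control") for k, i in enumerate(ids)}

    def test_builtin_ratio_values(self):
        table = _table({"a": dict(self.BASE, SPC=4.0), "b": self.BASE,
                        "c": self.BASE, "d": self.BASE})
        F = build_features(table, labels=self._labels("abcd"))
        vals = dict(zip(F.feature_names, F.X[0]))
        assert vals["GlycB/SPC"] == pytest.approx(0.25)
        assert vals["SPC/(GlycA+GlycB)"] == pytest.approx(2.0)
        assert vals["GlycA/GlycB"] == pytest.approx(1.0)

    def test_zero_denominator_sample_dropped_with_warning(self, caplog):
        import logging
        table = _table({"a": self.BASE, "b": dict(self.BASE, SPC=0.0),
                        "c": self.BASE, "d": self.BASE, "e": self.BASE})
        with caplog.at_level(logging.WARNING, logger="fidcraft.chemometrics"):
            F = build_features(table, labels=self._labels("abcde"))
        assert F.sample_ids == ["a", "c", "d", "e"]
        assert "b" in caplog.text

    def test_unknown_target_rejected(self):
        table = _table({i: self.BASE for i in "abcd"})
        bad = [RatioSpec("x", ("Nope",), ("SPC",))]
        with pytest.raises(ValueError, match="Nope"):
            build_features(table, bad, labels=self._labels("abcd"))


class TestPreprocess:
    def test_unit_variance_and_zero_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 3, size=(30, 4))
        Xs, means, scales = preprocess(X)
        np.testing.assert_allclose(Xs.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_constant_column_scale_one(self, caplog):
        import logging
        X = np.column_stack([np.ones(10), np.arange(10, dtype=float)])
        with caplog.at_level(logging.WARNING, logger="fidcraft.chemometrics"):
            Xs, _, scales = preprocess(X)
        assert scales[0] == 1.0
        np.testing.assert_allclose(Xs[:, 0], 0.0)

    def test_idempotent_on_scaled_output(self):
        rng = np.random.default_rng(2)
        Xs, _, _ = preprocess(rng.normal(size=(20, 3)))
        Xs2, _, _ = preprocess(Xs)
        np.testing.assert_allclose(Xs, Xs2, atol=1e-12)


class TestOplsDa:
    def test_matches_sklearn_pls_when_no_orthogonal_components(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 3))
        y = np.array([0] * 20 + [1] * 20, dtype=float)
        F = FeatureMatrix(X, list("abc"), y, _ids(40))
        ours = fit_opls_da(F, n_ortho=0)
        ref = PLSRegression(n_components=1, scale=True).fit(X, y)
        np.testing.assert_allclose(ours.predict(X), ref.predict(X).ravel(),
                                   atol=1e-10)

    def test_orthogonal_scores_uncorrelated_with_y_and_t(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 5))
        y = np.array([0] * 20 + [1] * 20, dtype=float)
        X[:, 0] += 2 * y
        F = FeatureMatrix(X, list("abcde"), y, _ids(40))
        model = fit_opls_da(F, n_ortho=2)
        yc = y - y.mean()
        for t_o in model.t_ortho:
            assert abs(t_o @ yc) <= 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(yc)
            assert abs(t_o @ model.t) <= 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(model.t)

    def test_separated_classes_high_r2(self):
        # no class overlap at all: 8 sigma between class means
        model = fit_opls_da(_split_feature(gap=8.0), 0)
        assert model.R2Y >= 0.9

    def test_single_feature_forces_plain_plsda(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="fidcraft.chemometrics"):
            model = fit_opls_da(_split_feature(), n_ortho=2)
        assert model.n_ortho == 0
        assert "forced to 0" in caplog.text

    def test_single_class_rejected(self):
        F = FeatureMatrix(np.random.default_rng(0).normal(size=(10, 1)),
                          ["f"], np.zeros(10), _ids(10))
        with pytest.raises(ValueError, match="two classes"):
            fit_opls_da(F, 0)

    def test_too_many_orthogonal_components_rejected(self):
        rng = np.random.default_rng(5)
        F = FeatureMatrix(rng.normal(size=(20, 2)), ["a", "b"],
                          np.array([0] * 10 + [1] * 10, float), _ids(20))
        with pytest.raises(ValueError, match="n_ortho"):
            fit_opls_da(F, 5)


class TestCrossValidation:
    def test_separated_feature_high_q2(self):
        assert cross_validate(_split_feature(), 0, seed=0) >= 0.8

    def test_noise_feature_q2_nonpositive_on_average(self):
        rng = np.random.default_rng(6)
        y = np.array([0] * 20 + [1] * 20, float)
        q2s = [
            cross_validate(
                FeatureMatrix(rng.standard_normal((40, 1)), ["f"], y, _ids(40)),
                0, seed=s,
            )
            for s in range(20)
        ]
        assert np.mean(q2s) <= 0.0

    def test_q2_below_r2_for_informative_model(self):
        F = _split_feature(gap=2.0, seed=7)
        model = fit_opls_da(F, 0)
        q2 = cross_validate(F, 0, seed=7)
        assert q2 <= model.R2Y + 1e-8

    def test_deterministic_given_seed(self):
        F = _split_feature(seed=8)
        assert cross_validate(F, 0, seed=3) == cross_validate(F, 0, seed=3)


class TestPermutationTest:
    def test_informative_feature_beats_null(self):
        report = permutation_test(_split_feature(seed=9), 0, n_perm=50, seed=1)
        assert report.original_Q2 > np.percentile(report.permuted_Q2, 95)

    def test_null_q2_near_zero_for_noise(self):
        rng = np.random.default_rng(10)
        y = np.array([0] * 20 + [1] * 20, float)
        F = FeatureMatrix(rng.standard_normal((40, 1)), ["f"], y, _ids(40))
        report = permutation_test(F, 0, n_perm=30, seed=2)
        assert np.mean(report.permuted_Q2) <= 0.1

    def test_report_lengths_and_determinism(self):
        F = _split_feature(seed=11)
        r1 = permutation_test(F, 0, n_perm=25, seed=5)
        r2 = permutation_test(F, 0, n_perm=25, seed=5)
        assert len(r1.permuted_Q2) == 25
        np.testing.assert_array_equal(r1.permuted_Q2, r2.permuted_Q2)


class TestExcludeOutliers:
    def test_clean_data_no_exclusions(self):
        kept, excluded = exclude_outliers(_split_feature(gap=2.0, seed=12),
                                          threshold=4.0)
        assert excluded == []
        assert kept.n_samples == 40

    def test_inflated_sample_excluded(self):
        F = _split_feature(gap=2.0, seed=13)
        F.X[5, 0] *= 10  # one wildly inflated amplitude ratio
        F.X[5, 0] += 30
        kept, excluded = exclude_outliers(F, threshold=4.0)
        assert "s5" in excluded
        assert kept.n_samples == 40 - len(excluded)

    def test_infinite_threshold_is_identity(self):
        F = _split_feature(seed=14)
        kept, excluded = exclude_outliers(F, threshold=np.inf)
        assert excluded == []
        assert kept is F or kept.n_samples == F.n_samples

    def test_at_most_ten_percent_removed(self):
        rng = np.random.default_rng(15)
        y = np.array([0] * 20 + [1] * 20, float)
        X = rng.standard_normal((40, 1))
        X[:10] += 50  # many extreme values
        F = FeatureMatrix(X, ["f"], y, _ids(40))
        _, excluded = exclude_outliers(F, threshold=2.0)
        assert len(excluded) <= 4
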