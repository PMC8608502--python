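import numpy as np
import pytest
from scipy import integrate, stats

import lungcad as lc
from lungcad.core import BinaryMask, Candidate, CTVolume, NoduleFeatures
from lungcad.errors import FeatureExtractionError, InputError
from lungcad.features import (
    classify_candidate,
    default_rule_model,
    extract_features,
    fit_classifier,
    load_model,
    save_model,
)


def make_blob_volume(semi_axes_mm, spacing=(1.0, 1.0, 1.0), shape=(32, 48, 48),
                     background=-800.0, blob_hu=-400.0):
    """An ellipsoidal blob centred in the grid, full mask."""
    sp = np.asarray(spacing)
    center = (np.asarray(shape) - 1) / 2.0 * sp
    z = (np.arange(shape[0]) * sp[0])[:, None, None]
    y = (np.arange(shape[1]) * sp[1])[None, :, None]
    x = (np.arange(shape[2]) * sp[2])[None, None, :]
    inside = (
        ((z - center[0]) / semi_axes_mm[0]) ** 2
        + ((y - center[1]) / semi_axes_mm[1]) ** 2
        + ((x - center[2]) / semi_axes_mm[2]) ** 2
    ) < 1.0
    vox = np.full(shape, background)
    vox[inside] = blob_hu
    vol = CTVolume(vox, tuple(spacing))
    mask = BinaryMask(np.ones(shape, dtype=np.uint8))
    idx = tuple(int(round(c / s)) for c, s in zip(center, sp))
    cand = Candidate(idx, tuple(center), radius_mm=float(max(semi_axes_mm)),
                     response=300.0)
    return vol, mask, cand, inside


class TestExtractFeatures:
    def test_solid_sphere_descriptors(self):
        vol, mask, cand, _ = make_blob_volume((5.0, 5.0, 5.0))
        f = extract_features(vol, mask, cand)
        assert f.circularity >= 0.9
        assert f.elongation <= 1.1
        assert f.equivalent_diameter_mm == pytest.approx(10.0, abs=1.0)
        assert f.contrast_hu == pytest.approx(400.0, abs=40.0)

    def test_ellipsoid_elongation_matches_moment_oracle(self):
        semi = (5.0, 10.0, 5.0)  # 2:1 in-plane axes
        vol, mask, cand, inside = make_blob_volume(semi)
        f = extract_features(vol, mask, cand)
        # brute-force second-moment oracle on the rasterised truth voxels
        coords = np.argwhere(inside).astype(float) * np.asarray(vol.spacing)
        eigvals = np.linalg.eigvalsh(np.cov(coords.T))
        oracle = float(np.sqrt(eigvals[-1] / eigvals[0]))
        assert f.elongation == pytest.approx(2.0, abs=0.2)
        assert f.elongation == pytest.approx(oracle, rel=0.05)

    def test_uniform_region_intensities_exact(self):
        vol, mask, cand, inside = make_blob_volume((4.0, 4.0, 4.0), blob_hu=-100.0)
        f = extract_features(vol, mask, cand)
        assert f.mean_hu == -100.0
        assert f.max_hu == -100.0
        # region minus shell, both uniform
        assert f.contrast_hu == pytest.approx(-100.0 - (-800.0))

    def test_constant_offset_shifts_only_intensity_features(self):
        vol, mask, cand, _ = make_blob_volume((4.0, 6.0, 4.0))
        shifted = CTVolume(vol.voxels + 137.0, vol.spacing)
        f0 = extract_features(vol, mask, cand)
        f1 = extract_features(shifted, mask, cand)
        assert f1.mean_hu == pytest.approx(f0.mean_hu + 137.0)
        assert f1.max_hu == pytest.approx(f0.max_hu + 137.0)
        for name in ("volume_mm3", "equivalent_diameter_mm", "circularity",
                     "elongation", "contrast_hu", "boundary_gradient_hu_per_mm"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), abs=1e-9)

    def test_anisotropic_grid_sphere_still_compact(self):
        vol, mask, cand, _ = make_blob_volume(
            (6.0, 6.0, 6.0), spacing=(2.0, 1.0, 1.0), shape=(24, 48, 48)
        )
        f = extract_features(vol, mask, cand)
        assert f.elongation <= 1.3
        assert f.equivalent_diameter_mm == pytest.approx(12.0, abs=1.5)

    def test_degenerate_region_raises(self):
        vox = np.full((9, 9, 9), -800.0)
        vox[4, 4, 4] = -100.0  # single bright voxel
        vol = CTVolume(vox, (1, 1, 1))
        mask = BinaryMask(np.ones((9, 9, 9), dtype=np.uint8))
        cand = Candidate((4, 4, 4), (4.0, 4.0, 4.0), 2.0, 300.0)
        with pytest.raises(FeatureExtractionError):
            extract_features(vol, mask, cand)


def two_gaussian_data(rng, n_per_class, delta_sd=1.0, dim=4):
    x0 = rng.normal(0.0, 1.0, size=(n_per_class, dim))
    x1 = rng.normal(delta_sd, 1.0, size=(n_per_class, dim))
    X = np.vstack([x0, x1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


def bayes_accuracy_oracle(delta_sd, dim):
    """Numeric-integration Bayes rate for two spherical Gaussians.

    The optimal rule depends only on the 1D projection onto the mean
    difference, where the classes are N(0,1) and N(delta*sqrt(dim), 1).
    """
    sep = delta_sd * np.sqrt(dim)
    err, _ = integrate.quad(
        lambda t: 0.5 * min(stats.norm.pdf(t, 0, 1), stats.norm.pdf(t, sep, 1)),
        -20, 20 + sep,
    )
    return 1.0 - err


class TestFitClassifier:
    def test_separable_clouds_train_perfectly(self):
        rng = np.random.default_rng(0)
        X, y = two_gaussian_data(rng, 100, delta_sd=6.0)
        model = fit_classifier(list(X), y)
        labels = [classify_candidate(x, model)[0] for x in X]
        assert labels == [str(c) for c in y]

    def test_holdout_accuracy_near_bayes_rate(self):
        rng = np.random.default_rng(1)
        X, y = two_gaussian_data(rng, 1000, delta_sd=1.0)
        Xt, yt = two_gaussian_data(rng, 1000, delta_sd=1.0)
        model = fit_classifier(list(X), y)
        correct = np.mean([classify_candidate(x, model)[0] == str(c) for x, c in zip(Xt, yt)])
        assert abs(correct - bayes_accuracy_oracle(1.0, 4)) <= 0.05

    def test_single_class_is_training_error(self):
        X = np.random.default_rng(2).normal(size=(10, 3))
        with pytest.raises(InputError):
            fit_classifier(list(X), np.zeros(10))

    def test_agrees_with_reference_discriminant(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X, y = two_gaussian_data(rng, 400, delta_sd=1.5)
        model = fit_classifier(list(X), y)
        ours = np.array([int(classify_candidate(x, model)[0] == "1") for x in X])
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert np.mean(ours == ref) >= 0.98

    def test_collinear_features_still_fit(self, caplog):
        rng = np.random.default_rng(4)
        X, y = two_gaussian_data(rng, 50, delta_sd=2.0, dim=3)
        X = np.hstack([X, X[:, :1]])  # duplicated column
        model = fit_classifier(list(X), y)
        assert np.all(np.isfinite(model.weights))


class TestClassifyCandidate:
    def _features(self, **overrides):
        base = dict(
            volume_mm3=500.0, equivalent_diameter_mm=9.8, circularity=0.95,
            elongation=1.1, mean_hu=-150.0, max_hu=-100.0, contrast_hu=600.0,
            boundary_gradient_hu_per_mm=200.0,
        )
        base.update(overrides)
        return NoduleFeatures(**base)

    def test_rule_model_accepts_compact_bright_candidate(self):
        label, score = classify_candidate(self._features(), default_rule_model())
        assert label == "nodule"
        assert score == 1.0

    def test_rule_model_rejects_below_min_size(self):
        f = self._features(equivalent_diameter_mm=1.5, volume_mm3=2.0)
        label, score = classify_candidate(f, default_rule_model())
        assert label == "non-nodule"
        assert score == 0.75

    def test_zero_weight_linear_model_scores_half(self):
        from lungcad.features import ClassifierModel

        model = ClassifierModel(
            kind="linear", weights=np.zeros(8), bias=0.0,
            feature_mean=np.zeros(8), feature_sd=np.ones(8),
        )
        _, score = classify_candidate(self._features(), model)
        assert score == 0.5

    def test_positive_class_draw_labeled_positive_at_oracle_rate(self):
        rng = np.random.default_rng(5)
        X, y = two_gaussian_data(rng, 1000, delta_sd=1.0)
        model = fit_classifier(list(X), y)
        draws = rng.normal(1.0, 1.0, size=(1000, 4))  # positive-class Gaussian
        frac = np.mean([classify_candidate(x, model)[0] == "1" for x in draws])
        oracle = bayes_accuracy_oracle(1.0, 4)
        # MC error ~ sqrt(p(1-p)/1000) ~ 0.012; allow model estimation error too
        assert abs(frac - oracle) <= 0.05

    def test_decision_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(6)
        X, y = two_gaussian_data(rng, 200, delta_sd=1.5)
        scaled = X.copy()
        scaled[:, 2] *= 1000.0
        m_raw = fit_classifier(list(X), y)
        m_scaled = fit_classifier(list(scaled), y)
        for x, xs in zip(X[:50], scaled[:50]):
            assert classify_candidate(x, m_raw)[0] == classify_candidate(xs, m_scaled)[0]

    def test_dimension_mismatch_is_input_error(self):
        rng = np.random.default_rng(7)
        X, y = two_gaussian_data(rng, 20, delta_sd=2.0)
        model = fit_classifier(list(X), y)
        with pytest.raises(InputError, match="dimension"):
            classify_candidate(np.zeros(7), model)

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        X, y = two_gaussian_data(rng, 50, delta_sd=2.0)
        model = fit_classifier(list(X), y)
        save_model(model, tmp_path / "model.json")
        back = load_model(tmp_path / "model.json")
        for x in X[:20]:
            assert classify_candidate(x, model) == classify_candidate(x, back)
        rules = default_rule_model()
        save_model(rules, tmp_path / "rules.json")
        assert load_model(tmp_path / "rules.json").thresholds == rules.thresholds

    def test_rules_keep_phantom_truth_nodules(self, easy_phantom):
        """Default screening never rejects a compact phantom truth nodule."""
        spec, volume, _, nodules = easy_phantom
        mask, _ = lc.segment_lungs(volume, min_volume_ml=50)
        model = default_rule_model()
        kept = 0
        for nod in nodules:
            idx = tuple(int(round(c / s)) for c, s in zip(nod.center_mm, volume.spacing))
            cand = Candidate(idx, nod.center_mm, nod.radius_mm, 500.0)
            f = extract_features(volume, mask, cand)
            if nod.radius_mm >= 2.0 and f.circularity >= 0.8:
                label, _ = classify_candidate(f, model)
                assert label == "nodule"
                kept += 1
        assert kept >= 5  # the check must actually exercise several nodules
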