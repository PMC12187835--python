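"""Training harness: schedule, freezing, determinism, prediction contracts."""

from __future__ import annotations

import numpy as np
import pytest

from slnpatch.metrics import ConfusionCounts, compute_metrics
from slnpatch.model import (
    BackboneSpec,
    MaskOracle,
    TrainConfig,
    build_model,
    evaluate_patches,
    lr_at,
    train,
)
from slnpatch.patches import DESIGNS, DatasetManifest, balance_classes, harvest_records, split_manifest
from slnpatch.synthetic import LOCAL_STYLE, generate_separable_slide


@pytest.fixture(scope="module")
def fixture_data():
    """Small separable slide with a balanced, split manifest."""
    slide = generate_separable_slide(6, 6, LOCAL_STYLE, seed=55)
    records = balance_classes(harvest_records([slide]), seed=55)
    manifest = split_manifest(
        DatasetManifest(records=records, design=DESIGNS["Tumor"], seed=55), seed=55
    )
    return manifest, {slide.slide_id: slide}


class TestLrSchedule:
    def test_cosine_closed_form(self):
        cfg = TrainConfig()
        T = 1000
        assert lr_at(0, T, cfg) == pytest.approx(2e-2)
        assert lr_at(T, T, cfg) == pytest.approx(cfg.min_lr, abs=1e-15)
        assert lr_at(T / 2, T, cfg) == pytest.approx((cfg.max_lr + cfg.min_lr) / 2)
        assert lr_at(T / 4, T, cfg) == pytest.approx(
            cfg.min_lr + (cfg.max_lr - cfg.min_lr) * (1 + np.cos(np.pi / 4)) / 2
        )

    def test_nonzero_floor(self):
        cfg = TrainConfig(min_lr=1e-3)
        assert lr_at(100, 100, cfg) == pytest.approx(1e-3)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            lr_at(0, 0, TrainConfig())


class TestBuildModel:
    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            build_model(BackboneSpec(name="resnet999"))

    def test_frozen_depth_bounds(self):
        with pytest.raises(ValueError, match="frozen_depth"):
            build_model(BackboneSpec(), TrainConfig(frozen_depth=9))

    def test_frozen_depth_zero_all_trainable(self):
        model = build_model(BackboneSpec(), TrainConfig(frozen_depth=0))
        trainable = list(model.net.trainable_params(0))
        all_params = list(model.net.trainable_params(0))
        assert len(trainable) == len(all_params) > 0
        assert model.frozen_checksums() == []

    def test_default_freezes_three_of_four_stages(self):
        model = build_model(BackboneSpec(), TrainConfig(frozen_depth=3))
        # stages 4 + head remain trainable: one conv (W, b) + one dense (W, b)
        names = [(type(layer).__name__, name) for layer, name, _ in model.net.trainable_params(3)]
        assert names == [("Conv2d", "W"), ("Conv2d", "b"), ("Dense", "W"), ("Dense", "b")]


class TestTraining:
    def test_one_epoch_smoke(self, fixture_data):
        manifest, slides = fixture_data
        model = build_model(BackboneSpec(), TrainConfig(epochs=1, seed=0))
        history = train(model, manifest, slides)
        assert len(history) == 1
        assert np.isfinite(history["loss"]).all()

    def test_frozen_stages_unchanged_after_training(self, fixture_data):
        manifest, slides = fixture_data
        model = build_model(BackboneSpec(), TrainConfig(epochs=2, seed=1))
        before_all = model.net.stage_checksums()
        train(model, manifest, slides)
        after_all = model.net.stage_checksums()
        assert after_all[:3] == before_all[:3]  # frozen stages bitwise intact
        assert after_all[-1] != before_all[-1]  # the head actually moved

    def test_training_deterministic_per_seed(self, fixture_data):
        manifest, slides = fixture_data
        tiles = np.stack([slides[r.slide_id].image[:90, :90] for r in manifest.records[:4]])
        probs = []
        for _ in range(2):
            model = build_model(BackboneSpec(), TrainConfig(epochs=2, seed=3))
            train(model, manifest, slides)
            probs.append(model.predict_proba(tiles))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_empty_or_single_class_train_split_rejected(self, fixture_data):
        manifest, slides = fixture_data
        unsplit = DatasetManifest(records=manifest.records, design=manifest.design, seed=0)
        model = build_model(BackboneSpec(), TrainConfig(epochs=1))
        with pytest.raises(ValueError, match="train split"):
            train(model, unsplit, slides)


class TestPrediction:
    def test_probabilities_normalized_and_order_preserved(self, fixture_data, rng):
        manifest, slides = fixture_data
        model = build_model(BackboneSpec(), TrainConfig(seed=2))
        tiles = rng.integers(0, 256, size=(5, 90, 90, 3)).astype(np.uint8)
        batch = np.concatenate([tiles, tiles[:1]])  # duplicate first tile at the end
        probs = model.predict_proba(batch)
        assert ((probs >= 0) & (probs <= 1)).all()
        assert probs[0] == probs[-1]

    def test_mask_oracle_pure_tumor_patch(self):
        mask = np.ones((90, 90), dtype=np.uint8)
        oracle = MaskOracle({"s": mask})
        probs = oracle.predict_proba(None, meta=[("s", 0, 0)])
        assert probs[0] == 1.0

    def test_evaluate_with_oracle_is_perfect(self, fixture_data):
        manifest, slides = fixture_data
        oracle = MaskOracle({sid: s.tumor_mask for sid, s in slides.items()})
        report = evaluate_patches(oracle, manifest, slides)
        assert report.accuracy == report.sensitivity == report.specificity == 1.0
        assert report.auc == 1.0

    def test_constant_negative_predictor_confusion(self, fixture_data):
        manifest, slides = fixture_data

        class ConstantModel:
            def predict_proba(self, tiles, meta=None):
                return np.zeros(len(tiles))

        report = evaluate_patches(ConstantModel(), manifest, slides)
        assert report.sensitivity == 0.0
        assert report.specificity == 1.0
        assert report.accuracy == pytest.approx(0.5, abs=0.02)  # balanced manifest

    def test_report_consistent_with_metric_formulas(self, fixture_data):
        manifest, slides = fixture_data
        oracle = MaskOracle({sid: s.tumor_mask for sid, s in slides.items()})
        report = evaluate_patches(oracle, manifest, slides)
        recomputed = compute_metrics(
            ConfusionCounts(report.counts.tp, report.counts.tn, report.counts.fp, report.counts.fn)
        )
        assert recomputed.f1 == report.f1
        assert recomputed.weighted_f1 == report.weighted_f1
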