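"""Tiling, tumor-content labeling, balancing, dataset designs and splitting."""

from __future__ import annotations

import numpy as np
import pytest

from slnpatch.patches import (
    DESIGNS,
    DatasetManifest,
    GridSpec,
    PatchRecord,
    balance_classes,
    build_dataset,
    class_pixel_histogram,
    harvest_records,
    label_patch,
    split_manifest,
    tile_grid,
    tile_tumor_contents,
    tumor_content,
)
from slnpatch.synthetic import EXTERNAL_STYLE, SlideSpec, generate_slide


def _record(label: str, i: int = 0, domain: str = "local", tc: float | None = None) -> PatchRecord:
    if tc is None:
        tc = 0.5 if label == "positive" else 0.0
    return PatchRecord(
        slide_id=f"s{i}", row=i, col=0, x0=0, y0=i * 90, tumor_content=tc, label=label, domain=domain
    )


class TestTileGrid:
    @pytest.mark.parametrize(
        "h, w, expected", [(900, 450, 50), (905, 457, 50), (89, 89, 0), (90, 90, 1)]
    )
    def test_known_counts(self, h, w, expected):
        assert len(tile_grid(h, w, GridSpec())) == expected

    def test_row_major_order_and_anchors(self):
        tiles = tile_grid(180, 270, GridSpec())
        assert tiles == [
            (0, 0, 0, 0), (0, 1, 90, 0), (0, 2, 180, 0),
            (1, 0, 0, 90), (1, 1, 90, 90), (1, 2, 180, 90),
        ]

    def test_counts_match_floor_arithmetic_sweep(self, rng):
        for _ in range(1000):
            h, w = (int(v) for v in rng.integers(1, 600, size=2))
            s = int(rng.integers(1, 120))
            count = len(tile_grid(h, w, GridSpec(patch_size=s, stride=s)))
            assert count == (h // s) * (w // s)

    def test_overlapping_grid_counts(self):
        # stride 30 on one axis of length L gives (L - 90)//30 + 1 anchors
        tiles = tile_grid(900, 900, GridSpec(patch_size=90, stride=30))
        assert len(tiles) == 28 * 28


class TestTumorContent:
    def test_extremes_and_exact_fraction(self):
        assert tumor_content(np.zeros((90, 90))) == 0.0
        assert tumor_content(np.ones((90, 90))) == 1.0
        tile = np.zeros(8100)
        tile[:1620] = 1
        assert tumor_content(tile.reshape(90, 90)) == 0.2

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            tumor_content(np.zeros((64, 64)))

    def test_vectorized_contents_match_per_tile_loop(self, rng):
        mask = (rng.random((300, 270)) < 0.3).astype(np.uint8)
        for stride in (90, 30):
            grid = GridSpec(patch_size=90, stride=stride)
            tcs = tile_tumor_contents(mask, grid)
            for r, c, x0, y0 in tile_grid(*mask.shape, grid):
                assert tcs[r, c] == tumor_content(mask[y0 : y0 + 90, x0 : x0 + 90])


class TestLabelPatch:
    @pytest.mark.parametrize(
        "tc, expected",
        [
            (0.0, "negative"),
            (0.5, "positive"),
            (1.0, "positive"),
            (0.2, "excluded"),
            (0.2 - 1e-9, "excluded"),
            (0.2 + 1e-9, "positive"),
            (0.1, "excluded"),
        ],
    )
    def test_trichotomy(self, tc, expected):
        assert label_patch(tc) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_patch(1.5)

    def test_every_tiled_patch_gets_exactly_one_label(self, rng):
        for tc in rng.random(200):
            assert label_patch(float(tc)) in ("positive", "negative", "excluded")


class TestBalance:
    def test_majority_subsampled_to_minority(self):
        records = [_record("positive", i) for i in range(100)] + [
            _record("negative", i + 100) for i in range(300)
        ]
        balanced = balance_classes(records, seed=0)
        labels = [r.label for r in balanced]
        assert labels.count("positive") == labels.count("negative") == 100

    def test_already_balanced_unchanged(self):
        records = [_record("positive", i) for i in range(50)] + [
            _record("negative", i + 50) for i in range(50)
        ]
        assert balance_classes(records, seed=1) == records

    def test_deterministic_per_seed(self):
        records = [_record("positive", i) for i in range(10)] + [
            _record("negative", i + 10) for i in range(40)
        ]
        assert balance_classes(records, seed=5) == balance_classes(records, seed=5)
        assert balance_classes(records, seed=5) != balance_classes(records, seed=6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balance_classes([_record("positive")], seed=0)


class TestSplit:
    def _manifest(self, n_pos: int, n_neg: int) -> DatasetManifest:
        records = [_record("positive", i) for i in range(n_pos)] + [
            _record("negative", i + n_pos) for i in range(n_neg)
        ]
        return DatasetManifest(records=records, design=DESIGNS["Tumor"], seed=0)

    def test_70_30_counts(self):
        split = split_manifest(self._manifest(500, 500), seed=1)
        assert split.split.count("train") == 700
        assert split.split.count("test") == 300

    def test_stratified_counts(self):
        split = split_manifest(self._manifest(100, 100), seed=2)
        for label in ("positive", "negative"):
            train = [r for r, s in zip(split.records, split.split) if s == "train" and r.label == label]
            test = [r for r, s in zip(split.records, split.split) if s == "test" and r.label == label]
            assert (len(train), len(test)) == (70, 30)

    def test_partition_and_determinism(self):
        m = self._manifest(33, 67)
        a = split_manifest(m, seed=3)
        b = split_manifest(m, seed=3)
        assert a.split == b.split
        assert all(s in ("train", "test") for s in a.split)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_manifest(self._manifest(10, 10), train_fraction=1.0)
        with pytest.raises(ValueError):
            split_manifest(self._manifest(10, 10), train_fraction=0.0)


@pytest.fixture(scope="module")
def fib_slide():
    """Slide where fibrosis forms a band around lesions, creating patches
    whose combined (tumor+fibrosis) content crosses the 20% threshold even
    though tumor alone does not."""
    return generate_slide(
        SlideSpec(
            width_px=900, height_px=900, domain=EXTERNAL_STYLE.__class__(name="local"),
            seed=31, tumor_fraction=0.12, fibrosis_fraction=0.08,
        )
    )


class TestBuildDataset:
    def test_manifest_balanced_for_every_design(self, small_slide, negative_slide):
        slides = [small_slide, negative_slide]
        for design_id in ("Tumor", "TumorFIB"):
            manifest = build_dataset(DESIGNS[design_id], slides, seed=1)
            counts = manifest.counts()
            assert counts["label:positive"] == counts["label:negative"] > 0

    def test_tumorfib_positives_superset_of_tumor(self, fib_slide, negative_slide):
        slides = [fib_slide, negative_slide]
        tumor_pos = {
            (r.slide_id, r.row, r.col)
            for r in harvest_records(slides, include_fibrosis=False)
            if r.label == "positive"
        }
        fib_pos = {
            (r.slide_id, r.row, r.col)
            for r in harvest_records(slides, include_fibrosis=True)
            if r.label == "positive"
        }
        assert tumor_pos <= fib_pos
        assert len(fib_pos) > len(tumor_pos)  # the fibrosis band flips some patches

    def test_tumor_extended_multiplies_tiles(self, small_slide, negative_slide):
        slides = [small_slide, negative_slide]
        base = harvest_records(slides, grid=GridSpec(), keep_excluded=True)
        dense = harvest_records(slides, grid=GridSpec(patch_size=90, stride=30), keep_excluded=True)
        # closed form: ((900-90)//30 + 1)^2 anchors per slide vs 10x10,
        # approaching 9x as slides grow (floor effects at the edges)
        assert len(dense) == 2 * 28 * 28
        assert len(dense) >= 7 * len(base)

    def test_interhospital_mixture_is_half_and_half(self, small_slide, negative_slide):
        local = [small_slide, negative_slide]
        ext_pos = generate_slide(
            SlideSpec(width_px=900, height_px=900, domain=EXTERNAL_STYLE, seed=41, tumor_fraction=0.18)
        )
        ext_neg = generate_slide(
            SlideSpec(width_px=900, height_px=900, domain=EXTERNAL_STYLE, seed=42)
        )
        manifest = build_dataset(DESIGNS["Interhospital"], local, [ext_pos, ext_neg], seed=3)
        counts = manifest.counts()
        assert counts["label:positive"] == counts["label:negative"]
        assert counts["domain:local"] == counts["domain:external"] == len(manifest.records) // 2

    def test_interhospital_requires_external(self, small_slide, negative_slide):
        with pytest.raises(ValueError, match="external"):
            build_dataset(DESIGNS["Interhospital"], [small_slide, negative_slide], seed=0)

    def test_manifest_csv_round_trip(self, small_slide, negative_slide, tmp_path):
        manifest = build_dataset(DESIGNS["Tumor"], [small_slide, negative_slide], seed=1)
        manifest = split_manifest(manifest, seed=1)
        path = manifest.save_csv(tmp_path / "m.csv")
        back = DatasetManifest.load_csv(path, DESIGNS["Tumor"], seed=1)
        assert back.records == manifest.records
        assert back.split == manifest.split


class TestPixelHistogram:
    def test_pure_patch_histograms(self):
        white = np.full((1, 90, 90, 3), 255, dtype=np.uint8)
        rec = [_record("negative", 0, tc=0.0)]
        hist = class_pixel_histogram(rec, {"s0": white[0]}, "negative")
        assert (hist[:, 255] == 8100).all() and hist.sum() == 3 * 8100
        black = np.zeros((90, 90, 3), dtype=np.uint8)
        hist = class_pixel_histogram(rec, {"s0": black}, "negative")
        assert (hist[:, 0] == 8100).all()

    def test_negative_class_has_more_white_mass(self, small_slide, negative_slide):
        slides = {s.slide_id: s for s in (small_slide, negative_slide)}
        records = harvest_records([small_slide, negative_slide])
        pos = class_pixel_histogram(records, slides, "positive")
        neg = class_pixel_histogram(records, slides, "negative")
        # white background tiles inflate the 255 bin of the negative class
        assert neg[:, 255].sum() / neg.sum() > pos[:, 255].sum() / pos.sum()
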