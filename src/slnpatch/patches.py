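"""Patch dataset construction.

Slides are tiled into 90 x 90 px patches on a regular grid. Each patch gets a
tumor content (TC) — the fraction of its pixels set in the ground-truth mask —
and is labeled by the trichotomy:

* ``positive`` if TC > 20% (no upper bound: any burden above the threshold
  counts, which keeps partially tumorous patches in the positive class);
* ``negative`` if TC = 0 exactly;
* ``excluded`` otherwise (0 < TC <= 20%): neither rule applies and the patch
  enters no class.

Four dataset designs are supported: ``Tumor`` (tumor-only masks), ``TumorFIB``
(tumor plus tumor-associated fibrosis in the mask before TC is computed),
``TumorExtended`` (denser, overlapping re-tiling of the same slides) and
``Interhospital`` (a 50%/50% mixture of local-domain and external-domain
patches). Every design ends class-balanced by uniform subsampling of the
majority class, and is split 70/30 into train/test, stratified by label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "PatchRecord",
    "DatasetDesign",
    "DatasetManifest",
    "DESIGNS",
    "tile_grid",
    "tumor_content",
    "tile_tumor_contents",
    "label_patch",
    "balance_classes",
    "harvest_records",
    "build_dataset",
    "split_manifest",
    "extract_patch",
    "patch_pixels",
    "class_pixel_histogram",
]

THETA_POS_DEFAULT = 0.20


@dataclass(frozen=True)
class GridSpec:
    """Regular tiling grid anchored at the slide's top-left corner."""

    patch_size: int = 90
    stride: int = 90

    def __post_init__(self) -> None:
        if self.patch_size <= 0 or self.stride <= 0:
            raise ValueError("patch_size and stride must be positive")
        if self.stride > self.patch_size:
            raise ValueError("stride must not exceed patch_size")


@dataclass(frozen=True)
class PatchRecord:
    slide_id: str
    row: int
    col: int
    x0: int
    y0: int
    tumor_content: float
    label: str
    domain: str
    pixels_path: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_content <= 1.0):
            raise ValueError(f"tumor_content outside [0,1]: {self.tumor_content}")
        if self.label not in ("positive", "negative", "excluded"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class DatasetDesign:
    """One of the four patch dataset designs."""

    id: str
    include_fibrosis: bool = False
    expansion_stride: int | None = None
    mixture_ratio: float = 0.5
    theta_pos: float = THETA_POS_DEFAULT

    def __post_init__(self) -> None:
        if self.id not in ("Tumor", "TumorFIB", "TumorExtended", "Interhospital"):
            raise ValueError(f"unknown design id {self.id!r}")
        if not (0.0 < self.mixture_ratio < 1.0):
            raise ValueError("mixture_ratio must be in (0,1)")
        if not (0.0 <= self.theta_pos < 1.0):
            raise ValueError("theta_pos must be in [0,1)")


DESIGNS: dict[str, DatasetDesign] = {
    "Tumor": DatasetDesign(id="Tumor"),
    "TumorFIB": DatasetDesign(id="TumorFIB", include_fibrosis=True),
    "TumorExtended": DatasetDesign(id="TumorExtended", expansion_stride=30),
    "Interhospital": DatasetDesign(id="Interhospital"),
}


@dataclass
class DatasetManifest:
    """Balanced patch records of one design plus their train/test assignment."""

    records: list[PatchRecord]
    design: DatasetDesign
    seed: int
    split: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.split:
            self.split = [None] * len(self.records)
        if len(self.split) != len(self.records):
            raise ValueError("split must align with records")

    def counts(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for r in self.records:
            tally[f"label:{r.label}"] = tally.get(f"label:{r.label}", 0) + 1
            tally[f"domain:{r.domain}"] = tally.get(f"domain:{r.domain}", 0) + 1
        return tally

    def subset(self, part: str) -> list[PatchRecord]:
        return [r for r, s in zip(self.records, self.split) if s == part]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "slide_id": r.slide_id,
                "row": r.row,
                "col": r.col,
                "x0": r.x0,
                "y0": r.y0,
                "tumor_content": r.tumor_content,
                "label": r.label,
                "domain": r.domain,
                "split": s if s is not None else "",
                "pixels_path": r.pixels_path or "",
            }
            for r, s in zip(self.records, self.split)
        ]
        return pd.DataFrame(rows)

    def save_csv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def load_csv(cls, path, design: DatasetDesign, seed: int = 0) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
        records = [
            PatchRecord(
                slide_id=str(row.slide_id),
                row=int(row.row),
                col=int(row.col),
                x0=int(row.x0),
                y0=int(row.y0),
                tumor_content=float(row.tumor_content),
                label=str(row.label),
                domain=str(row.domain),
                pixels_path=str(row.pixels_path) or None,
            )
            for row in df.itertuples()
        ]
        split = [s if s else None for s in df["split"].astype(str)]
        return cls(records=records, design=design, seed=seed, split=split)


def tile_grid(slide_height: int, slide_width: int, grid: GridSpec) -> list[tuple[int, int, int, int]]:
    """All (row, col, x0, y0) tile anchors, row-major; partial edge tiles dropped.

    For stride == patch_size == s the count is floor(H/s) * floor(W/s). A
    slide smaller than one patch yields an empty list.
    """
    if slide_height <= 0 or slide_width <= 0:
        raise ValueError("slide dimensions must be positive")
    s, st = grid.patch_size, grid.stride
    if slide_height < s or slide_width < s:
        return []
    n_rows = (slide_height - s) // st + 1
    n_cols = (slide_width - s) // st + 1
    return [(r, c, c * st, r * st) for r in range(n_rows) for c in range(n_cols)]


def tumor_content(mask_tile: np.ndarray, patch_size: int = 90) -> float:
    """Fraction of set pixels in one binary mask tile."""
    tile = np.asarray(mask_tile)
    if tile.shape != (patch_size, patch_size):
        raise ValueError(f"expected {patch_size}x{patch_size} tile, got {tile.shape}")
    return float(int(tile.sum()) / (patch_size * patch_size))


def tile_tumor_contents(mask: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Tumor content of every grid tile at once (integral-image sums).

    Returns an R x C float array aligned with :func:`tile_grid` ordering.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    s, st = grid.patch_size, grid.stride
    if h < s or w < s:
        return np.zeros((0, 0))
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    r0 = np.arange(0, h - s + 1, st)
    c0 = np.arange(0, w - s + 1, st)
    sums = (
        ii[np.ix_(r0 + s, c0 + s)]
        - ii[np.ix_(r0, c0 + s)]
        - ii[np.ix_(r0 + s, c0)]
        + ii[np.ix_(r0, c0)]
    )
    return sums / (s * s)


def label_patch(tc: float, theta_pos: float = THETA_POS_DEFAULT) -> str:
    """Apply the labeling trichotomy: TC > theta -> positive, TC = 0 -> negative,
    otherwise excluded."""
    if not (0.0 <= tc <= 1.0):
        raise ValueError(f"tumor content outside [0,1]: {tc}")
    if tc > theta_pos:
        return "positive"
    if tc == 0.0:
        return "negative"
    return "excluded"


def balance_classes(records, seed: int) -> list[PatchRecord]:
    """Subsample the majority class uniformly without replacement to the
    minority-class count. Deterministic per seed; record order of the kept
    class is preserved, sampled records keep their original relative order."""
    records = list(records)
    pos = [r for r in records if r.label == "positive"]
    neg = [r for r in records if r.label == "negative"]
    if not pos or not neg:
        raise ValueError(
            f"balancing undefined with {len(pos)} positives and {len(neg)} negatives"
        )
    rng = np.random.default_rng(seed)
    if len(pos) == len(neg):
        return pos + neg
    major, minor = (neg, pos) if len(neg) > len(pos) else (pos, neg)
    keep = np.sort(rng.choice(len(major), size=len(minor), replace=False))
    sampled = [major[i] for i in keep]
    return (minor + sampled) if major is neg else (sampled + minor)


def harvest_records(
    slides,
    include_fibrosis: bool = False,
    grid: GridSpec | None = None,
    theta_pos: float = THETA_POS_DEFAULT,
    keep_excluded: bool = False,
) -> list[PatchRecord]:
    """Tile each slide, compute tumor content and label every patch.

    ``slides`` is an iterable of SyntheticSlide-like objects exposing
    ``slide_id``, ``image``, ``tumor_mask``, ``fibrosis_mask`` and
    ``spec.domain.name``. Excluded patches are dropped unless requested.
    """
    grid = grid or GridSpec()
    out: list[PatchRecord] = []
    for slide in slides:
        mask = slide.tumor_mask
        if include_fibrosis:
            mask = (slide.tumor_mask.astype(bool) | slide.fibrosis_mask.astype(bool)).astype(
                np.uint8
            )
        tcs = tile_tumor_contents(mask, grid)
        domain = slide.spec.domain.name
        for r in range(tcs.shape[0]):
            for c in range(tcs.shape[1]):
                tc = float(tcs[r, c])
                label = label_patch(tc, theta_pos)
                if label == "excluded" and not keep_excluded:
                    continue
                out.append(
                    PatchRecord(
                        slide_id=slide.slide_id,
                        row=r,
                        col=c,
                        x0=c * grid.stride,
                        y0=r * grid.stride,
                        tumor_content=tc,
                        label=label,
                        domain=domain,
                    )
                )
    return out


def _balanced_pair_subsample(records, n_per_class: int, rng) -> list[PatchRecord]:
    pos = [r for r in records if r.label == "positive"]
    neg = [r for r in records if r.label == "negative"]
    keep_p = np.sort(rng.choice(len(pos), size=n_per_class, replace=False))
    keep_n = np.sort(rng.choice(len(neg), size=n_per_class, replace=False))
    return [pos[i] for i in keep_p] + [neg[i] for i in keep_n]


def build_dataset(
    design: DatasetDesign,
    slides_with_masks,
    external_slides=None,
    seed: int = 0,
    grid: GridSpec | None = None,
) -> DatasetManifest:
    """Assemble one design's balanced manifest from annotated slides.

    ``Interhospital`` balances the local Tumor-design records, balances the
    external-domain records, then subsamples both sides to a common per-class
    count so the final set is 50% local / 50% external and 50% positive /
    50% negative.
    """
    base_grid = grid or GridSpec()
    if design.id == "TumorExtended":
        stride = design.expansion_stride if design.expansion_stride is not None else 30
        if stride >= base_grid.patch_size:
            raise ValueError("expansion_stride must be smaller than patch_size")
        base_grid = GridSpec(patch_size=base_grid.patch_size, stride=stride)

    local = harvest_records(
        slides_with_masks,
        include_fibrosis=design.include_fibrosis,
        grid=base_grid,
        theta_pos=design.theta_pos,
    )

    if design.id != "Interhospital":
        records = balance_classes(local, seed)
        return DatasetManifest(records=records, design=design, seed=seed)

    if external_slides is None:
        raise ValueError("Interhospital design requires external_slides")
    rng = np.random.default_rng(seed)
    local_bal = balance_classes(local, seed)
    external = harvest_records(
        external_slides, include_fibrosis=False, grid=base_grid, theta_pos=design.theta_pos
    )
    external_bal = balance_classes(external, seed + 1)
    n_per_class = min(len(local_bal), len(external_bal)) // 2
    if n_per_class == 0:
        raise ValueError("not enough records on one side of the Interhospital mixture")
    records = _balanced_pair_subsample(local_bal, n_per_class, rng) + _balanced_pair_subsample(
        external_bal, n_per_class, rng
    )
    return DatasetManifest(records=records, design=design, seed=seed)


def split_manifest(
    manifest: DatasetManifest,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_by_label: bool = True,
) -> DatasetManifest:
    """Assign each record to train or test, stratified by label.

    Per-stratum train counts equal ``round(train_fraction * n)``; both parts
    are non-empty in every stratum. Deterministic per seed. Returns a new
    manifest sharing the records.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0,1) so both parts are non-empty")
    n = len(manifest.records)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)
    split: list[str | None] = [None] * n
    if stratify_by_label:
        strata: dict[str, list[int]] = {}
        for i, r in enumerate(manifest.records):
            strata.setdefault(r.label, []).append(i)
    else:
        strata = {"all": list(range(n))}
    for label, idx in strata.items():
        if len(idx) < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 records")
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(len(idx))
        for j in perm[:n_train]:
            split[idx[j]] = "train"
        for j in perm[n_train:]:
            split[idx[j]] = "test"
    return DatasetManifest(
        records=manifest.records, design=manifest.design, seed=manifest.seed, split=split
    )


def extract_patch(image: np.ndarray, record: PatchRecord, patch_size: int = 90) -> np.ndarray:
    """Cut one patch's pixels out of its slide raster."""
    return image[record.y0 : record.y0 + patch_size, record.x0 : record.x0 + patch_size]


def patch_pixels(records, slides: dict, patch_size: int = 90) -> np.ndarray:
    """Stack the pixel tiles of many records into an (N, s, s, 3) uint8 array.

    ``slides`` maps slide_id to an object with an ``image`` attribute (or to a
    raw H x W x 3 array).
    """
    tiles = []
    for r in records:
        slide = slides[r.slide_id]
        image = slide.image if hasattr(slide, "image") else slide
        tiles.append(extract_patch(image, r, patch_size))
    if not tiles:
        raise ValueError("no records to extract pixels for")
    return np.stack(tiles)


def class_pixel_histogram(records, slides: dict, side: str, patch_size: int = 90) -> np.ndarray:
    """256-bin intensity histogram per RGB channel over one class's patches.

    Returns a (3, 256) count array; each channel's bins sum to
    ``n_patches * patch_size**2``. On slides with white background the
    negative-side histogram shows more mass in bin 255 than the positive side.
    """
    if side not in ("positive", "negative"):
        raise ValueError("side must be 'positive' or 'negative'")
    selected = [r for r in records if r.label == side]
    if not selected:
        raise ValueError(f"no {side} records in selection")
    tiles = patch_pixels(selected, slides, patch_size)
    hist = np.zeros((3, 256), dtype=np.int64)
    for ch in range(3):
        hist[ch] = np.bincount(tiles[..., ch].ravel(), minlength=256)
    return hist
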