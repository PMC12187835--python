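"""Whole-slide testing: sliding-window prediction and per-slide scoring.

The slide is tiled into consecutive non-overlapping 90 x 90 patches; the
classifier's positive-class probability for each tile is written into a
probability matrix spatially registered to the slide (entry (r, c) is the
tile anchored at (c*s, r*s)). Thresholding at 0.5 (ties resolved to
negative) and comparing with a ground-truth grid derived from the tumor mask
yields per-slide confusion counts. Partial edge tiles are excluded, matching
the tiling convention.

The ground-truth rule at test time assigns a cell positive iff its tumor
content exceeds ``theta_gt`` (default 0.20, the training labeling threshold);
intermediate-content cells are negative so the grid is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .metrics import ConfusionCounts, MetricsReport
from .patches import GridSpec, tile_grid, tile_tumor_contents

__all__ = [
    "ProbabilityMatrix",
    "GroundTruthGrid",
    "predict_slide",
    "grid_ground_truth",
    "threshold_matrix",
    "slide_confusion",
    "aggregate_reports",
]


@dataclass
class ProbabilityMatrix:
    """R x C patch probabilities registered to a slide's tiling grid."""

    grid: np.ndarray
    grid_spec: GridSpec
    slide_id: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError("probability grid must be 2-D")
        if g.size and (g.min() < 0.0 or g.max() > 1.0):
            raise ValueError("probabilities must lie in [0,1]")
        self.grid = g

    def save_csv(self, path) -> Path:
        path = Path(path)
        rows, cols = np.indices(self.grid.shape)
        pd.DataFrame(
            {"row": rows.ravel(), "col": cols.ravel(), "probability": self.grid.ravel()}
        ).to_csv(path, index=False)
        return path

    def save_tiff(self, path) -> Path:
        path = Path(path)
        tifffile.imwrite(path, self.grid.astype(np.float32))
        return path


@dataclass
class GroundTruthGrid:
    """R x C binary reference labels derived from the tumor mask."""

    grid: np.ndarray
    theta_gt: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)


def predict_slide(
    model, slide, grid_spec: GridSpec | None = None, batch_size: int = 64
) -> ProbabilityMatrix:
    """Run the sliding-window prediction over one slide.

    ``slide`` is a SyntheticSlide-like object (``image`` + ``slide_id``) or a
    raw H x W x 3 array. The output is invariant to batch size and visiting
    order. Raises if the slide is smaller than one patch.
    """
    grid_spec = grid_spec or GridSpec()
    image = slide.image if hasattr(slide, "image") else np.asarray(slide)
    slide_id = getattr(slide, "slide_id", "")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 slide raster, got shape {image.shape}")
    h, w = image.shape[:2]
    anchors = tile_grid(h, w, grid_spec)
    if not anchors:
        raise ValueError(f"slide {h}x{w} is smaller than one {grid_spec.patch_size}px patch")
    s = grid_spec.patch_size
    n_rows = anchors[-1][0] + 1
    n_cols = anchors[-1][1] + 1
    probs = np.empty(len(anchors))
    for start in range(0, len(anchors), batch_size):
        chunk = anchors[start : start + batch_size]
        tiles = np.stack([image[y0 : y0 + s, x0 : x0 + s] for (_, _, x0, y0) in chunk])
        meta = [(slide_id, x0, y0) for (_, _, x0, y0) in chunk]
        probs[start : start + len(chunk)] = model.predict_proba(tiles, meta=meta)
    return ProbabilityMatrix(
        grid=probs.reshape(n_rows, n_cols), grid_spec=grid_spec, slide_id=slide_id
    )


def grid_ground_truth(
    mask: np.ndarray, grid_spec: GridSpec | None = None, theta_gt: float = 0.20
) -> GroundTruthGrid:
    """Cell positive iff tile tumor content > theta_gt; binary and exhaustive."""
    grid_spec = grid_spec or GridSpec()
    tcs = tile_tumor_contents(np.asarray(mask), grid_spec)
    if tcs.size == 0:
        raise ValueError("mask smaller than one patch")
    return GroundTruthGrid(grid=tcs > theta_gt, theta_gt=theta_gt)


def threshold_matrix(pm: ProbabilityMatrix, tau: float = 0.5) -> np.ndarray:
    """Binary grid: positive iff p > tau (a tie at tau is negative)."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must be in (0,1)")
    return pm.grid > tau


def slide_confusion(pred_grid: np.ndarray, gt_grid) -> ConfusionCounts:
    """Cell-wise confusion counts; TP+TN+FP+FN always equals R*C."""
    pred = np.asarray(pred_grid).astype(bool)
    truth = gt_grid.grid if isinstance(gt_grid, GroundTruthGrid) else np.asarray(gt_grid)
    truth = truth.astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"grid shapes differ: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


_METRIC_FIELDS = ("accuracy", "sensitivity", "specificity", "f1", "weighted_f1")


def aggregate_reports(reports: list[tuple[str, str, MetricsReport]], group_by: str) -> pd.DataFrame:
    """Mean +/- sample SD of metrics grouped by model or by slide.

    ``reports`` holds (model_id, slide_id, report) triples. ``group_by`` is
    ``"model"`` (statistics across slides per model) or ``"slide"``
    (statistics across models per slide). A singleton group reports SD 0.
    """
    if group_by not in ("model", "slide"):
        raise ValueError("group_by must be 'model' or 'slide'")
    if not reports:
        raise ValueError("no reports to aggregate")
    key_idx = 0 if group_by == "model" else 1
    groups: dict[str, list[MetricsReport]] = {}
    for item in reports:
        groups.setdefault(item[key_idx], []).append(item[2])
    rows = []
    for key in sorted(groups):
        members = groups[key]
        row: dict[str, object] = {group_by: key, "n": len(members)}
        for m in _METRIC_FIELDS:
            vals = np.array([getattr(r, m) for r in members], dtype=float)
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
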