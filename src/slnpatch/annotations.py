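"""Polygon annotations and binary masks.

Conventions used throughout the package (stated once, asserted everywhere):

* coordinates are 0-based, ``x`` rightward, ``y`` downward;
* pixel ``(row i, col j)`` occupies the half-open box ``[j, j+1) x [i, i+1)``
  with its center at ``(j + 0.5, i + 0.5)``;
* a pixel belongs to a polygon iff its center is inside under the even-odd
  (ray-crossing parity) fill rule;
* masks are strictly binary ``{0, 1}`` uint8 arrays, stored on disk as
  single-channel PNGs with values ``{0, 255}``.

Tumor masks assign 1 to tumor-cell pixels; the optional ``fibrosis`` class
marks tumor-associated stromal tissue annotated alongside tumor regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LABEL_VOCABULARY",
    "PolygonAnnotation",
    "BinaryMask",
    "AnnotationParseError",
    "read_labelme",
    "write_labelme",
    "rasterize",
    "rasterize_polygon",
    "read_mask",
    "write_mask",
]

LABEL_VOCABULARY: frozenset[str] = frozenset({"tumor", "fibrosis"})


class AnnotationParseError(ValueError):
    """A labelme file failed to parse (malformed JSON, missing fields, unknown label)."""


@dataclass(frozen=True)
class PolygonAnnotation:
    label: str
    vertices: tuple[tuple[float, float], ...]
    slide_id: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError(f"polygon needs >=3 vertices, got {len(self.vertices)}")


@dataclass
class BinaryMask:
    grid: np.ndarray
    slide_id: str = ""
    classes_included: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {g.shape}")
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be strictly binary, found values {vals[:10]}")
        self.grid = g.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


def read_labelme(path, allowed_labels: frozenset[str] = LABEL_VOCABULARY) -> list[PolygonAnnotation]:
    """Read a labelme-style JSON file into polygon annotations.

    The file must hold a ``"shapes"`` array of objects with ``label`` and
    ``points`` (``[[x, y], ...]`` pixel coordinates). Labels outside
    ``allowed_labels`` raise :class:`AnnotationParseError` naming the label
    and shape index. Coordinates are preserved exactly.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "shapes" not in payload:
        raise AnnotationParseError(f"{path}: missing 'shapes' array")
    slide_id = str(payload.get("imagePath", path.stem))
    annotations = []
    for i, shape in enumerate(payload["shapes"]):
        try:
            label = shape["label"]
            points = shape["points"]
        except (TypeError, KeyError) as exc:
            raise AnnotationParseError(f"{path}: shape {i} missing {exc}") from exc
        if label not in allowed_labels:
            raise AnnotationParseError(
                f"{path}: shape {i} has unknown label {label!r} "
                f"(allowed: {sorted(allowed_labels)})"
            )
        if len(points) < 3:
            raise AnnotationParseError(f"{path}: shape {i} has fewer than 3 points")
        vertices = tuple((float(x), float(y)) for x, y in points)
        annotations.append(PolygonAnnotation(label=label, vertices=vertices, slide_id=slide_id))
    return annotations


def write_labelme(annotations, shape: tuple[int, int], path, image_path: str = "") -> Path:
    """Write annotations as a labelme-style JSON (keys: shapes, imageHeight, imageWidth)."""
    path = Path(path)
    payload = {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {
                "label": a.label,
                "points": [[float(x), float(y)] for x, y in a.vertices],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for a in annotations
        ],
        "imagePath": image_path,
        "imageHeight": int(shape[0]),
        "imageWidth": int(shape[1]),
    }
    path.write_text(json.dumps(payload))
    return path


def rasterize_polygon(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization of one polygon onto an H x W grid.

    Scanline formulation of center-in-polygon parity: for each pixel row the
    crossing abscissae of the polygon edges with the horizontal line through
    the pixel centers are collected; a center at x = j + 0.5 is inside iff an
    odd number of crossings lies strictly to its right.
    """
    h, w = int(shape[0]), int(shape[1])
    vs = np.asarray(vertices, dtype=float)
    if vs.ndim != 2 or vs.shape[1] != 2 or len(vs) < 3:
        raise ValueError("vertices must be an (n>=3, 2) array of (x, y)")
    out = np.zeros((h, w), dtype=np.uint8)
    x1, y1 = vs[:, 0], vs[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    centers_x = np.arange(w) + 0.5
    ymin = max(0, int(np.floor(vs[:, 1].min() - 0.5)))
    ymax = min(h - 1, int(np.ceil(vs[:, 1].max())))
    for row in range(ymin, ymax + 1):
        yc = row + 0.5
        crossing = (y1 > yc) != (y2 > yc)
        if not crossing.any():
            continue
        xi = x1[crossing] + (yc - y1[crossing]) * (x2[crossing] - x1[crossing]) / (
            y2[crossing] - y1[crossing]
        )
        # parity of crossings to the right of each center
        counts = (centers_x[:, None] < xi[None, :]).sum(axis=1)
        out[row] = counts & 1
    return out


def rasterize(
    annotations,
    shape: tuple[int, int],
    classes_included=frozenset({"tumor"}),
    slide_id: str = "",
) -> BinaryMask:
    """Union-rasterize all polygons whose label is in ``classes_included``.

    A pixel is set iff its center lies inside at least one selected polygon
    (even-odd rule per polygon, union across polygons). Polygons entirely
    outside the grid contribute nothing and emit a warning.
    """
    classes_included = frozenset(classes_included)
    if not classes_included:
        raise ValueError("classes_included must be non-empty")
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    grid = np.zeros((h, w), dtype=np.uint8)
    for a in annotations:
        if a.label not in classes_included:
            continue
        vs = np.asarray(a.vertices, dtype=float)
        if vs[:, 0].max() < 0 or vs[:, 0].min() > w or vs[:, 1].max() < 0 or vs[:, 1].min() > h:
            warnings.warn(
                f"polygon with label {a.label!r} lies entirely outside {h}x{w}; ignored",
                stacklevel=2,
            )
            continue
        grid |= rasterize_polygon(a.vertices, (h, w))
    return BinaryMask(grid=grid, slide_id=slide_id, classes_included=classes_included)


def write_mask(mask: BinaryMask, path) -> Path:
    """Write a binary mask as a single-channel PNG with values {0, 255}."""
    path = Path(path)
    try:
        Image.fromarray(mask.grid * np.uint8(255), mode="L").save(path, format="PNG")
    except OSError as exc:
        raise OSError(f"failed to write mask to {path}: {exc}") from exc
    return path


def read_mask(path, slide_id: str = "") -> BinaryMask:
    """Read a {0, 255} single-channel PNG back into a binary mask.

    Any pixel value other than 0 or 255 is rejected.
    """
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("L"))
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(f"{path}: non-binary pixel values {bad.tolist()} (expected only 0/255)")
    return BinaryMask(grid=(arr == 255).astype(np.uint8), slide_id=slide_id or path.stem)
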