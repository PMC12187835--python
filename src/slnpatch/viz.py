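"""Probability-map visualization for pathologist review.

Two overlays are rendered from a slide's probability matrix:

* a high-contrast **binary map** painting every patch with probability above
  0.5 in a single solid color (default red);
* a **tri-color heatmap** binning probabilities into red (above 0.9), green
  (0.7 to 0.9) and blue (0.5 to 0.7); cells at or below 0.5 stay transparent.

Bins are half-open ``(lower, upper]``, so a probability of exactly 0.7 falls
in the blue bin and 0.9 in the green bin. Overlays are RGBA rasters at slide
resolution covering the tiled region (each cell paints its 90 x 90
footprint) and composit deterministically over the slide image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .inference import ProbabilityMatrix

__all__ = [
    "ColorScheme",
    "binary_map",
    "probability_heatmap",
    "compose_overlay",
    "render_report",
    "heatmap_bin_counts",
]

RED = (255, 0, 0)
GREEN = (0, 200, 0)
BLUE = (0, 0, 255)


@dataclass(frozen=True)
class ColorScheme:
    """Heatmap bins ``(lower, upper, rgb, opacity)`` plus the binary-map style.

    Bins must be contiguous half-open intervals covering (0.5, 1.0].
    """

    bins: tuple = (
        (0.9, 1.0, RED, 0.6),
        (0.7, 0.9, GREEN, 0.6),
        (0.5, 0.7, BLUE, 0.6),
    )
    binary_color: tuple[int, int, int] = RED
    binary_threshold: float = 0.5
    binary_opacity: float = 1.0

    def __post_init__(self) -> None:
        edges = sorted((lo, hi) for lo, hi, _, _ in self.bins)
        lo0 = edges[0][0]
        for (lo_a, hi_a), (lo_b, _) in zip(edges, edges[1:]):
            if hi_a != lo_b:
                raise ValueError("heatmap bins must be contiguous and non-overlapping")
        if not (lo0 == 0.5 and edges[-1][1] == 1.0):
            raise ValueError("heatmap bins must cover (0.5, 1.0]")


def _paint(pm: ProbabilityMatrix, painter) -> np.ndarray:
    # expand per-cell RGBA to the cells' pixel footprints
    s = pm.grid_spec.patch_size
    cell_rgba = painter(pm.grid)  # (r, c, 4) uint8
    return np.repeat(np.repeat(cell_rgba, s, axis=0), s, axis=1)


def binary_map(pm: ProbabilityMatrix, scheme: ColorScheme | None = None) -> np.ndarray:
    """RGBA overlay: solid ``binary_color`` on every cell with p > threshold."""
    scheme = scheme or ColorScheme()

    def painter(grid: np.ndarray) -> np.ndarray:
        cell = np.zeros(grid.shape + (4,), dtype=np.uint8)
        hot = grid > scheme.binary_threshold
        cell[hot, :3] = scheme.binary_color
        cell[hot, 3] = int(round(scheme.binary_opacity * 255))
        return cell

    return _paint(pm, painter)


def probability_heatmap(pm: ProbabilityMatrix, scheme: ColorScheme | None = None) -> np.ndarray:
    """RGBA overlay coloring each cell by its probability bin."""
    scheme = scheme or ColorScheme()
    if pm.grid.size and (pm.grid.min() < 0 or pm.grid.max() > 1):
        raise ValueError("probabilities outside [0,1]")

    def painter(grid: np.ndarray) -> np.ndarray:
        cell = np.zeros(grid.shape + (4,), dtype=np.uint8)
        for lo, hi, rgb, opacity in scheme.bins:
            inside = (grid > lo) & (grid <= hi)
            cell[inside, :3] = rgb
            cell[inside, 3] = int(round(opacity * 255))
        return cell

    return _paint(pm, painter)


def heatmap_bin_counts(pm: ProbabilityMatrix, scheme: ColorScheme | None = None) -> dict:
    """Number of cells per heatmap bin (keys ``"(lo, hi]"``) plus ``"transparent"``."""
    scheme = scheme or ColorScheme()
    counts = {}
    assigned = np.zeros(pm.grid.shape, dtype=bool)
    for lo, hi, _, _ in scheme.bins:
        inside = (pm.grid > lo) & (pm.grid <= hi)
        counts[f"({lo}, {hi}]"] = int(inside.sum())
        assigned |= inside
    counts["transparent"] = int((~assigned).sum())
    return counts


def compose_overlay(slide_image: np.ndarray, overlay: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Alpha-composite an RGBA overlay onto the slide (cropped to the overlay).

    ``alpha`` globally scales the overlay's own per-pixel opacity; 0 returns
    the slide region unchanged.
    """
    slide_image = np.asarray(slide_image)
    oh, ow = overlay.shape[:2]
    if slide_image.shape[0] < oh or slide_image.shape[1] < ow:
        raise ValueError(
            f"slide {slide_image.shape[:2]} smaller than overlay {(oh, ow)}"
        )
    base = slide_image[:oh, :ow, :3].astype(float)
    a = overlay[..., 3:4].astype(float) / 255.0 * float(alpha)
    blended = base * (1.0 - a) + overlay[..., :3].astype(float) * a
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)


def render_report(
    slide,
    ground_truth_mask: np.ndarray,
    pm: ProbabilityMatrix,
    path,
    scheme: ColorScheme | None = None,
    overlay_alpha: float = 1.0,
) -> Path:
    """Four-panel review figure: slide | ground truth | binary map | heatmap.

    Panels share the tiled-region dimensions; the figure is written as PNG.
    """
    scheme = scheme or ColorScheme()
    image = slide.image if hasattr(slide, "image") else np.asarray(slide)
    s = pm.grid_spec.patch_size
    r, c = pm.grid.shape
    region = image[: r * s, : c * s]
    gt = np.asarray(ground_truth_mask)[: r * s, : c * s]
    panels = [
        (region, "H&E slide"),
        (gt, "ground truth"),
        (compose_overlay(region, binary_map(pm, scheme), overlay_alpha), "binary map"),
        (compose_overlay(region, probability_heatmap(pm, scheme), overlay_alpha), "prediction map"),
    ]
    fig, axes = plt.subplots(1, 4, figsize=(16, 4.4))
    for ax, (panel, title) in zip(axes, panels):
        if panel.ndim == 2:
            ax.imshow(panel, cmap="gray", interpolation="nearest")
        else:
            ax.imshow(panel, interpolation="nearest")
        ax.set_title(title)
        ax.axis("off")
    fig.suptitle(pm.slide_id or getattr(slide, "slide_id", ""))
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
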