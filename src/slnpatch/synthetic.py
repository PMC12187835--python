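"""Synthetic whole-slide rasters with known ground truth.

Real sentinel-lymph-node slides are privacy-restricted, so the pipeline is
exercised on generated slides that reproduce the statistical features the
downstream method depends on:

* two staining domains differing in saturation and contrast (hospital scanner
  vs. external public dataset);
* tumor burdens spanning four orders of magnitude (0.03% to ~30% of slide
  pixels), realized exactly at pixel resolution;
* tumor-associated fibrosis forming a band around lesions, so mixed patches
  near the 20% tumor-content labeling threshold actually occur;
* white background inside the slide bounding box (negative patches therefore
  include pure-white tiles, inflating the 255 intensity bin).

Lesions are rendered as irregular blobs: isotropic Gaussian bumps placed at
patch-grid-aligned centers plus a smooth noise field, thresholded by exact
top-k selection so the realized tumor pixel count equals
``round(tumor_fraction * H * W)``. Grid alignment (configurable) keeps even
the smallest lesion resolvable at patch scale instead of being split across
four neighbouring tiles. Tumor tissue is rendered in a hue band disjoint from
normal tissue, so a simple color rule — and a small CNN — can separate the
classes; nucleus-level morphology is deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage
from skimage import measure

from .annotations import BinaryMask, PolygonAnnotation, write_labelme, write_mask

__all__ = [
    "DomainStyle",
    "SlideSpec",
    "SyntheticSlide",
    "GeometryError",
    "LOCAL_STYLE",
    "EXTERNAL_STYLE",
    "COHORT_TUMOR_FRACTIONS",
    "generate_slide",
    "generate_cohort",
    "export_slide",
]

#: Tumor pixel fractions of the five positive whole-slide testing cases
#: (0.03%, 0.35%, 5.11%, 18.64% and 29.41% of slide pixels).
COHORT_TUMOR_FRACTIONS: tuple[float, ...] = (0.0003, 0.0035, 0.0511, 0.1864, 0.2941)


class GeometryError(ValueError):
    """Requested pixel fractions are unreachable at the given slide size."""


@dataclass(frozen=True)
class DomainStyle:
    """Rendering style of one slide source (scanner/stain domain).

    Hue ranges are in degrees [0, 360); saturations are fractions in [0, 1].
    ``contrast_gain`` scales intensities around mid-gray (128) after
    colorization; ``texture_noise_sd`` is the per-pixel Gaussian texture on
    the 0-255 scale. Background pixels are set to ``background_rgb`` exactly.
    """

    name: str
    tissue_hue_range: tuple[float, float] = (300.0, 330.0)
    tissue_saturation_range: tuple[float, float] = (0.30, 0.45)
    tumor_hue_range: tuple[float, float] = (230.0, 260.0)
    tumor_saturation_range: tuple[float, float] = (0.55, 0.75)
    contrast_gain: float = 1.0
    texture_noise_sd: float = 4.0
    background_rgb: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        for rng_ in (self.tissue_saturation_range, self.tumor_saturation_range):
            lo, hi = rng_
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"saturation range must be within [0,1], got {rng_}")
        if self.contrast_gain <= 0:
            raise ValueError("contrast_gain must be positive")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be non-negative")


#: Hospital-scanner-like style: muted eosin pink, neutral contrast.
LOCAL_STYLE = DomainStyle(name="local")

#: External-dataset-like style: washed out relative to the local scanner —
#: lower contrast, lower saturation, slightly shifted hues. The magnitude of
#: the gap is a free parameter of the generator; the default is chosen so
#: that a model trained on one source measurably degrades on the other,
#: which is the regime the domain-shift experiment probes.
EXTERNAL_STYLE = DomainStyle(
    name="external",
    tissue_hue_range=(320.0, 350.0),
    tissue_saturation_range=(0.50, 0.65),
    tumor_hue_range=(255.0, 285.0),
    tumor_saturation_range=(0.40, 0.55),
    contrast_gain=0.6,
    texture_noise_sd=6.0,
)


@dataclass(frozen=True)
class SlideSpec:
    """Generation parameters of one synthetic slide.

    Fractions are of *total slide pixels*; tumor and fibrosis are disjoint
    subsets of tissue, so ``tumor + fibrosis <= tissue <= 1`` is required.
    """

    width_px: int
    height_px: int
    domain: DomainStyle
    seed: int
    resolution_um_per_px: float = 0.5
    tissue_fraction: float = 0.9
    tumor_fraction: float = 0.0
    fibrosis_fraction: float = 0.0
    lesion_area_px: int = 8100
    align_lesions_px: int | None = 90
    slide_id: str = ""

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        for name in ("tissue_fraction", "tumor_fraction", "fibrosis_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.tumor_fraction + self.fibrosis_fraction > self.tissue_fraction:
            raise ValueError(
                "tumor_fraction + fibrosis_fraction must not exceed tissue_fraction"
            )
        if self.lesion_area_px <= 0:
            raise ValueError("lesion_area_px must be positive")


@dataclass
class SyntheticSlide:
    """Rendered slide raster plus its pixel-exact ground-truth masks."""

    image: np.ndarray
    tumor_mask: np.ndarray
    fibrosis_mask: np.ndarray
    tissue_mask: np.ndarray
    spec: SlideSpec

    @property
    def slide_id(self) -> str:
        return self.spec.slide_id or f"{self.spec.domain.name}-s{self.spec.seed}"

    def measured_tumor_fraction(self) -> float:
        return float(self.tumor_mask.mean())


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian-correlated field.

    For large correlation lengths the field is generated on a coarse lattice
    and bilinearly upsampled; the result is deterministic in (rng state,
    shape, sigma).
    """
    h, w = shape
    ds = max(1, int(sigma // 4))
    if ds > 1:
        sh, sw = -(-h // ds) + 1, -(-w // ds) + 1
        small = ndimage.gaussian_filter(
            rng.standard_normal((sh, sw)), sigma=sigma / ds, mode="reflect"
        )
        f = ndimage.zoom(small, (h / sh, w / sw), order=1)[:h, :w]
    else:
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _top_k_mask(field: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Mask of the k candidate pixels with the highest field values."""
    out = np.zeros(field.shape, dtype=np.uint8)
    if k == 0:
        return out
    idx = np.flatnonzero(candidates)
    if k > idx.size:
        raise GeometryError(f"need {k} pixels but only {idx.size} candidates available")
    vals = field.ravel()[idx]
    sel = idx[np.argpartition(-vals, k - 1)[:k]]
    out.ravel()[sel] = 1
    return out


def _lesion_field(
    rng: np.random.Generator, spec: SlideSpec, tissue: np.ndarray, k: int
) -> np.ndarray:
    """Sum of Gaussian bumps at lesion centers plus a smooth irregularity field."""
    h, w = spec.height_px, spec.width_px
    n_lesions = max(1, int(round(k / spec.lesion_area_px)))
    step = spec.align_lesions_px
    if step:
        rows = np.arange(step // 2, h, step)
        cols = np.arange(step // 2, w, step)
        cand_r, cand_c = np.meshgrid(rows, cols, indexing="ij")
        cand_r, cand_c = cand_r.ravel(), cand_c.ravel()
        on_tissue = tissue[cand_r, cand_c].astype(bool)
        if on_tissue.any():
            cand_r, cand_c = cand_r[on_tissue], cand_c[on_tissue]
    else:
        idx = np.flatnonzero(tissue)
        if idx.size == 0:
            raise GeometryError("no tissue pixels available for lesion placement")
        pick = rng.choice(idx, size=min(n_lesions, idx.size), replace=False)
        cand_r, cand_c = np.unravel_index(pick, tissue.shape)
    if cand_r.size == 0:
        raise GeometryError("no candidate lesion centers on tissue")
    n_lesions = min(n_lesions, cand_r.size)
    order = rng.permutation(cand_r.size)[:n_lesions]
    centers = np.stack([cand_r[order], cand_c[order]], axis=1)

    field = 0.08 * _smooth_noise(rng, (h, w), sigma=12.0)
    r_target = np.sqrt((k / n_lesions) / np.pi)
    yy = np.arange(h)
    xx = np.arange(w)
    for cr, cc in centers:
        sigma = r_target * rng.uniform(0.55, 0.75)
        win = int(np.ceil(4 * sigma)) + 1
        r0, r1 = max(0, cr - win), min(h, cr + win + 1)
        c0, c1 = max(0, cc - win), min(w, cc + win + 1)
        dy = (yy[r0:r1, None] - cr) ** 2
        dx = (xx[None, c0:c1] - cc) ** 2
        field[r0:r1, c0:c1] += np.exp(-(dy + dx) / (2 * sigma**2))
    return field


def _hsv_to_rgb(h_deg: np.ndarray, s: np.ndarray, v: np.ndarray):
    """Vectorized HSV -> RGB (hue in degrees, s/v in [0,1]); returns r, g, b."""
    h = (h_deg % 360.0) / 60.0
    i = np.floor(h).astype(np.int8) % 6
    f = (h - np.floor(h)).astype(np.float32)
    p = v * (1.0 - s)
    q = v * (1.0 - f * s)
    t = v * (1.0 - (1.0 - f) * s)
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return r, g, b


def _render(
    rng: np.random.Generator,
    spec: SlideSpec,
    tissue: np.ndarray,
    tumor: np.ndarray,
    fibrosis: np.ndarray,
) -> np.ndarray:
    style = spec.domain
    h, w = spec.height_px, spec.width_px

    hue = np.zeros((h, w))
    sat = np.zeros((h, w))
    val = np.ones((h, w))

    jitter = _smooth_noise(rng, (h, w), sigma=30.0)

    def _band(rng_deg: tuple[float, float]) -> tuple[float, float]:
        lo, hi = rng_deg
        c = rng.uniform(lo, hi)
        return c, (hi - lo) / 4.0

    t_hue, t_hue_sd = _band(style.tissue_hue_range)
    u_hue, u_hue_sd = _band(style.tumor_hue_range)
    t_sat = rng.uniform(*style.tissue_saturation_range)
    u_sat = rng.uniform(*style.tumor_saturation_range)

    plain = tissue.astype(bool) & ~tumor.astype(bool) & ~fibrosis.astype(bool)
    fib = fibrosis.astype(bool)
    tum = tumor.astype(bool)

    hue[plain] = (t_hue + t_hue_sd * jitter[plain]) % 360.0
    sat[plain] = np.clip(t_sat + 0.05 * jitter[plain], 0.0, 1.0)
    val[plain] = np.clip(0.82 + 0.06 * jitter[plain], 0.0, 1.0)
    # fibrosis: same hue family as tissue but paler and less saturated
    hue[fib] = (t_hue + 10.0 + t_hue_sd * jitter[fib]) % 360.0
    sat[fib] = np.clip(0.55 * t_sat + 0.04 * jitter[fib], 0.0, 1.0)
    val[fib] = np.clip(0.90 + 0.04 * jitter[fib], 0.0, 1.0)
    # tumor: distinct hue band, denser (darker) and more saturated
    hue[tum] = (u_hue + u_hue_sd * jitter[tum]) % 360.0
    sat[tum] = np.clip(u_sat + 0.05 * jitter[tum], 0.0, 1.0)
    val[tum] = np.clip(0.55 + 0.06 * jitter[tum], 0.0, 1.0)

    any_tissue = tissue.astype(bool)
    img = np.stack(
        _hsv_to_rgb(hue.astype(np.float32), sat.astype(np.float32), val.astype(np.float32)),
        axis=-1,
    )
    img *= np.float32(255.0)
    img = 128.0 + style.contrast_gain * (img - 128.0)
    if style.texture_noise_sd > 0:
        img += style.texture_noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    img[~any_tissue] = np.asarray(style.background_rgb, dtype=np.uint8)
    return img


def generate_slide(spec: SlideSpec) -> SyntheticSlide:
    """Generate one synthetic slide.

    Deterministic in ``spec`` (including its seed). The realized tumor pixel
    count equals ``round(spec.tumor_fraction * H * W)`` exactly; the same
    holds for tissue and fibrosis. Raises :class:`GeometryError` when the
    requested fractions cannot be realized.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    n_px = h * w

    k_tissue = int(round(spec.tissue_fraction * n_px))
    k_tumor = int(round(spec.tumor_fraction * n_px))
    k_fib = int(round(spec.fibrosis_fraction * n_px))
    if k_tumor + k_fib > k_tissue:
        raise GeometryError(
            f"tumor ({k_tumor}) + fibrosis ({k_fib}) pixels exceed tissue ({k_tissue})"
        )

    tissue_field = _smooth_noise(rng, (h, w), sigma=max(8.0, min(h, w) / 8.0))
    tissue = _top_k_mask(tissue_field, np.ones((h, w), dtype=bool), k_tissue)

    if k_tumor > 0:
        lesion = _lesion_field(rng, spec, tissue, k_tumor)
        tumor = _top_k_mask(lesion, tissue.astype(bool), k_tumor)
        if k_fib > 0:
            fibrosis = _top_k_mask(lesion, tissue.astype(bool) & ~tumor.astype(bool), k_fib)
        else:
            fibrosis = np.zeros((h, w), dtype=np.uint8)
    else:
        if k_fib > 0:
            raise GeometryError("fibrosis is tumor-associated; cannot be placed without tumor")
        tumor = np.zeros((h, w), dtype=np.uint8)
        fibrosis = np.zeros((h, w), dtype=np.uint8)

    image = _render(rng, spec, tissue, tumor, fibrosis)
    return SyntheticSlide(
        image=image, tumor_mask=tumor, fibrosis_mask=fibrosis, tissue_mask=tissue, spec=spec
    )


def generate_cohort(
    fractions,
    styles,
    base_spec: SlideSpec,
    seed: int,
    fibrosis_ratio: float = 0.4,
) -> list[SyntheticSlide]:
    """One slide per (tumor fraction, style) pair, with spawned per-slide seeds.

    Fibrosis scales with tumor burden (``fibrosis = fibrosis_ratio * tumor``),
    reflecting that the stromal reaction surrounds lesions; negative slides
    (fraction 0) carry neither class.
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("fractions must be non-empty")
    for f in fractions:
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"tumor fraction {f} outside [0,1]")
    children = np.random.SeedSequence(seed).spawn(len(fractions) * len(list(styles)))
    slides = []
    i = 0
    for style in styles:
        for f in fractions:
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            spec = dataclasses.replace(
                base_spec,
                domain=style,
                tumor_fraction=f,
                fibrosis_fraction=f * fibrosis_ratio,
                seed=child_seed,
                slide_id=f"{style.name}-s{seed}-f{f:g}-{i:03d}",
            )
            slides.append(generate_slide(spec))
    return slides


def generate_separable_slide(
    n_rows: int,
    n_cols: int,
    style: DomainStyle,
    seed: int,
    positive_fraction: float = 0.5,
    patch_size: int = 90,
    slide_id: str = "",
) -> SyntheticSlide:
    """Calibration slide whose patch cells are wholly tumor or wholly normal.

    Each ``patch_size`` cell of an ``n_rows x n_cols`` grid is rendered
    entirely in the tumor hue band or entirely as normal tissue, so the patch
    classes are linearly separable in mean color (tumor content is exactly 1
    or 0 per cell). This is the capability fixture for the training harness;
    it deliberately removes the mixed-content difficulty of realistic slides.
    """
    rng = np.random.default_rng(seed)
    h, w = n_rows * patch_size, n_cols * patch_size
    n_pos = int(round(positive_fraction * n_rows * n_cols))
    flat = np.zeros(n_rows * n_cols, dtype=np.uint8)
    flat[rng.choice(n_rows * n_cols, size=n_pos, replace=False)] = 1
    cells = flat.reshape(n_rows, n_cols)
    tumor = np.kron(cells, np.ones((patch_size, patch_size), dtype=np.uint8))
    tissue = np.ones((h, w), dtype=np.uint8)
    fibrosis = np.zeros((h, w), dtype=np.uint8)
    spec = SlideSpec(
        width_px=w,
        height_px=h,
        domain=style,
        seed=seed,
        tissue_fraction=1.0,
        tumor_fraction=float(tumor.mean()),
        slide_id=slide_id or f"separable-{style.name}-s{seed}",
        align_lesions_px=patch_size,
    )
    image = _render(rng, spec, tissue, tumor, fibrosis)
    return SyntheticSlide(
        image=image, tumor_mask=tumor, fibrosis_mask=fibrosis, tissue_mask=tissue, spec=spec
    )


def _mask_to_polygons(mask: np.ndarray, label: str, slide_id: str) -> list[PolygonAnnotation]:
    if not mask.any():
        return []
    padded = np.pad(mask.astype(float), 1)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        pts = [(float(c - 0.5), float(r - 0.5)) for r, c in contour]
        if len(pts) >= 3:
            polys.append(PolygonAnnotation(label=label, vertices=tuple(pts), slide_id=slide_id))
    return polys


def export_slide(slide: SyntheticSlide, directory, image_format: str = "tiff") -> dict[str, Path]:
    """Write the slide raster, its mask PNGs, and a labelme-style JSON.

    The JSON holds the traced contours of the tumor and fibrosis masks;
    re-rasterizing them reproduces each mask up to contour-tracing tolerance.
    Returns a mapping from artifact name to path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = slide.slide_id
    paths: dict[str, Path] = {}
    try:
        if image_format == "tiff":
            paths["image"] = directory / f"{stem}.tif"
            tifffile.imwrite(paths["image"], slide.image)
        elif image_format == "png":
            paths["image"] = directory / f"{stem}.png"
            Image.fromarray(slide.image).save(paths["image"], format="PNG")
        else:
            raise ValueError(f"unsupported image_format {image_format!r}")
        for name, mask in (
            ("tumor_mask", slide.tumor_mask),
            ("fibrosis_mask", slide.fibrosis_mask),
            ("tissue_mask", slide.tissue_mask),
        ):
            paths[name] = write_mask(
                BinaryMask(grid=mask, slide_id=stem), directory / f"{stem}_{name}.png"
            )
        annotations = _mask_to_polygons(slide.tumor_mask, "tumor", stem) + _mask_to_polygons(
            slide.fibrosis_mask, "fibrosis", stem
        )
        paths["annotations"] = write_labelme(
            annotations,
            shape=slide.image.shape[:2],
            path=directory / f"{stem}.json",
            image_path=paths["image"].name,
        )
    except OSError as exc:
        raise OSError(f"failed exporting slide {stem!r} to {directory}: {exc}") from exc
    return paths
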