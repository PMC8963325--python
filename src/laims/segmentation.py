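"""Rule-based pixel classification of LA-ICP-MS images of prostate tissue.

The ³¹P channel drives the segmentation: gland epithelium is phosphorus-rich,
stroma phosphorus-poor, and glandular lumina are tissue-free cavities that
appear as low-P holes fully surrounded by high-P epithelium.  The chain is

1. tissue vs non-tissue: contrast-stretch the ³¹P map by clipping to the
   0.25–0.50 quantile interval, rescale to 8-bit, Gaussian-blur (5×5),
   Otsu-threshold, find connected foreground components; the component with
   the largest filled area is the tissue;
2. lumina: holes inside the tissue whose enclosed median ³¹P lies below the
   0.45 quantile of the full ³¹P data and whose surrounding ring (5×5
   dilation minus the hole) has a median above the 0.55 quantile;
3. gland vs stroma: clip on-tissue ³¹P to 0.05–0.95 quantiles, 8-bit, blur,
   Otsu, morphological opening (2×2, 1 iteration), reject components smaller
   than 0.05% of the image; pixels on/inside surviving components with raw
   ³¹P above the on-tissue median are gland, every other on-tissue non-lumen
   pixel is stroma;
4. zinc hotspots (prostatic calculi): luminal pixels whose ⁶⁴Zn value — after
   clipping to the 0.01–0.99 quantile range — exceeds
   Q0.75 + 1.5·IQR of the clipped data.

All quantiles use linear interpolation between order statistics so every
threshold is reproducible.  Foreground components use 8-connectivity, holes
the complementary 4-connectivity; equal largest areas break ties by scan
order.  The Gaussian blur derives sigma from the kernel size
(0.3·((k−1)/2 − 1) + 0.8) with reflective borders.

:func:`segment_section` applies the whole chain and crops to the analysis
rectangle (default 100×150 px = 1500×2250 µm at 15 µm/px).  Tissue and lumen
detection run on the full grid — the 0.25–0.50 clip needs a substantial
off-tissue fraction to stretch the tissue/background contrast — while the
gland/stroma and hotspot statistics are computed over the crop, whose
mostly-on-tissue composition places stroma near Q0.25 and gland near Q0.75
as the hotspot rule assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raw_io import ElementMap

OFF_TISSUE, STROMA, GLAND, LUMEN = 0, 1, 2, 3
CLASS_NAMES = {OFF_TISSUE: "off_tissue", STROMA: "stroma",
               GLAND: "gland", LUMEN: "lumen"}

_EIGHT = np.ones((3, 3), dtype=bool)   # foreground connectivity
_FOUR = ndimage.generate_binary_structure(2, 1)  # hole connectivity


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentationParams:
    """All tunable thresholds of the rule chain (defaults as used here)."""

    tissue_clip: tuple[float, float] = (0.25, 0.50)
    blur_kernel_px: int = 5
    lumen_low_q: float = 0.45
    lumen_high_q: float = 0.55
    ring_dilate_kernel_px: int = 5
    gs_clip: tuple[float, float] = (0.05, 0.95)
    open_kernel_px: int = 2
    open_iterations: int = 1
    min_contour_frac: float = 0.0005
    zn_clip: tuple[float, float] = (0.01, 0.99)
    zn_hot_q: float = 0.75
    zn_hot_iqr_mult: float = 1.5
    crop_shape_px: tuple[int, int] = (100, 150)

    def validate(self) -> None:
        for lo, hi in (self.tissue_clip, self.gs_clip, self.zn_clip):
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"quantile interval ({lo}, {hi}) invalid")
        if not 0 < self.lumen_low_q < self.lumen_high_q < 1:
            raise ValueError("lumen quantiles must satisfy 0 < low < high < 1")
        for k in (self.blur_kernel_px, self.ring_dilate_kernel_px,
                  self.open_kernel_px):
            if k < 1:
                raise ValueError("kernel sizes must be >= 1 px")
        if not 0 < self.min_contour_frac < 1:
            raise ValueError("min_contour_frac must lie in (0, 1)")


@dataclass
class SegmentationResult:
    """Per-pixel classes over the analysis crop plus the hotspot flag."""

    labels: np.ndarray          # int grid in {OFF_TISSUE, STROMA, GLAND, LUMEN}
    hotspot: np.ndarray         # bool grid; hotspot implies LUMEN
    crop_origin: tuple[int, int]
    params: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if self.labels.shape != self.hotspot.shape:
            raise ValueError("labels and hotspot grids must share shape")
        if np.any(self.hotspot & (self.labels != LUMEN)):
            raise ValueError("hotspot pixels must be luminal")

    def class_mask(self, cls: int) -> np.ndarray:
        return self.labels == cls

    def class_counts(self) -> dict[str, int]:
        out = {name: int(np.sum(self.labels == cls))
               for cls, name in CLASS_NAMES.items()}
        out["hotspot"] = int(self.hotspot.sum())
        return out


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def clip_quantiles(grid: np.ndarray, q_low: float, q_high: float) -> np.ndarray:
    """Clip values to the [q_low, q_high] quantile interval (linear
    interpolation over all finite values)."""
    if not 0 <= q_low < q_high <= 1:
        raise ValueError("need 0 <= q_low < q_high <= 1")
    grid = np.asarray(grid, dtype=float)
    finite = grid[np.isfinite(grid)]
    if finite.size == 0:
        raise SegmentationError("cannot clip an all-NaN grid")
    lo, hi = np.quantile(finite, [q_low, q_high])
    return np.clip(grid, lo, hi)


def to_grayscale_8bit(grid: np.ndarray) -> np.ndarray:
    """Affine min–max rescale to [0, 255], rounded half-up; a constant grid
    maps to all zeros."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(np.min(grid)), float(np.max(grid))
    if hi == lo:
        return np.zeros(grid.shape, dtype=np.uint8)
    scaled = (grid - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit image.

    Returns the threshold t maximizing the between-class variance of the
    split (<= t) vs (> t); foreground is strictly above t.  Ties take the
    lowest t.  A constant image has no valid split and raises.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("otsu_threshold expects 8-bit values")
        img = img.astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise SegmentationError("constant image: Otsu threshold undefined")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)                     # pixels <= t
    m0 = np.cumsum(hist * levels)            # intensity mass <= t
    total = m0[-1]
    w1 = n - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, m0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(valid, (total - m0) / np.maximum(w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(between))           # argmax takes the lowest tie


def _cv_like_sigma(kernel_px: int) -> float:
    # the customary kernel-size-to-sigma rule for small Gaussian kernels
    return 0.3 * ((kernel_px - 1) * 0.5 - 1.0) + 0.8


def gaussian_blur(grid: np.ndarray, kernel_px: int) -> np.ndarray:
    """Gaussian blur with kernel-size-derived sigma, reflective borders,
    truncated to the kernel footprint."""
    return ndimage.gaussian_filter(np.asarray(grid, dtype=float),
                                   sigma=_cv_like_sigma(kernel_px),
                                   radius=kernel_px // 2, mode="reflect")


def _components(binary: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(binary, structure=_EIGHT)


# ---------------------------------------------------------------------------
# tissue / lumen
# ---------------------------------------------------------------------------

@dataclass
class TissueContours:
    """Tissue mask (filled largest contour) and its inner contours (holes)."""

    tissue_mask: np.ndarray
    hole_labels: np.ndarray     # int grid; 0 outside holes
    n_holes: int


def find_tissue(p_map: ElementMap, params: SegmentationParams | None = None
                ) -> TissueContours:
    """Locate the tissue section on the ³¹P map.

    Pipeline: quantile clip → 8-bit → Gaussian blur → Otsu → connected
    components; pixels on or inside the largest-area (filled) component are
    tissue.  The holes of that component are returned as inner contours for
    the lumen rule.
    """
    params = params or SegmentationParams()
    params.validate()
    work = clip_quantiles(p_map.grid, *params.tissue_clip)
    img = to_grayscale_8bit(work)
    blurred = np.floor(gaussian_blur(img, params.blur_kernel_px) + 0.5)
    blurred = blurred.clip(0, 255).astype(np.uint8)
    try:
        thr = otsu_threshold(blurred)
    except SegmentationError as err:
        raise SegmentationError(f"no tissue contour found: {err}") from err
    fg = blurred > thr
    comp, n = _components(fg)
    if n == 0:
        raise SegmentationError("no tissue contour found: empty foreground")
    best, best_area = 0, -1
    for lab in range(1, n + 1):
        filled = ndimage.binary_fill_holes(comp == lab)
        area = int(filled.sum())
        if area > best_area:     # strict > keeps the first (scan-order) tie
            best, best_area = lab, area
    tissue = ndimage.binary_fill_holes(comp == best)
    holes = tissue & ~(comp == best)
    hole_labels, n_holes = ndimage.label(holes, structure=_FOUR)
    return TissueContours(tissue_mask=tissue, hole_labels=hole_labels,
                          n_holes=int(n_holes))


def find_lumina(p_map: ElementMap, contours: TissueContours,
                params: SegmentationParams | None = None) -> np.ndarray:
    """Classify inner contours as glandular lumina.

    A hole is a lumen when its enclosed median ³¹P falls below the
    ``lumen_low_q`` quantile of the full ³¹P grid AND the median over its
    surrounding ring (dilation by the ring kernel minus the hole) exceeds the
    ``lumen_high_q`` quantile.
    """
    params = params or SegmentationParams()
    grid = p_map.grid
    q_low, q_high = np.quantile(grid[np.isfinite(grid)],
                                [params.lumen_low_q, params.lumen_high_q])
    k = params.ring_dilate_kernel_px
    ring_struct = np.ones((k, k), dtype=bool)
    lumen = np.zeros(grid.shape, dtype=bool)
    for lab in range(1, contours.n_holes + 1):
        hole = contours.hole_labels == lab
        if np.median(grid[hole]) >= q_low:
            continue
        ring = ndimage.binary_dilation(hole, structure=ring_struct) & ~hole
        if ring.any() and np.median(grid[ring]) > q_high:
            lumen |= hole
    return lumen


# ---------------------------------------------------------------------------
# gland / stroma
# ---------------------------------------------------------------------------

def segment_glands_stroma(p_map: ElementMap, tissue_mask: np.ndarray,
                          lumen_mask: np.ndarray,
                          params: SegmentationParams | None = None
                          ) -> np.ndarray:
    """Split on-tissue, non-lumen pixels into gland epithelium and stroma.

    Returns a label grid over the full input shape with OFF_TISSUE, STROMA,
    GLAND, LUMEN.  If the on-tissue ³¹P data admit no Otsu split (uniform
    tissue), no gland contours exist and everything non-lumen is stroma.
    """
    params = params or SegmentationParams()
    params.validate()
    grid = p_map.grid
    on_tissue = grid[tissue_mask]
    if on_tissue.size == 0:
        raise SegmentationError("empty tissue mask")

    labels = np.full(grid.shape, OFF_TISSUE, dtype=np.int8)
    labels[tissue_mask] = STROMA
    labels[lumen_mask & tissue_mask] = LUMEN

    lo, hi = np.quantile(on_tissue, params.gs_clip)
    work = np.clip(grid, lo, hi)
    work[~tissue_mask] = lo
    img = to_grayscale_8bit(work)
    blurred = np.floor(gaussian_blur(img, params.blur_kernel_px) + 0.5)
    blurred = blurred.clip(0, 255).astype(np.uint8)
    try:
        thr = otsu_threshold(blurred)
    except SegmentationError:
        return labels               # uniform tissue: no gland contours
    fg = (blurred > thr) & tissue_mask
    fg = ndimage.binary_opening(fg, structure=np.ones(
        (params.open_kernel_px,) * 2, dtype=bool),
        iterations=params.open_iterations)
    comp, n = _components(fg)
    min_area = params.min_contour_frac * grid.size
    region = np.zeros(grid.shape, dtype=bool)
    for lab in range(1, n + 1):
        filled = ndimage.binary_fill_holes(comp == lab)
        if filled.sum() >= min_area:
            region |= filled
    median_p = float(np.median(on_tissue))
    gland = region & tissue_mask & ~lumen_mask & (grid > median_p)
    labels[gland] = GLAND
    return labels


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

def hotspot_threshold(zn_grid: np.ndarray,
                      params: SegmentationParams | None = None) -> float:
    """High-⁶⁴Zn cutoff: Q0.75 + 1.5·IQR of the 0.01–0.99-clipped data."""
    params = params or SegmentationParams()
    clipped = clip_quantiles(zn_grid, *params.zn_clip)
    q1, q3 = np.quantile(clipped, [1.0 - params.zn_hot_q, params.zn_hot_q])
    return float(q3 + params.zn_hot_iqr_mult * (q3 - q1))


def classify_hotspots(zn_map: ElementMap, lumen_mask: np.ndarray,
                      params: SegmentationParams | None = None) -> np.ndarray:
    """Flag luminal pixels with high ⁶⁴Zn ("prostate stones").

    A pixel is a hotspot when it is luminal AND its clipped ⁶⁴Zn value is
    strictly above the Q0.75 + 1.5·IQR threshold.  High-zinc pixels outside
    lumina are never flagged.
    """
    params = params or SegmentationParams()
    clipped = clip_quantiles(zn_map.grid, *params.zn_clip)
    return lumen_mask & (clipped > hotspot_threshold(zn_map.grid, params))


# ---------------------------------------------------------------------------
# crop and full chain
# ---------------------------------------------------------------------------

def crop_to_roi(grid: np.ndarray, crop_shape: tuple[int, int],
                crop_origin: tuple[int, int]) -> np.ndarray:
    """Crop a grid to the analysis rectangle; out-of-bounds crops raise."""
    r0, c0 = crop_origin
    h, w = crop_shape
    if r0 < 0 or c0 < 0 or r0 + h > grid.shape[0] or c0 + w > grid.shape[1]:
        raise SegmentationError(
            f"crop {crop_shape} at {crop_origin} exceeds grid {grid.shape}")
    return grid[r0:r0 + h, c0:c0 + w]


def auto_crop_origin(tissue_mask: np.ndarray,
                     crop_shape: tuple[int, int]) -> tuple[int, int]:
    """Origin that centres the crop on the tissue bounding box, clamped to
    the grid."""
    if not tissue_mask.any():
        raise SegmentationError("cannot centre a crop on an empty tissue mask")
    h, w = crop_shape
    if h > tissue_mask.shape[0] or w > tissue_mask.shape[1]:
        raise SegmentationError("crop larger than the grid")
    rows = np.flatnonzero(tissue_mask.any(axis=1))
    cols = np.flatnonzero(tissue_mask.any(axis=0))
    rc = (rows[0] + rows[-1] + 1) / 2.0
    cc = (cols[0] + cols[-1] + 1) / 2.0
    r0 = int(round(rc - h / 2.0))
    c0 = int(round(cc - w / 2.0))
    r0 = min(max(r0, 0), tissue_mask.shape[0] - h)
    c0 = min(max(c0, 0), tissue_mask.shape[1] - w)
    return r0, c0


def segment_section(p_map: ElementMap, zn_map: ElementMap,
                    params: SegmentationParams | None = None,
                    crop_origin: tuple[int, int] | None = None
                    ) -> SegmentationResult:
    """Full rule chain: tissue → lumina → crop → gland/stroma → hotspots.

    Tissue and lumen detection use the full grid; gland/stroma and hotspot
    statistics use the crop (see module docstring).  ``crop_origin``
    overrides the automatic tissue-centred placement.
    """
    params = params or SegmentationParams()
    params.validate()
    if p_map.shape != zn_map.shape:
        raise SegmentationError("P and Zn maps must share shape")
    contours = find_tissue(p_map, params)
    lumen_full = find_lumina(p_map, contours, params)

    origin = crop_origin if crop_origin is not None else \
        auto_crop_origin(contours.tissue_mask, params.crop_shape_px)
    shape = params.crop_shape_px
    p_crop = p_map.with_grid(crop_to_roi(p_map.grid, shape, origin))
    zn_crop = zn_map.with_grid(crop_to_roi(zn_map.grid, shape, origin))
    tissue_crop = crop_to_roi(contours.tissue_mask, shape, origin)
    lumen_crop = crop_to_roi(lumen_full, shape, origin)

    labels = segment_glands_stroma(p_crop, tissue_crop, lumen_crop, params)
    hotspot = classify_hotspots(zn_crop, labels == LUMEN, params)
    return SegmentationResult(labels=labels, hotspot=hotspot,
                              crop_origin=tuple(origin), params=params)
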