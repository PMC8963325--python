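"""Whole-tissue and per-class statistics, recovery rates, and zinc budgets.

Recovery rate: an element's mean tissue value under a preparation protocol
as a percentage of the fresh-frozen (FF) reference, which is 100% by
definition.  Whole-tissue averages exclude pixels with low ³¹P intensity
(default offset 1100 cps) — those bear no relation to the tissue.
Intersectional variation is the RSD (sample sd, n−1) of whole-section
averages across adjacent serial sections.

Per-class box statistics follow the usual Tukey conventions: box from Q1 to
Q3 (linear-interpolation quantiles), whiskers 1.5·IQR from the box edges,
clamped to the observed data range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .raw_io import INTENSITY, ElementMap
from .segmentation import GLAND, LUMEN, STROMA, SegmentationResult

DEFAULT_P_OFFSET_CPS = 1100.0


@dataclass
class RegionStats:
    """Distribution summary of one pixel class."""

    label: str
    n_pixels: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    rsd_pct: float

    @classmethod
    def empty(cls, label: str) -> "RegionStats":
        nan = float("nan")
        return cls(label, 0, nan, nan, nan, nan, nan, nan, nan)

    @property
    def defined(self) -> bool:
        return self.n_pixels > 0


def tissue_average(emap: ElementMap, p_map: ElementMap,
                   p_offset_cps: float = DEFAULT_P_OFFSET_CPS) -> float:
    """Mean over pixels whose ³¹P intensity is at or above the offset."""
    if emap.shape != p_map.shape:
        raise ValueError("maps must be aligned")
    if p_map.value_kind != INTENSITY:
        raise ValueError("the ³¹P mask map must be intensity-kind (cps)")
    mask = p_map.grid >= p_offset_cps
    if not mask.any():
        raise ValueError(f"no pixel reaches the ³¹P offset of {p_offset_cps} cps")
    return float(np.mean(emap.grid[mask]))


def recovery_rates(protocol_means: dict[str, dict[str, float]],
                   reference: str = "FF") -> dict[str, dict[str, float]]:
    """Per-protocol, per-element recovery in % of the reference protocol."""
    if reference not in protocol_means:
        raise ValueError(f"reference protocol {reference!r} missing")
    ref = protocol_means[reference]
    out: dict[str, dict[str, float]] = {}
    for proto, means in protocol_means.items():
        out[proto] = {}
        for element, mean in means.items():
            if element not in ref:
                raise ValueError(f"{reference} lacks element {element!r}")
            if ref[element] == 0:
                raise ValueError(f"{reference} mean for {element!r} is zero")
            out[proto][element] = 100.0 * mean / ref[element]
    return out


def intersectional_rsd(replicate_means: list[float]) -> float:
    """RSD (%) of whole-section means across parallel serial sections."""
    if len(replicate_means) < 2:
        raise ValueError("need at least 2 replicate sections")
    means = np.asarray(replicate_means, dtype=float)
    m = float(np.mean(means))
    if m == 0:
        raise ValueError("zero mean: RSD undefined")
    return 100.0 * float(np.std(means, ddof=1)) / m


def _region_stats(label: str, values: np.ndarray) -> RegionStats:
    if values.size == 0:
        return RegionStats.empty(label)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    # fences clamped to the observed range; with IQR 0 they collapse to Q1=Q3
    wlo = float(inside.min()) if inside.size else float(q1)
    whi = float(inside.max()) if inside.size else float(q3)
    mean = float(np.mean(values))
    rsd = (100.0 * float(np.std(values, ddof=1)) / mean
           if values.size > 1 and mean != 0 else float("nan"))
    return RegionStats(label=label, n_pixels=int(values.size), mean=mean,
                       median=float(med), q1=float(q1), q3=float(q3),
                       whisker_low=wlo, whisker_high=whi, rsd_pct=rsd)


def class_stats(conc_map: ElementMap, seg: SegmentationResult
                ) -> dict[str, RegionStats]:
    """Box statistics of the map per segmentation class.

    Hotspot pixels are reported as their own class and removed from the
    lumen class; an empty class yields ``n_pixels == 0`` with NaN moments.
    """
    if conc_map.shape != seg.labels.shape:
        raise ValueError("map and segmentation must be aligned")
    grid = conc_map.grid
    masks = {
        "stroma": seg.labels == STROMA,
        "gland": seg.labels == GLAND,
        "lumen": (seg.labels == LUMEN) & ~seg.hotspot,
        "hotspot": seg.hotspot,
    }
    return {name: _region_stats(name, grid[mask])
            for name, mask in masks.items()}


def relative_distribution(conc_map: ElementMap, seg: SegmentationResult
                          ) -> dict[str, float]:
    """Fraction of total zinc held by gland, stroma, and hotspots
    (normalized to their combined total; fractions sum to 1)."""
    if conc_map.shape != seg.labels.shape:
        raise ValueError("map and segmentation must be aligned")
    grid = conc_map.grid
    totals = {
        "gland": float(grid[seg.labels == GLAND].sum()),
        "stroma": float(grid[seg.labels == STROMA].sum()),
        "hotspot": float(grid[seg.hotspot].sum()),
    }
    denom = sum(totals.values())
    if denom <= 0:
        raise ValueError("zero total zinc across gland/stroma/hotspot")
    return {k: v / denom for k, v in totals.items()}


def isotope_correlation(map_a: ElementMap, map_b: ElementMap,
                        mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two channels over masked pixels."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must be aligned")
    if mask is None:
        mask = np.ones(map_a.shape, dtype=bool)
    a, b = map_a.grid[mask], map_b.grid[mask]
    if a.size < 2:
        raise ValueError("need at least 2 masked pixels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def hotspot_roi_average(conc_map: ElementMap, roi_mask: np.ndarray) -> float:
    """Mean over a hotspot region of interest (mask-based ROI)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if conc_map.shape != roi_mask.shape:
        raise ValueError("map and ROI must be aligned")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    return float(np.mean(conc_map.grid[roi_mask]))


def hotspot_roi_averages(conc_map: ElementMap, roi_mask: np.ndarray
                         ) -> list[float]:
    """Per-ROI means over the connected components of a hotspot mask,
    enabling between-ROI RSDs."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    comp, n = ndimage.label(roi_mask, structure=np.ones((3, 3), dtype=bool))
    return [float(np.mean(conc_map.grid[comp == lab]))
            for lab in range(1, n + 1)]
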