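"""Synthetic prostate-tissue phantoms with known ground truth.

The generator emulates the morphology the segmentation rules were designed
for: a roughly elliptical tissue section at 15 µm/px in which high-phosphorus
gland epithelium forms rings (annuli) around phosphorus-poor glandular lumina,
embedded in low-phosphorus stroma.  Gland epithelium makes up ~40% of the
solid tissue, stroma ~60%.  A few lumina carry dense zinc deposits (corpora
amylacea / prostatic calculi, "hotspots": ~850 µg/g Zn, phosphorus-poor,
150–400 µm across).

Sample-preparation washout is modelled as a compartment-wise multiplicative
retention factor per element (fresh-frozen FF = 1.0 everywhere).  Acquisition
is rendered line by line: the reading for a channel is

    M_line * (sensitivity * concentration + background) + eps_reading

with ``M_line`` lognormal (one draw per line and channel, modelling
line-to-line ablation/transport efficiency drift; unit mean, CV =
``noise_multiplicative_cv``) and ``eps_reading`` Gaussian per reading
(detector noise), floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .raw_io import (CHANNEL_ELEMENT, CONCENTRATION, ChannelTrace, ElementMap,
                     LineScanSet)

# compartment labels (shared with segmentation ground-truth comparisons)
BACKGROUND, STROMA, GLAND, LUMEN, HOTSPOT = 0, 1, 2, 3, 4
COMPARTMENT_NAMES = {BACKGROUND: "background", STROMA: "stroma",
                     GLAND: "gland", LUMEN: "lumen", HOTSPOT: "hotspot"}
COMPARTMENT_IDS = {v: k for k, v in COMPARTMENT_NAMES.items()}

#: (element, compartment) -> µg/g.  Zn levels are typical of normal
#: peripheral-zone prostate tissue
#: (glands ~450, stroma ~340, hotspots ~850 µg/g); P levels give the strong
#: gland/stroma contrast the segmentation exploits, with hotspots P-poor
#: (below the 1100 cps on-tissue offset at default sensitivity).
DEFAULT_CONCENTRATIONS: dict[tuple[str, str], float] = {
    ("Zn", "stroma"): 340.0, ("Zn", "gland"): 450.0,
    ("Zn", "lumen"): 20.0, ("Zn", "hotspot"): 850.0,
    ("P", "stroma"): 1200.0, ("P", "gland"): 3000.0,
    ("P", "lumen"): 30.0, ("P", "hotspot"): 80.0,
    ("Fe", "stroma"): 120.0, ("Fe", "gland"): 150.0,
    ("Fe", "lumen"): 5.0, ("Fe", "hotspot"): 20.0,
}


class GeometryError(ValueError):
    """Requested phantom geometry cannot be realised."""


@dataclass
class GeometryParams:
    """Phantom geometry defaults (µm unless noted).

    The default 120x170 px grid at 15 µm/px leaves margin for the 100x150 px
    analysis crop.  Glands are annuli (epithelium ring around a lumen disk)
    placed by rejection sampling; by default glands are added until the
    epithelium fraction of solid tissue reaches ``gland_fraction``.
    """

    grid_shape: tuple[int, int] = (120, 170)
    pixel_size_um: float = 15.0
    tissue_semiaxes_um: tuple[float, float] = (850.0, 1230.0)
    gland_fraction: float = 0.40
    gland_count: int | None = None          # exact count; None = fraction-driven
    max_glands: int = 40
    gland_outer_radius_um: tuple[float, float] = (100.0, 280.0)
    lumen_radius_ratio: float = 0.5
    hotspot_count: int = 3
    hotspot_diameter_um: tuple[float, float] = (150.0, 400.0)
    placement_margin_um: float = 30.0
    max_attempts_per_gland: int = 2000

    def validate(self) -> None:
        if min(self.tissue_semiaxes_um) <= 0 or self.pixel_size_um <= 0:
            raise GeometryError("tissue radii and pixel size must be positive")
        lo, hi = self.gland_outer_radius_um
        if lo <= 0 or hi < lo:
            raise GeometryError("gland radius range must be positive and ordered")
        if hi >= min(self.tissue_semiaxes_um):
            raise GeometryError("gland radii must be smaller than the tissue radius")
        if not 0 < self.lumen_radius_ratio < 1:
            raise GeometryError("lumen_radius_ratio must lie in (0, 1)")
        if not 0 <= self.gland_fraction < 1:
            raise GeometryError("gland_fraction must lie in [0, 1)")


@dataclass
class TissuePhantom:
    """Ground-truth compartment label image plus concentration table."""

    label_grid: np.ndarray                      # int grid of compartment ids
    pixel_size_um: float
    conc_table: dict[tuple[str, str], float]    # (element, compartment) -> µg/g
    seed: int
    geometry: GeometryParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_grid.shape

    def compartment_mask(self, compartment: int) -> np.ndarray:
        return self.label_grid == compartment

    def on_tissue_mask(self) -> np.ndarray:
        return self.label_grid != BACKGROUND

    def solid_tissue_mask(self) -> np.ndarray:
        """Stroma + gland epithelium (lumina are tissue-free cavities)."""
        return np.isin(self.label_grid, (STROMA, GLAND))

    def gland_fraction(self) -> float:
        """Epithelium fraction of solid tissue (gland / (gland + stroma))."""
        g = int(np.sum(self.label_grid == GLAND))
        s = int(np.sum(self.label_grid == STROMA))
        return g / (g + s) if g + s else 0.0

    def elements(self) -> list[str]:
        return sorted({el for el, _ in self.conc_table})


@dataclass
class ProtocolEffect:
    """Compartment-wise multiplicative retention (washout) per element.

    FF (fresh frozen) is the reference: retention 1.0 everywhere.
    """

    name: str
    retention: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for key, r in self.retention.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention {key} = {r} outside [0, 1]")

    @classmethod
    def uniform(cls, name: str, per_element: dict[str, float],
                compartments: tuple[str, ...] = ("stroma", "gland", "lumen", "hotspot"),
                ) -> "ProtocolEffect":
        """Compartment-uniform retention, one factor per element."""
        table = {(el, comp): r for el, r in per_element.items()
                 for comp in compartments}
        return cls(name, table)


def default_protocols() -> dict[str, ProtocolEffect]:
    """The four preparation protocols with their default retentions:

    - FF   fresh frozen, the 100% reference;
    - RTV  room-temperature vacuum dried: recoveries >= 96.2% (P 99.9, Fe 96.2);
    - FFix formalin fixed: Zn in gland/stroma down to ~41%, hotspots retained,
      P 61.9%, Fe 63.0%;
    - FFPS formalin fixed + paraffin sealed: Zn gland/stroma ~16%, hotspots
      ~50%, P 61.0%, Fe 61.4%.
    """
    comps = ("stroma", "gland", "lumen", "hotspot")
    ff = ProtocolEffect.uniform("FF", {"Zn": 1.0, "P": 1.0, "Fe": 1.0}, comps)
    rtv = ProtocolEffect.uniform("RTV", {"Zn": 0.97, "P": 0.999, "Fe": 0.962}, comps)
    ffix = ProtocolEffect("FFix", {
        ("Zn", "stroma"): 0.41, ("Zn", "gland"): 0.41,
        ("Zn", "lumen"): 0.41, ("Zn", "hotspot"): 1.0,
        **{("P", c): 0.619 for c in comps},
        **{("Fe", c): 0.630 for c in comps},
    })
    ffps = ProtocolEffect("FFPS", {
        ("Zn", "stroma"): 0.16, ("Zn", "gland"): 0.16,
        ("Zn", "lumen"): 0.16, ("Zn", "hotspot"): 0.50,
        **{("P", c): 0.610 for c in comps},
        **{("Fe", c): 0.614 for c in comps},
    })
    return {p.name: p for p in (ff, rtv, ffix, ffps)}


@dataclass
class AcquisitionConfig:
    """Laser/ICP-MS acquisition parameters (typical quadrupole defaults)."""

    spot_size_um: float = 15.0
    scan_speed_um_s: float = 45.0
    dwell_time_ms: dict[str, float] = field(default_factory=lambda: {
        "64Zn": 75.0, "66Zn": 75.0, "31P": 50.0, "57Fe": 50.0})
    sensitivity_cps_per_ugg: dict[str, float] = field(default_factory=lambda: {
        "64Zn": 50.0, "66Zn": 28.0, "31P": 10.0, "57Fe": 5.0})
    background_cps: dict[str, float] = field(default_factory=lambda: {
        "64Zn": 200.0, "66Zn": 120.0, "31P": 50.0, "57Fe": 40.0})
    noise_multiplicative_cv: float = 0.05
    noise_additive_sd_cps: float = 30.0

    def validate(self) -> None:
        if self.spot_size_um <= 0 or self.scan_speed_um_s <= 0:
            raise ValueError("spot size and scan speed must be positive")
        if any(d <= 0 for d in self.dwell_time_ms.values()):
            raise ValueError("dwell times must be positive")
        if self.noise_multiplicative_cv < 0 or self.noise_additive_sd_cps < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def channels(self) -> list[str]:
        return list(self.dwell_time_ms)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semiaxes_px: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semiaxes_px[0]) ** 2 + \
           ((cc - center[1]) / semiaxes_px[1]) ** 2 <= 1.0


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px ** 2


def generate_phantom(geometry: GeometryParams | None = None,
                     conc_table: dict[tuple[str, str], float] | None = None,
                     seed: int = 0) -> TissuePhantom:
    """Build a ground-truth tissue phantom.

    Glands (epithelium annuli with enclosed lumina) are placed by rejection
    sampling with a separation constraint that keeps every lumen fully
    surrounded by its own epithelium.  When ``geometry.gland_count`` is None,
    glands are added until the epithelium fraction of solid tissue reaches
    ``geometry.gland_fraction`` (a bounded attempt budget applies; a shortfall
    of more than 10 percentage points raises :class:`GeometryError`).
    """
    geom = geometry or GeometryParams()
    geom.validate()
    table = dict(conc_table if conc_table is not None else DEFAULT_CONCENTRATIONS)
    if any(v < 0 for v in table.values()):
        raise ValueError("concentrations must be non-negative")

    rng = np.random.default_rng([int(seed), 0])   # geometry stream
    px = geom.pixel_size_um
    shape = geom.grid_shape
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    semi_px = (geom.tissue_semiaxes_um[0] / px, geom.tissue_semiaxes_um[1] / px)

    labels = np.full(shape, BACKGROUND, dtype=np.int8)
    tissue = _ellipse_mask(shape, center, semi_px)
    labels[tissue] = STROMA
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise GeometryError("tissue ellipse contains no pixels")

    # --- gland placement -------------------------------------------------
    want_count = geom.gland_count
    target = geom.gland_fraction
    margin_px = geom.placement_margin_um / px
    placed: list[tuple[float, float, float, float]] = []  # (r, c, ro_px, ri_px)

    def fraction() -> float:
        g = int(np.sum(labels == GLAND))
        s = int(np.sum(labels == STROMA))
        return g / (g + s) if g + s else 0.0

    n_goal = want_count if want_count is not None else geom.max_glands
    while len(placed) < n_goal:
        if want_count is None and fraction() >= target:
            break
        ro_um = rng.uniform(*geom.gland_outer_radius_um)
        ro = ro_um / px
        ri = ro * geom.lumen_radius_ratio
        ok = False
        for _ in range(geom.max_attempts_per_gland):
            # center uniform within the tissue ellipse shrunk so the disk fits
            a, b = semi_px[0] - ro, semi_px[1] - ro
            if a <= 0 or b <= 0:
                break
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v > 1:
                continue
            r0, c0 = center[0] + u * a, center[1] + v * b
            # lumen i must never touch ring j and vice versa
            if all(math.hypot(r0 - pr, c0 - pc) >=
                   max(ro + pri, pro + ri) + margin_px
                   for pr, pc, pro, pri in placed):
                ok = True
                break
        if not ok:
            break  # space exhausted for this radius draw
        outer = _disk_mask(shape, (r0, c0), ro) & tissue
        inner = _disk_mask(shape, (r0, c0), ri)
        labels[outer] = GLAND
        labels[inner & tissue] = LUMEN
        placed.append((r0, c0, ro, ri))

    if want_count is not None and len(placed) < want_count:
        raise GeometryError(
            f"could only place {len(placed)} of {want_count} requested glands "
            f"without overlap within the attempt budget")
    if want_count is None and target > 0:
        got = fraction()
        if got < target - 0.10:
            raise GeometryError(
                f"gland fraction {got:.2f} falls more than 10 points short of "
                f"the requested {target:.2f}: glands do not fit")

    # --- hotspots inside the largest lumina ------------------------------
    if geom.hotspot_count > 0 and placed:
        by_lumen = sorted(placed, key=lambda g: -g[3])
        hosts = by_lumen[: geom.hotspot_count]
        lo_um, hi_um = geom.hotspot_diameter_um
        for r0, c0, _ro, ri in hosts:
            radius = rng.uniform(lo_um, hi_um) / (2 * px)
            radius = min(radius, ri - 2.0)       # keep a lumen margin ring
            if radius < 1.0:
                continue                          # lumen too small to host one
            spot = _disk_mask(shape, (r0, c0), radius)
            labels[spot & (labels == LUMEN)] = HOTSPOT

    return TissuePhantom(label_grid=labels, pixel_size_um=px, conc_table=table,
                         seed=int(seed), geometry=geom)


# ---------------------------------------------------------------------------
# washout and acquisition rendering
# ---------------------------------------------------------------------------

def apply_protocol(phantom: TissuePhantom,
                   effect: ProtocolEffect) -> dict[str, ElementMap]:
    """Concentration maps after protocol-specific washout.

    Pixel value = conc_table[element, compartment] * retention[element,
    compartment]; background pixels are 0.  A missing retention entry for any
    (element, compartment) present in the phantom raises.
    """
    labels = phantom.label_grid
    present = {COMPARTMENT_NAMES[c] for c in np.unique(labels) if c != BACKGROUND}
    maps: dict[str, ElementMap] = {}
    for element in phantom.elements():
        grid = np.zeros(labels.shape, dtype=float)
        for comp_name in present:
            key = (element, comp_name)
            if key not in phantom.conc_table:
                raise ValueError(f"no concentration for {key}")
            if key not in effect.retention:
                raise ValueError(
                    f"protocol {effect.name!r} lacks a retention entry for {key}")
            mask = labels == COMPARTMENT_IDS[comp_name]
            grid[mask] = phantom.conc_table[key] * effect.retention[key]
        maps[element] = ElementMap(element=element, grid=grid,
                                   value_kind=CONCENTRATION,
                                   pixel_size_um=phantom.pixel_size_um)
    return maps


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def simulate_linescans(maps: dict[str, ElementMap], acq: AcquisitionConfig,
                       seed: int = 0) -> LineScanSet:
    """Render concentration maps as per-line transient signals.

    One image row is one ablated line (line spacing = spot size).  Each
    channel is sampled at its own dwell time; the reading at time t takes the
    concentration of the pixel under the reading centre.
    """
    acq.validate()
    if not maps:
        raise ValueError("no maps to simulate")
    shapes = {m.shape for m in maps.values()}
    sizes = {m.pixel_size_um for m in maps.values()}
    if len(shapes) != 1 or len(sizes) != 1:
        raise ValueError("maps must share grid shape and pixel size")
    (n_rows, n_cols), px = shapes.pop(), sizes.pop()
    line_length_um = n_cols * px

    channels = [ch for ch in acq.channels if CHANNEL_ELEMENT[ch] in maps]
    if not channels:
        raise ValueError("no acquisition channel matches the provided maps")
    rng = np.random.default_rng([int(seed), 1])   # noise stream

    lines: list[dict[str, ChannelTrace]] = []
    for row in range(n_rows):
        line: dict[str, ChannelTrace] = {}
        for ch in channels:
            dt_s = acq.dwell_time_ms[ch] * 1e-3
            interval_um = acq.scan_speed_um_s * dt_s
            n_read = math.ceil(line_length_um / interval_um - 1e-9)
            k = np.arange(n_read)
            times = k * dt_s
            cols = np.minimum(((k + 0.5) * interval_um / px).astype(int),
                              n_cols - 1)
            conc = maps[CHANNEL_ELEMENT[ch]].grid[row, cols]
            signal = acq.sensitivity_cps_per_ugg[ch] * conc + acq.background_cps[ch]
            m = _lognormal_factors(rng, acq.noise_multiplicative_cv, 1)[0]
            eps = (rng.normal(0.0, acq.noise_additive_sd_cps, size=n_read)
                   if acq.noise_additive_sd_cps > 0 else 0.0)
            values = np.maximum(m * signal + eps, 0.0)
            line[ch] = ChannelTrace(times, values)
        lines.append(line)

    return LineScanSet(lines=lines, channel_names=channels,
                       dwell_time_ms={ch: acq.dwell_time_ms[ch] for ch in channels},
                       scan_speed_um_s=acq.scan_speed_um_s,
                       line_spacing_um=acq.spot_size_um,
                       spot_size_um=acq.spot_size_um)


def generate_standard_set(nominal_concs_ugg: list[float],
                          acq: AcquisitionConfig,
                          lines_per_standard: int = 10,
                          element: str = "Zn",
                          line_length_um: float = 2250.0,
                          pixel_size_um: float = 15.0,
                          seed: int = 0) -> list[tuple[float, LineScanSet]]:
    """Render homogeneous calibration standards as line-scan sets.

    Each standard is a uniform block at its nominal concentration, ablated as
    ``lines_per_standard`` lines.  A blank (0) must be present — the
    LOD/LOQ criteria are undefined without one.
    """
    if not any(c == 0 for c in nominal_concs_ugg):
        raise ValueError("standard set must include a blank (0 µg/g): "
                         "LOD/LOQ are undefined without one")
    if any(c < 0 for c in nominal_concs_ugg):
        raise ValueError("nominal concentrations must be non-negative")
    n_cols = int(round(line_length_um / pixel_size_um))
    out: list[tuple[float, LineScanSet]] = []
    for i, conc in enumerate(nominal_concs_ugg):
        grid = np.full((lines_per_standard, n_cols), float(conc))
        emap = ElementMap(element=element, grid=grid, value_kind=CONCENTRATION,
                          pixel_size_um=pixel_size_um)
        ls = simulate_linescans({element: emap}, acq,
                                seed=np.random.SeedSequence([int(seed), 2, i])
                                .generate_state(1)[0] % (2**31))
        out.append((float(conc), ls))
    return out


def write_truth(phantom: TissuePhantom, directory,
                effect: ProtocolEffect | None = None) -> None:
    """Write the ground truth beside a simulated dataset: the compartment
    label image as 8-bit TIFF plus the concentration (and optionally
    retention) tables as CSV."""
    import pandas as pd
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "labels.tif",
                     phantom.label_grid.astype(np.uint8))
    rows = [{"element": el, "compartment": comp, "concentration_ugg": c}
            for (el, comp), c in sorted(phantom.conc_table.items())]
    pd.DataFrame(rows).to_csv(directory / "concentrations.csv", index=False)
    if effect is not None:
        rows = [{"element": el, "compartment": comp, "retention": r}
                for (el, comp), r in sorted(effect.retention.items())]
        pd.DataFrame(rows).to_csv(directory / "retention.csv", index=False)


#: solution concentrations (µg/mL) of the six-point serial dilution used for
#: the gelatin standards; with 100 mg gelatin + 900 µL spike these give
#: nominal levels 0.9 … 450 µg/g plus the blank.
DEFAULT_STANDARD_SOLUTIONS_UG_ML = [0.0, 1.0, 10.0, 50.0, 100.0, 250.0, 500.0]
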