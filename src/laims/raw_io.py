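"""Line-scan ingestion and conversion of transient signals into 2D elemental maps.

A laser-ablation ICP-MS experiment produces one transient intensity series per
ablated line and per isotope channel.  Because each channel has its own dwell
time (here 75 ms for the zinc isotopes, 50 ms for P and Fe at 45 µm/s scan
speed), the channels sample the line at different native spacings (3.375 µm vs
2.25 µm).  :func:`lines_to_map` bin-averages each channel onto a common pixel
grid (default 15 µm, equal to the laser spot size and line spacing), which is
the only mean-preserving resampling choice.

Conventions: image row = line index (acquisition order, unidirectional
left-to-right scans), column = along-scan bin, 0-based, origin upper-left.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: isotope channel -> element symbol
CHANNEL_ELEMENT = {"31P": "P", "57Fe": "Fe", "64Zn": "Zn", "66Zn": "Zn"}

INTENSITY = "intensity"
CONCENTRATION = "concentration"

_LINE_FILE_RE = re.compile(r"line_(\d+)\.csv$")


@dataclass
class ChannelTrace:
    """One channel's transient signal along a single ablated line."""

    times_s: np.ndarray
    intensities_cps: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities_cps = np.asarray(self.intensities_cps, dtype=float)
        if self.times_s.shape != self.intensities_cps.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times_s.size < 1:
            raise ValueError("a line trace needs at least one reading")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing within a line")


@dataclass
class LineScanSet:
    """Ordered per-line transient signals plus acquisition metadata.

    ``lines`` is an ordered list; each entry maps channel name ->
    :class:`ChannelTrace`.  The channel set must be identical across lines.
    """

    lines: list[dict[str, ChannelTrace]]
    channel_names: list[str]
    dwell_time_ms: dict[str, float]
    scan_speed_um_s: float
    line_spacing_um: float
    spot_size_um: float

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("a LineScanSet needs at least one line")
        chans = set(self.channel_names)
        for i, line in enumerate(self.lines):
            if set(line) != chans:
                raise ValueError(
                    f"line {i} channels {sorted(line)} != declared {sorted(chans)}"
                )

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def sampling_interval_um(self, channel: str) -> float:
        """Native along-scan spacing of one reading for *channel*."""
        return self.scan_speed_um_s * self.dwell_time_ms[channel] * 1e-3


@dataclass
class ElementMap:
    """One isotope channel's 2D grid with pixel geometry.

    ``value_kind`` is ``"intensity"`` (cps) or ``"concentration"`` (µg/g).
    """

    element: str
    grid: np.ndarray
    value_kind: str
    pixel_size_um: float
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.value_kind not in (INTENSITY, CONCENTRATION):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def with_grid(self, grid: np.ndarray, value_kind: str | None = None) -> "ElementMap":
        return replace(self, grid=np.asarray(grid, dtype=float),
                       value_kind=value_kind or self.value_kind)


# ---------------------------------------------------------------------------
# line-scan files
# ---------------------------------------------------------------------------

def write_linescans(ls: LineScanSet, directory: str | Path) -> None:
    """Write one tidy CSV per line (channel, time_s, intensity_cps) plus a
    YAML acquisition sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, line in enumerate(ls.lines):
        frames = []
        for ch in ls.channel_names:
            tr = line[ch]
            frames.append(pd.DataFrame({
                "channel": ch,
                "time_s": tr.times_s,
                "intensity_cps": tr.intensities_cps,
            }))
        pd.concat(frames, ignore_index=True).to_csv(
            directory / f"line_{i:04d}.csv", index=False)
    meta = {
        "channel_names": list(ls.channel_names),
        "dwell_time_ms": {k: float(v) for k, v in ls.dwell_time_ms.items()},
        "scan_speed_um_s": float(ls.scan_speed_um_s),
        "line_spacing_um": float(ls.line_spacing_um),
        "spot_size_um": float(ls.spot_size_um),
    }
    with open(directory / "acquisition.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_linescans(directory: str | Path) -> LineScanSet:
    """Read a line-scan directory written by :func:`write_linescans`.

    Negative intensities are clipped to zero (count logged); non-monotone
    times or an inconsistent channel set raise, naming the offending file.
    """
    directory = Path(directory)
    meta_path = directory / "acquisition.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"no acquisition.yaml in {directory}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    channels = list(meta["channel_names"])

    files = sorted(p for p in directory.glob("line_*.csv") if _LINE_FILE_RE.search(p.name))
    if not files:
        raise FileNotFoundError(f"no line files found in {directory}")

    n_clipped = 0
    lines: list[dict[str, ChannelTrace]] = []
    for path in files:
        df = pd.read_csv(path)
        for col in ("channel", "time_s", "intensity_cps"):
            if col not in df.columns:
                raise ValueError(f"{path.name}: missing column {col!r}")
        present = set(df["channel"].unique())
        if present != set(channels):
            missing = sorted(set(channels) - present)
            extra = sorted(present - set(channels))
            raise ValueError(
                f"{path.name}: channel set mismatch (missing {missing}, extra {extra})")
        line: dict[str, ChannelTrace] = {}
        for ch, grp in df.groupby("channel", sort=False):
            t = grp["time_s"].to_numpy(dtype=float)
            y = grp["intensity_cps"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{path.name}: non-monotone time in channel {ch}")
            neg = y < 0
            if neg.any():
                n_clipped += int(neg.sum())
                y = np.where(neg, 0.0, y)
            line[str(ch)] = ChannelTrace(t, y)
        lines.append(line)
    if n_clipped:
        logger.warning("clipped %d negative readings to 0 while reading %s",
                       n_clipped, directory)
    return LineScanSet(
        lines=lines,
        channel_names=channels,
        dwell_time_ms=dict(meta["dwell_time_ms"]),
        scan_speed_um_s=float(meta["scan_speed_um_s"]),
        line_spacing_um=float(meta["line_spacing_um"]),
        spot_size_um=float(meta["spot_size_um"]),
    )


# ---------------------------------------------------------------------------
# signal -> image
# ---------------------------------------------------------------------------

def lines_to_map(ls: LineScanSet, channel: str,
                 target_pixel_size_um: float = 15.0) -> ElementMap:
    """Bin-average one channel's per-line transient signals into a 2D map.

    Reading *r* is centred at ``scan_speed * (t_r - t_0)`` plus half a native
    sampling interval; readings are averaged into along-scan bins of width
    ``target_pixel_size_um``.  One image row per line, rows in acquisition
    order.  Rows are truncated to the shortest common width (warned) so the
    result is rectangular.
    """
    if channel not in ls.channel_names:
        raise ValueError(f"channel {channel!r} not in line-scan set "
                         f"(have {ls.channel_names})")
    native = ls.sampling_interval_um(channel)
    if target_pixel_size_um < native - 1e-9:
        raise ValueError(
            f"target pixel size {target_pixel_size_um} µm would upsample the "
            f"{channel} native spacing of {native} µm")

    rows: list[np.ndarray] = []
    widths: list[int] = []
    for line in ls.lines:
        tr = line[channel]
        x = ls.scan_speed_um_s * (tr.times_s - tr.times_s[0]) + 0.5 * native
        line_length = tr.times_s.size * native
        width = int(math.floor(line_length / target_pixel_size_um + 1e-9))
        bins = np.floor(x / target_pixel_size_um).astype(int)
        keep = bins < width
        sums = np.bincount(bins[keep], weights=tr.intensities_cps[keep],
                           minlength=width)
        counts = np.bincount(bins[keep], minlength=width)
        if np.any(counts == 0):  # cannot occur when target >= native spacing
            raise RuntimeError("empty along-scan bin")
        rows.append(sums / counts)
        widths.append(width)

    w = min(widths)
    if len(set(widths)) > 1:
        logger.warning("line lengths differ (%d..%d bins); truncating to %d",
                       min(widths), max(widths), w)
    grid = np.vstack([r[:w] for r in rows])
    return ElementMap(element=channel, grid=grid, value_kind=INTENSITY,
                      pixel_size_um=float(target_pixel_size_um))


# ---------------------------------------------------------------------------
# map files
# ---------------------------------------------------------------------------

def write_map(emap: ElementMap, path: str | Path, format: str | None = None) -> None:
    """Write an :class:`ElementMap` as a CSV grid or 32-bit float TIFF.

    Metadata travels in ``# key: value`` comment lines (CSV) or a YAML
    sidecar ``<path>.yaml`` (TIFF).
    """
    path = Path(path)
    fmt = format or ("tiff" if path.suffix.lower() in (".tif", ".tiff") else "csv")
    meta = {"element": emap.element, "value_kind": emap.value_kind,
            "pixel_size_um": float(emap.pixel_size_um),
            "origin": [int(emap.origin[0]), int(emap.origin[1])]}
    if fmt == "csv":
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            np.savetxt(fh, emap.grid, delimiter=",", fmt="%.10g")
    elif fmt == "tiff":
        tifffile.imwrite(path, emap.grid.astype(np.float32))
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)
    else:
        raise ValueError(f"unsupported map format {fmt!r} (use 'csv' or 'tiff')")


def read_map(path: str | Path) -> ElementMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = np.asarray(tifffile.imread(path), dtype=float)
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
    elif path.suffix.lower() == ".csv":
        meta = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for raw in fh:
                raw = raw.strip()
                if not raw:
                    continue
                if raw.startswith("#"):
                    k, _, v = raw.lstrip("# ").partition(":")
                    meta[k.strip()] = yaml.safe_load(v.strip())
                    continue
                rows.append([float(tok) for tok in raw.split(",")])
        if not rows:
            raise ValueError(f"{path}: no data rows")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"{path}: non-rectangular CSV grid (row lengths {sorted(lengths)})")
        grid = np.asarray(rows, dtype=float)
    else:
        raise ValueError(f"unsupported map format for {path}")
    origin = tuple(meta.get("origin", (0, 0)))
    return ElementMap(element=str(meta["element"]), grid=grid,
                      value_kind=str(meta["value_kind"]),
                      pixel_size_um=float(meta["pixel_size_um"]),
                      origin=(int(origin[0]), int(origin[1])))
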