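"""Extracted ion maps (EIMs), TIC normalization and image export.

An EIM accumulates, per MS1 scan, the summed intensity of centroid peaks
within a symmetric ppm window around a target m/z, into the scan's pixel.
With TIC normalization each pixel is divided by that pixel's total ion
current, which cancels shot-to-shot desorption variation; pixels that were
never visited, or whose TIC is zero, are missing (NaN), not zero.

Stored grids are never rescaled: percentile clipping for display is applied
only at PNG export, and the CSV export round-trips the grid bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .formats_io import PositionLog, RawRun, ValidationError
from .geometry import RasterGeometry, TICMap, build_tic_map, scan_to_pixel

__all__ = [
    "IonImage",
    "extract_ion_image",
    "matrix_ion_trace",
    "merge_channels",
    "save_image_png",
    "save_grid_csv",
    "load_grid_csv",
]


@dataclass
class IonImage:
    """Per-pixel intensity of a narrow m/z window around a target."""

    target_mz: float
    tol_ppm: float
    grid: np.ndarray
    normalized: bool


def _window_sum(scan, target_mz: float, tol_ppm: float) -> float:
    tol_da = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(scan.mz, target_mz - tol_da, side="left")
    hi = np.searchsorted(scan.mz, target_mz + tol_da, side="right")
    return float(scan.intensity[lo:hi].sum())


def extract_ion_image(
    run: RawRun,
    geom: RasterGeometry,
    log: PositionLog,
    target_mz: float,
    tol_ppm: float,
    normalize: bool = False,
    tic_map: Optional[TICMap] = None,
) -> IonImage:
    """Build the extracted ion map for *target_mz* +/- *tol_ppm*.

    Per MS1 scan, intensities of peaks inside the window are summed and
    accumulated into the scan's pixel.  With ``normalize`` each pixel is
    divided by its TIC (zero-TIC pixels become NaN).  The target must lie
    inside the run's mass range.
    """
    lo, hi = run.mass_range
    if not lo <= target_mz <= hi:
        raise ValidationError(
            f"target m/z {target_mz} outside run mass range [{lo}, {hi}]"
        )
    grid = np.full((geom.n_lines, geom.n_cols), np.nan)
    for scan in run.scans:
        if scan.ms_level != 1:
            continue
        pixel = scan_to_pixel(scan.time_s, geom, log)
        if pixel is None:
            continue
        if np.isnan(grid[pixel]):
            grid[pixel] = 0.0
        grid[pixel] += _window_sum(scan, target_mz, tol_ppm)
    if normalize:
        if tic_map is None:
            tic_map = build_tic_map(run, geom, log)
        with np.errstate(invalid="ignore", divide="ignore"):
            grid = grid / tic_map.grid
        grid[np.isinf(grid)] = np.nan
    return IonImage(target_mz=target_mz, tol_ppm=tol_ppm, grid=grid, normalized=normalize)


def matrix_ion_trace(run: RawRun, target_mz: float, tol_ppm: float) -> np.ndarray:
    """Extracted-ion chromatogram across MS1 scans (times, intensities).

    Useful for diagnosing persistent matrix signals (e.g. the CHCA-related
    m/z 265.96 ion): a near-constant trace over the laser-active region
    marks a matrix ion.  Returns an array of shape (n_ms1, 2) with scan
    time and windowed intensity.
    """
    rows = [
        (scan.time_s, _window_sum(scan, target_mz, tol_ppm))
        for scan in run.scans
        if scan.ms_level == 1
    ]
    return np.array(rows).reshape(-1, 2)


def merge_channels(images: Sequence[IonImage]) -> np.ndarray:
    """Composite 2-3 ion images into an RGB array.

    Each channel is min-max scaled to [0, 1] independently (NaN treated as
    0); an all-zero or missing channel stays black.  Returns an array of
    shape (n_lines, n_cols, 3).
    """
    if not 2 <= len(images) <= 3:
        raise ValidationError("merge_channels takes 2 or 3 images")
    shape = images[0].grid.shape
    if any(image.grid.shape != shape for image in images):
        raise ValidationError("channel dimensions differ")
    rgb = np.zeros(shape + (3,))
    for channel, image in enumerate(images):
        grid = np.nan_to_num(image.grid, nan=0.0)
        lo, hi = grid.min(), grid.max()
        if hi > lo:
            rgb[:, :, channel] = (grid - lo) / (hi - lo)
    return rgb


def save_image_png(
    image, path, cmap: str = "viridis", clip_percentile: float = 99.5
) -> None:
    """Export a grid (IonImage, TICMap or array) as a false-color PNG.

    Display scaling clips at the given intensity percentile to tame hot
    pixels; the stored grid is never modified.  Missing pixels render
    black.  A 3-channel array is written as RGB directly.
    """
    import matplotlib
    from matplotlib import cm
    from PIL import Image

    grid = getattr(image, "grid", image)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim == 3:
        rgb = np.clip(grid, 0.0, 1.0)
        out = (rgb * 255).astype(np.uint8)
        Image.fromarray(out, mode="RGB").save(path)
        return
    finite = grid[np.isfinite(grid)]
    if finite.size:
        vmax = float(np.percentile(finite, clip_percentile))
        vmin = float(finite.min())
    else:
        vmin, vmax = 0.0, 1.0
    if vmax <= vmin:
        vmax = vmin + 1.0
    scaled = np.clip((grid - vmin) / (vmax - vmin), 0.0, 1.0)
    colormap = matplotlib.colormaps[cmap]
    rgba = colormap(np.nan_to_num(scaled, nan=0.0))
    rgba[np.isnan(grid)] = (0.0, 0.0, 0.0, 1.0)
    Image.fromarray((rgba[:, :, :3] * 255).astype(np.uint8), mode="RGB").save(path)


def save_grid_csv(image, path) -> None:
    """Write a grid as CSV; missing (NaN) pixels become empty cells."""
    grid = getattr(image, "grid", image)
    with open(path, "w", encoding="utf-8") as handle:
        for row in np.asarray(grid, dtype=float):
            handle.write(
                ",".join("" if np.isnan(v) else repr(float(v)) for v in row) + "\n"
            )


def load_grid_csv(path) -> np.ndarray:
    """Read a grid CSV written by :func:`save_grid_csv` (empty cells -> NaN)."""
    rows = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line and not rows:
                continue
            rows.append([float(v) if v else np.nan for v in line.split(",")])
    return np.array(rows)
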