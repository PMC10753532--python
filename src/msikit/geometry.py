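"""Map the time-ordered scan stream onto the raster pixel grid.

A constant-speed raster acquisition moves the sample plate under the laser
at ``plate_velocity_um_s`` while the instrument cycles at
``cycle_period_s`` per full scan, so along-track pixel size is velocity x
cycle period unless explicitly overridden.  Pixel coordinates are 0-based
``(row, col)``; row is the raster line index and col increases along the
motion direction (flipped on odd rows when ``serpentine`` is set).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .formats_io import PositionLog, RawRun, ValidationError

__all__ = ["RasterGeometry", "TICMap", "laser_active", "scan_to_pixel", "build_tic_map"]


@dataclass
class RasterGeometry:
    """Raster-scan geometry of a constant-speed MSI acquisition.

    ``pixel_pitch_um`` (along-track pixel size) defaults to
    ``plate_velocity_um_s * cycle_period_s`` — one pixel per full-scan
    cycle — but can be overridden.
    """

    plate_velocity_um_s: float
    line_spacing_um: float
    cycle_period_s: float
    n_lines: int
    n_cols: int
    pixel_pitch_um: Optional[float] = None
    serpentine: bool = False

    def __post_init__(self) -> None:
        if self.pixel_pitch_um is None:
            self.pixel_pitch_um = self.plate_velocity_um_s * self.cycle_period_s
        for name in ("plate_velocity_um_s", "line_spacing_um", "cycle_period_s",
                     "pixel_pitch_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_lines < 1 or self.n_cols < 1:
            raise ValidationError("grid dimensions must be >= 1")

    @classmethod
    def from_position_log(
        cls,
        log: PositionLog,
        plate_velocity_um_s: float,
        cycle_period_s: float,
        pixel_pitch_um: Optional[float] = None,
        serpentine: bool = False,
    ) -> "RasterGeometry":
        """Derive grid dimensions and line spacing from a position log."""
        n_lines = len(log.lines)
        ys = [line[3] for line in log.lines]
        spacing = (
            float(np.median(np.diff(sorted(ys)))) if n_lines > 1 and max(ys) > min(ys) else 1.0
        )
        pitch = pixel_pitch_um or plate_velocity_um_s * cycle_period_s
        n_cols = max(
            1,
            max(
                int(np.ceil((t1 - t0) * plate_velocity_um_s / pitch))
                for _, t0, t1, _ in log.lines
            ),
        )
        return cls(
            plate_velocity_um_s=plate_velocity_um_s,
            line_spacing_um=spacing,
            cycle_period_s=cycle_period_s,
            n_lines=n_lines,
            n_cols=n_cols,
            pixel_pitch_um=pitch,
            serpentine=serpentine,
        )


@dataclass
class TICMap:
    """Per-pixel total ion current with a laser-active mask.

    ``grid`` holds summed MS1 TIC per pixel; pixels never visited are NaN
    (missing), not zero.  ``mask`` is True where the pixel's scans were
    acquired with the laser active.
    """

    grid: np.ndarray
    mask: np.ndarray

    @property
    def visited(self) -> np.ndarray:
        return ~np.isnan(self.grid)


def laser_active(t: float, log: PositionLog) -> bool:
    """True iff *t* falls inside a laser-on interval (half-open [on, off))."""
    intervals = log.laser_intervals
    i = bisect.bisect_right([iv[0] for iv in intervals], t) - 1
    return i >= 0 and intervals[i][0] <= t < intervals[i][1]


def scan_to_pixel(
    t: float, geom: RasterGeometry, log: PositionLog
) -> Optional[tuple[int, int]]:
    """Pixel coordinate of a scan acquired at time *t*, or None between lines.

    The row is the raster line whose ``[t_start, t_end)`` contains *t*; the
    column is ``floor((t - t_start) * velocity / pitch)`` clipped to the
    grid, reversed on odd rows for serpentine rasters.
    """
    starts = [line[1] for line in log.lines]
    i = bisect.bisect_right(starts, t) - 1
    if i < 0:
        return None
    row_index, t0, t1, _ = log.lines[i]
    if not (t0 <= t < t1):
        return None
    # epsilon guards against scans at exact pixel boundaries landing one
    # column early through float rounding
    col = int(np.floor((t - t0) * geom.plate_velocity_um_s / geom.pixel_pitch_um + 1e-9))
    col = min(max(col, 0), geom.n_cols - 1)
    if geom.serpentine and row_index % 2 == 1:
        col = geom.n_cols - 1 - col
    if not 0 <= row_index < geom.n_lines:
        return None
    return (row_index, col)


def build_tic_map(run: RawRun, geom: RasterGeometry, log: PositionLog) -> TICMap:
    """Accumulate every MS1 scan's TIC into its pixel.

    Multiple scans landing in one pixel are summed, preserving total ion
    count.  MS2 scans are excluded.  The mask marks pixels whose scans were
    laser-active.
    """
    grid = np.full((geom.n_lines, geom.n_cols), np.nan)
    mask = np.zeros((geom.n_lines, geom.n_cols), dtype=bool)
    for scan in run.scans:
        if scan.ms_level != 1:
            continue
        pixel = scan_to_pixel(scan.time_s, geom, log)
        if pixel is None:
            continue
        row, col = pixel
        if np.isnan(grid[row, col]):
            grid[row, col] = 0.0
        grid[row, col] += scan.tic
        if laser_active(scan.time_s, log):
            mask[row, col] = True
    return TICMap(grid=grid, mask=mask)
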