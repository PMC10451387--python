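"""Center-of-pressure extraction from raw device signals.

Two device families are supported:

* a flexible pressure-sensing mat: 68 x 48 = 3264 cells sampled at 23 Hz,
  from which the CoP is the force-weighted centroid of the loaded cell
  centers;
* a four-corner load-cell board (consumer force-plate style), where the CoP
  follows from the standard lever equations of the corner forces.

Grid geometry note: the mat's cells are nominally 21 mm x 36 mm but the
overall mat measures 1530 mm x 1820 mm, which implies a cell *pitch*
(center-to-center spacing) of 22.5 mm x 37.9 mm; the pitch is therefore a
configurable geometry parameter rather than a hard-coded cell size.

Axis convention (see :mod:`ictsib.types`): x runs along the grid columns /
board length, y along the grid rows / board width, origin at device center.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateLoadError, EmptyTrialError, SamplingError
from .types import Condition, CopTrial

MM_PER_CM = 10.0

#: Longest run of sub-threshold interior frames bridged by interpolation.
MAX_INTERIOR_GAP = 3


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of the pressure-sensing grid."""

    n_cols: int = 68
    n_rows: int = 48
    pitch_x_mm: float = 22.5
    pitch_y_mm: float = 37.9
    fs: float = 23.0

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid must have a positive number of cells")
        if self.pitch_x_mm <= 0 or self.pitch_y_mm <= 0:
            raise ValueError("cell pitch must be positive")

    @property
    def cell_x_cm(self) -> np.ndarray:
        """x coordinate (cm) of each column's cell centers, origin at grid center."""
        j = np.arange(self.n_cols)
        return (j - (self.n_cols - 1) / 2) * self.pitch_x_mm / MM_PER_CM

    @property
    def cell_y_cm(self) -> np.ndarray:
        """y coordinate (cm) of each row's cell centers, origin at grid center."""
        i = np.arange(self.n_rows)
        return ((self.n_rows - 1) / 2 - i) * self.pitch_y_mm / MM_PER_CM


@dataclass
class PressureFrameSeries:
    """A time series of pressure-grid frames (kgf per cell)."""

    geometry: GridGeometry
    frames: np.ndarray  # (n_t, n_rows, n_cols), nonnegative
    time: np.ndarray  # seconds

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.geometry.n_rows,
            self.geometry.n_cols,
        ):
            raise ValueError(
                f"frames must have shape (n_t, {self.geometry.n_rows}, "
                f"{self.geometry.n_cols}), got {self.frames.shape}"
            )
        if len(self.time) != self.frames.shape[0]:
            raise ValueError("frame count must equal len(time)")
        if np.any(self.frames < 0):
            raise ValueError("pressure values must be nonnegative")


@dataclass
class CornerLoadSeries:
    """Force signals (kgf) of the four corner load cells of a board.

    Corners are named viewing the board from above: tl/tr = top-left/right
    (positive y side), bl/br = bottom-left/right. The board length L spans x,
    the width W spans y.
    """

    tl: np.ndarray
    tr: np.ndarray
    bl: np.ndarray
    br: np.ndarray
    board_length_cm: float = 43.3
    board_width_cm: float = 22.8
    time: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sigs = [np.asarray(s, dtype=float) for s in (self.tl, self.tr, self.bl, self.br)]
        self.tl, self.tr, self.bl, self.br = sigs
        n = len(self.tl)
        if n == 0 or any(len(s) != n for s in sigs):
            raise ValueError("corner signals must be equal-length and non-empty")
        if self.time is None:
            raise ValueError("time vector is required")
        self.time = np.asarray(self.time, dtype=float)
        if len(self.time) != n:
            raise ValueError("time must have the same length as the corner signals")


def _infer_fs(time: np.ndarray) -> float:
    dt = np.diff(time)
    if len(dt) == 0 or np.any(dt <= 0):
        raise SamplingError("time vector must be strictly increasing with >= 2 samples")
    return 1.0 / float(np.median(dt))


def _bridge_gaps(valid: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Drop invalid prefix/suffix, interpolate short interior gaps.

    Returns the trimmed/interpolated (x, y) and the start index of the kept
    run. Interior gaps longer than :data:`MAX_INTERIOR_GAP` raise.
    """
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        raise EmptyTrialError("all frames are below the load threshold")
    start, stop = idx[0], idx[-1] + 1
    v = valid[start:stop]
    xs, ys = xs[start:stop].copy(), ys[start:stop].copy()
    if not v.all():
        bad = ~v
        # locate runs of invalid interior frames
        edges = np.diff(bad.astype(int))
        run_starts = np.nonzero(edges == 1)[0] + 1
        run_ends = np.nonzero(edges == -1)[0] + 1
        for a, b in zip(run_starts, run_ends):
            if b - a > MAX_INTERIOR_GAP:
                raise EmptyTrialError(
                    f"interior gap of {b - a} sub-threshold frames exceeds "
                    f"the {MAX_INTERIOR_GAP}-frame limit"
                )
        good = np.nonzero(v)[0]
        allidx = np.arange(len(v))
        xs = np.interp(allidx, good, xs[good])
        ys = np.interp(allidx, good, ys[good])
    return xs, ys, int(start)


def cop_from_grid(
    series: PressureFrameSeries,
    min_total_load_kgf: float = 10.0,
    condition: Condition = Condition.EO_FIRM,
    subject_id: str = "",
) -> CopTrial:
    """CoP trajectory as the per-frame force-weighted centroid of cell centers.

    Frames whose total load falls below ``min_total_load_kgf`` (the mat's
    lower sensing range by default) are invalid: an invalid prefix or suffix
    is dropped (the trial is re-timed), interior gaps of up to
    :data:`MAX_INTERIOR_GAP` frames are linearly interpolated, and longer
    gaps raise, preserving the uniform-sampling contract of
    :class:`~ictsib.types.CopTrial`.
    """
    geom = series.geometry
    total = series.frames.sum(axis=(1, 2))
    valid = total >= min_total_load_kgf
    safe_total = np.where(total > 0, total, 1.0)
    xs = np.einsum("trc,c->t", series.frames, geom.cell_x_cm) / safe_total
    ys = np.einsum("trc,r->t", series.frames, geom.cell_y_cm) / safe_total
    xs, ys, start = _bridge_gaps(valid, xs, ys)
    if len(xs) < 2:
        raise EmptyTrialError("fewer than 2 usable frames above the load threshold")
    fs = _infer_fs(series.time)
    t = np.arange(len(xs)) / fs
    return CopTrial(t, xs, ys, fs, condition, subject_id)


def cop_from_corners(
    loads: CornerLoadSeries,
    condition: Condition = Condition.EO_FIRM,
    subject_id: str = "",
) -> CopTrial:
    """CoP trajectory from four corner load cells via the lever equations.

    ``cop_x = (L/2) * ((tr+br) - (tl+bl)) / total`` and
    ``cop_y = (W/2) * ((tl+tr) - (bl+br)) / total``.
    """
    total = loads.tl + loads.tr + loads.bl + loads.br
    if np.any(total <= 0):
        bad = int(np.argmax(total <= 0))
        raise DegenerateLoadError(f"frame {bad} has non-positive total load")
    x = (loads.board_length_cm / 2) * ((loads.tr + loads.br) - (loads.tl + loads.bl)) / total
    y = (loads.board_width_cm / 2) * ((loads.tl + loads.tr) - (loads.bl + loads.br)) / total
    fs = _infer_fs(loads.time)
    t = np.arange(len(x)) / fs
    return CopTrial(t, x, y, fs, condition, subject_id)
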