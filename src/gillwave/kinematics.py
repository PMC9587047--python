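"""Fish trajectories, electrode selection, and swimming speed.

Under free-swimming conditions the ventilatory signal is measured by a
126-electrode array on the tank floor (210 x 140 mm).  Because the signal
decays with distance from the fish, the analysis channel is re-selected
every 5 s as the electrode nearest the tracked fish position, and the
selected windows are concatenated into a single channel whose 5-s segment
boundaries coincide with the selection windows.  The same trajectory also
yields the average swimming speed per 5-s window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, SelectionError, ShapeError, SpecError
from .io import Recording

TANK_W_MM = 210.0
TANK_H_MM = 140.0
N_ELECTRODES = 126
SELECTION_WINDOW_S = 5.0


@dataclass
class Trajectory:
    """2-D fish positions over time (mm, tank frame, origin lower-left)."""

    times_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    frame_rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if not len(self.times_s) == len(self.x_mm) == len(self.y_mm):
            raise ShapeError("times, x and y must have equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise SpecError("trajectory timestamps must be strictly increasing")

    @property
    def duration_s(self) -> float:
        if len(self.times_s) < 2:
            return 0.0
        return float(self.times_s[-1] - self.times_s[0])

    def out_of_bounds(self, w_mm: float = TANK_W_MM, h_mm: float = TANK_H_MM) -> np.ndarray:
        """Boolean mask of positions outside the tank (flagged, not clamped)."""
        return (
            (self.x_mm < 0) | (self.x_mm > w_mm) | (self.y_mm < 0) | (self.y_mm > h_mm)
        )


@dataclass
class ElectrodeGrid:
    """Electrode positions on the tank floor."""

    positions_mm: np.ndarray
    tank_w_mm: float = TANK_W_MM
    tank_h_mm: float = TANK_H_MM

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.ndim != 2 or self.positions_mm.shape[1] != 2:
            raise ShapeError("positions must be (n, 2)")
        x, y = self.positions_mm.T
        if (x < 0).any() or (x > self.tank_w_mm).any() or (y < 0).any() or (y > self.tank_h_mm).any():
            raise SpecError("electrode positions must lie within the tank")
        if len(np.unique(self.positions_mm, axis=0)) != len(self.positions_mm):
            raise SpecError("electrode positions must be distinct")

    @property
    def n_electrodes(self) -> int:
        return len(self.positions_mm)


def default_grid() -> ElectrodeGrid:
    """The 126-electrode array as a 14 x 9 lattice at 15 mm pitch.

    14 columns x 9 rows is the near-uniform rectangular factorization of
    126 matching the 210:140 tank aspect; the lattice is centered, so
    electrode (row, col) sits at (7.5 + 15*col, 7.5 + 15*row) mm and the
    index is row-major: ``index = row * 14 + col``.  Real electrode
    coordinates, if known, can be supplied via :func:`grid_from_positions`.
    """
    cols, rows, pitch = 14, 9, 15.0
    xs = pitch / 2 + pitch * np.arange(cols)
    ys = pitch / 2 + pitch * np.arange(rows)
    pos = np.array([(x, y) for y in ys for x in xs])
    return ElectrodeGrid(pos)


def grid_from_positions(path) -> ElectrodeGrid:
    """Load an electrode layout from an ``index,x_mm,y_mm`` CSV."""
    import pandas as pd

    df = pd.read_csv(path).sort_values("index")
    return ElectrodeGrid(df[["x_mm", "y_mm"]].to_numpy())


@dataclass
class ChannelSelection:
    """Per-window nearest electrode indices."""

    window_starts_s: np.ndarray
    electrode_index: np.ndarray
    window_s: float = SELECTION_WINDOW_S

    def __post_init__(self) -> None:
        self.window_starts_s = np.asarray(self.window_starts_s, dtype=float)
        self.electrode_index = np.asarray(self.electrode_index, dtype=int)
        if len(self.window_starts_s) != len(self.electrode_index):
            raise ShapeError("window starts and indices must align")


def nearest_electrode(
    traj: Trajectory,
    grid: ElectrodeGrid,
    window_s: float = SELECTION_WINDOW_S,
    duration_s: float | None = None,
    aggregator: str = "mean",
) -> ChannelSelection:
    """Select, per window, the electrode nearest the fish.

    The fish position within each window is summarized by ``aggregator``
    ("mean", "median", or "start"), and the electrode of minimum Euclidean
    distance is chosen; exact ties break toward the lowest index.  Windows
    containing no tracked frames raise :class:`SelectionError`.
    """
    dur = duration_s if duration_s is not None else traj.times_s[-1] - traj.times_s[0] if len(traj.times_s) else 0.0
    t0 = traj.times_s[0] if len(traj.times_s) else 0.0
    n_win = int(round(dur / window_s))
    if n_win < 1:
        raise SelectionError("trajectory shorter than one selection window")
    starts = t0 + window_s * np.arange(n_win)
    idx = np.empty(n_win, dtype=int)
    for w, ws in enumerate(starts):
        in_win = (traj.times_s >= ws) & (traj.times_s < ws + window_s)
        if w == n_win - 1:  # closed right edge on the final window
            in_win |= traj.times_s == ws + window_s
        if not in_win.any():
            raise SelectionError(f"no tracked frames in window starting at {ws:.1f} s")
        xs, ys = traj.x_mm[in_win], traj.y_mm[in_win]
        if aggregator == "mean":
            px, py = xs.mean(), ys.mean()
        elif aggregator == "median":
            px, py = np.median(xs), np.median(ys)
        elif aggregator == "start":
            px, py = xs[0], ys[0]
        else:
            raise SpecError(f"unknown aggregator {aggregator!r}")
        d2 = (grid.positions_mm[:, 0] - px) ** 2 + (grid.positions_mm[:, 1] - py) ** 2
        idx[w] = int(np.argmin(d2))  # first minimum -> lowest index on ties
    return ChannelSelection(starts, idx, window_s)


def stitch_channel(rec: Recording, sel: ChannelSelection) -> Recording:
    """Concatenate, per selection window, the samples of the chosen electrode.

    The output is a single ventilatory channel of the same length as the
    input; window boundaries coincide with multiples of the selection
    window so downstream 5-s segmentation aligns 1:1 with selections.
    """
    n_per_win = int(round(sel.window_s * rec.rate_hz))
    if len(sel.electrode_index) * n_per_win != rec.n_samples:
        raise AlignmentError(
            f"{len(sel.electrode_index)} windows x {n_per_win} samples != "
            f"{rec.n_samples} recording samples"
        )
    if sel.electrode_index.max(initial=-1) >= rec.n_channels:
        raise AlignmentError("selection refers to a channel outside the recording")
    pieces = [
        rec.samples[ch, w * n_per_win : (w + 1) * n_per_win]
        for w, ch in enumerate(sel.electrode_index)
    ]
    return Recording(
        np.concatenate(pieces)[None, :],
        rate_hz=rec.rate_hz,
        channel_roles=["ventilatory"],
        start_time_s=rec.start_time_s,
    )


def average_speed(
    traj: Trajectory, window_s: float = SELECTION_WINDOW_S, duration_s: float | None = None
) -> np.ndarray:
    """Average swimming speed per window (mm/s).

    Sum of frame-to-frame Euclidean displacements within the window divided
    by the elapsed tracked time in the window.  Windows with fewer than two
    frames are undefined and reported as NaN.  Invariant under rigid
    rotation/translation of the trajectory.
    """
    dur = duration_s if duration_s is not None else traj.duration_s
    t0 = traj.times_s[0] if len(traj.times_s) else 0.0
    n_win = int(round(dur / window_s))
    out = np.full(max(n_win, 0), np.nan)
    for w in range(n_win):
        ws = t0 + w * window_s
        in_win = (traj.times_s >= ws) & (traj.times_s < ws + window_s)
        if w == n_win - 1:
            in_win |= traj.times_s == ws + window_s
        if in_win.sum() < 2:
            continue
        xs, ys, ts = traj.x_mm[in_win], traj.y_mm[in_win], traj.times_s[in_win]
        path = np.sum(np.hypot(np.diff(xs), np.diff(ys)))
        elapsed = ts[-1] - ts[0]
        if elapsed > 0:
            out[w] = path / elapsed
    return out
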