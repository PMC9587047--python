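"""Recordings, cohort metadata, and file input/output.

A :class:`Recording` is the in-memory container for every bioelectric
signal the package touches: ECG sampled at 1 kHz under restraint,
ventilatory/array channels at 500 Hz under free swimming, and the optical
ventilatory signal derived from gill-region video (mean ROI brightness at
100 fps).  Recordings round-trip through HDF5 (native) and wide CSV.

Cohort metadata carries the per-individual covariates used downstream by
the dose-response models: caffeine concentration (0, 1, 50 or 100 mg/L),
condition, sex, and the 72-h survival flag that gates inclusion.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import shapely

from .errors import DomainError, EmptyRoiError, FormatError, ShapeError

CHANNEL_ROLES = ("ecg", "ventilatory", "array")

#: sampling rates used in the experiments, Hz (ECG; array/ventilatory; video)
ECG_RATE_HZ = 1000.0
ARRAY_RATE_HZ = 500.0
RESTRAINT_VIDEO_FPS = 100.0
FREESWIM_VIDEO_FPS = 29.97


@dataclass
class Recording:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``.
    rate_hz
        Common sampling rate of all channels, Hz.
    channel_roles
        One role per channel, each in ``{"ecg", "ventilatory", "array"}``.
    start_time_s
        Time of the first sample.
    """

    samples: np.ndarray
    rate_hz: float
    channel_roles: Sequence[str]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise ShapeError("samples must be a (n_channels, n_samples) matrix with n_samples >= 1")
        if not self.rate_hz > 0:
            raise DomainError(f"rate_hz must be positive, got {self.rate_hz}")
        self.channel_roles = list(self.channel_roles)
        if len(self.channel_roles) != self.samples.shape[0]:
            raise ShapeError(
                f"{len(self.channel_roles)} roles for {self.samples.shape[0]} channels"
            )
        for role in self.channel_roles:
            if role not in CHANNEL_ROLES:
                raise FormatError(f"unknown channel role {role!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.rate_hz

    def channel(self, role: str) -> np.ndarray:
        """Return the first channel with the given role (1-D view)."""
        try:
            i = self.channel_roles.index(role)
        except ValueError:
            raise FormatError(f"recording has no {role!r} channel") from None
        return self.samples[i]


@dataclass(frozen=True)
class CohortMetadata:
    """Covariates for one individual fish."""

    individual_id: str
    concentration_mg_per_l: float
    condition: str  # "restraint" | "free_swimming"
    sex: str = "unknown"  # "M" | "F" | "unknown"
    survived_72h: bool = True
    anesthetic_ul_per_l: float = 260.0

    def __post_init__(self) -> None:
        if self.concentration_mg_per_l < 0:
            raise DomainError("concentration must be nonnegative")
        if self.condition not in ("restraint", "free_swimming"):
            raise FormatError(f"unknown condition {self.condition!r}")
        if self.sex not in ("M", "F", "unknown"):
            raise FormatError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class RoiPolygon:
    """Simple polygon in pixel coordinates (x = column, y = row)."""

    vertices: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ShapeError("polygon needs at least 3 vertices")
        if not shapely.Polygon(verts).is_valid:
            raise ShapeError("polygon must be simple (non-self-intersecting)")

    def as_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


# ---------------------------------------------------------------------------
# Recording file formats
#
# HDF5 (native): dataset "/signals" [channels x samples] with attrs
# "rate_hz", "roles", "start_time_s".
# CSV (wide): line 1 "rate_hz=<r>;start_time_s=<t>", line 2 the channel
# roles as column names "<role>:<index>", then one row per sample.
# ---------------------------------------------------------------------------


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording to HDF5 or CSV (inferred from suffix by default)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("signals", data=rec.samples)
            ds.attrs["rate_hz"] = rec.rate_hz
            ds.attrs["roles"] = list(rec.channel_roles)
            ds.attrs["start_time_s"] = rec.start_time_s
    elif fmt == "csv":
        with open(path, "w", newline="") as f:
            f.write(f"rate_hz={rec.rate_hz!r};start_time_s={rec.start_time_s!r}\n")
            w = _csv.writer(f)
            w.writerow(f"{role}:{i}" for i, role in enumerate(rec.channel_roles))
            for row in rec.samples.T:
                w.writerow(repr(float(v)) for v in row)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        If the rate/role metadata is missing.
    ShapeError
        If channels are ragged (CSV rows of unequal length).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "signals" not in f:
                raise FormatError("HDF5 recording must contain a /signals dataset")
            ds = f["signals"]
            if "rate_hz" not in ds.attrs or "roles" not in ds.attrs:
                raise FormatError("missing rate_hz/roles attributes on /signals")
            roles = [r.decode() if isinstance(r, bytes) else str(r) for r in ds.attrs["roles"]]
            return Recording(
                samples=ds[...],
                rate_hz=float(ds.attrs["rate_hz"]),
                channel_roles=roles,
                start_time_s=float(ds.attrs.get("start_time_s", 0.0)),
            )
    if fmt == "csv":
        with open(path, newline="") as f:
            meta_line = f.readline().strip()
            meta = {}
            for item in meta_line.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    meta[k.strip()] = v.strip()
            if "rate_hz" not in meta:
                raise FormatError("CSV recording header must declare rate_hz")
            reader = _csv.reader(f)
            try:
                header = next(reader)
            except StopIteration:
                raise FormatError("CSV recording has no channel header") from None
            roles = [col.rsplit(":", 1)[0] for col in header]
            rows = []
            for row in reader:
                if not row:
                    continue
                if len(row) != len(roles):
                    raise ShapeError("ragged CSV row: channels of unequal length")
                rows.append([float(v) for v in row])
            if not rows:
                raise ShapeError("CSV recording has no samples")
            return Recording(
                samples=np.asarray(rows).T,
                rate_hz=float(meta["rate_hz"]),
                channel_roles=roles,
                start_time_s=float(meta.get("start_time_s", 0.0)),
            )
    raise FormatError(f"unknown recording format {fmt!r}")


def roi_mean_brightness(
    frames: np.ndarray, roi: RoiPolygon, frame_rate_hz: float
) -> Recording:
    """Mean brightness inside a polygonal ROI, per frame.

    This is the optical ventilatory signal under restraint: an ROI is drawn
    around the gill area and the mean pixel value inside it tracks opercular
    movement.  A pixel belongs to the ROI iff its center (col + 0 offset,
    i.e. integer coordinates ``(x=j, y=i)``) is covered by the polygon;
    boundary pixels are included.

    Returns a single-channel ventilatory :class:`Recording` at the frame rate.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ShapeError("frames must be (n_frames, height, width)")
    n, h, w = frames.shape
    poly = roi.as_shapely()
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise ShapeError("ROI extends beyond frame bounds")
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    pts = shapely.points(jj.ravel(), ii.ravel())
    inside = shapely.covers(poly, pts).reshape(h, w)
    if not inside.any():
        raise EmptyRoiError("polygon encloses no pixel centers")
    sig = frames[:, inside].mean(axis=1)
    return Recording(sig[None, :], rate_hz=frame_rate_hz, channel_roles=["ventilatory"])


def filter_cohort(meta: Sequence[CohortMetadata]) -> list[CohortMetadata]:
    """Keep only individuals that survived 72 h after the experiment.

    This is the study's sole inclusion criterion; it is applied before any
    analysis stage (one restrained fish in the 50 mg/L group failed it,
    reducing that dose from 120 to 96 segments).  Order is preserved and
    the operation is idempotent.
    """
    return [m for m in meta if m.survived_72h]


def write_metadata(meta: Sequence[CohortMetadata], path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = _csv.writer(f)
        w.writerow(["individual_id", "condition", "concentration_mg_per_l", "sex", "survived_72h"])
        for m in meta:
            w.writerow([m.individual_id, m.condition, m.concentration_mg_per_l, m.sex,
                        str(m.survived_72h).lower()])


def read_metadata(path: str | Path) -> list[CohortMetadata]:
    out = []
    with open(path, newline="") as f:
        reader = _csv.DictReader(f)
        required = {"individual_id", "condition", "concentration_mg_per_l", "survived_72h"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"metadata CSV must have columns {sorted(required)}")
        for row in reader:
            out.append(
                CohortMetadata(
                    individual_id=row["individual_id"],
                    condition=row["condition"],
                    concentration_mg_per_l=float(row["concentration_mg_per_l"]),
                    sex=row.get("sex", "unknown") or "unknown",
                    survived_72h=row["survived_72h"].strip().lower() in ("true", "1", "yes"),
                )
            )
    ids = [m.individual_id for m in out]
    if len(ids) != len(set(ids)):
        raise FormatError("individual_id must be unique within a cohort")
    return out


def read_tracking(path: str | Path):
    """Read a fish trajectory from a ``time_s,x_mm,y_mm`` CSV.

    Timestamps must be strictly increasing.  Returns a
    :class:`~gillwave.kinematics.Trajectory`.
    """
    from .kinematics import Trajectory

    path = Path(path)
    times, xs, ys = [], [], []
    with open(path, newline="") as f:
        reader = _csv.DictReader(f)
        required = {"time_s", "x_mm", "y_mm"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError("tracking CSV must have columns time_s,x_mm,y_mm")
        for row in reader:
            times.append(float(row["time_s"]))
            xs.append(float(row["x_mm"]))
            ys.append(float(row["y_mm"]))
    t = np.asarray(times)
    if len(t) == 0:
        raise FormatError("empty tracking file")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise FormatError("tracking timestamps must be strictly increasing")
    return Trajectory(times_s=t, x_mm=np.asarray(xs), y_mm=np.asarray(ys))


def read_tracking_pose(
    path: str | Path,
    bodypart: str,
    px_to_mm: float,
    frame_rate_hz: float = FREESWIM_VIDEO_FPS,
):
    """Import shim for three-header-row markerless-pose CSV exports.

    Pose-estimation software writes a scorer/bodyparts/coords header; this
    selects one named body part, converts pixel coordinates to mm with the
    supplied scale factor, and derives timestamps from the frame rate.
    """
    import pandas as pd

    from .kinematics import Trajectory

    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    cols = {c[1] for c in df.columns}
    if bodypart not in cols:
        raise FormatError(f"body part {bodypart!r} not in tracking file (has {sorted(cols)})")
    sub = df.xs(bodypart, axis=1, level=1)
    x = sub.xs("x", axis=1, level=1).to_numpy().ravel() * px_to_mm
    y = sub.xs("y", axis=1, level=1).to_numpy().ravel() * px_to_mm
    t = np.arange(len(x)) / frame_rate_hz
    return Trajectory(times_s=t, x_mm=x, y_mm=y, frame_rate_hz=frame_rate_hz)
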