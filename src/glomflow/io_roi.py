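"""Movie, ROI and trace containers plus TIFF/YAML/CSV round-trip I/O.

Conventions shared by every analysis module:

* pixel coordinates are 0-based ``(row, col)`` with row 0 at the image top;
* time windows are half-open ``[t_start, t_end)`` in seconds;
* frame *n* is assigned the midpoint time ``(n + 0.5) * dt``;
* ROI label 0 is reserved for background.

The frame interval ``dt`` travels as sidecar metadata (YAML) rather than
being parsed from TIFF tags, so round trips are bit-exact regardless of the
writing software's tag dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Movie",
    "RoiSet",
    "TraceSet",
    "read_movie",
    "write_movie",
    "read_roiset",
    "write_roiset",
    "extract_traces",
    "frame_times",
    "window_slice",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected layout."""


@dataclass(frozen=True)
class Movie:
    """A fluorescence time series: ``frames[t, row, col]`` in counts.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), finite and non-negative, T >= 2.
    frame_interval
        Seconds between consecutive frames (dt > 0). The nominal
        acquisition here is 5 Hz, i.e. dt = 0.2 s.
    """

    frames: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames (no time axis otherwise)")
        if not np.isfinite(frames).all():
            raise ValueError("frames contain non-finite values")
        if (frames < 0).any():
            raise ValueError("fluorescence counts must be >= 0")
        if not (self.frame_interval > 0):
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame midpoint times in seconds."""
        return frame_times(self.n_frames, self.frame_interval)


def frame_times(n_frames: int, dt: float) -> np.ndarray:
    """Midpoint time stamps ``(n + 0.5) * dt`` for frames 0..n_frames-1."""
    return (np.arange(n_frames) + 0.5) * dt


def window_slice(n_frames: int, dt: float, window: tuple[float, float]) -> np.ndarray:
    """Indices of frames whose midpoint lies in the half-open window [t0, t1)."""
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError(f"empty or inverted window {window}")
    t = frame_times(n_frames, dt)
    return np.flatnonzero((t >= t0) & (t < t1))


@dataclass(frozen=True)
class RoiSet:
    """Integer-labelled ROI image; label 0 is background.

    ``names`` maps each nonzero label to a human-readable string. Every
    named label must occur in the image.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"labels must be H x W, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int32)
        if (labels < 0).any():
            raise ValueError("ROI labels must be >= 0")
        present = set(np.unique(labels).tolist()) - {0}
        names = dict(self.names) if self.names else {int(k): f"roi{int(k)}" for k in sorted(present)}
        if 0 in names:
            raise ValueError("label 0 is reserved for background and cannot be named")
        missing = set(names) - present
        if missing:
            raise ValueError(f"named labels absent from the image: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "names", names)

    @property
    def label_values(self) -> list[int]:
        return sorted(self.names)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class TraceSet:
    """Per-ROI mean-fluorescence traces, one column per named ROI."""

    values: np.ndarray  # (T, n_rois)
    names: list[str]
    frame_interval: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("trace values must be T x n_rois")
        if values.shape[1] != len(self.names):
            raise ValueError("one name per trace column required")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", list(self.names))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return frame_times(self.n_frames, self.frame_interval)

    def trace(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# File I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_movie(movie: Movie, path: str | Path, *, dtype: str = "uint16") -> None:
    """Write a movie as a multi-page TIFF (one page per frame) plus a YAML
    sidecar carrying the frame interval.

    Counts are rounded to the requested integer dtype; values outside its
    range raise rather than silently clipping.
    """
    path = Path(path)
    frames = np.round(movie.frames)
    info = np.iinfo(np.dtype(dtype))
    if frames.min() < info.min or frames.max() > info.max:
        raise ValueError(
            f"counts in [{frames.min():g}, {frames.max():g}] do not fit dtype {dtype}"
        )
    tifffile.imwrite(path, frames.astype(dtype), photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump({"frame_interval_s": float(movie.frame_interval)}, fh)


def read_movie(path: str | Path, frame_interval: float | None = None) -> Movie:
    """Read a multi-page TIFF movie.

    ``frame_interval`` may be given explicitly; otherwise the YAML sidecar
    written by :func:`write_movie` is consulted.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise FormatError(f"ragged page shapes in {path.name}: {sorted(shapes)}")
        frames = tif.asarray()
    if frames.ndim == 2:
        raise FormatError(f"{path.name} has a single page; a movie needs a time axis")
    if frames.ndim != 3:
        raise FormatError(f"{path.name} is not a T x H x W stack (shape {frames.shape})")
    if frame_interval is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(
                f"no frame interval given and no sidecar {sidecar.name}; pass frame_interval"
            )
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        frame_interval = float(meta["frame_interval_s"])
    return Movie(frames=np.asarray(frames, dtype=float), frame_interval=frame_interval)


def write_roiset(rois: RoiSet, path: str | Path) -> None:
    """Write ROI labels as a 16-bit integer TIFF plus a YAML name sidecar."""
    path = Path(path)
    tifffile.imwrite(path, rois.labels.astype(np.uint16), photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump({"names": {int(k): v for k, v in rois.names.items()}}, fh)


def read_roiset(path: str | Path) -> RoiSet:
    path = Path(path)
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise FormatError(f"{path.name} is not a 2-D label image (shape {labels.shape})")
    names: dict[int, str] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        names = {int(k): str(v) for k, v in (meta.get("names") or {}).items()}
    return RoiSet(labels=labels.astype(np.int32), names=names)


def extract_traces(movie: Movie, rois: RoiSet) -> TraceSet:
    """Unweighted per-frame mean over each named ROI's pixels.

    Raises if an ROI mask is empty or the ROI image does not match the movie
    frame shape. The result is independent of pixel enumeration order.
    """
    if rois.labels.shape != movie.frame_shape:
        raise ValueError(
            f"ROI shape {rois.labels.shape} does not match frames {movie.frame_shape}"
        )
    names: list[str] = []
    columns: list[np.ndarray] = []
    for label in rois.label_values:
        mask = rois.mask(label)
        if not mask.any():
            raise ValueError(f"ROI '{rois.names[label]}' (label {label}) has an empty mask")
        names.append(rois.names[label])
        columns.append(movie.frames[:, mask].mean(axis=1))
    return TraceSet(
        values=np.column_stack(columns), names=names, frame_interval=movie.frame_interval
    )
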