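"""Pearson correlation analyses: ROI matrices, seed maps, power titration.

All correlations use the sample-normalised Pearson coefficient

    rho(A, B) = 1/(N-1) * sum_i ((A_i - mu_A)/sigma_A) * ((B_i - mu_B)/sigma_B)

with sigma the (N-1)-normalised sample standard deviation, evaluated over
the frames of a half-open time window.  Zero-variance traces or pixels are
flagged undefined rather than silently mapped to 0 or NaN — background
pixels of noiseless recordings are common and a fabricated "r = 0" would
be indistinguishable from a measured decorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_roi import Movie, RoiSet, window_slice
from .synthetic import StimulusProtocol

__all__ = [
    "CorrelationMatrix",
    "SeedCorrelationMap",
    "ZeroVarianceError",
    "pearson",
    "correlation_matrix",
    "seed_map",
    "titration_analysis",
]


class ZeroVarianceError(ValueError):
    """A correlation was requested against a constant trace."""


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length traces (N >= 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"traces must be 1-D of equal length, got {a.shape} and {b.shape}")
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    sa = a.std(ddof=1)
    sb = b.std(ddof=1)
    if sa == 0 or sb == 0:
        raise ZeroVarianceError("correlation undefined for a zero-variance trace")
    z = ((a - a.mean()) / sa) * ((b - b.mean()) / sb)
    return float(z.sum() / (n - 1))


@dataclass(frozen=True)
class CorrelationMatrix:
    """ROI x ROI Pearson matrix over a time window.

    ``defined`` flags rows/columns backed by nonzero-variance traces;
    entries involving an undefined ROI are NaN and excluded from the
    symmetry/unit-diagonal guarantees.
    """

    values: np.ndarray
    names: list[str]
    window: tuple[float, float]
    n_frames: int
    defined: np.ndarray  # bool per ROI

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        d = np.asarray(self.defined, dtype=bool)
        k = len(self.names)
        if v.shape != (k, k) or d.shape != (k,):
            raise ValueError("matrix/name/flag sizes disagree")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "defined", d)
        object.__setattr__(self, "names", list(self.names))

    def mean_offdiagonal(self) -> float:
        """Mean of defined off-diagonal entries (each unordered pair once)."""
        k = len(self.names)
        iu = np.triu_indices(k, 1)
        vals = self.values[iu]
        ok = self.defined[iu[0]] & self.defined[iu[1]]
        if not ok.any():
            raise ZeroVarianceError("no defined off-diagonal entries")
        return float(vals[ok].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def correlation_matrix(traces, window: tuple[float, float] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson matrix of a (Dff)TraceSet over a half-open window.

    ROIs with zero temporal variance inside the window are flagged
    undefined (NaN row/column except the unit diagonal).
    """
    values = traces.values
    dt = traces.frame_interval
    if window is None:
        window = (0.0, values.shape[0] * dt)
    idx = window_slice(values.shape[0], dt, window)
    if idx.size < 3:
        raise ValueError(f"window {window} selects {idx.size} frames; need >= 3")
    seg = values[idx]
    k = seg.shape[1]
    sd = seg.std(axis=0, ddof=1)
    defined = sd > 0
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    z = np.zeros_like(seg)
    z[:, defined] = (seg[:, defined] - seg[:, defined].mean(axis=0)) / sd[defined]
    sub = (z[:, defined].T @ z[:, defined]) / (idx.size - 1)
    np.fill_diagonal(sub, 1.0)
    out[np.ix_(defined, defined)] = sub
    return CorrelationMatrix(
        values=out, names=list(traces.names), window=tuple(window), n_frames=int(idx.size),
        defined=defined,
    )


@dataclass(frozen=True)
class SeedCorrelationMap:
    """Per-pixel Pearson r of each pixel trace against a seed trace."""

    values: np.ndarray  # H x W, NaN where undefined
    seed: tuple[int, int]
    window: tuple[float, float]
    undefined_mask: np.ndarray  # bool H x W: zero temporal variance

    def mean_over(self, mask: np.ndarray, absolute: bool = False) -> float:
        """Mean (or mean absolute) r over the defined pixels of a mask."""
        ok = np.asarray(mask, dtype=bool) & ~self.undefined_mask
        if not ok.any():
            raise ZeroVarianceError("no defined pixels under the mask")
        vals = self.values[ok]
        return float(np.abs(vals).mean() if absolute else vals.mean())


def seed_map(
    movie: Movie,
    seed: tuple[int, int],
    window: tuple[float, float] | None = None,
    smoothing: float | None = None,
    seed_radius: int = 0,
) -> SeedCorrelationMap:
    """Seed-based pixelwise correlation map.

    Correlates every pixel's trace with the seed pixel's trace over the
    frames of the half-open window.  Optional Gaussian pre-smoothing
    (``smoothing`` = spatial sigma in px) is applied identically to every
    frame — seed included — before correlating; ``seed_radius`` > 0
    averages a disc of pixels around the seed into the reference trace.

    Pearson r is invariant to per-pixel affine rescaling, so raw counts and
    dF/F movies give identical maps.
    """
    h, w = movie.frame_shape
    if not (0 <= seed[0] < h and 0 <= seed[1] < w):
        raise ValueError(f"seed {seed} outside frame {movie.frame_shape}")
    if window is None:
        window = (0.0, movie.duration)
    idx = window_slice(movie.n_frames, movie.frame_interval, window)
    if idx.size < 3:
        raise ValueError(f"window {window} selects {idx.size} frames; need >= 3")
    frames = movie.frames[idx]
    if smoothing is not None and smoothing > 0:
        frames = gaussian_filter(frames, sigma=(0, smoothing, smoothing), mode="nearest")

    if seed_radius > 0:
        rr, cc = np.ogrid[:h, :w]
        disc = (rr - seed[0]) ** 2 + (cc - seed[1]) ** 2 <= seed_radius**2
        seed_trace = frames[:, disc].mean(axis=1)
    else:
        seed_trace = frames[:, seed[0], seed[1]]
    s_sd = seed_trace.std(ddof=1)
    if s_sd == 0:
        raise ZeroVarianceError(f"seed pixel {seed} has zero temporal variance")

    n = idx.size
    flat = frames.reshape(n, -1)
    sd = flat.std(axis=0, ddof=1)
    undefined = (sd == 0).reshape(h, w)
    zs = (seed_trace - seed_trace.mean()) / s_sd
    r = np.full(flat.shape[1], np.nan)
    ok = sd > 0
    zp = (flat[:, ok] - flat[:, ok].mean(axis=0)) / sd[ok]
    r[ok] = zp.T @ zs / (n - 1)
    return SeedCorrelationMap(
        values=r.reshape(h, w), seed=tuple(seed), window=tuple(window),
        undefined_mask=undefined,
    )


def titration_analysis(
    movie: Movie,
    protocol: StimulusProtocol,
    rois: RoiSet,
    r_threshold: float = 0.7,
    smoothing: float | None = 3.0,
    window_length: float | None = None,
) -> pd.DataFrame:
    """Activated area and activated-ROI set per titration event.

    All events must share one target (the titration point).  For each event
    a seed map is computed at the target over ``[onset + dt, onset + dt +
    window_length)`` (stimulus frame excluded; the window defaults to the
    inter-stimulus interval) and the analysis reports the number of pixels
    with r >= ``r_threshold`` plus the set of ROIs whose mean map value
    reaches the threshold.
    """
    targets = {e.target for e in protocol.events}
    if len(targets) != 1:
        raise ValueError(f"titration events must share one target, got {sorted(targets)}")
    (target,) = targets
    dt = movie.frame_interval
    onsets = [e.onset_time for e in protocol.events]
    if window_length is None:
        gaps = np.diff(onsets)
        window_length = float(gaps.min()) - dt if gaps.size else movie.duration - onsets[0] - dt
    rows = []
    for ei, event in enumerate(protocol.events):
        w = (event.onset_time + dt, event.onset_time + dt + window_length)
        if ei + 1 < len(onsets) and w[1] > onsets[ei + 1] + dt / 2:
            raise ValueError("per-event windows overlap; shorten window_length")
        smap = seed_map(movie, target, window=w, smoothing=smoothing)
        area = int(np.nansum(smap.values >= r_threshold))
        activated = {
            rois.names[label]
            for label in rois.label_values
            if smap.mean_over(rois.mask(label)) >= r_threshold
        }
        rows.append(
            {
                "event": ei,
                "power_mw": event.power,
                "activated_area_px": area,
                "activated_rois": tuple(sorted(activated)),
            }
        )
    return pd.DataFrame(rows)
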