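"""Continuous Morlet wavelet transform, cross-wavelet coherence and phase.

The mother wavelet is the complex Morlet

    psi0(eta) = pi**(-1/4) * exp(-eta**2 / 2) * exp(i * omega0 * eta)

with dimensionless frequency ``omega0`` (default 5) and dimensionless time
``eta = t / s`` for scale ``s``.  For a record of N samples x_n with step
dt the transform is the discrete convolution

    W_n(s) = sqrt(dt / s) * sum_n' x_n' * psi0*[(n' - n) * dt / s]

evaluated for all n at once in the Fourier domain after zero-padding to
the next power of two.  Magnitude-squared coherence of two records follows
the standard smoothed-cross-spectrum estimator

    R2_n(s) = |S(s^-1 W^XY)|**2 / ( S(s^-1 |W^X|**2) * S(s^-1 |W^Y|**2) )

with W^XY = W^X conj(W^Y) and S a smoothing operator acting in time (a
Gaussian of standard deviation s, the wavelet's own footprint) and in
scale (a boxcar of 0.6 octaves).  Because the same positive-weight
smoother appears in numerator and denominator, Cauchy-Schwarz bounds R2 by
1 and self-coherence is identically 1 wherever defined.

The phase of the smoothed cross-spectrum is reported for the ordered pair
(x, y) with the convention that a positive phase means x leads y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

__all__ = [
    "WaveletParams",
    "WaveletSpectrum",
    "CoherenceMap",
    "PhaseField",
    "cwt_morlet",
    "smooth",
    "wavelet_coherence",
    "phase_arrows",
    "cone_of_influence",
    "circular_mean",
]


@dataclass(frozen=True)
class WaveletParams:
    """Morlet transform configuration.

    ``scales`` may be given explicitly (strictly increasing, in seconds);
    otherwise a dyadic grid is built from ``smallest_scale`` (default 2*dt)
    up to N*dt/4 with ``voices_per_octave`` scales per octave.
    """

    omega0: float = 5.0
    voices_per_octave: int = 12
    smallest_scale: float | None = None
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.omega0 > 0):
            raise ValueError("omega0 must be > 0")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")
        if self.scales is not None:
            s = np.asarray(self.scales, dtype=float)
            if s.ndim != 1 or s.size < 1 or (np.diff(s) <= 0).any():
                raise ValueError("scales must be strictly increasing and 1-D")
            object.__setattr__(self, "scales", s)

    @property
    def fourier_factor(self) -> float:
        """Wavelength-to-scale ratio: lambda = fourier_factor * s."""
        return 4 * np.pi / (self.omega0 + np.sqrt(2 + self.omega0**2))

    def frequency_of_scale(self, scales: np.ndarray) -> np.ndarray:
        return 1.0 / (self.fourier_factor * np.asarray(scales, dtype=float))

    def scale_of_frequency(self, frequency: float) -> float:
        return 1.0 / (self.fourier_factor * frequency)

    def build_scales(self, n: int, dt: float) -> np.ndarray:
        if self.scales is not None:
            if self.scales[0] < 2 * dt:
                raise ValueError(f"smallest scale {self.scales[0]} below 2*dt = {2 * dt}")
            if self.scales[-1] > n * dt:
                raise ValueError(f"scale {self.scales[-1]} exceeds the record length {n * dt}")
            return self.scales
        s0 = self.smallest_scale if self.smallest_scale is not None else 2 * dt
        if s0 < 2 * dt:
            raise ValueError(f"smallest_scale {s0} below 2*dt = {2 * dt}")
        s_max = n * dt / 4
        if s_max < s0:
            raise ValueError("record too short for the requested smallest scale")
        n_octaves = np.log2(s_max / s0)
        j = np.arange(int(np.floor(n_octaves * self.voices_per_octave)) + 1)
        return s0 * 2.0 ** (j / self.voices_per_octave)


def cone_of_influence(n: int, dt: float) -> np.ndarray:
    """Maximum reliable scale per time index.

    The Morlet envelope e-folds over sqrt(2)*s in time, so a sample closer
    than sqrt(2)*s to either record boundary is edge-contaminated at scale
    s; the cone is the largest uncontaminated scale, maximal at the record
    centre and vanishing toward both edges.
    """
    idx = np.arange(n)
    edge_distance = (np.minimum(idx, n - 1 - idx) + 0.5) * dt
    return edge_distance / np.sqrt(2.0)


@dataclass(frozen=True)
class WaveletSpectrum:
    coefficients: np.ndarray  # complex, N_times x N_scales
    scales: np.ndarray
    dt: float
    coi: np.ndarray  # per-time maximum reliable scale
    params: WaveletParams = field(default_factory=WaveletParams)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def frequencies(self) -> np.ndarray:
        return self.params.frequency_of_scale(self.scales)

    def inside_coi(self) -> np.ndarray:
        """Boolean N_times x N_scales mask of edge-safe cells."""
        return self.scales[None, :] <= self.coi[:, None]


def cwt_morlet(
    x: np.ndarray, dt: float, params: WaveletParams | None = None
) -> WaveletSpectrum:
    """Continuous Morlet wavelet transform of a real record.

    The record is mean-subtracted and zero-padded to the next power of two;
    the padding's reach is reflected in the cone of influence.
    """
    params = params or WaveletParams()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("record must be 1-D")
    n = x.size
    if n < 8:
        raise ValueError(f"record too short ({n} samples); need >= 8")
    if not np.isfinite(x).all():
        raise ValueError("record contains non-finite values")
    if not (dt > 0):
        raise ValueError("dt must be > 0")
    scales = params.build_scales(n, dt)

    npad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(x - x.mean(), npad)
    omega = 2 * np.pi * np.fft.fftfreq(npad, dt)
    coeff = np.empty((n, scales.size), dtype=complex)
    positive = omega > 0
    for j, s in enumerate(scales):
        # analytic Morlet in the frequency domain with the sqrt(dt/s)
        # time-domain normalisation folded in
        psi_hat = np.zeros(npad)
        psi_hat[positive] = (
            np.sqrt(2 * np.pi * s / dt)
            * np.pi**-0.25
            * np.exp(-0.5 * (s * omega[positive] - params.omega0) ** 2)
        )
        coeff[:, j] = np.fft.ifft(xhat * psi_hat)[:n]
    return WaveletSpectrum(
        coefficients=coeff, scales=scales, dt=dt, coi=cone_of_influence(n, dt), params=params
    )


def _smooth_real(field: np.ndarray, scales: np.ndarray, dt: float, voices: int) -> np.ndarray:
    out = np.empty_like(field)
    norm = np.empty_like(field)
    ones = np.ones(field.shape[0])
    for j, s in enumerate(scales):
        sigma = s / dt  # Gaussian std of s seconds, in samples
        out[:, j] = gaussian_filter1d(field[:, j], sigma, mode="constant", cval=0.0)
        norm[:, j] = gaussian_filter1d(ones, sigma, mode="constant", cval=0.0)
    out /= norm  # truncated-kernel renormalisation: constants are fixed points
    width = max(1, int(round(0.6 * voices)))
    if width > 1 and scales.size > 1:
        ones_s = np.ones(scales.size)
        num = uniform_filter1d(out, width, axis=1, mode="constant", cval=0.0)
        den = uniform_filter1d(ones_s, width, mode="constant", cval=0.0)
        out = num / den[None, :]
    return out


def smooth(
    field: np.ndarray,
    scales: np.ndarray,
    dt: float,
    voices_per_octave: int = 12,
) -> np.ndarray:
    """Smoothing operator S: Gaussian in time (std = s at each scale) then a
    boxcar of 0.6 octaves across scales, both renormalised at the edges so
    a constant field is a fixed point.  Accepts real or complex fields.
    """
    field = np.asarray(field)
    scales = np.asarray(scales, dtype=float)
    if field.ndim != 2 or field.shape[1] != scales.size:
        raise ValueError(f"field must be N_times x {scales.size}, got {field.shape}")
    if np.iscomplexobj(field):
        return _smooth_real(field.real.copy(), scales, dt, voices_per_octave) + 1j * _smooth_real(
            field.imag.copy(), scales, dt, voices_per_octave
        )
    return _smooth_real(field.astype(float), scales, dt, voices_per_octave)


@dataclass(frozen=True)
class CoherenceMap:
    """Time x scale magnitude-squared coherence with phase and cone."""

    r2: np.ndarray  # in [0, 1], NaN where undefined
    phase: np.ndarray  # radians in (-pi, pi]; positive: x leads y
    scales: np.ndarray
    dt: float
    coi: np.ndarray
    params: WaveletParams

    @property
    def frequencies(self) -> np.ndarray:
        return self.params.frequency_of_scale(self.scales)

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.r2.shape[0]) + 0.5) * self.dt

    def inside_coi(self) -> np.ndarray:
        return self.scales[None, :] <= self.coi[:, None]

    def mean_coherence_by_frequency(
        self, window: tuple[float, float] | None = None, coi_only: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """(frequencies, mean r2) over a time window, optionally restricted
        to the cone interior; frequencies with no valid cell are NaN."""
        sel = np.ones(self.r2.shape[0], dtype=bool)
        if window is not None:
            t = self.times
            sel = (t >= window[0]) & (t < window[1])
        valid = np.isfinite(self.r2) & sel[:, None]
        if coi_only:
            valid &= self.inside_coi()
        sums = np.where(valid, self.r2, 0.0).sum(axis=0)
        counts = valid.sum(axis=0)
        mean = np.full(self.scales.size, np.nan)
        ok = counts > 0
        mean[ok] = sums[ok] / counts[ok]
        return self.frequencies, mean

    def peak_frequency(
        self, window: tuple[float, float] | None = None, coi_only: bool = True
    ) -> float:
        """Frequency at which the (windowed, cone-interior) mean r2 peaks."""
        freqs, mean = self.mean_coherence_by_frequency(window, coi_only)
        if not np.isfinite(mean).any():
            raise ValueError("no valid coherence cells in the requested window")
        return float(freqs[np.nanargmax(mean)])


def wavelet_coherence(
    x: np.ndarray, y: np.ndarray, dt: float, params: WaveletParams | None = None
) -> CoherenceMap:
    """Smoothed magnitude-squared wavelet coherence of two records."""
    params = params or WaveletParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("records must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("coherence undefined for a zero-variance record")
    wx = cwt_morlet(x, dt, params)
    wy = cwt_morlet(y, dt, params)
    inv_s = 1.0 / wx.scales[None, :]
    voices = params.voices_per_octave
    num = smooth(inv_s * wx.coefficients * np.conj(wy.coefficients), wx.scales, dt, voices)
    den_x = smooth(inv_s * np.abs(wx.coefficients) ** 2, wx.scales, dt, voices)
    den_y = smooth(inv_s * np.abs(wy.coefficients) ** 2, wx.scales, dt, voices)
    den = den_x * den_y
    # cells whose smoothed auto-spectra are numerically indistinguishable
    # from zero carry no information; flag them undefined instead of
    # dividing floating-point dust by floating-point dust
    floor = 1e-12 * np.nanmax(den)
    valid = den > floor
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.abs(num) ** 2 / den
    r2 = np.where(valid, np.clip(r2, 0.0, 1.0), np.nan)
    phase = np.where(valid, np.angle(num), np.nan)
    return CoherenceMap(
        r2=r2, phase=phase, scales=wx.scales, dt=dt, coi=wx.coi, params=params
    )


def circular_mean(angles: np.ndarray) -> float:
    """Angle of the resultant vector: atan2(sum sin, sum cos).

    Raises if the resultant vanishes (the mean direction is undefined).
    """
    angles = np.asarray(angles, dtype=float)
    x = np.cos(angles).sum()
    y = np.sin(angles).sum()
    if np.hypot(x, y) < 1e-12 * max(1, angles.size):
        raise ValueError("zero resultant: circular mean undefined")
    return float(np.arctan2(y, x))


@dataclass(frozen=True)
class PhaseField:
    """Block-aggregated circular-mean phase arrows of a coherence map."""

    arrows: np.ndarray  # (time blocks, scale blocks), NaN where undefined
    block_size: tuple[int, int]
    time_edges: np.ndarray  # sample-index edges, len = n_time_blocks + 1
    scale_edges: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.arrows)


def phase_arrows(
    cmap: CoherenceMap,
    blocks: tuple[int, int] = (8, 4),
    r2_min: float = 0.5,
    coi_only: bool = True,
) -> PhaseField:
    """Circular-mean phase per time x scale block.

    ``blocks`` = (number of time blocks, number of scale blocks) tiling the
    map.  A block's arrow is the circular mean over phases of cells with
    r2 >= ``r2_min`` (and inside the cone when ``coi_only``); blocks with
    no qualifying cell or a vanishing resultant are flagged undefined.
    """
    nt, ns = cmap.r2.shape
    tb, sb = blocks
    if not (1 <= tb <= nt and 1 <= sb <= ns):
        raise ValueError(f"blocks {blocks} do not tile a {nt} x {ns} map")
    t_edges = np.linspace(0, nt, tb + 1).round().astype(int)
    s_edges = np.linspace(0, ns, sb + 1).round().astype(int)
    qualify = np.isfinite(cmap.r2) & (cmap.r2 >= r2_min)
    if coi_only:
        qualify &= cmap.inside_coi()
    arrows = np.full((tb, sb), np.nan)
    for i in range(tb):
        for j in range(sb):
            cell = qualify[t_edges[i] : t_edges[i + 1], s_edges[j] : s_edges[j + 1]]
            if not cell.any():
                continue
            phases = cmap.phase[t_edges[i] : t_edges[i + 1], s_edges[j] : s_edges[j + 1]][cell]
            try:
                arrows[i, j] = circular_mean(phases)
            except ValueError:
                pass  # zero resultant stays flagged undefined
    return PhaseField(
        arrows=arrows, block_size=(tb, sb), time_edges=t_edges, scale_edges=s_edges
    )
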