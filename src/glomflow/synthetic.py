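"""Synthetic antennal-lobe movie generator with ground truth.

Emulates the three study conditions the analysis modules are built for:

* point optogenetic stimulation (200 ms pulses, 20 s apart, 0.02-0.05 mW)
  of glomerular compartments in a 128 x 128, 5 Hz recording;
* power-dependent activation with a per-glomerulus threshold and lateral
  excitatory coupling that recruits neighbours at higher powers;
* spontaneous and stimulus-gated coupled oscillations in the 0.5-2 Hz band.

The latent dynamics are continuous-time in definition and sampled at frame
midpoints.  Per glomerulus the latent drive is

    u_k(t) = clip( d_k(t) + o_k(t) + sum_j C[k, j] * gate_j(t) * u_j(t) , -1, 1)

where ``d_k`` is the direct optical drive, ``o_k`` the optional intrinsic
oscillator and ``C`` the pairwise excitatory gain (zero diagonal).  The
drive is convolved with a peak-normalised difference-of-exponentials
calcium kernel ``k(t) = exp(-t/decay) - exp(-t/rise)`` and mapped to
fluorescence ``F = baseline * (1 + a * transient_amplitude / 100)``.

Direct drive: the stimulation footprint is an isotropic Gaussian in power;
a glomerulus is directly driven when the peak footprint power over its mask
reaches its activation threshold, with an amplitude that ramps linearly
from the threshold to a saturation power (clipped to 1).  The ramp gives
the graded neighbour recruitment seen in power-titration experiments while
keeping one threshold parameter per glomerulus.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_roi import Movie, RoiSet, frame_times

__all__ = [
    "Oscillator",
    "Glomerulus",
    "SyntheticScene",
    "StimulusEvent",
    "StimulusProtocol",
    "EventRecord",
    "GroundTruth",
    "InvalidSceneError",
    "build_two_glomerulus_scene",
    "build_six_region_scene",
    "simulate_movie",
    "coupled_oscillation_scenario",
    "titration_protocol",
    "scene_roiset",
    "calcium_kernel",
    "scene_from_spec",
    "protocol_from_spec",
    "protocol_to_spec",
]

#: latent-drive level above which a glomerulus counts as activated in the
#: ground-truth bookkeeping (direct or coupling-mediated)
ACTIVATION_DRIVE_MIN = 0.1


class InvalidSceneError(ValueError):
    """Scene geometry or parameters violate the generator's invariants."""


@dataclass(frozen=True)
class Oscillator:
    """Intrinsic sinusoidal activity of a glomerulus.

    ``amplitude`` is the observed peak dF/F percent of the oscillation; the
    generator pre-compensates the calcium-kernel gain at ``frequency`` so
    the rasterised movie actually oscillates with this amplitude.
    """

    frequency: float  # Hz
    amplitude: float  # dF/F percent, peak
    phase: float = 0.0  # rad


@dataclass(frozen=True)
class Glomerulus:
    name: str
    mask: np.ndarray  # bool H x W
    activation_threshold: float = 0.012  # mW
    transient_amplitude: float = 80.0  # dF/F percent at drive saturation
    rise_time: float = 0.3  # s
    decay_time: float = 25.0  # s
    oscillator: Oscillator | None = None

    def validate(self, frame_shape: tuple[int, int], frame_rate: float) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(frame_shape):
            raise InvalidSceneError(
                f"glomerulus '{self.name}': mask shape {mask.shape} != frame {frame_shape}"
            )
        if not mask.any():
            raise InvalidSceneError(f"glomerulus '{self.name}': empty mask")
        if not (0 < self.rise_time < self.decay_time):
            raise InvalidSceneError(
                f"glomerulus '{self.name}': need 0 < rise_time < decay_time, "
                f"got {self.rise_time}, {self.decay_time}"
            )
        if not (self.activation_threshold > 0):
            raise InvalidSceneError(f"glomerulus '{self.name}': activation_threshold must be > 0")
        if self.oscillator is not None:
            if not (0 < self.oscillator.frequency < frame_rate / 2):
                raise InvalidSceneError(
                    f"glomerulus '{self.name}': oscillator frequency "
                    f"{self.oscillator.frequency} Hz violates Nyquist at {frame_rate} Hz"
                )


@dataclass(frozen=True)
class SyntheticScene:
    """Glomerular geometry plus dynamical parameters generating a movie."""

    frame_shape: tuple[int, int]
    frame_rate: float
    glomeruli: tuple[Glomerulus, ...]
    baseline_level: float = 1000.0  # counts
    noise_sigma: float = 180.0  # counts, Gaussian read noise per pixel
    shot_noise: bool = False
    coupling_matrix: np.ndarray | None = None  # K x K, zero diagonal, >= 0
    coupling_gate: str = "always"  # "always" | "post_direct"
    saturation_power: float = 0.05  # mW: drive amplitude reaches 1 here
    rng_seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.glomeruli)
        coupling = self.coupling_matrix
        if coupling is None:
            coupling = np.zeros((k, k))
        coupling = np.asarray(coupling, dtype=float)
        object.__setattr__(self, "coupling_matrix", coupling)
        object.__setattr__(self, "glomeruli", tuple(self.glomeruli))
        object.__setattr__(self, "frame_shape", tuple(int(v) for v in self.frame_shape))
        self.validate()

    def validate(self) -> None:
        if not (self.frame_rate > 0):
            raise InvalidSceneError("frame_rate must be > 0")
        if not (self.baseline_level > 0):
            raise InvalidSceneError("baseline_level must be > 0")
        if self.noise_sigma < 0:
            raise InvalidSceneError("noise_sigma must be >= 0")
        if self.coupling_gate not in ("always", "post_direct"):
            raise InvalidSceneError(f"unknown coupling_gate '{self.coupling_gate}'")
        k = len(self.glomeruli)
        c = self.coupling_matrix
        if c.shape != (k, k):
            raise InvalidSceneError(f"coupling_matrix shape {c.shape} != ({k}, {k})")
        if (c < 0).any():
            raise InvalidSceneError("coupling_matrix entries must be >= 0")
        if np.diag(c).any():
            raise InvalidSceneError("coupling_matrix diagonal must be zero")
        occupancy = np.zeros(self.frame_shape, dtype=int)
        for glom in self.glomeruli:
            glom.validate(self.frame_shape, self.frame_rate)
            occupancy += np.asarray(glom.mask, dtype=bool)
        if (occupancy > 1).any():
            raise InvalidSceneError("glomerulus masks overlap")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.glomeruli]


@dataclass(frozen=True)
class StimulusEvent:
    onset_time: float  # s
    duration: float  # s
    power: float  # mW
    target: tuple[int, int]  # (row, col)


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered point-stimulation events plus the in-plane activation spread.

    ``footprint_sigma`` is the Gaussian sigma of the activation footprint in
    pixels.  At the nominal 1 um/pixel scale the default of 2 px gives a
    full width at half maximum of ~4.7 um, inside the 5 x 5 um stimulation
    spot of the imaging configuration this generator emulates.
    """

    events: tuple[StimulusEvent, ...]
    footprint_sigma: float = 2.0  # px

    def __post_init__(self) -> None:
        events = tuple(self.events)
        onsets = [e.onset_time for e in events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset_time")
        for e in events:
            if not (e.duration > 0):
                raise ValueError(f"event at t={e.onset_time}: duration must be > 0")
            if not (e.power > 0):
                raise ValueError(f"event at t={e.onset_time}: power must be > 0")
        if not (self.footprint_sigma > 0):
            raise ValueError("footprint_sigma must be > 0")
        object.__setattr__(self, "events", events)

    @property
    def end_time(self) -> float:
        if not self.events:
            return 0.0
        return max(e.onset_time + e.duration for e in self.events)


@dataclass(frozen=True)
class EventRecord:
    """Ground-truth activation bookkeeping for one stimulation event."""

    onset_time: float
    power: float
    target: tuple[int, int]
    direct: frozenset[str]
    activated: frozenset[str]

    @property
    def indirect(self) -> frozenset[str]:
        return self.activated - self.direct


@dataclass(frozen=True)
class GroundTruth:
    names: tuple[str, ...]
    events: tuple[EventRecord, ...]
    latent_dff: np.ndarray  # T x K, noiseless dF/F percent per glomerulus
    times: np.ndarray  # frame midpoints, s
    oscillation: dict | None = None  # {"frequency": Hz, "onset": s} for scenarios
    scene: "SyntheticScene | None" = None


# ---------------------------------------------------------------------------
# kernels and drives


def calcium_kernel(rise_time: float, decay_time: float, dt: float) -> np.ndarray:
    """Peak-normalised difference-of-exponentials kernel sampled at dt.

    Truncated where the decaying exponential falls below 1e-4 of its peak,
    so a single-frame unit drive produces a transient with unit peak.
    """
    t_end = decay_time * math.log(1e4)
    t = np.arange(0.0, t_end, dt)
    k = np.exp(-t / decay_time) - np.exp(-t / rise_time)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: rise_time must be < decay_time")
    return k / peak


def _kernel_gain(kernel: np.ndarray, frequency: float, dt: float) -> float:
    """Magnitude of the sampled kernel's transfer function at `frequency`."""
    n = np.arange(kernel.size)
    return float(abs(np.sum(kernel * np.exp(-2j * np.pi * frequency * n * dt))))


def _footprint_peak_power(event: StimulusEvent, sigma: float, mask: np.ndarray) -> float:
    rows, cols = np.nonzero(mask)
    d2 = (rows - event.target[0]) ** 2 + (cols - event.target[1]) ** 2
    return float(event.power * np.exp(-d2.min() / (2.0 * sigma**2)))


def _drive_amplitude(peak_power: float, threshold: float, saturation_power: float) -> float:
    """Graded direct-drive amplitude: 0 below threshold, linear ramp to 1."""
    if peak_power < threshold:
        return 0.0
    if saturation_power <= threshold:
        return 1.0
    return float(np.clip((peak_power - threshold) / (saturation_power - threshold), 0.0, 1.0))


def _solve_latent(
    direct: np.ndarray,
    osc: np.ndarray,
    coupling: np.ndarray,
    gate: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> np.ndarray:
    """Fixed point of u = clip(d + o + C @ (gate * u), -1, 1), per time sample."""
    u = np.clip(direct + osc, -1.0, 1.0)
    for _ in range(max_iter):
        u_new = np.clip(direct + osc + (coupling @ (gate * u)), -1.0, 1.0)
        if np.max(np.abs(u_new - u)) < tol:
            return u_new
        u = u_new
    return u


def simulate_movie(
    scene: SyntheticScene,
    protocol: StimulusProtocol,
    duration: float,
    seed: int | None = None,
) -> tuple[Movie, GroundTruth]:
    """Render a fluorescence movie from a scene and a stimulation protocol.

    Deterministic for fixed (scene, protocol, seed); ``seed`` defaults to
    ``scene.rng_seed``.  Raises if the recording does not cover the protocol
    or an oscillator violates the Nyquist limit.
    """
    scene.validate()
    if duration < protocol.end_time:
        raise ValueError(
            f"duration {duration} s does not cover the protocol (ends {protocol.end_time} s)"
        )
    dt = scene.frame_interval
    n_frames = int(round(duration * scene.frame_rate))
    if n_frames < 2:
        raise ValueError("duration too short: need at least 2 frames")
    times = frame_times(n_frames, dt)
    k_glom = len(scene.glomeruli)

    # direct drive (K x T) and per-event direct sets
    direct = np.zeros((k_glom, n_frames))
    event_direct: list[set[str]] = []
    for event in protocol.events:
        in_event = (times >= event.onset_time) & (times < event.onset_time + event.duration)
        hit: set[str] = set()
        for gi, glom in enumerate(scene.glomeruli):
            peak = _footprint_peak_power(event, protocol.footprint_sigma, glom.mask)
            if peak >= glom.activation_threshold:
                hit.add(glom.name)
                amp = _drive_amplitude(peak, glom.activation_threshold, scene.saturation_power)
                direct[gi, in_event] = np.maximum(direct[gi, in_event], amp)
        event_direct.append(hit)

    # intrinsic oscillators, kernel-gain compensated
    kernels = [calcium_kernel(g.rise_time, g.decay_time, dt) for g in scene.glomeruli]
    osc = np.zeros((k_glom, n_frames))
    osc_meta: dict | None = None
    for gi, glom in enumerate(scene.glomeruli):
        if glom.oscillator is None:
            continue
        o = glom.oscillator
        gain = _kernel_gain(kernels[gi], o.frequency, dt)
        latent_amp = (o.amplitude / glom.transient_amplitude) / gain
        osc[gi] = latent_amp * np.sin(2 * np.pi * o.frequency * times + o.phase)
        osc_meta = {"frequency": o.frequency, "onset": 0.0}

    # coupling gate per source glomerulus
    gate = np.ones((k_glom, n_frames))
    if scene.coupling_gate == "post_direct":
        gate[:] = 0.0
        for gi, glom in enumerate(scene.glomeruli):
            hits = [
                e.onset_time
                for e, hit in zip(protocol.events, event_direct)
                if glom.name in hit
            ]
            if hits:
                gate[gi, times >= min(hits)] = 1.0

    u = _solve_latent(direct, osc, scene.coupling_matrix, gate)
    # activation bookkeeping uses the stimulus-driven latent alone, so a
    # spontaneous oscillator cannot masquerade as an elicited response
    u_stim = _solve_latent(direct, np.zeros_like(osc), scene.coupling_matrix, gate)

    records = []
    for event, hit in zip(protocol.events, event_direct):
        in_event = (times >= event.onset_time) & (times < event.onset_time + event.duration)
        activated = {
            scene.glomeruli[gi].name
            for gi in range(k_glom)
            if in_event.any() and u_stim[gi, in_event].max() >= ACTIVATION_DRIVE_MIN
        }
        records.append(
            EventRecord(
                onset_time=event.onset_time,
                power=event.power,
                target=event.target,
                direct=frozenset(hit),
                activated=frozenset(activated | hit),
            )
        )

    # convolve with the calcium kernel and rasterise
    latent_dff = np.zeros((n_frames, k_glom))
    frames = np.full((n_frames, *scene.frame_shape), float(scene.baseline_level))
    for gi, glom in enumerate(scene.glomeruli):
        a = np.convolve(u[gi], kernels[gi])[:n_frames]
        dff = a * glom.transient_amplitude
        latent_dff[:, gi] = dff
        frames[:, np.asarray(glom.mask, dtype=bool)] = (
            scene.baseline_level * (1.0 + dff / 100.0)
        )[:, None]

    rng = np.random.default_rng(scene.rng_seed if seed is None else seed)
    if scene.shot_noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    if scene.noise_sigma > 0:
        frames = frames + rng.normal(0.0, scene.noise_sigma, size=frames.shape)
    frames = np.clip(frames, 0.0, None)

    movie = Movie(frames=frames, frame_interval=dt)
    truth = GroundTruth(
        names=tuple(scene.names),
        events=tuple(records),
        latent_dff=latent_dff,
        times=times,
        oscillation=osc_meta,
        scene=scene,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# scene builders


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def scene_roiset(scene: SyntheticScene) -> RoiSet:
    """Integer-labelled ROI image of a scene (label k = k-th glomerulus)."""
    labels = np.zeros(scene.frame_shape, dtype=np.int32)
    names = {}
    for gi, glom in enumerate(scene.glomeruli, start=1):
        labels[np.asarray(glom.mask, dtype=bool)] = gi
        names[gi] = glom.name
    return RoiSet(labels=labels, names=names)


def build_two_glomerulus_scene(seed: int = 0, **options) -> SyntheticScene:
    """Two adjacent disc glomeruli in a 128 x 128 frame at 5 Hz.

    Glomerulus 1 (the stimulation target) has a threshold below the lowest
    titration power (0.02 mW), glomerulus 2 above it, so a titration from
    0.02 to 0.05 mW starts perfectly confined and then recruits the
    neighbour through lateral coupling.  Centroids are jittered by the seed
    (+-3 px) so different seeds give different geometries.

    Keyword ``options`` override scene fields (e.g. ``noise_sigma=0``) or
    the builder's own geometry (``radius``, ``centers``, ``coupling``,
    ``thresholds``, ``amplitudes``, ``oscillators``).
    """
    rng = np.random.default_rng(seed)
    shape = options.pop("frame_shape", (128, 128))
    radius = options.pop("radius", 6.0)
    jitter = rng.integers(-3, 4, size=4)
    default_centers = (
        (64 + int(jitter[0]), 44 + int(jitter[1])),
        (64 + int(jitter[2]), 70 + int(jitter[3])),
    )
    centers = options.pop("centers", default_centers)
    thresholds = options.pop("thresholds", (0.012, 0.024))
    amplitudes = options.pop("amplitudes", (80.0, 80.0))
    oscillators = options.pop("oscillators", (None, None))
    coupling = options.pop("coupling", 0.2)
    rise = options.pop("rise_time", 0.3)
    decay = options.pop("decay_time", 25.0)
    if np.isscalar(coupling):
        coupling = [[0.0, float(coupling)], [float(coupling), 0.0]]

    glomeruli = tuple(
        Glomerulus(
            name=f"glomerulus{i + 1}",
            mask=_disc_mask(shape, centers[i], radius),
            activation_threshold=thresholds[i],
            transient_amplitude=amplitudes[i],
            rise_time=rise,
            decay_time=decay,
            oscillator=oscillators[i],
        )
        for i in range(2)
    )
    return SyntheticScene(
        frame_shape=shape,
        frame_rate=options.pop("frame_rate", 5.0),
        glomeruli=glomeruli,
        coupling_matrix=np.asarray(coupling, dtype=float),
        rng_seed=seed,
        **options,
    )


#: default titration power ladder, mW (10 stimuli, 0.02 -> 0.05)
TITRATION_POWERS = tuple(np.round(np.linspace(0.02, 0.05, 10), 6))


def titration_protocol(
    target: tuple[int, int],
    powers=TITRATION_POWERS,
    first_onset: float = 20.0,
    interval: float = 20.0,
    duration: float = 0.2,
    footprint_sigma: float = 2.0,
) -> StimulusProtocol:
    """Ascending-power point stimulation of one target, 200 ms / 20 s apart."""
    events = tuple(
        StimulusEvent(
            onset_time=first_onset + i * interval,
            duration=duration,
            power=float(p),
            target=target,
        )
        for i, p in enumerate(powers)
    )
    return StimulusProtocol(events=events, footprint_sigma=footprint_sigma)


def glomerulus_centroid(glom: Glomerulus) -> tuple[int, int]:
    rows, cols = np.nonzero(np.asarray(glom.mask, dtype=bool))
    return int(round(rows.mean())), int(round(cols.mean()))


def coupled_oscillation_scenario(
    seed: int = 0,
    duration: float = 80.0,
    stim_time: float = 40.0,
    frequency: float = 1.0,
) -> tuple[Movie, GroundTruth]:
    """Spontaneously oscillating glomerulus whose stimulation couples the
    neighbour into phase-locked oscillation.

    Before the 200 ms stimulus only glomerulus 1 oscillates (at
    ``frequency``, inside the 0.5-2 Hz band); the stimulus gates on strong
    lateral coupling, after which glomerulus 2 oscillates phase-locked to
    glomerulus 1.  Ground truth records the oscillation frequency and the
    stimulus onset.
    """
    scene = build_two_glomerulus_scene(
        seed,
        coupling=0.8,
        coupling_gate="post_direct",
        decay_time=5.0,
        amplitudes=(40.0, 40.0),
        oscillators=(
            Oscillator(frequency=frequency, amplitude=15.0, phase=0.0),
            None,
        ),
    )
    target = glomerulus_centroid(scene.glomeruli[0])
    # power just above glomerulus 1's threshold: the pulse gates on the
    # lateral coupling while barely perturbing the ongoing oscillation
    protocol = StimulusProtocol(
        events=(StimulusEvent(onset_time=stim_time, duration=0.2, power=0.013, target=target),),
        footprint_sigma=2.0,
    )
    movie, truth = simulate_movie(scene, protocol, duration)
    truth = replace(
        truth,
        oscillation={"frequency": frequency, "onset": stim_time},
    )
    return movie, truth


def build_six_region_scene(seed: int = 0, **options) -> SyntheticScene:
    """Six brain-region compartments (left/right AL, MB, posterior brain)
    with ipsilateral coupling from the antennal lobe stronger than the
    contralateral couplings, emulating a whole-brain stimulation recording.
    """
    rng = np.random.default_rng(seed)
    shape = options.pop("frame_shape", (128, 128))
    # (row, col): ALs frontal, MBs medial, posterior brain caudal
    base = {
        "AL_left": (100, 40),
        "AL_right": (100, 88),
        "MB_left": (64, 34),
        "MB_right": (64, 94),
        "PB_left": (28, 44),
        "PB_right": (28, 84),
    }
    radius = options.pop("radius", 11.0)
    names = list(base)
    jit = rng.integers(-2, 3, size=(len(names), 2))
    glomeruli = tuple(
        Glomerulus(
            name=name,
            mask=_disc_mask(shape, (base[name][0] + int(jit[i, 0]), base[name][1] + int(jit[i, 1])), radius),
            activation_threshold=0.012,
            transient_amplitude=60.0,
            rise_time=0.3,
            decay_time=10.0,
        )
        for i, name in enumerate(names)
    )
    # row k receives from column j; ipsilateral AL->MB strongest, then
    # AL->posterior, AL->contralateral MB, MB<->MB, AL<->AL weakest
    idx = {n: i for i, n in enumerate(names)}
    c = np.zeros((6, 6))

    def link(dst: str, src: str, w: float) -> None:
        c[idx[dst], idx[src]] = w

    for side, other in (("left", "right"), ("right", "left")):
        link(f"MB_{side}", f"AL_{side}", 0.60)
        link(f"PB_{side}", f"AL_{side}", 0.35)
        link(f"MB_{side}", f"AL_{other}", 0.25)
        link(f"MB_{side}", f"MB_{other}", 0.20)
        link(f"AL_{side}", f"AL_{other}", 0.15)
    coupling = options.pop("coupling", c)
    return SyntheticScene(
        frame_shape=shape,
        frame_rate=options.pop("frame_rate", 5.0),
        glomeruli=glomeruli,
        coupling_matrix=np.asarray(coupling, dtype=float),
        noise_sigma=options.pop("noise_sigma", 200.0),
        rng_seed=seed,
        **options,
    )


# ---------------------------------------------------------------------------
# YAML-friendly specs


def scene_from_spec(spec: dict) -> SyntheticScene:
    """Build a scene from a plain dict (parsed YAML/JSON).

    Glomeruli are given as discs: ``{name, center: [row, col], radius,
    threshold, amplitude, rise_time, decay_time, oscillator: {frequency,
    amplitude, phase}}``.
    """
    spec = copy.deepcopy(spec)
    shape = tuple(spec.get("frame_shape", (128, 128)))
    glomeruli = []
    for g in spec["glomeruli"]:
        osc = g.get("oscillator")
        glomeruli.append(
            Glomerulus(
                name=g["name"],
                mask=_disc_mask(shape, tuple(g["center"]), float(g["radius"])),
                activation_threshold=float(g.get("threshold", 0.012)),
                transient_amplitude=float(g.get("amplitude", 80.0)),
                rise_time=float(g.get("rise_time", 0.3)),
                decay_time=float(g.get("decay_time", 25.0)),
                oscillator=Oscillator(
                    frequency=float(osc["frequency"]),
                    amplitude=float(osc["amplitude"]),
                    phase=float(osc.get("phase", 0.0)),
                )
                if osc
                else None,
            )
        )
    return SyntheticScene(
        frame_shape=shape,
        frame_rate=float(spec.get("frame_rate", 5.0)),
        glomeruli=tuple(glomeruli),
        baseline_level=float(spec.get("baseline_level", 1000.0)),
        noise_sigma=float(spec.get("noise_sigma", 180.0)),
        shot_noise=bool(spec.get("shot_noise", False)),
        coupling_matrix=np.asarray(spec["coupling"], dtype=float)
        if "coupling" in spec
        else None,
        coupling_gate=spec.get("coupling_gate", "always"),
        saturation_power=float(spec.get("saturation_power", 0.05)),
        rng_seed=int(spec.get("rng_seed", 0)),
    )


def protocol_from_spec(spec: dict) -> StimulusProtocol:
    events = tuple(
        StimulusEvent(
            onset_time=float(e["onset"]),
            duration=float(e.get("duration", 0.2)),
            power=float(e["power"]),
            target=tuple(int(v) for v in e["target"]),
        )
        for e in spec["events"]
    )
    return StimulusProtocol(
        events=events, footprint_sigma=float(spec.get("footprint_sigma", 2.0))
    )


def protocol_to_spec(protocol: StimulusProtocol) -> dict:
    return {
        "footprint_sigma": protocol.footprint_sigma,
        "events": [
            {
                "onset": e.onset_time,
                "duration": e.duration,
                "power": e.power,
                "target": list(e.target),
            }
            for e in protocol.events
        ],
    }
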