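"""End-to-end experiment pipelines over real or synthetic recordings.

Three experiment kinds are orchestrated:

``whole_brain``
    Point stimulation of one antennal lobe while imaging region-level
    activity across the brain; per-repetition Pearson correlation matrices
    between region dF/F traces plus their arithmetic mean.
``titration``
    Repeated stimulation of one glomerulus with ascending laser power;
    per-power seed-based correlation maps, activated-pixel areas and
    activated-glomerulus sets.
``oscillation``
    A spontaneously oscillating glomerulus stimulated once; 10 s pre/post
    correlation matrices, wavelet coherence between the stimulated
    glomerulus and its neighbour, phase arrows and the frequency of
    maximal post-stimulus coherence.

Every run is a pure function of (inputs, config, seed) and, when an output
directory is given, writes its tables as CSV together with a manifest
(config hash, seed, library versions) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, response, synthetic
from .coherence import CoherenceMap, PhaseField, WaveletParams, phase_arrows, wavelet_coherence
from .connectivity import CorrelationMatrix
from .io_roi import extract_traces, read_movie, read_roiset

__all__ = [
    "ExperimentConfig",
    "WholeBrainResult",
    "TitrationResult",
    "OscillationResult",
    "run_whole_brain",
    "run_titration",
    "run_oscillation",
    "run_experiment",
]

log = logging.getLogger(__name__)

_KINDS = ("whole_brain", "titration", "oscillation")


@dataclass
class ExperimentConfig:
    """Validated configuration of one experiment run.

    Either the three input paths (movie/rois/protocol) or ``synthetic=True``
    (generate the experiment's default synthetic scene) must be given.
    """

    kind: str
    movie_path: str | None = None
    rois_path: str | None = None
    protocol_path: str | None = None
    synthetic: bool = True
    rng_seed: int = 0
    # analysis parameters
    response_window_s: float = 5.0
    correlation_window_s: float = 10.0
    r_threshold: float = 0.7
    seed_map_smoothing_px: float = 6.0
    titration_smoothing_px: float = 3.0
    n_repetitions: int = 3
    stimulus_power_mw: float = 0.025
    wavelet: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got '{self.kind}'")
        paths = (self.movie_path, self.rois_path, self.protocol_path)
        if not self.synthetic and any(p is None for p in paths):
            raise ValueError(
                "non-synthetic runs need movie_path, rois_path and protocol_path"
            )
        if self.synthetic and any(p is not None for p in paths):
            raise ValueError("give either synthetic=True or input paths, not both")
        if not (0 < self.r_threshold <= 1.01):
            raise ValueError(f"r_threshold out of range: {self.r_threshold}")
        if self.correlation_window_s <= 0 or self.response_window_s <= 0:
            raise ValueError("analysis windows must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def wavelet_params(self) -> WaveletParams:
        return WaveletParams(**self.wavelet)

    def digest(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _load_inputs(config: ExperimentConfig):
    movie = read_movie(config.movie_path)
    rois = read_roiset(config.rois_path)
    with open(config.protocol_path) as fh:
        protocol = synthetic.protocol_from_spec(yaml.safe_load(fh))
    return movie, rois, protocol


def _write_manifest(config: ExperimentConfig, out_dir: Path, outputs: list[str]) -> None:
    import glomflow

    manifest = {
        "config": asdict(config),
        "config_sha256": config.digest(),
        "rng_seed": config.rng_seed,
        "versions": {"glomflow": glomflow.__version__, "numpy": np.__version__},
        "outputs": outputs,
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def _pre_post_windows(
    onset: float, duration: float, dt: float, length: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """10 s-style windows flanking a stimulus, the stimulus frame excluded
    from both: pre = [onset - length, onset), post = [end + dt, end + dt + length)."""
    end = onset + duration
    return (onset - length, onset), (end + dt, end + dt + length)


# ---------------------------------------------------------------------------
# whole-brain connectivity


@dataclass(frozen=True)
class WholeBrainResult:
    per_repetition: tuple[CorrelationMatrix, ...]
    mean_matrix: pd.DataFrame  # arithmetic mean of per-repetition r
    traces: response.DffTraceSet
    summary: pd.DataFrame


def run_whole_brain(config: ExperimentConfig) -> WholeBrainResult:
    """Region-to-region correlation matrices under repeated AL stimulation.

    Per stimulus repetition, the Pearson matrix of region dF/F traces over
    ``[onset + dt, onset + correlation_window_s)`` is computed; the result
    also carries the arithmetic mean of the per-repetition matrices.
    """
    if config.kind != "whole_brain":
        raise ValueError(f"config.kind is '{config.kind}', expected 'whole_brain'")
    if config.synthetic:
        scene = synthetic.build_six_region_scene(config.rng_seed)
        target = synthetic.glomerulus_centroid(scene.glomeruli[0])  # left AL
        events = tuple(
            synthetic.StimulusEvent(
                onset_time=20.0 + 20.0 * i,
                duration=0.2,
                power=config.stimulus_power_mw,
                target=target,
            )
            for i in range(config.n_repetitions)
        )
        protocol = synthetic.StimulusProtocol(events=events)
        duration = events[-1].onset_time + 20.0
        movie, _ = synthetic.simulate_movie(scene, protocol, duration)
        rois = synthetic.scene_roiset(scene)
    else:
        movie, rois, protocol = _load_inputs(config)
    if len(rois.label_values) < 2:
        raise ValueError("whole-brain analysis needs >= 2 named ROIs")
    if not protocol.events:
        raise ValueError("whole-brain analysis needs >= 1 stimulus event")

    traces = extract_traces(movie, rois)
    dff_traces = response.dff(traces, protocol=protocol)
    summary = response.stimulus_locked_summary(dff_traces, protocol, config.response_window_s)
    dt = movie.frame_interval
    mats = []
    for event in protocol.events:
        window = (event.onset_time + dt, event.onset_time + dt + config.correlation_window_s)
        mats.append(connectivity.correlation_matrix(dff_traces, window))
        log.info("whole_brain: matrix over %s (%d frames)", window, mats[-1].n_frames)
    mean_values = np.mean([m.values for m in mats], axis=0)
    mean_matrix = pd.DataFrame(mean_values, index=mats[0].names, columns=mats[0].names)

    result = WholeBrainResult(
        per_repetition=tuple(mats), mean_matrix=mean_matrix, traces=dff_traces, summary=summary
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        outputs = []
        for i, m in enumerate(mats):
            name = f"correlation_rep{i}.csv"
            m.to_csv(out / name)
            outputs.append(name)
        mean_matrix.to_csv(out / "correlation_mean.csv")
        dff_traces.to_csv(out / "dff_traces.csv")
        summary.to_csv(out / "event_summary.csv", index=False)
        outputs += ["correlation_mean.csv", "dff_traces.csv", "event_summary.csv"]
        _write_manifest(config, out, outputs)
    return result


# ---------------------------------------------------------------------------
# power titration


@dataclass(frozen=True)
class TitrationResult:
    table: pd.DataFrame  # power, activated area, activated ROI set per event
    truth: synthetic.GroundTruth | None


def run_titration(config: ExperimentConfig) -> TitrationResult:
    """Activated area and glomerulus set versus stimulation power."""
    if config.kind != "titration":
        raise ValueError(f"config.kind is '{config.kind}', expected 'titration'")
    truth = None
    if config.synthetic:
        scene = synthetic.build_two_glomerulus_scene(config.rng_seed)
        target = synthetic.glomerulus_centroid(scene.glomeruli[0])
        protocol = synthetic.titration_protocol(target)
        duration = protocol.events[-1].onset_time + 20.0
        movie, truth = synthetic.simulate_movie(scene, protocol, duration)
        rois = synthetic.scene_roiset(scene)
    else:
        movie, rois, protocol = _load_inputs(config)
    table = connectivity.titration_analysis(
        movie,
        protocol,
        rois,
        r_threshold=config.r_threshold,
        smoothing=config.titration_smoothing_px,
    )
    log.info("titration: %d events, areas %s", len(table), table["activated_area_px"].tolist())
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        export = table.copy()
        export["activated_rois"] = export["activated_rois"].map(lambda s: ";".join(s))
        export.to_csv(out / "titration.csv", index=False)
        _write_manifest(config, out, ["titration.csv"])
    return TitrationResult(table=table, truth=truth)


# ---------------------------------------------------------------------------
# elicited oscillations


@dataclass(frozen=True)
class OscillationResult:
    pre_matrix: CorrelationMatrix
    post_matrix: CorrelationMatrix
    coherence: CoherenceMap
    phases: PhaseField
    peak_frequency_hz: float
    traces: response.DffTraceSet


def run_oscillation(config: ExperimentConfig) -> OscillationResult:
    """Pre/post correlation matrices plus wavelet coherence of the
    stimulated glomerulus against its neighbour, with the frequency of
    maximal post-stimulus coherence."""
    if config.kind != "oscillation":
        raise ValueError(f"config.kind is '{config.kind}', expected 'oscillation'")
    if config.synthetic:
        movie, truth = synthetic.coupled_oscillation_scenario(config.rng_seed)
        rois = synthetic.scene_roiset(truth.scene)
        onset = truth.oscillation["onset"]
        stim_duration = 0.2  # the scenario's 200 ms point stimulus
        protocol = synthetic.StimulusProtocol(
            events=(
                synthetic.StimulusEvent(
                    onset_time=onset, duration=stim_duration,
                    power=truth.events[0].power, target=truth.events[0].target,
                ),
            )
        )
    else:
        movie, rois, protocol = _load_inputs(config)
        onset = protocol.events[0].onset_time
        stim_duration = protocol.events[0].duration
    traces = extract_traces(movie, rois)
    dff_traces = response.dff(traces, protocol=protocol)
    dt = movie.frame_interval
    pre_w, post_w = _pre_post_windows(onset, stim_duration, dt, config.correlation_window_s)
    pre_m = connectivity.correlation_matrix(dff_traces, pre_w)
    post_m = connectivity.correlation_matrix(dff_traces, post_w)

    x = dff_traces.values[:, 0]
    y = dff_traces.values[:, 1]
    cmap = wavelet_coherence(x, y, dt, config.wavelet_params())
    peak = cmap.peak_frequency(window=post_w, coi_only=True)
    phases = phase_arrows(cmap, blocks=(8, 4), r2_min=0.5)
    log.info(
        "oscillation: pre r=%.3f post r=%.3f peak %.3f Hz",
        pre_m.mean_offdiagonal(), post_m.mean_offdiagonal(), peak,
    )
    result = OscillationResult(
        pre_matrix=pre_m,
        post_matrix=post_m,
        coherence=cmap,
        phases=phases,
        peak_frequency_hz=peak,
        traces=dff_traces,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pre_m.to_csv(out / "correlation_pre.csv")
        post_m.to_csv(out / "correlation_post.csv")
        dff_traces.to_csv(out / "dff_traces.csv")
        pd.DataFrame(
            cmap.r2, index=cmap.times, columns=cmap.frequencies
        ).to_csv(out / "coherence_r2.csv")
        pd.DataFrame({"time_s": cmap.times, "coi_scale_s": cmap.coi}).to_csv(
            out / "coi.csv", index=False
        )
        with open(out / "oscillation_summary.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "peak_frequency_hz": float(peak),
                    "pre_mean_offdiag_r": float(pre_m.mean_offdiagonal()),
                    "post_mean_offdiag_r": float(post_m.mean_offdiagonal()),
                },
                fh,
            )
        _write_manifest(
            config,
            out,
            [
                "correlation_pre.csv",
                "correlation_post.csv",
                "dff_traces.csv",
                "coherence_r2.csv",
                "coi.csv",
                "oscillation_summary.yaml",
            ],
        )
    return result


def run_experiment(config: ExperimentConfig):
    """Dispatch a config to the matching pipeline."""
    runner = {
        "whole_brain": run_whole_brain,
        "titration": run_titration,
        "oscillation": run_oscillation,
    }[config.kind]
    return runner(config)
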