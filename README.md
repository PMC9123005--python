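# glomflow

Analysis of two-photon calcium-imaging movies of the insect olfactory
system under spatially selective optogenetic stimulation — written for
experimenters who point a blue laser at single antennal-lobe glomeruli
(ChR2-XXL actuation, GCaMP6 readout) and want to quantify where and when
the elicited activity goes.

The package covers the full readout chain:

* **ΔF/F response extraction** — per-ROI traces normalised to a
  pre-stimulus baseline, `ΔF/F₀ [%] = 100 (F − F₀)/F₀`, with
  stimulus-locked peak/mean summaries;
* **Pearson correlation analyses** — region-to-region matrices, windowed
  pre/post-stimulus matrices, and seed-based pixelwise maps, all using the
  sample coefficient
  `ρ(A,B) = 1/(N−1) Σᵢ ((Aᵢ−μ_A)/σ_A)((Bᵢ−μ_B)/σ_B)`;
* **power-titration selectivity** — per-power seed maps, coherently
  activated area (pixels with r ≥ threshold) and activated-glomerulus
  sets;
* **Morlet wavelet coherence** — a from-scratch continuous wavelet
  transform with mother wavelet `ψ₀(η) = π^(−1/4) exp(−η²/2) exp(iω₀η)`
  (ω₀ = 5), cross-wavelet `W^XY = W^X W^Y*`, smoothed magnitude-squared
  coherence
  `R²ₙ(s) = |S(s⁻¹W^XY)|² / (S(s⁻¹|W^X|²) · S(s⁻¹|W^Y|²))`,
  cone of influence, and circular-mean phase arrows;
* **a synthetic antennal-lobe movie generator** — glomerular compartments
  with threshold-gated optical drive, lateral excitatory coupling,
  intrinsic 0.5–2 Hz oscillators, calcium-kernel dynamics and imaging
  noise, with per-event ground truth for validating every analysis above.

Movies are multi-page TIFF (one page per frame) with the frame interval in
a YAML sidecar; ROI sets are integer-labelled TIFF images; traces and
matrices export to CSV.

## Worked example

Run the elicited-oscillation experiment end to end on its synthetic
scenario (a spontaneously oscillating glomerulus is stimulated for 200 ms;
the stimulus couples the neighbouring glomerulus into phase-locked
oscillation):

```sh
$ printf 'kind: oscillation\nrng_seed: 0\n' > osc.yaml
$ glomflow run --config osc.yaml
{"peak_frequency_hz": 1.138, "pre_mean_offdiag_r": 0.211, "post_mean_offdiag_r": 0.847}
```

Before the stimulus the two glomeruli are essentially uncorrelated
(r ≈ 0.21 over the 10 s pre-window); afterwards they oscillate together
(r ≈ 0.85), and the wavelet coherence between their ΔF/F traces peaks at
≈ 1.1 Hz — recovering the scenario's 1 Hz generator inside the 0.5–2 Hz
band where such collective oscillations live.

The power-titration experiment shows threshold-confined activation
spreading with laser power:

```sh
$ printf 'kind: titration\nrng_seed: 0\n' > tit.yaml
$ glomflow run --config tit.yaml
 event  power_mw  activated_area_px             activated_rois
     0  0.020000                 97             (glomerulus1,)
     ...
     9  0.050000                422 (glomerulus1, glomerulus2)
```

At the lowest power (0.02 mW) the coherently activated area is confined to
the targeted glomerulus; increasing power recruits the neighbour through
lateral coupling, and the activated area grows monotonically.

The same pieces are available as a library:

```python
from glomflow import build_two_glomerulus_scene, simulate_movie, seed_map
from glomflow.synthetic import StimulusProtocol, StimulusEvent, glomerulus_centroid

scene = build_two_glomerulus_scene(seed=0)
target = glomerulus_centroid(scene.glomeruli[0])
protocol = StimulusProtocol(events=(StimulusEvent(5.0, 0.2, 0.02, target),))
movie, truth = simulate_movie(scene, protocol, duration=60.0)
smap = seed_map(movie, target, window=(5.2, 60.0), smoothing=6.0)
```

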