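# Methods

## Conventions

Pixels are 0-based `(row, col)` with row 0 at the top; time windows are
half-open `[t0, t1)`; frame *n* carries the midpoint time `(n + 0.5)·δt`.
The nominal acquisition is 128 × 128 pixels at 5 Hz (δt = 0.2 s), with a
scene pixel scale of ~1 µm. The frame interval is metadata (YAML sidecar
or explicit argument), never parsed from TIFF tags, so round trips are
bit-exact across writers.

## ΔF/F and stimulus-locked summaries

Responses are `ΔF/F₀ [%] = 100 (F − F₀)/F₀` with F₀ the per-ROI arithmetic
mean over a baseline window. The default baseline is every frame before
the first stimulus onset: a single global F₀ rather than per-event
re-baselining, because repeated stimulation at 20 s intervals rides on
persistent activity from earlier stimuli and re-baselining would hide that
accumulation. Baselines overlapping a stimulus log a warning but proceed;
non-positive baselines are an error (the normalisation is undefined).
An opt-in linear detrend (fit over the baseline window) is available but
off by default. The stimulus-locked summary reports the peak and mean ΔF/F
per ROI in `[onset, onset + 5 s)`; 5 s comfortably contains the transient
rise at these kinetics while staying inside the 20 s inter-stimulus gap.

## Correlation analyses

All correlations are the sample Pearson coefficient with (N−1)
normalisation, evaluated over the frames of a half-open window. Windowed
pre/post matrices default to 10 s on each side of the stimulus with the
stimulus frame excluded from both (whether that frame belongs to either
window is otherwise arbitrary). Zero-variance traces and pixels are
*flagged undefined* (NaN plus an explicit mask), never silently mapped to
0: background pixels of noiseless synthetic movies are common, and a
fabricated r = 0 would be indistinguishable from a measured
decorrelation.

Seed maps correlate every pixel trace against the stimulation pixel's
trace. Optional Gaussian pre-smoothing is applied identically to every
frame (seed included), and an optional disc-averaged seed (radius k
pixels) is available because the physical stimulation spot is a ≤ 5 × 5 µm
area rather than a point. Pearson r is invariant under per-pixel affine
rescaling, so maps computed on raw counts and on ΔF/F are identical; the
implementation therefore runs on raw counts.

Two smoothing defaults serve two different questions:

* **selectivity maps** (is activation confined to the target?) use
  σ = 6 px, about the glomerular radius. At the realistic per-pixel
  signal-to-noise of these recordings, single-pixel correlations
  understate the coherence of a compartment that genuinely shares one
  signal; smoothing at the structure scale recovers it.
* **titration area counting** (how far does coherent activation reach?)
  uses σ = 3 px, keeping the r ≥ 0.7 boundary steep so the counted area
  tracks the activation footprint rather than the smoothing kernel.

The titration analysis computes one seed map per stimulation event over
`[onset + δt, onset + δt + 19.8 s)` (the inter-stimulus interval, stimulus
frame excluded) and reports the count of pixels with r ≥ 0.7 plus the set
of ROIs whose mean map value reaches 0.7. The threshold is explicit and
configurable; 0.7 separates compartments sharing most of their signal
variance from incidental correlation at these noise levels.

## Wavelet coherence

The continuous wavelet transform uses the analytic Morlet wavelet with
ω₀ = 5, implemented in the Fourier domain after mean subtraction and
zero-padding to the next power of two, with the `√(δt/s)` time-domain
normalisation. Scales are dyadic, 12 voices per octave, from 2δt up to
N·δt/4; frequencies follow the Morlet Fourier factor
λ = 4πs/(ω₀ + √(2 + ω₀²)). The convolution uses the conjugated wavelet
(the standard analytic-transform convention), which fixes the phase sign:
positive phase of the pair (x, y) means x leads y.

The smoothing operator S is a Gaussian in time with standard deviation s
(the wavelet's own footprint at that scale) followed by a 0.6-octave
boxcar across scales; both kernels are renormalised at record edges so a
constant field is an exact fixed point. Because the identical
positive-weight smoother appears in the numerator and both denominator
factors, Cauchy–Schwarz bounds R² by 1 and self-coherence is identically
1 wherever defined. The denominator of R² uses |W^X|² and |W^Y|² — one
factor per record; using the same record twice would break the
self-coherence identity. Cells whose smoothed auto-spectra are
numerically indistinguishable from zero (below 10⁻¹² of the map maximum)
are flagged undefined rather than divided out as floating-point dust.

The cone of influence at each time index is the largest scale whose
√2·s envelope e-folding time stays inside the record; quantitative
statements (band means, peak frequencies) are restricted to the cone
interior. Phase arrows are circular means, `a_m = atan2(Σ sin aᵢ, Σ cos aᵢ)`,
over time × scale blocks of cells with r² ≥ 0.5; blocks with no qualifying
cell or a vanishing resultant are flagged undefined.

One estimator property worth knowing: at small scales the time smoother
averages fewer independent estimates, so the coherence of noisy records is
biased slightly upward there and the argmax frequency of a genuine
oscillation lands a voice or two high (≈ 1.1 Hz for a 1 Hz generator).
The CWT *power* peak does not share this bias and calibrates to an FFT
periodogram within one voice; the coherence peak is still well inside the
oscillation band.

## The synthetic generator

The generator exists to give every analysis a recording whose answer is
known. Per glomerulus the latent drive is

    u_k(t) = clip( d_k(t) + o_k(t) + Σⱼ C[k,j] · gate_j(t) · u_j(t), −1, 1 )

solved per time sample by fixed-point iteration (the coupling matrix is
non-negative with zero diagonal; saturation guarantees convergence), then
convolved with a peak-normalised difference-of-exponentials calcium kernel
`k(t) = e^(−t/τ_decay) − e^(−t/τ_rise)` and rasterised as
`F = baseline · (1 + a · A/100)` with A the transient amplitude in ΔF/F
percent. Gaussian read noise (and optional Poisson shot noise) is applied
last; both are switchable to zero so closed-form oracles apply exactly.

**Direct drive.** The stimulation footprint is an isotropic Gaussian in
power (σ = 2 px ≈ FWHM 4.7 µm, matching a ≤ 5 × 5 µm spot). A glomerulus
is *directly* activated when the peak footprint power over its mask
reaches its activation threshold; the drive amplitude then ramps linearly
from the threshold to a saturation power, clipped at 1. A binary
(all-or-none) drive was considered and rejected: with an all-or-none
drive, the coupled neighbour's response would be power-independent and the
graded recruitment seen in titration experiments could not occur. The
ramp keeps one threshold parameter per glomerulus while adding a single
shared saturation power.

**Defaults and why** (two-glomerulus scene):

| parameter | default | rationale |
|---|---|---|
| frame shape / rate | 128 × 128 @ 5 Hz | nominal acquisition |
| glomerulus radius | 6 px (≈ 12 µm diameter) | small antennal-lobe glomerulus |
| activation thresholds | 0.012 / 0.024 mW | straddle the lowest titration power (0.02 mW): target fires at p₁, neighbour never directly |
| saturation power | 0.05 mW | top of the titration ladder, so activation grows over the whole 0.02–0.05 mW range |
| transient amplitude | 80 % ΔF/F | strong optogenetically driven GCaMP6 response |
| rise / decay time | 0.3 s / 25 s | fast indicator rise; slow decay reflecting the persistent activity that accumulates across 20 s stimulus gaps |
| lateral coupling | 0.2 | recruits the neighbour around the middle of the power ladder |
| baseline / noise σ | 1000 / 180 counts | single-frame ROI-mean SNR ≈ 10 for the weakest elicited transient |
| titration powers | 10 stimuli, 0.02 → 0.05 mW | 200 ms pulses, 20 s apart |

Ground truth records, per event, the directly activated set (footprint
rule) and the activated set (stimulus-driven latent drive ≥ 0.1, computed
with oscillators excluded so spontaneous activity cannot masquerade as an
elicited response), plus the noiseless latent ΔF/F traces.

**Oscillators and the coupled-oscillation scenario.** Intrinsic
oscillators are sinusoids added to the latent drive; their amplitude
parameter is the *observed* ΔF/F percent, achieved by pre-compensating the
calcium kernel's gain at the oscillator frequency (a 1 Hz rhythm would
otherwise be attenuated several-fold by a slow indicator). The scenario
uses a 1 Hz, 15 % oscillator on glomerulus 1, strong coupling (0.8) gated
to switch on at the source's first direct activation
(`coupling_gate="post_direct"`), a 5 s decay, and a stimulus just above
threshold (0.013 mW) — the pulse gates on the lateral coupling while
barely perturbing the ongoing oscillation, so the post-stimulus coherence
is carried by the rhythm itself rather than by a shared slow transient.
Before the stimulus only glomerulus 1 oscillates; afterwards glomerulus 2
is an exact scaled copy of the shared latent, hence phase-locked.

**The six-region scene** (whole-brain experiment) places left/right
antennal lobes, mushroom bodies and posterior-brain discs with coupling
ranked ipsilateral AL→MB (0.6) > ipsilateral AL→posterior (0.35) >
contralateral AL→MB (0.25) > MB↔MB (0.2) > AL↔AL (0.15), so the recovered
correlation matrix should rank ipsilateral pairs above contralateral
ones.

**What the generator does not emulate:** motion artefacts, bleaching,
opsin photocycle kinetics, out-of-plane structure, spatially correlated
noise, and the heterogeneous glomerular tiling of a real antennal lobe.
Passing tests therefore demonstrate that the analyses recover known
structure under realistic noise — not that they are robust to registration
error or slow drift, which real recordings would add.

## Pipelines and problem sizes

Each experiment pipeline is a pure function of (inputs, config, seed) and
writes CSV tables plus a manifest (config hash, seed, library versions)
when given an output directory. The standard problem sizes are: 60 s
(300 frames) for the selectivity experiment, 220 s (1100 frames) for the
ten-stimulus titration, 80 s (400 frames) for the oscillation scenario,
and three 20 s repetitions for the whole-brain run — all single-CPU,
seconds each.

## Known limitations

* The graded-drive ramp is a phenomenological stand-in for the real
  power–recruitment curve; only its monotonicity and threshold are
  meaningful.
* Seed-map means inside a compartment depend visibly on the smoothing
  scale at SNR ≈ 10; the σ = 6 px default is calibrated to the default
  6 px glomerular radius and should be rescaled for other geometries.
* The coherence peak-frequency estimator carries the small-scale bias
  described above (≲ 2 voices); band membership is robust, exact
  frequency readout should use the CWT power spectrum.
* No significance testing is attached to correlation or coherence values;
  the analyses are descriptive, as is standard for these readouts.
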