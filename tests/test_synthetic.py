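import dataclasses

import numpy as np
import pytest

from glomflow import (
    Oscillator,
    StimulusEvent,
    StimulusProtocol,
    build_two_glomerulus_scene,
    coupled_oscillation_scenario,
    simulate_movie,
)
from glomflow.synthetic import (
    InvalidSceneError,
    calcium_kernel,
    glomerulus_centroid,
    scene_roiset,
)


def _centroids(scene):
    return [glomerulus_centroid(g) for g in scene.glomeruli]


class TestSceneBuilder:
    def test_masks_disjoint_nonempty_within_frame(self):
        scene = build_two_glomerulus_scene(0)
        m1, m2 = (np.asarray(g.mask) for g in scene.glomeruli)
        assert m1.sum() >= 30 and m2.sum() >= 30
        assert not (m1 & m2).any()
        assert m1.shape == scene.frame_shape == (128, 128)

    def test_same_seed_reproduces_scene_field_by_field(self):
        a = build_two_glomerulus_scene(3)
        b = build_two_glomerulus_scene(3)
        for ga, gb in zip(a.glomeruli, b.glomeruli):
            np.testing.assert_array_equal(ga.mask, gb.mask)
            assert dataclasses.replace(ga, mask=None) == dataclasses.replace(gb, mask=None)
        np.testing.assert_array_equal(a.coupling_matrix, b.coupling_matrix)

    def test_different_seeds_move_centroids(self):
        assert _centroids(build_two_glomerulus_scene(0)) != _centroids(
            build_two_glomerulus_scene(1)
        )

    def test_overlapping_override_rejected(self):
        with pytest.raises(InvalidSceneError, match="overlap"):
            build_two_glomerulus_scene(0, centers=((64, 60), (64, 62)))

    def test_nyquist_violating_oscillator_rejected(self):
        with pytest.raises(InvalidSceneError, match="Nyquist"):
            build_two_glomerulus_scene(
                0, oscillators=(Oscillator(frequency=3.0, amplitude=10.0), None)
            )


class TestSimulateMovie:
    def test_null_dynamics_is_flat_baseline(self, quiet_scene):
        movie, _ = simulate_movie(quiet_scene, StimulusProtocol(events=()), 10.0)
        assert np.all(movie.frames == quiet_scene.baseline_level)

    def test_subthreshold_event_equals_no_event(self, quiet_scene):
        target = glomerulus_centroid(quiet_scene.glomeruli[0])
        sub = StimulusProtocol(
            events=(StimulusEvent(5.0, 0.2, quiet_scene.glomeruli[0].activation_threshold / 2,
                                  target),)
        )
        m_sub, truth = simulate_movie(quiet_scene, sub, 20.0)
        m_null, _ = simulate_movie(quiet_scene, StimulusProtocol(events=()), 20.0)
        np.testing.assert_array_equal(m_sub.frames, m_null.frames)
        assert truth.events[0].activated == frozenset()

    def test_single_target_activation_matches_boxcar_kernel_oracle(self, quiet_recording):
        movie, truth, protocol, rois = quiet_recording
        scene_glom = truth.scene.glomeruli[0]
        m1 = rois.mask(1)
        m2 = rois.mask(2)
        dt = movie.frame_interval
        post = movie.times >= protocol.events[0].onset_time
        dff1 = (movie.frames[:, m1].mean(axis=1) / truth.scene.baseline_level - 1) * 100
        dff2 = (movie.frames[:, m2].mean(axis=1) / truth.scene.baseline_level - 1) * 100
        assert dff1[post].mean() > 0
        np.testing.assert_allclose(dff2, 0.0, atol=1e-12)
        # oracle: explicit convolution of the boxcar drive with the kernel
        kern = calcium_kernel(scene_glom.rise_time, scene_glom.decay_time, dt)
        drive = np.zeros(movie.n_frames)
        e = protocol.events[0]
        in_event = (movie.times >= e.onset_time) & (movie.times < e.onset_time + e.duration)
        amp = (e.power - scene_glom.activation_threshold) / (
            truth.scene.saturation_power - scene_glom.activation_threshold
        )
        drive[in_event] = min(1.0, amp)
        expected = np.convolve(drive, kern)[: movie.n_frames] * scene_glom.transient_amplitude
        np.testing.assert_allclose(dff1, expected, atol=1e-9)

    def test_bit_identical_for_fixed_seed(self):
        scene = build_two_glomerulus_scene(2)
        target = glomerulus_centroid(scene.glomeruli[0])
        protocol = StimulusProtocol(events=(StimulusEvent(5.0, 0.2, 0.03, target),))
        a, _ = simulate_movie(scene, protocol, 20.0)
        b, _ = simulate_movie(scene, protocol, 20.0)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_noiseless_dff_linear_in_transient_amplitude(self):
        kwargs = dict(noise_sigma=0.0, coupling=0.0)
        s1 = build_two_glomerulus_scene(0, amplitudes=(40.0, 40.0), **kwargs)
        s2 = build_two_glomerulus_scene(0, amplitudes=(80.0, 80.0), **kwargs)
        target = glomerulus_centroid(s1.glomeruli[0])
        protocol = StimulusProtocol(events=(StimulusEvent(5.0, 0.2, 0.03, target),))
        m1, t1 = simulate_movie(s1, protocol, 20.0)
        m2, t2 = simulate_movie(s2, protocol, 20.0)
        np.testing.assert_allclose(2 * t1.latent_dff, t2.latent_dff, atol=1e-12)

    @pytest.mark.parametrize("powers", [(0.013, 0.02, 0.03, 0.05)])
    def test_directly_activated_set_monotone_in_power(self, quiet_scene, powers):
        target = glomerulus_centroid(quiet_scene.glomeruli[0])
        previous = frozenset()
        for p in powers:
            protocol = StimulusProtocol(events=(StimulusEvent(5.0, 0.2, p, target),))
            _, truth = simulate_movie(quiet_scene, protocol, 10.0)
            assert previous <= truth.events[0].direct
            previous = truth.events[0].direct

    def test_background_pixels_stay_at_baseline_without_noise(self, quiet_recording):
        movie, truth, _, rois = quiet_recording
        background = rois.labels == 0
        assert np.all(movie.frames[:, background] == truth.scene.baseline_level)

    def test_duration_not_covering_protocol_rejected(self, quiet_scene):
        protocol = StimulusProtocol(events=(StimulusEvent(30.0, 0.2, 0.03, (64, 44)),))
        with pytest.raises(ValueError, match="cover"):
            simulate_movie(quiet_scene, protocol, 20.0)


class TestCoupledOscillationScenario:
    def test_pre_uncorrelated_post_synchronised_latents(self):
        movie, truth = coupled_oscillation_scenario(0)
        onset = truth.oscillation["onset"]
        pre = truth.times < onset
        # skip the coupling-onset transient: glomerulus 2's calcium kernel
        # needs a few seconds to settle into the shared rhythm
        post = truth.times >= onset + 10.0
        x_pre, y_pre = truth.latent_dff[pre, 0], truth.latent_dff[pre, 1]
        # glomerulus 2 is silent before the stimulus
        np.testing.assert_allclose(y_pre, 0.0, atol=1e-9)
        assert x_pre.std() > 0
        x_post, y_post = truth.latent_dff[post, 0], truth.latent_dff[post, 1]
        r_post = np.corrcoef(x_post, y_post)[0, 1]
        assert r_post > 0.9

    def test_noiseless_post_traces_are_phase_locked(self):
        movie, truth = coupled_oscillation_scenario(0)
        onset = truth.oscillation["onset"]
        # once the pre-gate kernel tail has decayed, glomerulus 2's latent is
        # a scaled copy of glomerulus 1's: phase-locked, amplitude C times
        late = truth.times >= onset + 25.0
        x = truth.latent_dff[late, 0]
        y = truth.latent_dff[late, 1]
        coupling = truth.scene.coupling_matrix[1, 0]
        assert np.corrcoef(x - x.mean(), y - y.mean())[0, 1] > 0.999
        assert y.std() / x.std() == pytest.approx(coupling, rel=0.05)

    def test_ground_truth_records_generator_frequency(self):
        _, truth = coupled_oscillation_scenario(1, frequency=1.25)
        assert truth.oscillation["frequency"] == 1.25
        assert truth.scene.glomeruli[0].oscillator.frequency == 1.25
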