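import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from glomflow import (
    Movie,
    StimulusEvent,
    StimulusProtocol,
    correlation_matrix,
    pearson,
    seed_map,
    titration_analysis,
)
from glomflow.connectivity import ZeroVarianceError
from glomflow.io_roi import TraceSet
from glomflow.synthetic import (
    build_two_glomerulus_scene,
    glomerulus_centroid,
    scene_roiset,
    simulate_movie,
    titration_protocol,
)


class TestPearson:
    def test_perfect_linear_relations(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0, abs=1e-12)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_four_point_example(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_and_short_inputs_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="3 samples"):
            pearson([1, 2], [3, 4])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=arrays(float, 12, elements=st.floats(-100, 100)),
        b=arrays(float, 12, elements=st.floats(-100, 100)),
        gain=st.floats(0.01, 50),
        shift=st.floats(-100, 100),
    )
    def test_matches_numpy_and_is_affine_invariant(self, a, b, gain, shift):
        if a.std(ddof=1) < 1e-6 or b.std(ddof=1) < 1e-6:
            return
        r = pearson(a, b)
        assert r == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-9)
        assert pearson(b, a) == pytest.approx(r, abs=1e-12)
        assert pearson(gain * a + shift, b) == pytest.approx(r, abs=1e-7)


def _traces(values, names=None, dt=0.2):
    return TraceSet(
        values=np.asarray(values, dtype=float),
        names=names or [f"r{i}" for i in range(np.asarray(values).shape[1])],
        frame_interval=dt,
    )


class TestCorrelationMatrix:
    def test_identical_traces_give_unit_offdiagonal(self, rng):
        x = rng.normal(size=50)
        m = correlation_matrix(_traces(np.column_stack([x, x])))
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_has_small_r(self):
        rng = np.random.default_rng(7)
        m = correlation_matrix(_traces(rng.normal(size=(1000, 2))))
        assert abs(m.values[0, 1]) < 0.1

    def test_symmetric_unit_diagonal_bounded(self, rng):
        m = correlation_matrix(_traces(rng.normal(size=(40, 5))))
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m.values), 1.0)
        assert np.all(np.abs(m.values) <= 1 + 1e-12)

    def test_roi_subset_equals_submatrix(self, rng):
        values = rng.normal(size=(60, 4))
        full = correlation_matrix(_traces(values))
        sub = correlation_matrix(_traces(values[:, 1:3], names=["r1", "r2"]))
        np.testing.assert_allclose(full.values[1:3, 1:3], sub.values, atol=1e-12)

    def test_zero_variance_roi_flagged_not_fabricated(self, rng):
        values = np.column_stack([rng.normal(size=30), np.full(30, 5.0)])
        m = correlation_matrix(_traces(values))
        assert m.defined.tolist() == [True, False]
        assert np.isnan(m.values[0, 1])

    def test_window_outside_recording_rejected(self, rng):
        with pytest.raises(ValueError, match="frames"):
            correlation_matrix(_traces(rng.normal(size=(30, 2))), window=(100.0, 200.0))


class TestSeedMap:
    def _structured_movie(self):
        # mask pixels share one fluctuating trace; the rest is constant
        frames = np.full((20, 10, 10), 50.0)
        trace = 50 + 10 * np.sin(np.arange(20))
        frames[:, 2:5, 2:5] = trace[:, None, None]
        return Movie(frames=frames, frame_interval=0.2)

    def test_shared_trace_region_is_one_rest_undefined(self):
        movie = self._structured_movie()
        smap = seed_map(movie, (3, 3))
        region = np.zeros((10, 10), dtype=bool)
        region[2:5, 2:5] = True
        np.testing.assert_allclose(smap.values[region], 1.0, atol=1e-12)
        assert np.isnan(smap.values[~region]).all()
        assert smap.undefined_mask[~region].all()

    def test_seed_pixel_value_is_exactly_one(self, rng):
        movie = Movie(frames=rng.uniform(10, 20, (30, 8, 8)), frame_interval=0.2)
        smap = seed_map(movie, (4, 4))
        assert smap.values[4, 4] == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_constant_offset_image(self, rng):
        frames = rng.uniform(10, 20, (30, 8, 8))
        offset = rng.uniform(0, 5, (8, 8))
        a = seed_map(Movie(frames=frames, frame_interval=0.2), (4, 4))
        b = seed_map(Movie(frames=frames + offset, frame_interval=0.2), (4, 4))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_zero_variance_seed_rejected(self):
        movie = self._structured_movie()
        with pytest.raises(ZeroVarianceError, match="seed"):
            seed_map(movie, (0, 0))

    def test_smoothing_applied_identically_keeps_seed_at_one(self, rng):
        movie = Movie(frames=rng.uniform(10, 20, (30, 16, 16)), frame_interval=0.2)
        smap = seed_map(movie, (8, 8), smoothing=2.0)
        assert smap.values[8, 8] == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def titration_run():
    scene = build_two_glomerulus_scene(0)
    target = glomerulus_centroid(scene.glomeruli[0])
    protocol = titration_protocol(target)
    movie, truth = simulate_movie(scene, protocol, protocol.events[-1].onset_time + 20.0)
    return movie, protocol, scene_roiset(scene), truth


class TestTitrationAnalysis:

    def test_unreachable_threshold_gives_empty_sets(self, titration_run):
        movie, protocol, rois, _ = titration_run
        table = titration_analysis(movie, protocol, rois, r_threshold=1.01)
        assert all(s == () for s in table["activated_rois"])
        assert (table["activated_area_px"] == 0).all()

    def test_lowest_power_confined_to_target_highest_recruits_neighbour(self, titration_run):
        movie, protocol, rois, truth = titration_run
        table = titration_analysis(movie, protocol, rois)
        assert table["activated_rois"].iloc[0] == ("glomerulus1",)
        assert set(table["activated_rois"].iloc[-1]) >= {"glomerulus1", "glomerulus2"}
        # ground truth agrees on the confinement at the lowest power
        assert truth.events[0].activated == {"glomerulus1"}

    def test_area_tracks_power(self, titration_run):
        movie, protocol, rois, _ = titration_run
        table = titration_analysis(movie, protocol, rois)
        areas = table["activated_area_px"].to_numpy()
        powers = table["power_mw"].to_numpy()
        from scipy.stats import spearmanr

        rho = spearmanr(powers, areas).statistic
        assert rho > 0.95

    def test_mixed_targets_rejected(self, titration_run):
        movie, _, rois, _ = titration_run
        bad = StimulusProtocol(
            events=(
                StimulusEvent(10.0, 0.2, 0.02, (60, 40)),
                StimulusEvent(30.0, 0.2, 0.03, (60, 70)),
            )
        )
        with pytest.raises(ValueError, match="share one target"):
            titration_analysis(movie, bad, rois)
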