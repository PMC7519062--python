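"""Iterative harness conservation, baseline exactness, RNN predictor contracts."""

import numpy as np
import pytest

from trackcast import (BaselineConfig, ConvLSTMForecaster,
                       LinearBaselineForecaster, ObservationWindow, Scene,
                       Track, baseline_predict_step, build_rnn_predictor,
                       iterative_predict)
from trackcast.forecast import _EchoPredictor


def ballistic_scene(n_agents=3, n_frames=60, seed=0, scene_id="s0"):
    rng = np.random.default_rng(seed)
    tracks = []
    for i in range(n_agents):
        v = rng.uniform(-2, 2, 2)
        xy = rng.uniform(0, 100, 2) + np.outer(np.arange(n_frames), v)
        tracks.append(Track(f"c{i}", "immune", np.arange(n_frames), xy))
    return Scene(scene_id, tracks)


class RecordingPredictor:
    """Echo predictor that records every input window it receives."""

    def __init__(self):
        self.windows = []

    def predict_step(self, window_xy):
        self.windows.append(np.asarray(window_xy).copy())
        return np.asarray(window_xy)[:, -1].copy()


class TestIterativeHarness:
    def test_constant_predictor_yields_constant_ending(self):
        scene = ballistic_scene()
        w = ObservationWindow(0, 19, 39)
        results = iterative_predict(_EchoPredictor(), scene, w)
        for r, t in zip(results, scene.tracks):
            np.testing.assert_array_equal(
                r.predicted_ending, np.tile(t.xy[19], (20, 1)))

    def test_prediction_length_and_n_conservation(self):
        scene = ballistic_scene(n_frames=250)
        w = ObservationWindow(0, 119, 239)
        rec = RecordingPredictor()
        results = iterative_predict(rec, scene, w)
        assert len(rec.windows) == 120                    # one per stage
        assert all(win.shape[1] == w.n_inputs for win in rec.windows)
        assert all(r.predicted_ending.shape == (120, 2) for r in results)

    def test_sliding_window_contents(self):
        # stage k+1 input = ground truth beyond T_start+k plus the k
        # previously predicted positions
        scene = ballistic_scene(n_agents=1, n_frames=20)
        w = ObservationWindow(0, 9, 14)
        rec = RecordingPredictor()
        iterative_predict(rec, scene, w)
        truth = scene.tracks[0].xy
        np.testing.assert_array_equal(rec.windows[0][0], truth[0:10])
        # echo predicts position at frame 9 for every later frame
        expected_stage2 = np.vstack([truth[1:10], truth[9][None, :]])
        np.testing.assert_array_equal(rec.windows[1][0], expected_stage2)

    def test_single_stage_base_case(self):
        scene = ballistic_scene()
        w = ObservationWindow(0, 19, 20)
        results = iterative_predict(_EchoPredictor(), scene, w)
        assert all(r.predicted_ending.shape == (1, 2) for r in results)

    def test_uncovered_tracks_reported(self):
        short = Track("short", "immune", np.arange(10), np.zeros((10, 2)))
        scene = ballistic_scene()
        scene.tracks.append(short)
        report = {}
        iterative_predict(_EchoPredictor(), scene, ObservationWindow(0, 19, 39),
                          report=report)
        assert report["excluded"][scene.scene_id] == ["short"]

    def test_tumor_follows_ground_truth_not_prediction(self):
        rng = np.random.default_rng(0)
        tumor_xy = np.cumsum(rng.normal(size=(40, 2)), axis=0)
        tracks = [Track("i0", "immune", np.arange(40), np.zeros((40, 2))),
                  Track("t0", "tumor", np.arange(40), tumor_xy)]
        scene = Scene("s", tracks)
        w = ObservationWindow(0, 19, 39)
        rec = RecordingPredictor()
        results = iterative_predict(rec, scene, w)
        # only the immune track is predicted ...
        assert [r.cell_id for r in results] == ["i0"]
        # ... and the tumor row of a later window holds ground truth
        np.testing.assert_array_equal(rec.windows[5][1, -1], tumor_xy[24])


class TestBaseline:
    def test_ballistic_exactness_at_all_horizons(self):
        scene = ballistic_scene(n_frames=200, seed=1)
        w = ObservationWindow(0, 99, 199)
        results = LinearBaselineForecaster(tau=9).fit().predict(scene, w)
        for r in results:
            np.testing.assert_allclose(r.predicted_ending,
                                       r.ground_truth_ending, atol=1e-8)

    def test_stationary_track(self):
        xy = np.tile([5.0, 7.0], (20, 1))[None, :, :]
        np.testing.assert_array_equal(baseline_predict_step(xy)[0], [5.0, 7.0])

    def test_hand_computed_mean_velocity(self):
        # velocities: 5 steps of (1,0) then 4 of (0,1); tau=9
        steps = [(1.0, 0.0)] * 5 + [(0.0, 1.0)] * 4
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])[None, :, :]
        nxt = baseline_predict_step(xy, BaselineConfig(tau=9))[0]
        np.testing.assert_allclose(nxt, [5 + 5 / 9, 4 + 4 / 9])

    def test_window_shorter_than_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            baseline_predict_step(np.zeros((1, 5, 2)), BaselineConfig(tau=9))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            BaselineConfig(tau=0)


class TestConvLstmPredictor:
    def test_smoke_and_finite_predictions(self):
        scenes = [ballistic_scene(seed=s, scene_id=f"s{s}") for s in range(2)]
        w = ObservationWindow(0, 29, 59)
        est = build_rnn_predictor(scenes, w, epochs=2, obs_len=8, seed=0)
        results = est.predict(scenes[0], w)
        assert len(results) == 3
        assert all(np.isfinite(r.predicted_ending).all() for r in results)

    def test_consumes_time_by_coordinate_matrix(self):
        est = ConvLSTMForecaster(obs_len=8, epochs=1, seed=0)
        est.fit([ballistic_scene()], ObservationWindow(0, 29, 59))
        # the network maps a (batch, 2-channel, time) series to (batch, 2)
        from trackcast._autodiff import Tensor
        out = est.net_(Tensor(np.zeros((5, 2, 8))))
        assert out.shape == (5, 2)

    def test_learns_straight_lines(self):
        scenes = [ballistic_scene(seed=s, n_agents=6, scene_id=f"s{s}")
                  for s in range(3)]
        w = ObservationWindow(0, 29, 59)
        est = ConvLSTMForecaster(obs_len=8, epochs=60, windows_per_track=4,
                                 learning_rate=3e-3, seed=1)
        est.fit(scenes, w)
        held_out = ballistic_scene(seed=77, n_agents=4, scene_id="held")
        xy = np.stack([t.xy[:30] for t in held_out.tracks])
        truth = np.stack([t.xy[30] for t in held_out.tracks])
        err = np.linalg.norm(est.predict_step(xy) - truth, axis=1).mean()
        step = np.mean([np.linalg.norm(np.diff(t.xy, axis=0), axis=1).mean()
                        for t in held_out.tracks])
        assert err < step

    def test_ragged_tracks_are_padded_for_training(self):
        tracks = [Track("a", "immune", np.arange(40),
                        np.cumsum(np.ones((40, 2)), axis=0)),
                  Track("b", "immune", np.arange(25),
                        np.cumsum(np.ones((25, 2)), axis=0))]
        scene = Scene("s", tracks)
        est = ConvLSTMForecaster(obs_len=8, epochs=1, seed=0)
        est.fit([scene], ObservationWindow(0, 14, 24))   # trains without error
        assert hasattr(est, "net_")


class TestSganStability:
    def test_stationary_scene_does_not_diverge(self):
        from trackcast import SocialGANForecaster
        est = SocialGANForecaster(embed_dim=8, encoder_hidden_dim=8,
                                  decoder_hidden_dim=12, pool_embed_dim=4,
                                  pool_out_dim=6, pooling_grid_cells=4,
                                  noise_dim=2, seed=0).init_untrained()
        xy = np.tile([100.0, 100.0], (4, 1, 1)) + np.zeros((4, 121, 2))
        tracks = [Track(f"c{i}", "immune", np.arange(301),
                        np.tile([100.0, 100.0], (301, 1))) for i in range(4)]
        scene = Scene("s", tracks)
        w = ObservationWindow(0, 120, 300)
        results = est.predict(scene, w, rng=np.random.default_rng(0))
        for r in results:
            assert np.all(np.abs(r.predicted_ending - 100.0) < 500.0)
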