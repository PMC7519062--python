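"""Social GAN predictor: pooling oracle, equivariances, training contracts."""

import numpy as np
import pytest

from trackcast import Scene, SganConfig, SocialGANForecaster, Track, halves_window
from trackcast.sgan import (discriminate, encode_scene, pooling_assignment,
                            pooling_pairs)


def brute_force_grid(positions, grid_cells, neighborhood):
    """Independent re-implementation of the binning rule: for each agent i,
    scan every other agent j and place it by explicit interval tests."""
    pos = np.asarray(positions, float)
    n = pos.shape[0]
    G = grid_cells
    half = neighborhood / 2.0
    w = neighborhood / G
    A = np.zeros((n * G * G, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx, dy = pos[j] - pos[i]
            if not (-half < dx <= half and -half < dy <= half):
                continue
            # find the half-open interval (lo, hi] containing the offset
            cx = next(k for k in range(G)
                      if -half + k * w < dx <= -half + (k + 1) * w + 1e-12)
            cy = next(k for k in range(G)
                      if -half + k * w < dy <= -half + (k + 1) * w + 1e-12)
            A[i * G * G + cy * G + cx, j] = 1.0
    return A


def tiny_scene(n_agents=4, n_frames=40, seed=0, speed=1.0, scene_id="s0"):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n_agents)
    start = rng.uniform(0, 50, (n_agents, 2))
    tracks = []
    for i in range(n_agents):
        step = speed * np.array([np.cos(theta[i]), np.sin(theta[i])])
        xy = start[i] + np.outer(np.arange(n_frames), step)
        xy += 0.2 * rng.standard_normal((n_frames, 2))
        tracks.append(Track(f"c{i}", "immune", np.arange(n_frames), xy))
    return Scene(scene_id, tracks)


def tiny_forecaster(**over):
    params = dict(embed_dim=8, encoder_hidden_dim=8, decoder_hidden_dim=12,
                  discriminator_hidden_dim=8, noise_dim=2, pool_embed_dim=4,
                  pool_out_dim=6, pooling_grid_cells=4, epochs=2,
                  train_obs_len=8, train_pred_len=4, windows_per_scene=2,
                  seed=0)
    params.update(over)
    return SocialGANForecaster(**params)


class TestPoolingGrid:
    def test_matches_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 8))
            pos = rng.uniform(-30, 30, (n, 2))
            A = pooling_assignment(pos, 4, 20.0)
            B = brute_force_grid(pos, 4, 20.0)
            np.testing.assert_array_equal(A, B)

    def test_boundary_offset_goes_to_lower_cell(self):
        # neighbour exactly on the internal boundary between cells
        G, nb = 4, 20.0   # cell width 5
        pos = np.array([[0.0, 0.0], [5.0, 0.0]])   # dx exactly on a boundary
        A = pooling_assignment(pos, G, nb)
        B = brute_force_grid(pos, G, nb)
        np.testing.assert_array_equal(A, B)
        # agent 1 at dx=+5 from agent 0: interval (0, 5] -> cx=2 (lower cell)
        cy, cx = 1, 2
        assert A[0 * G * G + cy * G + cx, 1] == 1.0

    def test_single_agent_grid_is_empty(self):
        src, dst = pooling_pairs(np.zeros((1, 2)), [(0, 1)], 4, 20.0)
        assert src.size == 0 and dst.size == 0

    def test_two_close_agents_pool_each_other(self):
        pos = np.array([[0.0, 0.0], [1.0, 1.0]])
        A = pooling_assignment(pos, 4, 20.0)
        assert A[:16, 1].sum() == 1.0 and A[16:, 0].sum() == 1.0

    def test_groups_never_cross_scene_boundaries(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.0], [1.5, 0.0]])
        src, dst = pooling_pairs(pos, [(0, 2), (2, 4)], 4, 20.0)
        for s, d in zip(src, dst):
            assert (s < 2) == (d < 2 * 16)


class TestGeneratorForward:
    def test_encode_scene_shapes(self):
        est = tiny_forecaster().init_untrained()
        scene = tiny_scene(n_agents=5)
        h = encode_scene(est, [t.slice_frames(0, 19) for t in scene.tracks])
        assert h.shape == (5, 8)

    def test_agent_permutation_equivariance(self):
        est = tiny_forecaster(use_noise=False).init_untrained()
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.standard_normal((6, 15, 2)), axis=1)
        out = est.one_step(xy, rng)
        perm = np.array([3, 0, 5, 1, 4, 2])
        out_perm = est.one_step(xy[perm], rng)
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_translation_covariance(self):
        est = tiny_forecaster(use_noise=False).init_untrained()
        rng = np.random.default_rng(1)
        xy = np.cumsum(rng.standard_normal((4, 15, 2)), axis=1)
        shift = np.array([123.0, -45.0])
        out = est.one_step(xy, rng)
        out_shifted = est.one_step(xy + shift, rng)
        np.testing.assert_allclose(out_shifted, out + shift, atol=1e-9)

    def test_one_step_deterministic_given_noise_state(self):
        est = tiny_forecaster(use_noise=False).init_untrained()
        xy = np.cumsum(np.ones((3, 12, 2)), axis=1)
        a = est.one_step(xy, np.random.default_rng(0))
        b = est.one_step(xy, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestDiscriminator:
    def test_untrained_scores_in_unit_interval(self):
        est = tiny_forecaster().init_untrained()
        rng = np.random.default_rng(0)
        traj = np.cumsum(rng.standard_normal((6, 20, 2)), axis=1)
        scores = discriminate(est, traj)
        assert scores.shape == (6,)
        assert np.all((scores > 0) & (scores < 1))

    def test_identical_inputs_identical_scores(self):
        est = tiny_forecaster().init_untrained()
        traj = np.cumsum(np.ones((2, 20, 2)), axis=1)
        s = discriminate(est, np.vstack([traj, traj]))
        np.testing.assert_array_equal(s[:2], s[2:])

    def test_training_separates_smooth_real_from_noise_fake(self):
        # after adversarial training on smooth scenes, smooth trajectories
        # should look more real than white-noise ones
        scenes = [tiny_scene(seed=s, scene_id=f"s{s}") for s in range(3)]
        est = tiny_forecaster(epochs=30, seed=1)
        est.fit(scenes, halves_window(40))
        rng = np.random.default_rng(2)
        smooth = np.stack([np.outer(np.arange(39), [1.0, 0.5])
                           + rng.normal(0, 0.1, (39, 2)) for _ in range(8)])
        noise = np.stack([np.cumsum(rng.normal(0, 3.0, (39, 2)), axis=0) * 0
                          + rng.normal(0, 5.0, (39, 2)) for _ in range(8)])
        assert discriminate(est, smooth).mean() > discriminate(est, noise).mean()


class TestTraining:
    def test_smoke_single_epoch_history(self):
        est = tiny_forecaster(epochs=1)
        est.fit([tiny_scene()], halves_window(40))
        assert len(est.history_["g_loss"]) == 1
        assert len(est.history_["d_loss"]) == 1
        assert np.isfinite(est.history_["g_loss"][0])

    def test_run_to_run_determinism(self):
        scenes = [tiny_scene(seed=3)]
        w = halves_window(40)
        h1 = tiny_forecaster(epochs=3, seed=5).fit(scenes, w).history_
        h2 = tiny_forecaster(epochs=3, seed=5).fit(scenes, w).history_
        assert h1 == h2

    def test_overfit_two_agent_scene_beats_displacement_scale(self):
        scene = tiny_scene(n_agents=2, seed=4, speed=1.0)
        w = halves_window(40)
        est = tiny_forecaster(epochs=150, adversarial_weight=0.0,
                              use_noise=False, seed=2)
        est.fit([scene], w)
        xy = np.stack([t.xy[:20] for t in scene.tracks])
        truth = np.stack([t.xy[20] for t in scene.tracks])
        pred = est.one_step(xy, np.random.default_rng(0))
        err = np.linalg.norm(pred - truth, axis=1).mean()
        step_scale = np.mean([np.linalg.norm(np.diff(t.xy, axis=0), axis=1).mean()
                              for t in scene.tracks])
        assert err < step_scale

    def test_window_not_covered_raises(self):
        est = tiny_forecaster()
        short = tiny_scene(n_frames=10)
        with pytest.raises(ValueError, match="covers"):
            est.fit([short], halves_window(40))


class TestPersistence:
    def test_save_load_forward_bit_identical(self, tmp_path):
        scenes = [tiny_scene(seed=6)]
        est = tiny_forecaster(epochs=2).fit(scenes, halves_window(40))
        path = tmp_path / "model.npz"
        est.save(path)
        back = SocialGANForecaster.load(path)
        xy = np.cumsum(np.ones((4, 12, 2)), axis=1)
        a = est.one_step(xy, np.random.default_rng(3))
        b = back.one_step(xy, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)
        assert back.history_ == est.history_

    def test_sklearn_params_roundtrip(self):
        est = tiny_forecaster(epochs=7)
        clone_params = est.get_params()
        est2 = SocialGANForecaster(**clone_params)
        assert est2.get_params() == clone_params
        assert est2.epochs == 7


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [dict(embed_dim=0), dict(batch_size=0),
                                     dict(variety_k=0),
                                     dict(pooling_neighborhood=0.0)])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            SganConfig(**bad)
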