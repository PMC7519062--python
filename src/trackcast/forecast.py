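"""Iterative long-term prediction and the two competing predictors.

The harness implements the sliding-window recursion shared by every
predictor: at each stage the one-step map receives the current N-position
input window (ground truth for observed frames, previously predicted
positions beyond them), emits the next position for every agent, the window
slides forward by one frame and N stays constant.  All predictors — the
social GAN, the ballistic linear baseline and the conv-LSTM-conv recurrent
model — are invoked one step per stage through the same harness.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator

from . import _autodiff as ad
from ._autodiff import Tensor
from ._nn import Adam, Conv1d, LSTMCell, Module
from .io import ObservationWindow, Scene, Track, pad_with_dummy_points


@dataclasses.dataclass
class PredictionResult:
    """Paired ground-truth and predicted track ending for one cell."""

    scene_id: str
    cell_id: str
    window: ObservationWindow
    ground_truth_ending: np.ndarray   # (n_predict, 2)
    predicted_ending: np.ndarray      # (n_predict, 2)
    predictor: str

    def __post_init__(self):
        gt = np.asarray(self.ground_truth_ending, float)
        pr = np.asarray(self.predicted_ending, float)
        if gt.shape != pr.shape or gt.shape[0] != self.window.n_predict:
            raise ValueError("endings must both cover [t_p_start, t_p_end]")
        self.ground_truth_ending = gt
        self.predicted_ending = pr

    def spliced_track(self, full_track: Track) -> Track:
        """Full-length track with the ending replaced by the prediction
        (observed frames stay ground truth)."""
        if full_track.cell_id != self.cell_id:
            raise ValueError("track/result cell mismatch")
        frames = np.arange(full_track.t0, self.window.t_p_end + 1)
        obs = full_track.positions_at(
            np.arange(full_track.t0, self.window.t_p_start))
        return Track(self.cell_id, full_track.population, frames,
                     np.vstack([obs, self.predicted_ending]))

    def predicted_track(self) -> Track:
        frames = np.arange(self.window.t_p_start, self.window.t_p_end + 1)
        return Track(self.cell_id, "immune", frames, self.predicted_ending)

    def ground_truth_track(self) -> Track:
        frames = np.arange(self.window.t_p_start, self.window.t_p_end + 1)
        return Track(self.cell_id, "immune", frames, self.ground_truth_ending)


@dataclasses.dataclass(frozen=True)
class BaselineConfig:
    """Linear ballistic baseline: mean velocity over the last tau steps."""

    tau: int = 9

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


def baseline_predict_step(window_xy: np.ndarray,
                          config: BaselineConfig = BaselineConfig()) -> np.ndarray:
    """Next positions from the mean of the last tau instantaneous velocities.

    ``window_xy``: (n_agents, N, 2) with N >= tau + 1.  Velocity is the
    per-frame displacement; the prediction advances one frame.
    """
    xy = np.asarray(window_xy, float)
    if xy.shape[1] < config.tau + 1:
        raise ValueError(f"window of {xy.shape[1]} positions is shorter than "
                         f"tau+1 = {config.tau + 1}")
    v = np.diff(xy[:, -(config.tau + 1):], axis=1).mean(axis=1)
    return xy[:, -1] + v


def iterative_predict(predictor, scene: Scene, window: ObservationWindow,
                      predictor_name: str = "custom",
                      report: dict | None = None) -> list[PredictionResult]:
    """Run the sliding-window one-step recursion over a scene.

    ``predictor`` exposes ``predict_step(window_xy) -> next positions`` for
    all agents jointly.  Tumor agents take part in the input window (they
    are visible to social pooling) but their positions are taken from
    ground truth at every stage rather than predicted.  Tracks not covering
    [T_start, t_p_end] are excluded and reported.
    """
    tracks = [t for t in scene.tracks if t.covers(window.t_start, window.t_p_end)]
    excluded = [t.cell_id for t in scene.tracks
                if not t.covers(window.t_start, window.t_p_end)]
    if report is not None:
        report.setdefault("excluded", {})[scene.scene_id] = excluded
    if not tracks:
        return []
    fixed = np.array([t.population == "tumor" for t in tracks])
    n = window.n_inputs
    frames_obs = np.arange(window.t_start, window.t_obs + 1)
    buf = np.stack([t.positions_at(frames_obs) for t in tracks])  # (A, N, 2)
    predicted = []
    for k in range(1, window.n_predict + 1):
        assert buf.shape[1] == n, "input count N must stay constant"
        next_pos = np.asarray(predictor.predict_step(buf), float)
        if next_pos.shape != (buf.shape[0], 2):
            raise ValueError("predictor returned wrong shape")
        frame = window.t_obs + k
        if fixed.any():
            truth = np.stack([t.positions_at([frame])[0] for t in tracks])
            next_pos[fixed] = truth[fixed]
        predicted.append(next_pos)
        buf = np.concatenate([buf[:, 1:], next_pos[:, None, :]], axis=1)
    pred = np.stack(predicted, axis=1)                            # (A, P, 2)
    frames_end = np.arange(window.t_p_start, window.t_p_end + 1)
    results = []
    for i, t in enumerate(tracks):
        if fixed[i]:
            continue
        results.append(PredictionResult(
            scene.scene_id, t.cell_id, window,
            ground_truth_ending=t.positions_at(frames_end),
            predicted_ending=pred[i], predictor=predictor_name))
    return results


class LinearBaselineForecaster(BaseEstimator):
    """Ballistic linear predictor (sklearn-style; fitting is a no-op)."""

    def __init__(self, tau: int = 9):
        self.tau = tau

    def fit(self, scenes=None, window=None):
        self.config_ = BaselineConfig(self.tau)
        return self

    def predict_step(self, window_xy: np.ndarray) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        return baseline_predict_step(window_xy, self.config_)

    def predict(self, scenes, window: ObservationWindow) -> list[PredictionResult]:
        if not hasattr(self, "config_"):
            self.fit()
        scenes = [scenes] if isinstance(scenes, Scene) else scenes
        out = []
        for scene in scenes:
            out.extend(iterative_predict(self, scene, window,
                                         predictor_name="baseline_linear"))
        return out


class _EchoPredictor:
    """Repeats the last input position (harness conservation oracle)."""

    def predict_step(self, window_xy: np.ndarray) -> np.ndarray:
        return np.asarray(window_xy)[:, -1].copy()


# ---------------------------------------------------------------------------
# Conv-LSTM-Conv recurrent predictor (per-track, non-social)


class _RnnNet(Module):
    """Four 1-D conv layers (ReLU), an LSTM, four 1-D conv layers with a
    linear final activation, over a (time, x/y-coordinate) series."""

    def __init__(self, channels: int, hidden: int, kernel: int,
                 rng: np.random.Generator):
        self.conv_in = [Conv1d(2 if i == 0 else channels, channels, kernel, rng)
                        for i in range(4)]
        self.lstm = LSTMCell(channels, hidden, rng)
        self.conv_out = [Conv1d(hidden if i == 0 else channels,
                                channels if i < 3 else 2, kernel, rng)
                         for i in range(4)]
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 2, T) displacement series -> (B, 2) next displacement."""
        for conv in self.conv_in:
            x = ad.relu(conv(x))
        B, C, T = x.shape
        h, c = self.lstm.zero_state(B)
        hs = []
        for t in range(T):
            h, c = self.lstm(x[:, :, t], h, c)
            hs.append(h)
        y = ad.stack(hs, axis=2)                    # (B, hidden, T)
        for i, conv in enumerate(self.conv_out):
            y = conv(y)
            if i < 3:
                y = ad.relu(y)                      # final layer stays linear
        return y[:, :, -1]                          # (B, 2)


class ConvLSTMForecaster(BaseEstimator):
    """Per-track recurrent one-step predictor (the RNN comparison model).

    Requires equal-length training tracks; ragged inputs must first be
    equalized with dummy-point repetition (never zero padding).  Trains on
    (window, next displacement) pairs with an MSE loss and plugs into the
    same iterative harness as the other predictors.
    """

    def __init__(self, channels: int = 16, hidden: int = 32, kernel: int = 3,
                 obs_len: int = 16, epochs: int = 20, learning_rate: float = 1e-3,
                 windows_per_track: int = 4, seed: int = 0):
        self.channels = channels
        self.hidden = hidden
        self.kernel = kernel
        self.obs_len = obs_len
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.windows_per_track = windows_per_track
        self.seed = seed

    def fit(self, scenes: list[Scene], window: ObservationWindow):
        rng = np.random.default_rng(self.seed)
        self.net_ = _RnnNet(self.channels, self.hidden, self.kernel, rng)
        tracks = [t for scene in scenes for t in scene.non_tumor_tracks()]
        if not tracks:
            raise ValueError("no training tracks")
        target_len = max(len(t) for t in tracks)
        ragged = any(len(t) != target_len for t in tracks)
        if ragged:
            tracks = [pad_with_dummy_points(t, target_len) for t in tracks]
        series = np.stack([np.diff(t.xy, axis=0) for t in tracks])  # (B,T-1,2)
        opt = Adam(self.net_.parameters(), lr=self.learning_rate)
        L = self.obs_len
        history = []
        for _ in range(self.epochs):
            total = 0.0
            for _w in range(self.windows_per_track):
                o = int(rng.integers(0, series.shape[1] - L))
                x = series[:, o:o + L].transpose(0, 2, 1)           # (B,2,L)
                target = series[:, o + L]                           # (B,2)
                pred = self.net_(Tensor(x))
                loss = ad.tmean(ad.square(pred - Tensor(target)))
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data)
            history.append(total / self.windows_per_track)
        self.history_ = history
        return self

    def predict_step(self, window_xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(window_xy, float)
        disp = np.diff(xy, axis=1)[:, -self.obs_len:]
        with ad.no_grad():
            d = self.net_(Tensor(disp.transpose(0, 2, 1))).data
        return xy[:, -1] + d

    def predict(self, scenes, window: ObservationWindow) -> list[PredictionResult]:
        scenes = [scenes] if isinstance(scenes, Scene) else scenes
        out = []
        for scene in scenes:
            out.extend(iterative_predict(self, scene, window,
                                         predictor_name="rnn"))
        return out


def build_rnn_predictor(train_scenes: list[Scene], window: ObservationWindow,
                        **params) -> ConvLSTMForecaster:
    """Train the conv-LSTM-conv predictor; thin functional wrapper."""
    return ConvLSTMForecaster(**params).fit(train_scenes, window)
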