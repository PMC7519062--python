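"""Trajectory containers, CSV persistence, window splitting and padding.

The on-disk dialect is a plain CSV with header
``scene_id,cell_id,population,frame,x,y`` (frames 0-based), the lowest common
denominator of single-particle tracker exports.  Coordinates are kept in the
scene's native unit (micrometres or pixels); unit conversion is explicit and
never implied.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

POPULATIONS = ("immune", "tumor", "cancer")
CSV_COLUMNS = ["scene_id", "cell_id", "population", "frame", "x", "y"]


class TrackValidationError(ValueError):
    """Raised on malformed trajectory data (names the offending row/cell)."""


@dataclasses.dataclass
class Track:
    """One cell's time-ordered positions.

    frames are strictly increasing, contiguous integers; ``xy`` is an
    ``(n, 2)`` float array in the parent scene's unit.  ``padded`` flags
    dummy points added by :func:`pad_with_dummy_points`.
    """

    cell_id: str
    population: str
    frames: np.ndarray
    xy: np.ndarray
    padded: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.population not in POPULATIONS:
            raise TrackValidationError(
                f"cell {self.cell_id}: unknown population {self.population!r}")
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise TrackValidationError(
                f"cell {self.cell_id}: frames/coordinates shape mismatch")
        if self.frames.size < 2:
            raise TrackValidationError(f"cell {self.cell_id}: fewer than 2 points")
        d = np.diff(self.frames)
        if np.any(d <= 0):
            raise TrackValidationError(
                f"cell {self.cell_id}: frame indices not strictly increasing")
        if np.any(d != 1):
            raise TrackValidationError(f"cell {self.cell_id}: gap in frame indices")
        if not np.all(np.isfinite(self.xy)):
            raise TrackValidationError(f"cell {self.cell_id}: non-finite coordinate")
        if self.padded is None:
            self.padded = np.zeros(self.frames.size, dtype=bool)

    def __len__(self) -> int:
        return self.frames.size

    @property
    def t0(self) -> int:
        return int(self.frames[0])

    @property
    def t1(self) -> int:
        return int(self.frames[-1])

    def covers(self, t_from: int, t_to: int) -> bool:
        return self.t0 <= t_from and self.t1 >= t_to

    def slice_frames(self, t_from: int, t_to: int) -> "Track":
        """Points with frame in the closed interval [t_from, t_to]."""
        mask = (self.frames >= t_from) & (self.frames <= t_to)
        if mask.sum() < 2:
            raise TrackValidationError(
                f"cell {self.cell_id}: slice [{t_from}, {t_to}] has < 2 points")
        return Track(self.cell_id, self.population, self.frames[mask],
                     self.xy[mask], self.padded[mask])

    def positions_at(self, frames) -> np.ndarray:
        idx = np.asarray(frames) - self.t0
        if np.any(idx < 0) or np.any(idx >= len(self)):
            raise TrackValidationError(
                f"cell {self.cell_id}: requested frames outside track")
        return self.xy[idx]


@dataclasses.dataclass
class Scene:
    """One 'social' video or ROI: co-temporal tracks sharing a time base."""

    scene_id: str
    tracks: list[Track]
    frame_interval: float = 20.0  # seconds per frame
    unit: str = "um"
    unit_scale: float | None = None  # length per pixel, when unit == "pixel"
    condition_label: str = ""

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise TrackValidationError("frame_interval must be positive")
        if self.unit not in ("um", "pixel"):
            raise TrackValidationError(f"unknown unit {self.unit!r}")
        n_tumor = sum(t.population == "tumor" for t in self.tracks)
        if n_tumor > 1:
            raise TrackValidationError(
                f"scene {self.scene_id}: more than one tumor track")

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval / 60.0

    @property
    def tumor_track(self) -> Track | None:
        for t in self.tracks:
            if t.population == "tumor":
                return t
        return None

    def non_tumor_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.population != "tumor"]


@dataclasses.dataclass(frozen=True)
class ObservationWindow:
    """Bookkeeping of the iterative test: observe [T_start, T_obs], predict
    [t_p_start, t_p_end] with t_p_start = T_obs + 1 (0-based frames)."""

    t_start: int
    t_obs: int
    t_p_end: int

    def __post_init__(self):
        if not (self.t_start < self.t_obs < self.t_p_end):
            raise ValueError(
                f"require T_start < T_obs < t_p_end, got "
                f"({self.t_start}, {self.t_obs}, {self.t_p_end})")

    @property
    def t_p_start(self) -> int:
        return self.t_obs + 1

    @property
    def n_inputs(self) -> int:
        """N = T_obs - T_start + 1: positions fed to the predictor."""
        return self.t_obs - self.t_start + 1

    @property
    def n_predict(self) -> int:
        return self.t_p_end - self.t_obs

    def shifted(self, k: int) -> "ObservationWindow":
        return ObservationWindow(self.t_start + k, self.t_obs + k, self.t_p_end + k)


def halves_window(n_frames: int, predicted_fraction: float = 0.5) -> ObservationWindow:
    """Window observing the first (1 - f) of a video and predicting the last f."""
    if not 0.0 < predicted_fraction < 1.0:
        raise ValueError("predicted_fraction must be in (0, 1)")
    t_obs = n_frames - 1 - int(round(predicted_fraction * n_frames))
    return ObservationWindow(0, t_obs, n_frames - 1)


# ---------------------------------------------------------------------------
# CSV persistence


def write_tracks(scenes: list[Scene], path) -> None:
    rows = []
    for scene in scenes:
        for track in scene.tracks:
            for f, (x, y) in zip(track.frames, track.xy):
                rows.append((scene.scene_id, track.cell_id, track.population,
                             int(f), x, y))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    # %.17g guarantees exact binary round-trip of float64 coordinates
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracks(path, frame_interval: float = 20.0, unit: str = "um",
                condition_label: str = "") -> list[Scene]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError(f"{path.name}: missing column(s) {missing}")
    df["_row"] = np.arange(2, len(df) + 2)  # 1-based file rows incl. header
    scenes = []
    for scene_id, sdf in df.groupby("scene_id", sort=False):
        tracks = []
        for cell_id, cdf in sdf.groupby("cell_id", sort=False):
            frames = cdf["frame"].to_numpy()
            dup = pd.Series(frames).duplicated()
            if dup.any():
                row = int(cdf["_row"].to_numpy()[dup.to_numpy()][0])
                raise TrackValidationError(
                    f"{path.name} row {row}: duplicate (cell {cell_id}, "
                    f"frame {frames[dup.to_numpy()][0]})")
            order = np.argsort(frames, kind="stable")
            if not np.array_equal(order, np.arange(len(order))):
                row = int(cdf["_row"].to_numpy()[int(np.argmin(np.diff(frames) > 0)) + 1])
                raise TrackValidationError(
                    f"{path.name} row {row}: non-monotone frames for cell {cell_id}")
            pops = cdf["population"].unique()
            if len(pops) > 1:
                raise TrackValidationError(
                    f"{path.name}: cell {cell_id} has multiple populations {pops}")
            tracks.append(Track(str(cell_id), str(pops[0]), frames,
                                cdf[["x", "y"]].to_numpy()))
        scenes.append(Scene(str(scene_id), tracks, frame_interval=frame_interval,
                            unit=unit, condition_label=condition_label))
    return scenes


# ---------------------------------------------------------------------------
# Window splitting and dummy-point padding


def split_window(scene: Scene, window: ObservationWindow,
                 ) -> tuple[list[Track], list[Track], list[str]]:
    """Split each covering track into (starting slice, ending slice).

    Starting slice: frames in [T_start, T_obs]; ending slice: frames in
    [t_p_start, t_p_end].  Tracks not covering the full window are excluded
    and their ids returned for reporting.
    """
    starting, ending, excluded = [], [], []
    for track in scene.tracks:
        if not track.covers(window.t_start, window.t_p_end):
            excluded.append(track.cell_id)
            continue
        starting.append(track.slice_frames(window.t_start, window.t_obs))
        ending.append(track.slice_frames(window.t_p_start, window.t_p_end))
    return starting, ending, excluded


def pad_with_dummy_points(track: Track, target_len: int,
                          lead: int = 0) -> Track:
    """Equalize track length by replicating first/last positions.

    ``lead`` of the added points go before the start (replicas of the first
    position); the remainder after the end (replicas of the last position).
    Padded points are flagged, original points unchanged.
    """
    extra = target_len - len(track)
    if extra < 0:
        raise ValueError(
            f"target_len {target_len} shorter than track length {len(track)}")
    if not 0 <= lead <= extra:
        raise ValueError("lead padding exceeds total padding")
    if extra == 0:
        return track
    trail = extra - lead
    frames = np.arange(track.t0 - lead, track.t1 + trail + 1)
    xy = np.vstack([np.repeat(track.xy[:1], lead, axis=0),
                    track.xy,
                    np.repeat(track.xy[-1:], trail, axis=0)])
    padded = np.concatenate([np.ones(lead, bool), track.padded,
                             np.ones(trail, bool)])
    return Track(track.cell_id, track.population, frames, xy, padded)
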