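"""Kinematic and interaction descriptors of track endings.

All descriptors operate on an "ending" — the slice of a trajectory inside the
prediction window — supplied either as a :class:`~trackcast.io.Track` or as a
bare ``(n, 2)`` coordinate array.  Times are taken from the frame interval in
minutes; speeds are in length-units per minute, angles in radians.

* mean straight-line speed: d(first, last) / T_p, with T_p the ending
  duration;
* max distance travelled: max over t of d(first, Z_t) — the farthest the
  cell gets from where the ending starts;
* persistence (straightness index): net displacement over total path length,
  in [0, 1], 1 for a perfectly straight path;
* mean angular speed: mean absolute turning angle between consecutive
  displacement vectors per unit time, proportional to path curvature;
* mean interaction time: number of frames an immune cell spends strictly
  closer than R_int to the tumor centre.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Scene, Track

KINEMATIC_SET = ("max_distance_travelled", "mean_straight_speed",
                 "persistence", "mean_angular_speed")
PHANTOM_SET = ("max_distance_travelled", "mean_straight_speed")
INTERACTION_SET = ("mean_interaction_time",)


def _coords(ending) -> np.ndarray:
    xy = ending.xy if isinstance(ending, Track) else np.asarray(ending, float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("ending must be an (n>=2, 2) coordinate sequence")
    return xy


def mean_straight_line_speed(ending, frame_interval_min: float) -> float:
    """Net displacement over duration, length-units per minute."""
    xy = _coords(ending)
    t_p = (xy.shape[0] - 1) * frame_interval_min
    if t_p <= 0:
        raise ValueError("ending duration must be positive")
    return float(np.linalg.norm(xy[-1] - xy[0]) / t_p)


def max_distance_travelled(ending) -> float:
    """Maximum Euclidean distance from the ending's first point."""
    xy = _coords(ending)
    return float(np.linalg.norm(xy - xy[0], axis=1).max())


def persistence(ending) -> float:
    """Straightness index: net displacement / total path length, in [0, 1].

    Returns ``nan`` for a zero-length path (undefined).
    """
    xy = _coords(ending)
    path = np.linalg.norm(np.diff(xy, axis=0), axis=1).sum()
    if path == 0.0:
        return float("nan")
    return float(np.linalg.norm(xy[-1] - xy[0]) / path)


def mean_angular_speed(ending, frame_interval_min: float) -> float:
    """Mean absolute turning angle per minute (radians/min).

    Zero-length steps carry no direction and are skipped.
    """
    xy = _coords(ending)
    if xy.shape[0] < 3:
        raise ValueError("mean angular speed needs >= 3 points")
    steps = np.diff(xy, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    keep = norms > 0
    steps = steps[keep]
    if steps.shape[0] < 2:
        return float("nan")
    ang = np.arctan2(steps[:, 1], steps[:, 0])
    turn = np.diff(ang)
    turn = np.abs((turn + np.pi) % (2 * np.pi) - np.pi)  # wrap to [0, pi]
    return float(turn.mean() / frame_interval_min)


def interaction_frames(immune_ending, tumor_positions, r_int: float) -> int:
    """Frames with centre-to-centre distance strictly below ``r_int``."""
    if r_int <= 0:
        raise ValueError("r_int must be positive")
    xy = _coords(immune_ending)
    tum = np.asarray(tumor_positions, float)
    if tum.shape != xy.shape:
        raise ValueError("tumor positions must cover the same frames as the ending")
    return int((np.linalg.norm(xy - tum, axis=1) < r_int).sum())


def mean_interaction_time(immune_endings, tumor_ending, r_int: float,
                          frame_interval_min: float | None = None,
                          ) -> tuple[np.ndarray, float]:
    """Per-immune-track interaction frame counts and their mean.

    When ``frame_interval_min`` is given, values are converted to minutes.
    """
    tum = _coords(tumor_ending)
    counts = np.array([interaction_frames(e, tum, r_int) for e in immune_endings],
                      dtype=float)
    if frame_interval_min is not None:
        counts = counts * frame_interval_min
    return counts, float(counts.mean()) if counts.size else float("nan")


# ---------------------------------------------------------------------------
# Tabular descriptor extraction


def compute_descriptors(endings_by_scene: dict[str, list[Track]],
                        frame_interval_min: float,
                        names=KINEMATIC_SET,
                        source: str = "ground_truth",
                        condition_label: str = "",
                        tumor_endings: dict[str, Track] | None = None,
                        r_int: float | None = None) -> pd.DataFrame:
    """Compute named descriptors for every ending, one row per (track, name).

    ``endings_by_scene`` maps scene id to track endings; ``tumor_endings``
    (same keys) and ``r_int`` are required when ``mean_interaction_time`` is
    requested.
    """
    rows = []
    for scene_id, endings in endings_by_scene.items():
        tum = None
        if tumor_endings is not None:
            tum = tumor_endings.get(scene_id)
        for track in endings:
            for name in names:
                if name == "max_distance_travelled":
                    value = max_distance_travelled(track)
                elif name == "mean_straight_speed":
                    value = mean_straight_line_speed(track, frame_interval_min)
                elif name == "persistence":
                    value = persistence(track)
                elif name == "mean_angular_speed":
                    value = mean_angular_speed(track, frame_interval_min)
                elif name == "mean_interaction_time":
                    if tum is None or r_int is None:
                        raise ValueError(
                            "mean_interaction_time needs tumor endings and r_int")
                    value = float(interaction_frames(track, tum.xy, r_int))
                else:
                    raise ValueError(f"unknown descriptor {name!r}")
                rows.append((scene_id, track.cell_id, condition_label, source,
                             name, value))
    return pd.DataFrame(rows, columns=["scene_id", "cell_id", "condition_label",
                                       "source", "name", "value"])


def endings_from_scenes(scenes: list[Scene], window) -> dict[str, list[Track]]:
    """Ground-truth non-tumor endings per scene for a prediction window."""
    from .io import split_window

    out = {}
    for scene in scenes:
        _, endings, _ = split_window(scene, window)
        out[scene.scene_id] = [e for e in endings if e.population != "tumor"]
    return out
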