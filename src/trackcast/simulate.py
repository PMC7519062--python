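"""Stochastic phantom models of immune-cell migration and tumor-immune interaction.

Two fully synthetic "atlases" of social scenes are generated:

* one population: 16 immune cells per video in collective migration, each a
  random walk with drift constant in modulus (|mu|, per-cell fixed random
  heading), isotropic Gaussian positional noise and soft-core repulsion
  between cells of the same population;
* two populations: the immune cells drift toward a tumor cell performing a
  pure random walk; inside the interaction radius R_int (sum of the two cell
  radii) an attractive force of the same modulus |mu| acts on the immune cell
  for an imposed effectiveness time T_eff, after which the cell departs with
  a fresh random heading and does not re-engage.  Every attraction episode is
  logged with its on/off frames.

Per-frame update: x_{t+1} = x_t + mu*dt + sigma*eta_t + F_rep, with eta_t
standard bivariate normal and F_rep a summed soft-core displacement of
magnitude ``repulsion_strength * (1 - d/repulsion_range)`` away from each
neighbour closer than ``repulsion_range``.  Positions reflect at the field
boundaries.  The test-role parameterization uses |mu| = 3 um/min and
T_eff = 8.3 min over 100 videos; the training role |mu| = 3.4 um/min and
T_eff = 13.3 min over 10 videos; every video is 240 frames at 1 frame/20 s.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import Scene, Track


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """All phantom-model parameters.

    Lengths in micrometres, times in the stated unit per field:
    ``drift_modulus`` in um/min, ``dt`` in seconds per frame, ``t_eff`` in
    minutes, noise sigmas in um per step.
    """

    n_videos: int | None = None     # None -> role default (100 test / 10 train)
    n_immune: int = 16
    n_frames: int = 240
    dt: float = 20.0
    drift_modulus: float = 3.0
    drift_direction_policy: str = "per_cell_fixed_random"
    noise_sigma: float = 1.5
    repulsion_strength: float = 1.0
    repulsion_range: float = 12.0
    two_population: bool = False
    t_eff: float = 8.3
    immune_radius: float = 6.0
    tumor_radius: float = 12.0
    tumor_noise_sigma: float = 0.5
    field_size: tuple[float, float] = (2000.0, 2000.0)
    init_box: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.n_immune < 1:
            raise ConfigurationError("n_immune must be >= 1")
        if self.noise_sigma < 0 or self.tumor_noise_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")
        if self.drift_modulus < 0:
            raise ConfigurationError("drift modulus must be non-negative")
        if self.immune_radius <= 0 or self.tumor_radius <= 0:
            raise ConfigurationError("cell radii must be positive")
        if self.repulsion_strength < 0 or self.repulsion_range <= 0:
            raise ConfigurationError("repulsion parameters out of range")
        if not 0 < self.init_box <= min(self.field_size):
            raise ConfigurationError("init_box must be positive and fit the field")
        if self.drift_direction_policy not in ("per_cell_fixed_random",
                                               "toward_target"):
            raise ConfigurationError(
                f"unknown drift policy {self.drift_direction_policy!r}")
        if self.two_population:
            if self.t_eff <= 0 or self.t_eff_frames < 1:
                raise ConfigurationError("t_eff must span at least one frame")
            if self.r_int >= min(self.field_size):
                raise ConfigurationError("interaction radius exceeds field")

    @property
    def r_int(self) -> float:
        """Interaction radius: sum of tumor and immune cell radii (um)."""
        return self.immune_radius + self.tumor_radius

    @property
    def t_eff_frames(self) -> int:
        """Effectiveness time rounded to whole frames."""
        return int(round(self.t_eff * 60.0 / self.dt))

    @property
    def duration_min(self) -> float:
        return self.n_frames * self.dt / 60.0


@dataclasses.dataclass(frozen=True)
class AttractionEvent:
    """One logged tumor-attraction episode of an immune cell."""

    scene_id: str
    immune_id: str
    t_on: int
    t_off: int

    @property
    def duration_frames(self) -> int:
        return self.t_off - self.t_on

    def duration_min(self, dt: float) -> float:
        return self.duration_frames * dt / 60.0


TEST_ROLE = {"drift_modulus": 3.0, "t_eff": 8.3, "n_videos": 100}
TRAIN_ROLE = {"drift_modulus": 3.4, "t_eff": 13.3, "n_videos": 10}


def _repulsion(pos: np.ndarray, strength: float, rng_range: float) -> np.ndarray:
    """Soft-core pairwise repulsive displacement for positions (n, 2)."""
    if strength == 0.0 or pos.shape[0] < 2:
        return np.zeros_like(pos)
    diff = pos[:, None, :] - pos[None, :, :]          # i - j
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    active = dist < rng_range
    if not active.any():
        return np.zeros_like(pos)
    with np.errstate(invalid="ignore"):
        unit = np.where(dist[..., None] > 0, diff / dist[..., None], 0.0)
    mag = np.where(active, strength * (1.0 - dist / rng_range), 0.0)
    return (mag[..., None] * unit).sum(axis=1)


def _reflect(pos: np.ndarray, field: tuple[float, float]) -> np.ndarray:
    for ax, lim in enumerate(field):
        p = pos[:, ax]
        p = np.abs(p)                      # reflect at 0
        over = p > lim
        p[over] = 2 * lim - p[over]        # reflect at lim (single bounce)
        p = np.clip(p, 0.0, lim)
        pos[:, ax] = p
    return pos


def _drift_step(config: SimConfig) -> float:
    """Drift displacement per frame in um."""
    return config.drift_modulus * config.dt / 60.0


def _seed_positions(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Initial positions uniform in a centred seeding box.

    The field is kept much larger than the seeded region (an ROI around a
    cell cluster) so that drifted migration essentially never touches the
    reflecting boundary within a video."""
    fx, fy = config.field_size
    half = config.init_box / 2.0
    centre = np.array([fx / 2.0, fy / 2.0])
    return centre + rng.uniform(-half, half, size=(n, 2))


def simulate_one_population(config: SimConfig, seed: int | None = None,
                            scene_id: str = "scene0",
                            condition_label: str = "") -> Scene:
    """Simulate one collective-migration scene of ``n_immune`` immune cells."""
    if config.two_population:
        raise ConfigurationError("config is two-population; "
                                 "use simulate_two_population")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, T = config.n_immune, config.n_frames
    pos = _seed_positions(config, n, rng)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    headings = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    step = _drift_step(config)
    traj = np.empty((T, n, 2))
    traj[0] = pos
    for t in range(1, T):
        move = step * headings
        move += config.noise_sigma * rng.standard_normal((n, 2))
        move += _repulsion(pos, config.repulsion_strength, config.repulsion_range)
        pos = _reflect(pos + move, config.field_size)
        traj[t] = pos
    tracks = [Track(f"immune{i:02d}", "immune", np.arange(T), traj[:, i])
              for i in range(n)]
    return Scene(scene_id, tracks, frame_interval=config.dt,
                 condition_label=condition_label)


def simulate_two_population(config: SimConfig, seed: int | None = None,
                            scene_id: str = "scene0", condition_label: str = "",
                            ) -> tuple[Scene, list[AttractionEvent]]:
    """Simulate immune cells migrating toward / interacting with a tumor cell.

    Returns the scene (immune tracks plus one tumor track) and the log of
    attraction episodes; each logged episode lasts exactly
    ``config.t_eff_frames`` frames (episodes that would be cut short by the
    video end are not started, so the log is exact).
    """
    if not config.two_population:
        raise ConfigurationError("config is one-population; "
                                 "use simulate_one_population")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, T = config.n_immune, config.n_frames
    fx, fy = config.field_size
    tumor = np.array([fx / 2.0, fy / 2.0])
    pos = _seed_positions(config, n, rng)
    step = _drift_step(config)
    dur = config.t_eff_frames
    # per-cell engagement state
    APPROACH, ENGAGED, DEPARTED = 0, 1, 2
    mode = np.full(n, APPROACH)
    t_off = np.full(n, -1)
    departed_heading = np.zeros((n, 2))
    events: list[AttractionEvent] = []

    traj = np.empty((T, n, 2))
    tumor_traj = np.empty((T, 2))
    traj[0] = pos
    tumor_traj[0] = tumor
    for t in range(1, T):
        # engagement bookkeeping at the state of frame t-1
        dist = np.linalg.norm(pos - tumor, axis=1)
        for i in range(n):
            if mode[i] == APPROACH and dist[i] < config.r_int:
                if (t - 1) + dur <= T - 1:
                    mode[i] = ENGAGED
                    t_off[i] = (t - 1) + dur
                    events.append(AttractionEvent(scene_id, f"immune{i:02d}",
                                                  t_on=t - 1, t_off=int(t_off[i])))
            elif mode[i] == ENGAGED and t - 1 >= t_off[i]:
                mode[i] = DEPARTED
                phi = rng.uniform(0, 2 * np.pi)
                departed_heading[i] = (np.cos(phi), np.sin(phi))
        # drift: toward the tumor while approaching or engaged, fixed random
        # heading after the episode
        to_tumor = tumor - pos
        d = np.linalg.norm(to_tumor, axis=1, keepdims=True)
        toward = np.where(d > 0, to_tumor / np.maximum(d, 1e-12), 0.0)
        drift_dir = np.where((mode == DEPARTED)[:, None], departed_heading, toward)
        move = step * drift_dir
        move += config.noise_sigma * rng.standard_normal((n, 2))
        move += _repulsion(pos, config.repulsion_strength, config.repulsion_range)
        pos = _reflect(pos + move, config.field_size)
        tumor = _reflect((tumor + config.tumor_noise_sigma *
                          rng.standard_normal(2))[None, :], config.field_size)[0]
        traj[t] = pos
        tumor_traj[t] = tumor

    tracks = [Track(f"immune{i:02d}", "immune", np.arange(T), traj[:, i])
              for i in range(n)]
    tracks.append(Track("tumor00", "tumor", np.arange(T), tumor_traj))
    scene = Scene(scene_id, tracks, frame_interval=config.dt,
                  condition_label=condition_label)
    return scene, events


def generate_atlas(config: SimConfig, role: str,
                   ) -> tuple[list[Scene], list[AttractionEvent]]:
    """Generate a train- or test-role atlas of phantom scenes.

    ``role='test'`` parameterizes |mu| = 3 um/min (and T_eff = 8.3 min) over
    100 videos; ``role='train'`` |mu| = 3.4 um/min (and T_eff = 13.3 min)
    over 10 videos.  ``config.n_videos`` overrides the video count.  Scene
    seeds are spawned independently from ``config.seed``.
    """
    if role not in ("train", "test"):
        raise ConfigurationError(f"unknown role {role!r}")
    params = dict(TEST_ROLE if role == "test" else TRAIN_ROLE)
    n_videos = config.n_videos if config.n_videos is not None else params["n_videos"]
    config = dataclasses.replace(config, n_videos=n_videos,
                                 drift_modulus=params["drift_modulus"],
                                 t_eff=params["t_eff"])
    children = np.random.SeedSequence(config.seed).spawn(n_videos)
    scenes: list[Scene] = []
    events: list[AttractionEvent] = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        sid = f"{role}_{i:03d}"
        if config.two_population:
            scene, ev = simulate_two_population(config, seed=seed, scene_id=sid,
                                                condition_label=role)
            events.extend(ev)
        else:
            scene = simulate_one_population(config, seed=seed, scene_id=sid,
                                            condition_label=role)
        scenes.append(scene)
    return scenes, events


def write_events(events: list[AttractionEvent], path) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(e) for e in events],
                 columns=["scene_id", "immune_id", "t_on", "t_off"],
                 ).to_csv(path, index=False)
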