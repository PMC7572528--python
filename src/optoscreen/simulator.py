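"""Seeded agent-based larva simulator.

Generates synthetic head/tail tracks with the statistical structure the
behavioural analysis assumes: run-and-turn locomotion (persistent heading
with von Mises noise and Poisson-timed reorientations) modulated by the
opsin-weighted irradiance sensed at the head under any stimulus protocol.

Response modes map to the behaviours evoked by the different opsin/driver
combinations:

``none``
    light-indifferent control animal,
``avoid``
    nociceptive photo-avoidance: the animal turns away when it senses
    supra-threshold light at its head or just ahead of it (larval
    photo-sensing is anterior-weighted, and confined larvae are observed to
    turn when *approaching* a lit border, so avoidance here is anticipatory
    by one body length rather than purely reactive),
``stop``
    motor-system activation/silencing: crawling speed scales down as
    ``1 - d/d_sat``,
``contract``
    muscle contraction: the emitted head-tail distance shortens by up to
    30%,
``roll``
    nociceptive rolling: a rolling flag is raised and speed increases 1.5x
    while the drive stays above threshold.

The model is deliberately minimal — it reproduces confinement, guidance
and dose-dependent slowing, not peristalsis or opsin photocycle kinetics.
All randomness flows from a single seed through per-agent child streams,
so output is bit-reproducible and independent of agent count ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as osio
from .metrics import RegionTrajectory, normalised_metric, period_mean
from .photometry import DisplayModel, Spectrum, effective_drive
from .presets import action_spectrum, honor8_display
from .stimulus import (BLACK, Protocol, StimulusStep, build_colour_sequence,
                       make_moving_ring, schedule_of)

__all__ = [
    "AgentParams",
    "SimConfig",
    "simulate",
    "dose_response",
    "make_fixture_suite",
    "maze_lit_mask",
    "ring_experiment",
    "maze_experiment",
]

RESPONSE_MODES = ("none", "avoid", "stop", "contract", "roll")
ROLL_SPEED_FACTOR = 1.5
CONTRACT_MAX_FRACTION = 0.3
AVOID_MAX_RESAMPLES = 20


@dataclass
class AgentParams:
    """Locomotion and opsin-response parameters of one simulated larva.

    Defaults are desk-scale larval crawling values: 0.5 mm/s baseline
    speed, one spontaneous reorientation per ~10 s, 4 mm body length.  The
    activation threshold default of 0.41 µW/mm² is the published minimum
    power density that evoked an optogenetic response.
    """

    baseline_speed_mm_s: float = 0.5
    turn_rate_hz: float = 0.1
    turn_kappa: float = 8.0
    response_mode: str = "none"
    drive_threshold_uw_mm2: float = 0.41
    drive_sat_uw_mm2: float = 2.0
    body_length_mm: float = 4.0
    dt_s: float = 0.5
    anticipatory_avoidance: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.baseline_speed_mm_s < 0 or self.drive_threshold_uw_mm2 < 0:
            raise ValueError("speeds and thresholds must be non-negative")
        if self.dt_s <= 0:
            raise ValueError("dt must be positive")
        if self.drive_sat_uw_mm2 <= 0:
            raise ValueError("drive_sat must be positive")
        if self.response_mode not in RESPONSE_MODES:
            raise ValueError(f"unknown response mode {self.response_mode!r}")


@dataclass
class SimConfig:
    """One simulated experiment: arena, protocol, optics, sampling."""

    protocol: Protocol
    n_agents: int = 10
    display: DisplayModel | None = None
    action: Spectrum | None = None
    duration_s: float | None = None
    sampling_interval_s: float = 1.0
    placement: str = "uniform"  # or "inside-region"
    placement_region: RegionTrajectory | None = None
    initial_positions_mm: np.ndarray | None = None

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("need at least one agent")
        if self.placement not in ("uniform", "inside-region"):
            raise ValueError("placement must be 'uniform' or 'inside-region'")
        if self.placement == "inside-region" and self.placement_region is None:
            raise ValueError("inside-region placement needs a placement_region")
        if self.display is None:
            self.display = honor8_display()
        if self.action is None:
            self.action = action_spectrum("cschrimson")
        if self.duration_s is None:
            self.duration_s = self.protocol.total_duration_s


class _DriveSampler:
    """Opsin-weighted irradiance at a point, with per-colour caching.

    Evaluates the analytic (unblurred) light field of the active step: the
    point-in-pattern query shared with the rasteriser times the effective
    drive of the step's RGB colour.
    """

    def __init__(self, protocol: Protocol, display: DisplayModel, action: Spectrum):
        self.protocol = protocol
        self.display = display
        self.action = action
        self._cache: dict[tuple[int, int, int], float] = {BLACK: 0.0}
        # precompute step start times for O(log n) lookup
        durations = [s.duration_s for s in protocol.steps]
        self._starts = np.concatenate(([0.0], np.cumsum(durations)))

    def _step_at(self, t: float) -> tuple[StimulusStep, float] | tuple[None, float]:
        if t >= self._starts[-1]:  # display dark after the protocol ends
            return None, 0.0
        k = int(np.searchsorted(self._starts, t, side="right")) - 1
        return self.protocol.steps[k], t - self._starts[k]

    def drive_of_rgb(self, rgb: tuple[int, int, int]) -> float:
        if rgb not in self._cache:
            self._cache[rgb] = effective_drive(self.display, rgb, self.action)
        return self._cache[rgb]

    def __call__(self, x: float, y: float, t: float) -> float:
        step, tau = self._step_at(t)
        if step is None or step.rgb == BLACK:
            return 0.0
        if not bool(step.lit_at(x, y, tau, self.protocol.arena_mm)):
            return 0.0
        return self.drive_of_rgb(step.rgb)


def _reflect(pos: float, lo: float, hi: float) -> tuple[float, bool]:
    bounced = False
    while pos < lo or pos > hi:  # small steps: at most one bounce in practice
        if pos < lo:
            pos = 2 * lo - pos
        else:
            pos = 2 * hi - pos
        bounced = True
    return pos, bounced


def _place_agents(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = config.protocol.arena_mm
    if config.initial_positions_mm is not None:
        pos = np.asarray(config.initial_positions_mm, dtype=float)
        if pos.shape != (config.n_agents, 2):
            raise ValueError("initial positions must be (n_agents, 2)")
        if np.any((pos[:, 0] < 0) | (pos[:, 0] > w) | (pos[:, 1] < 0) | (pos[:, 1] > h)):
            raise ValueError("agent initialised outside arena")
        return pos
    out = np.empty((config.n_agents, 2))
    for i in range(config.n_agents):
        for attempt in range(10000):
            p = rng.uniform([0, 0], [w, h])
            if config.placement == "uniform" or bool(
                    config.placement_region.contains(p[None, :], np.array([0.0]))[0]):
                out[i] = p
                break
        else:
            raise ValueError("could not place agent inside region within arena")
    return out


def _simulate_agent(agent_id: str, start_xy: np.ndarray, config: SimConfig,
                    params: AgentParams, drive: _DriveSampler,
                    rng: np.random.Generator) -> "Track":
    from .metrics import Track

    dt = params.dt_s
    n_steps = int(round(config.duration_s / dt))
    record_every = max(1, int(round(config.sampling_interval_s / dt)))
    p_turn = 1.0 - math.exp(-params.turn_rate_hz * dt)
    mode = params.response_mode
    bl = params.body_length_mm
    thr = params.drive_threshold_uw_mm2
    sat = params.drive_sat_uw_mm2
    w, h = config.protocol.arena_mm

    x, y = float(start_xy[0]), float(start_xy[1])
    heading = rng.uniform(-math.pi, math.pi)

    times, heads, tails, rolls = [], [], [], []

    def record(t, d_here):
        times.append(t)
        heads.append((x, y))
        length = bl
        if mode == "contract":
            length = bl * (1.0 - CONTRACT_MAX_FRACTION * min(1.0, d_here / sat))
        tails.append((x - length * math.cos(heading), y - length * math.sin(heading)))
        rolls.append(mode == "roll" and d_here >= thr)

    d_here = drive(x, y, 0.0)
    record(0.0, d_here)

    for k in range(n_steps):
        t = k * dt
        d_here = drive(x, y, t)

        triggered = False
        if mode == "avoid":
            trigger_level = d_here
            if params.anticipatory_avoidance:
                probe = drive(x + bl * math.cos(heading), y + bl * math.sin(heading), t)
                trigger_level = max(trigger_level, probe)
            if trigger_level >= thr:
                triggered = True
                for _ in range(AVOID_MAX_RESAMPLES):
                    cand = rng.uniform(-math.pi, math.pi)
                    d_probe = drive(x + bl * math.cos(cand), y + bl * math.sin(cand), t)
                    if d_probe < trigger_level:
                        heading = cand
                        break
                else:
                    heading = rng.uniform(-math.pi, math.pi)

        if not triggered:
            if rng.random() < p_turn:
                heading = rng.uniform(-math.pi, math.pi)
            else:
                heading += rng.vonmises(0.0, params.turn_kappa)

        speed = params.baseline_speed_mm_s
        if mode == "stop":
            speed *= max(0.0, 1.0 - d_here / sat)
        elif mode == "roll" and d_here >= thr:
            speed *= ROLL_SPEED_FACTOR

        x += speed * dt * math.cos(heading)
        y += speed * dt * math.sin(heading)
        x, bx = _reflect(x, 0.0, w)
        y, by = _reflect(y, 0.0, h)
        if bx:
            heading = math.pi - heading
        if by:
            heading = -heading

        if (k + 1) % record_every == 0:
            record((k + 1) * dt, drive(x, y, (k + 1) * dt))

    return Track(
        animal_id=agent_id,
        times_s=np.asarray(times),
        head_mm=np.asarray(heads),
        tail_mm=np.asarray(tails),
        rolling=np.asarray(rolls, dtype=bool),
    )


def simulate(config: SimConfig, params: AgentParams) -> list:
    """Run one seeded experiment and return one Track per agent.

    The seed in ``params`` is split into independent per-agent streams, so
    the same seed always yields byte-identical trajectories.
    """
    ss = np.random.SeedSequence(params.seed)
    placement_rng = np.random.default_rng(ss.spawn(1)[0])
    agent_seeds = ss.spawn(config.n_agents)
    starts = _place_agents(config, placement_rng)
    drive = _DriveSampler(config.protocol, config.display, config.action)
    tracks = []
    for i in range(config.n_agents):
        rng = np.random.default_rng(agent_seeds[i])
        tracks.append(_simulate_agent(
            f"{params.response_mode}_{i:02d}", starts[i], config, params, drive, rng))
    return tracks


# ---------------------------------------------------------------------------
# canonical experiments


def ring_experiment(mode: str = "avoid", n_agents: int = 10, seed: int = 0,
                    duration_s: float = 1290.0,
                    arena_mm: tuple[float, float] = (260.0, 60.0),
                    start_centre_mm: tuple[float, float] = (30.0, 30.0),
                    ) -> tuple[SimConfig, AgentParams, RegionTrajectory]:
    """Moving-ring confinement: a 17/47 mm annulus translating at 0.17 mm/s.

    Avoid-mode agents start inside the dark safe zone (the ring's inner
    circle); control (``none``) agents start uniformly in the arena.  The
    arena is longer than a real display so the ring never reaches a wall
    over the 21.5 min run.  Head positions are sampled every 1 s.
    """
    ring = make_moving_ring(17.0, 47.0, 0.17, direction=(1.0, 0.0),
                            rgb=(255, 255, 255), duration_s=duration_s,
                            start_centre_mm=start_centre_mm)
    protocol = Protocol(steps=[ring], arena_mm=arena_mm, mm_per_px=0.5)
    safe = RegionTrajectory.from_ring_step(ring)
    config = SimConfig(
        protocol=protocol, n_agents=n_agents, sampling_interval_s=1.0,
        placement="inside-region" if mode == "avoid" else "uniform",
        placement_region=safe if mode == "avoid" else None)
    params = AgentParams(response_mode=mode, seed=seed)
    return config, params, safe


def maze_lit_mask(channel_mm: float = 20.0, left_band_mm: float = 7.0,
                  right_band_mm: float = 37.0, height_mm: float = 40.0,
                  mm_per_px: float = 0.5) -> np.ndarray:
    """Lit mask of the optical maze: a dark vertical channel between two
    white bands (7 mm on the left, 37 mm on the right).  255 = lit."""
    width_mm = left_band_mm + channel_mm + right_band_mm
    w = int(round(width_mm / mm_per_px))
    h = int(round(height_mm / mm_per_px))
    mask = np.full((h, w), 255, dtype=np.uint8)
    c0 = int(round(left_band_mm / mm_per_px))
    c1 = int(round((left_band_mm + channel_mm) / mm_per_px))
    mask[:, c0:c1] = 0
    return mask


def maze_experiment(mode: str = "avoid", n_agents: int = 11, seed: int = 0,
                    duration_s: float = 1290.0,
                    ) -> tuple[SimConfig, AgentParams, RegionTrajectory]:
    """Maze confinement: dark 20 mm channel flanked by lit bands.

    Avoid-mode agents start inside the dark channel; head positions are
    sampled every 5 s for 21 min 30 s.
    """
    mask = maze_lit_mask()
    arena_mm = (64.0, 40.0)
    step = StimulusStep(duration_s=duration_s, pattern="image",
                        rgb=(255, 255, 255), image_mask=mask)
    protocol = Protocol(steps=[step], arena_mm=arena_mm, mm_per_px=0.5)
    safe = RegionTrajectory.from_dark_mask(mask, arena_mm)
    config = SimConfig(
        protocol=protocol, n_agents=n_agents, sampling_interval_s=5.0,
        placement="inside-region" if mode == "avoid" else "uniform",
        placement_region=safe if mode == "avoid" else None)
    params = AgentParams(response_mode=mode, seed=seed)
    return config, params, safe


# ---------------------------------------------------------------------------
# dose-response


def dose_response(params: AgentParams, drive_levels: Sequence[int],
                  n_agents: int = 10, channel: str = "red",
                  stim_s: float = 20.0, black_s: float = 30.0,
                  n_repeats: int = 3,
                  display: DisplayModel | None = None,
                  action: Spectrum | None = None,
                  arena_mm: tuple[float, float] = (60.0, 40.0)) -> pd.DataFrame:
    """Normalised speed versus display brightness.

    For each drive level (0-255 on one channel, ascending) a full-field
    colour-sequence protocol of ``n_repeats`` stimulations (20 s light,
    30 s dark) is simulated and the group mean +/- s.e.m. of the per-animal
    normalised speed is reported together with the opsin-weighted power
    density of the level.
    """
    if list(drive_levels) != sorted(drive_levels):
        raise ValueError("drive levels must be ascending")
    display = display if display is not None else honor8_display()
    action = action if action is not None else action_spectrum("cschrimson")
    idx = ("red", "green", "blue").index(channel)
    rows = []
    for level_i, level in enumerate(drive_levels):
        rgb = [0, 0, 0]
        rgb[idx] = int(level)
        rgb = tuple(rgb)
        protocol = build_colour_sequence(stim_s, black_s, [rgb] * n_repeats,
                                         arena_mm=arena_mm)
        config = SimConfig(protocol=protocol, n_agents=n_agents,
                           display=display, action=action,
                           sampling_interval_s=1.0)
        # distinct but seed-derived stream per level
        level_params = replace(params, seed=params.seed * 1000 + level_i)
        tracks = simulate(config, level_params)
        schedule = schedule_of(protocol)
        drive = effective_drive(display, rgb, action)
        if rgb == BLACK:
            # black "stimulation" periods: behaviour is baseline by construction
            ratios = np.ones(n_agents)
        else:
            pm = pd.concat([period_mean(tr, schedule, "speed") for tr in tracks])
            norm = normalised_metric(pm)
            ratios = norm[norm["valid"]].groupby("animal_id")["ratio"].mean().to_numpy()
        rows.append({
            "level": level, "rgb": rgb, "drive_uw_mm2": drive,
            "mean_normalised_speed": float(np.mean(ratios)),
            "sem_normalised_speed": float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))
            if len(ratios) > 1 else np.nan,
            "n": len(ratios),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture suite


def make_fixture_suite(seed: int, out_dir) -> dict[str, Path]:
    """Write the canonical synthetic datasets used throughout the tests.

    Ring experiment (10 avoid + 10 control agents, 1 s sampling), maze
    experiment (11 avoid + 10 control, 5 s sampling, plus the maze mask
    PNG), and one four-colour sequence experiment per response mode.
    Regenerating with the same seed reproduces every file byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    # stable derived sub-seeds (< 2**31) for each experiment
    sub = [int(s) % (2 ** 31) for s in ss.generate_state(8)]
    paths: dict[str, Path] = {}

    ring_dir = out / "ring"
    ring_dir.mkdir(exist_ok=True)
    for i, mode in enumerate(("avoid", "none")):
        config, params, safe = ring_experiment(mode=mode, n_agents=10, seed=sub[i])
        tracks = simulate(config, params)
        p = ring_dir / f"tracks_{mode}.csv"
        osio.write_tracks_csv(tracks, p)
        paths[f"ring_{mode}"] = p
    paths["ring_protocol"] = ring_dir / "protocol.yaml"
    config, _, _ = ring_experiment()
    osio.write_protocol(config.protocol, paths["ring_protocol"])

    maze_dir = out / "maze"
    maze_dir.mkdir(exist_ok=True)
    mask = maze_lit_mask()
    paths["maze_mask"] = maze_dir / "maze_mask.png"
    osio.write_mask_png(mask, paths["maze_mask"])
    for i, (mode, n) in enumerate((("avoid", 11), ("none", 10))):
        config, params, safe = maze_experiment(mode=mode, n_agents=n, seed=sub[2 + i])
        tracks = simulate(config, params)
        p = maze_dir / f"tracks_{mode}.csv"
        osio.write_tracks_csv(tracks, p)
        paths[f"maze_{mode}"] = p

    seq_dir = out / "colour_sequence"
    seq_dir.mkdir(exist_ok=True)
    protocol = build_colour_sequence(20.0, 60.0, ["red", "green", "blue", "white"])
    paths["sequence_protocol"] = seq_dir / "protocol.yaml"
    osio.write_protocol(protocol, paths["sequence_protocol"])
    for i, mode in enumerate(RESPONSE_MODES):
        config = SimConfig(protocol=protocol, n_agents=10, sampling_interval_s=1.0)
        params = AgentParams(response_mode=mode, seed=sub[4] + i)
        tracks = simulate(config, params)
        p = seq_dir / f"tracks_{mode}.csv"
        osio.write_tracks_csv(tracks, p)
        paths[f"sequence_{mode}"] = p
    return paths
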