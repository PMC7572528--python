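"""Stimulus protocols and their rendering to frames and irradiance maps.

A protocol is an ordered list of timed steps, each displaying one light
pattern (full-field colour, rectangle, circle, ring/annulus, or an image
mask) that may translate at constant velocity.  Protocols compile to a
period schedule (for the behavioural analysis), rasterise to RGB frames,
and convert to per-channel irradiance maps at the specimen plane using a
display model.

Coordinates are millimetres with the origin at the arena's top-left corner,
x rightward and y downward; rasters are row-major with pixel (0, 0) at the
top-left and pixel centres at half-integer multiples of ``mm_per_px``.
Pattern edges are hard: a pixel is lit iff its centre lies inside the
analytic region (no anti-aliasing), which makes lit areas exactly
computable in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .photometry import DisplayModel

__all__ = [
    "StimulusStep",
    "Protocol",
    "Period",
    "PeriodSchedule",
    "Frame",
    "LightField",
    "SyncMarker",
    "COLOURS",
    "build_colour_sequence",
    "make_moving_ring",
    "render_frame",
    "schedule_of",
    "light_field",
    "colour_at",
]

BLACK = (0, 0, 0)

COLOURS = {
    "black": (0, 0, 0),
    "red": (255, 0, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
    "white": (255, 255, 255),
}
_RGB_TO_LABEL = {v: k for k, v in COLOURS.items()}

_PATTERNS = ("full_field", "rectangle", "circle", "ring", "image")


def _as_rgb(colour) -> tuple[int, int, int]:
    if isinstance(colour, str):
        try:
            return COLOURS[colour.lower()]
        except KeyError:
            raise ValueError(f"unknown colour name {colour!r}") from None
    rgb = tuple(int(v) for v in colour)
    if len(rgb) != 3 or any(not 0 <= v <= 255 for v in rgb):
        raise ValueError(f"invalid rgb triple {colour!r}")
    return rgb


@dataclass
class StimulusStep:
    """One timed light pattern.

    ``geometry`` keys depend on the pattern: ring needs ``inner_diameter_mm``
    and ``outer_diameter_mm``; rectangle ``width_mm``/``height_mm``; circle
    ``diameter_mm``.  ``position_mm`` is the pattern centre at step start and
    the centre translates at ``velocity_mm_s`` during the step.  An image
    pattern is lit wherever its grayscale mask (stretched over the arena) is
    nonzero.
    """

    duration_s: float
    pattern: str = "full_field"
    rgb: tuple[int, int, int] = (255, 255, 255)
    geometry: dict = field(default_factory=dict)
    position_mm: tuple[float, float] = (0.0, 0.0)
    velocity_mm_s: tuple[float, float] = (0.0, 0.0)
    image_mask: np.ndarray | None = None
    sync_marker: bool = True

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("step duration must be positive")
        if self.pattern not in _PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        self.rgb = _as_rgb(self.rgb)
        if self.pattern == "ring":
            inner = self.geometry.get("inner_diameter_mm")
            outer = self.geometry.get("outer_diameter_mm")
            if inner is None or outer is None or not inner < outer:
                raise ValueError("ring requires inner_diameter_mm < outer_diameter_mm")
        if self.pattern == "image":
            if self.image_mask is None:
                raise ValueError("image pattern requires a mask")
            self.image_mask = np.asarray(self.image_mask)

    def centre_at(self, t_in_step: float) -> tuple[float, float]:
        return (self.position_mm[0] + self.velocity_mm_s[0] * t_in_step,
                self.position_mm[1] + self.velocity_mm_s[1] * t_in_step)

    def lit_at(self, x_mm, y_mm, t_in_step: float, arena_mm: tuple[float, float]):
        """Vectorised point-in-pattern query at a time within the step."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        if self.pattern == "full_field":
            return np.ones(np.broadcast(x, y).shape, dtype=bool)
        cx, cy = self.centre_at(t_in_step)
        if self.pattern == "rectangle":
            w = self.geometry["width_mm"]
            h = self.geometry["height_mm"]
            return (np.abs(x - cx) <= w / 2) & (np.abs(y - cy) <= h / 2)
        if self.pattern == "circle":
            r = self.geometry["diameter_mm"] / 2
            return (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2
        if self.pattern == "ring":
            ri = self.geometry["inner_diameter_mm"] / 2
            ro = self.geometry["outer_diameter_mm"] / 2
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            return (d2 >= ri ** 2) & (d2 <= ro ** 2)
        # image: nearest mask pixel, mask stretched over the arena
        mh, mw = self.image_mask.shape[:2]
        col = np.clip((x / arena_mm[0] * mw).astype(int), 0, mw - 1)
        row = np.clip((y / arena_mm[1] * mh).astype(int), 0, mh - 1)
        return self.image_mask[row, col] > 0


@dataclass(frozen=True)
class SyncMarker:
    """Small white disc shown whenever the display is non-black.

    Placed outside the experimental area in the physical setup so that
    video frames can be aligned with stimulus onsets.
    """

    centre_mm: tuple[float, float]
    diameter_mm: float = 2.0


@dataclass
class Protocol:
    """An ordered stimulus sequence on a fixed arena."""

    steps: list[StimulusStep]
    arena_mm: tuple[float, float] = (60.0, 40.0)
    mm_per_px: float = 0.5
    sync_marker: SyncMarker | None = None

    def __post_init__(self):
        if not self.steps:
            raise ValueError("protocol needs at least one step")
        if self.arena_mm[0] <= 0 or self.arena_mm[1] <= 0 or self.mm_per_px <= 0:
            raise ValueError("arena dimensions and scale must be positive")

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.steps))

    def step_at(self, t_s: float) -> tuple[StimulusStep, float]:
        """Active step and the time elapsed within it, for 0 <= t < total."""
        if not 0 <= t_s < self.total_duration_s:
            raise ValueError(f"t={t_s} outside [0, {self.total_duration_s})")
        start = 0.0
        for step in self.steps:
            if t_s < start + step.duration_s:
                return step, t_s - start
            start += step.duration_s
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class Period:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PeriodSchedule:
    """Contiguous half-open labelled intervals [start, end) tiling [0, T)."""

    periods: list[Period]

    def __post_init__(self):
        if not self.periods:
            raise ValueError("empty schedule")
        if self.periods[0].start_s != 0:
            raise ValueError("schedule must start at 0")
        for a, b in zip(self.periods, self.periods[1:]):
            if b.start_s != a.end_s:
                raise ValueError("periods must be contiguous and non-overlapping")
        for p in self.periods:
            if p.end_s <= p.start_s:
                raise ValueError("periods must have positive duration")

    @property
    def total_duration_s(self) -> float:
        return self.periods[-1].end_s

    def period_at(self, t_s: float) -> Period:
        for p in self.periods:
            if p.start_s <= t_s < p.end_s:
                return p
        raise ValueError(f"t={t_s} outside schedule")

    def stimulation_periods(self) -> list[Period]:
        return [p for p in self.periods if p.label != "black"]


@dataclass
class Frame:
    """One rasterised RGB frame (uint8, row-major, origin top-left)."""

    rgb: np.ndarray  # (H, W, 3) uint8
    mm_per_px: float
    timestamp_s: float


@dataclass
class LightField:
    """Per-channel irradiance (µW/mm²) at the specimen plane.

    ``irradiance`` has shape (H, W, 3) with channels ordered red, green,
    blue.
    """

    irradiance: np.ndarray
    mm_per_px: float
    timestamp_s: float

    def total(self) -> np.ndarray:
        return self.irradiance.sum(axis=2)


# ---------------------------------------------------------------------------
# protocol builders


def build_colour_sequence(stim_s: float, black_s: float, colours: Sequence,
                          initial_black: bool = True, trailing_black: bool = True,
                          arena_mm: tuple[float, float] = (60.0, 40.0),
                          mm_per_px: float = 0.5) -> Protocol:
    """Full-field colour sequence with interleaved black rest periods.

    Each stimulation of ``stim_s`` seconds is preceded by a black period of
    ``black_s`` seconds (the baseline for speed/length normalisation).  The
    classic four-colour experiment ``build_colour_sequence(20, 60,
    ["red", "green", "blue", "white"])`` yields 9 periods totalling 380 s.
    """
    if stim_s <= 0 or black_s <= 0:
        raise ValueError("durations must be positive")
    colours = list(colours)
    if not colours:
        raise ValueError("colour list must be non-empty")
    steps: list[StimulusStep] = []

    def black_step():
        return StimulusStep(duration_s=black_s, pattern="full_field", rgb=BLACK)

    if initial_black:
        steps.append(black_step())
    for i, colour in enumerate(colours):
        if i > 0:
            steps.append(black_step())
        steps.append(StimulusStep(duration_s=stim_s, pattern="full_field",
                                  rgb=_as_rgb(colour)))
    if trailing_black:
        steps.append(black_step())
    return Protocol(steps=steps, arena_mm=arena_mm, mm_per_px=mm_per_px)


def make_moving_ring(inner_d_mm: float, outer_d_mm: float, speed_mm_s: float,
                     direction: tuple[float, float] = (1.0, 0.0),
                     rgb=(255, 255, 255), duration_s: float = 1290.0,
                     start_centre_mm: tuple[float, float] = (30.0, 30.0)) -> StimulusStep:
    """An annulus of light translating at constant speed.

    The region inside the inner circle is the dark "safe zone" used to
    confine photo-avoiding larvae; the published geometry is a 17 mm inner /
    47 mm outer diameter ring moving at 0.17 mm/s.
    """
    if not inner_d_mm < outer_d_mm:
        raise ValueError("ring requires inner diameter < outer diameter")
    if speed_mm_s < 0:
        raise ValueError("speed must be non-negative")
    d = np.asarray(direction, dtype=float)
    norm = np.hypot(*d)
    if norm == 0 and speed_mm_s > 0:
        raise ValueError("direction must be non-zero for a moving ring")
    v = tuple(speed_mm_s * d / norm) if norm else (0.0, 0.0)
    return StimulusStep(
        duration_s=duration_s, pattern="ring", rgb=rgb,
        geometry={"inner_diameter_mm": inner_d_mm, "outer_diameter_mm": outer_d_mm},
        position_mm=tuple(start_centre_mm), velocity_mm_s=v,
    )


# ---------------------------------------------------------------------------
# rendering


def _pixel_centres(protocol: Protocol) -> tuple[np.ndarray, np.ndarray, int, int]:
    w_px = max(1, int(round(protocol.arena_mm[0] / protocol.mm_per_px)))
    h_px = max(1, int(round(protocol.arena_mm[1] / protocol.mm_per_px)))
    x = (np.arange(w_px) + 0.5) * protocol.mm_per_px
    y = (np.arange(h_px) + 0.5) * protocol.mm_per_px
    return x, y, w_px, h_px


def render_frame(protocol: Protocol, t_s: float) -> Frame:
    """Rasterise the active pattern at time ``t_s``.

    Unlit pixels are black; the sync marker (if the protocol defines one) is
    drawn as a white disc whenever the active step is non-black.
    """
    step, tau = protocol.step_at(t_s)
    x, y, w_px, h_px = _pixel_centres(protocol)
    xx, yy = np.meshgrid(x, y)
    raster = np.zeros((h_px, w_px, 3), dtype=np.uint8)
    if step.rgb != BLACK:
        lit = step.lit_at(xx, yy, tau, protocol.arena_mm)
        raster[lit] = step.rgb
        if protocol.sync_marker is not None and step.sync_marker:
            m = protocol.sync_marker
            disc = (xx - m.centre_mm[0]) ** 2 + (yy - m.centre_mm[1]) ** 2 \
                <= (m.diameter_mm / 2) ** 2
            raster[disc] = (255, 255, 255)
    return Frame(rgb=raster, mm_per_px=protocol.mm_per_px, timestamp_s=t_s)


def colour_at(protocol: Protocol, point_mm: tuple[float, float],
              t_s: float) -> tuple[int, int, int]:
    """Displayed RGB at a single point, without rasterising.

    Matches the rasteriser's lit test exactly (shared containment code) in
    the limit of vanishing pixel size; used by the agent simulator to sense
    light at the larva's head.
    """
    step, tau = protocol.step_at(t_s)
    if step.rgb == BLACK:
        return BLACK
    lit = step.lit_at(point_mm[0], point_mm[1], tau, protocol.arena_mm)
    return step.rgb if bool(lit) else BLACK


def schedule_of(protocol: Protocol) -> PeriodSchedule:
    """Label each step by its colour and return the half-open period tiling."""
    periods = []
    start = 0.0
    for step in protocol.steps:
        label = _RGB_TO_LABEL.get(step.rgb, "custom")
        periods.append(Period(label=label, start_s=start, end_s=start + step.duration_s))
        start += step.duration_s
    return PeriodSchedule(periods=periods)


# ---------------------------------------------------------------------------
# irradiance


def spread_kernel(display: DisplayModel, mm_per_px: float,
                  truncate: float = 0.995) -> np.ndarray:
    """Radially symmetric point-spread kernel induced by the cover glass.

    Derived from the display's angular emission profile: flux emitted at
    polar angle theta lands at lateral radius ``t * tan(theta)`` at the top
    of the glass.  The kernel is truncated at the ``truncate`` containment
    radius and renormalised to integrate to exactly 1 (flux conservation).
    """
    t = display.glass_thickness_mm
    prof = display.angular
    th_max = np.radians(prof.angles_deg[-1])
    theta = np.linspace(0.0, th_max, 20001)
    inten = np.interp(np.degrees(theta), prof.angles_deg, prof.radiant_intensity)
    w = inten * np.sin(theta)
    cdf = np.concatenate(([0.0], np.cumsum((w[1:] + w[:-1]) * 0.5 * np.diff(theta))))
    cdf /= cdf[-1]
    # work below the truncation quantile so tan stays bounded
    th_cut = np.interp(truncate, cdf, theta)
    keep = theta <= th_cut
    r = t * np.tan(theta[keep])
    c = cdf[keep]
    r_max = r[-1]
    # areal flux density p(r) = dC/dr / (2 pi r)
    dcdr = np.gradient(c, r)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = dcdr / (2 * np.pi * r)
    dens[0] = dens[1]
    half = int(np.ceil(r_max / mm_per_px))
    ax = (np.arange(-half, half + 1)) * mm_per_px
    dist = np.hypot(*np.meshgrid(ax, ax))
    kernel = np.interp(dist, r, dens, right=0.0) * mm_per_px ** 2
    s = kernel.sum()
    if s <= 0:
        kernel = np.zeros_like(kernel)
        kernel[half, half] = 1.0
        return kernel
    return kernel / s


def light_field(frame: Frame, display: DisplayModel, blur: bool = False) -> LightField:
    """Convert an RGB frame to per-channel irradiance at the specimen plane.

    Each pixel's drive value maps through the channel transfer curve to an
    irradiance; with ``blur=True`` each channel is convolved with the
    glass-spread kernel (which integrates to 1, so total flux is conserved
    up to raster-boundary leakage).
    """
    planes = []
    for idx, name in enumerate(("red", "green", "blue")):
        ch = display.channels[name]
        drive = frame.rgb[:, :, idx].astype(float)
        planes.append(ch.max_power_density * ch.transfer(drive))
    irr = np.stack(planes, axis=2)
    if blur:
        from scipy.signal import oaconvolve

        kernel = spread_kernel(display, frame.mm_per_px)
        irr = np.stack(
            [oaconvolve(irr[:, :, k], kernel, mode="same") for k in range(3)], axis=2)
        irr = np.clip(irr, 0.0, None)
    return LightField(irradiance=irr, mm_per_px=frame.mm_per_px,
                      timestamp_s=frame.timestamp_s)
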