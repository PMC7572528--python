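"""Behavioural quantification of larval tracks.

Implements the track-level measurements used to score optogenetic
responses: instantaneous crawling speed and body length, per-period means
and their normalisation to the preceding dark baseline, net x-velocity,
the prisoner index (fraction of time an animal's head stays inside a
possibly moving safe region), expected occupancy of a maze, the rolling
fraction of a group, a Gaussian summary of positions along an axis, and
Student t statistics.

Tracks are head (and optionally tail) positions in millimetres sampled at
strictly increasing times, emulating manual frame-by-frame tracking.
Period boundaries are half-open ``[start, end)``: a sample exactly at a
boundary belongs to the later period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import PeriodSchedule, StimulusStep

__all__ = [
    "Track",
    "RegionTrajectory",
    "GaussianPositionFit",
    "instantaneous_speed",
    "larval_length",
    "period_mean",
    "normalised_metric",
    "mean_x_velocity",
    "prisoner_index",
    "expected_occupancy",
    "rolling_fraction",
    "position_gaussian",
    "t_statistics",
    "group_summary",
]

#: baseline guard: a dark-period mean below this (mm/s or mm) cannot serve
#: as a normalisation denominator and flags the ratio invalid instead
BASELINE_EPS = 0.01


@dataclass
class Track:
    """One animal's time-stamped positions.

    head_mm (and tail_mm when present) are (n, 2) arrays of x/y in mm.
    """

    animal_id: str
    times_s: np.ndarray
    head_mm: np.ndarray
    tail_mm: np.ndarray | None = None
    rolling: np.ndarray | None = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.head_mm = np.asarray(self.head_mm, dtype=float)
        n = self.times_s.size
        if n < 2:
            raise ValueError("a track needs at least 2 samples")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("track times must be strictly increasing")
        if self.head_mm.shape != (n, 2) or not np.all(np.isfinite(self.head_mm)):
            raise ValueError("head positions must be finite (n, 2)")
        if self.tail_mm is not None:
            self.tail_mm = np.asarray(self.tail_mm, dtype=float)
            if self.tail_mm.shape != (n, 2) or not np.all(np.isfinite(self.tail_mm)):
                raise ValueError("tail positions must be finite (n, 2)")
        if self.rolling is not None:
            self.rolling = np.asarray(self.rolling, dtype=bool)
            if self.rolling.shape != (n,):
                raise ValueError("rolling flags must align with samples")

    @property
    def n_samples(self) -> int:
        return self.times_s.size

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


@dataclass
class RegionTrajectory:
    """A safe region, possibly translating at constant velocity.

    ``kind`` is ``"disc"`` (radius_mm around a moving centre — the interior
    of a confinement ring's inner circle) or ``"mask"`` (static: inside
    wherever the stored boolean raster is True, stretched over the arena).
    """

    kind: str
    radius_mm: float | None = None
    centre0_mm: tuple[float, float] = (0.0, 0.0)
    velocity_mm_s: tuple[float, float] = (0.0, 0.0)
    inside_mask: np.ndarray | None = None
    arena_mm: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind == "disc":
            if self.radius_mm is None or self.radius_mm <= 0:
                raise ValueError("disc region needs a positive radius")
        elif self.kind == "mask":
            if self.inside_mask is None or self.arena_mm is None:
                raise ValueError("mask region needs a mask and arena dimensions")
            self.inside_mask = np.asarray(self.inside_mask, dtype=bool)
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")

    @classmethod
    def disc(cls, radius_mm, centre0_mm=(0.0, 0.0), velocity_mm_s=(0.0, 0.0)):
        return cls("disc", radius_mm=radius_mm, centre0_mm=tuple(centre0_mm),
                   velocity_mm_s=tuple(velocity_mm_s))

    @classmethod
    def from_ring_step(cls, step: StimulusStep) -> "RegionTrajectory":
        """Safe zone of a ring stimulus: the interior of its inner circle."""
        if step.pattern != "ring":
            raise ValueError("step is not a ring pattern")
        return cls.disc(step.geometry["inner_diameter_mm"] / 2,
                        step.position_mm, step.velocity_mm_s)

    @classmethod
    def from_dark_mask(cls, lit_mask: np.ndarray, arena_mm) -> "RegionTrajectory":
        """Safe zone of a maze stimulus: wherever the lit mask is zero."""
        return cls("mask", inside_mask=np.asarray(lit_mask) == 0,
                   arena_mm=tuple(arena_mm))

    def contains(self, xy_mm: np.ndarray, times_s: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy_mm, dtype=float))
        t = np.atleast_1d(np.asarray(times_s, dtype=float))
        if self.kind == "disc":
            cx = self.centre0_mm[0] + self.velocity_mm_s[0] * t
            cy = self.centre0_mm[1] + self.velocity_mm_s[1] * t
            return (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2 <= self.radius_mm ** 2
        mh, mw = self.inside_mask.shape
        col = np.clip((xy[:, 0] / self.arena_mm[0] * mw).astype(int), 0, mw - 1)
        row = np.clip((xy[:, 1] / self.arena_mm[1] * mh).astype(int), 0, mh - 1)
        return self.inside_mask[row, col]


# ---------------------------------------------------------------------------
# per-sample series


def instantaneous_speed(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Chord speed between consecutive samples, assigned to interval ends.

    Returns ``(times, speeds)`` with one value per inter-sample interval.
    """
    dt = np.diff(track.times_s)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps")
    disp = np.linalg.norm(np.diff(track.head_mm, axis=0), axis=1)
    return track.times_s[1:], disp / dt


def larval_length(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample head-tail Euclidean distance in mm."""
    if track.tail_mm is None:
        raise ValueError("track has no tail positions")
    return track.times_s, np.linalg.norm(track.head_mm - track.tail_mm, axis=1)


# ---------------------------------------------------------------------------
# period bookkeeping


def period_mean(track: Track, schedule: PeriodSchedule, quantity: str = "speed",
                window_s: float | None = None) -> pd.DataFrame:
    """Mean speed or body length per schedule period for one track.

    ``window_s`` restricts the mean to the final ``window_s`` seconds of
    each period — the analysis rule for slow-closing opsins whose effect
    has not fully decayed until just before the next stimulation.  Periods
    containing no samples are flagged invalid rather than raising.

    A speed value describes an inter-sample interval and counts towards a
    period only if the whole interval ``[t_i, t_{i+1})`` lies inside it;
    intervals straddling a period boundary are discarded.  Length values
    are instantaneous and assigned by their half-open sample time.
    """
    if quantity == "speed":
        end_times, values = instantaneous_speed(track)
        lo, hi = track.times_s[:-1], track.times_s[1:]
    elif quantity == "length":
        times, values = larval_length(track)
        lo = hi = times
    else:
        raise ValueError("quantity must be 'speed' or 'length'")
    rows = []
    for i, p in enumerate(schedule.periods):
        if quantity == "speed":
            sel = (lo >= p.start_s) & (hi <= p.end_s)
        else:
            sel = (lo >= p.start_s) & (lo < p.end_s)
        if window_s is not None:
            sel &= lo >= p.end_s - window_s
        n = int(sel.sum())
        rows.append({
            "animal_id": track.animal_id, "period_index": i, "label": p.label,
            "start_s": p.start_s, "end_s": p.end_s, "quantity": quantity,
            "mean_value": float(values[sel].mean()) if n else np.nan,
            "n_samples": n, "valid": n > 0,
        })
    return pd.DataFrame(rows)


def normalised_metric(period_means: pd.DataFrame,
                      baseline_eps: float = BASELINE_EPS) -> pd.DataFrame:
    """Stimulation-period values divided by the preceding dark baseline.

    One row per non-black period, per animal.  Ratios whose baseline is
    invalid or below ``baseline_eps`` are flagged invalid and should be
    excluded from group means.
    """
    out = []
    for animal, df in period_means.groupby("animal_id", sort=False):
        df = df.sort_values("period_index").reset_index(drop=True)
        for i, row in df.iterrows():
            if row["label"] == "black":
                continue
            if i == 0 or df.loc[i - 1, "label"] != "black":
                raise ValueError(
                    f"stimulation period {row['label']!r} at index "
                    f"{row['period_index']} has no preceding black period")
            base = df.loc[i - 1]
            valid = bool(row["valid"] and base["valid"]
                         and base["mean_value"] >= baseline_eps)
            out.append({
                "animal_id": animal, "period_index": int(row["period_index"]),
                "label": row["label"], "quantity": row["quantity"],
                "value": row["mean_value"], "baseline": base["mean_value"],
                "ratio": row["mean_value"] / base["mean_value"] if valid else np.nan,
                "valid": valid,
            })
    return pd.DataFrame(out)


def group_summary(normalised: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.e.m. of valid per-animal ratios, per stimulation period."""
    valid = normalised[normalised["valid"]]
    rows = []
    for (idx, label), df in valid.groupby(["period_index", "label"], sort=True):
        r = df["ratio"].to_numpy()
        rows.append({
            "period_index": idx, "label": label, "n": r.size,
            "mean_ratio": float(r.mean()),
            "sem_ratio": float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else np.nan,
            "n_invalid": int((normalised["period_index"] == idx).sum() - r.size),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confinement metrics


def mean_x_velocity(track: Track, t0: float | None = None,
                    t1: float | None = None) -> float:
    """Net x-displacement rate (mm/s) between the samples nearest t0 and t1."""
    t = track.times_s
    i0 = 0 if t0 is None else int(np.argmin(np.abs(t - t0)))
    i1 = t.size - 1 if t1 is None else int(np.argmin(np.abs(t - t1)))
    if i1 - i0 < 1:
        raise ValueError("time span covers fewer than 2 samples")
    return float((track.head_mm[i1, 0] - track.head_mm[i0, 0]) / (t[i1] - t[i0]))


def prisoner_index(track: Track, region: RegionTrajectory) -> float:
    """Fraction of total time the head stays inside the safe region.

    Each inter-sample interval contributes its duration if the head was
    inside the (possibly moving) region at the interval's start.
    """
    inside = region.contains(track.head_mm, track.times_s)
    dt = np.diff(track.times_s)
    return float(np.sum(dt[inside[:-1]]) / track.duration_s)


def expected_occupancy(safe_mask: np.ndarray, chamber_mask: np.ndarray) -> float:
    """Area ratio of the safe zone to the whole chamber, by pixel counting.

    The prisoner index expected of animals indifferent to the light pattern.
    """
    safe = np.asarray(safe_mask) > 0
    chamber = np.asarray(chamber_mask) > 0
    if safe.shape != chamber.shape:
        raise ValueError("masks must share a shape")
    if not chamber.any():
        raise ValueError("empty chamber mask")
    if np.any(safe & ~chamber):
        raise ValueError("safe zone extends outside the chamber")
    return float(safe.sum() / chamber.sum())


def rolling_fraction(tracks: Sequence[Track],
                     schedule: PeriodSchedule | None = None) -> pd.DataFrame:
    """Percentage of animals rolling at each shared sample time."""
    if not tracks:
        raise ValueError("no tracks")
    for tr in tracks:
        if tr.rolling is None:
            raise ValueError(f"track {tr.animal_id!r} has no rolling labels")
    times = tracks[0].times_s
    for tr in tracks[1:]:
        if tr.times_s.shape != times.shape or not np.allclose(tr.times_s, times):
            raise ValueError("tracks must share a common time grid")
    flags = np.stack([tr.rolling for tr in tracks])
    df = pd.DataFrame({
        "time_s": times,
        "pct_rolling": 100.0 * flags.mean(axis=0),
        "n_tracked": flags.shape[0],
    })
    if schedule is not None:
        df["label"] = [schedule.period_at(t).label
                       if t < schedule.total_duration_s else "end" for t in times]
    return df


# ---------------------------------------------------------------------------
# positional distribution


@dataclass
class GaussianPositionFit:
    mean_mm: float
    sd_mm: float
    ci95_mm: tuple[float, float]
    #: distances of the CI bounds to the segment's start and end
    margin_mm: tuple[float, float]
    hist_counts: np.ndarray
    bin_edges_mm: np.ndarray
    n: int
    degenerate: bool


def position_gaussian(tracks: Sequence[Track],
                      axis_segment: tuple[tuple[float, float], tuple[float, float]],
                      bin_mm: float = 1.0) -> GaussianPositionFit:
    """Gaussian summary of pooled head positions along an axis segment.

    Positions are projected onto the segment (coordinate 0 at the first
    endpoint); the fit uses moment estimates (sample mean/sd), the 95%
    interval is ``mean +/- 1.96 sd``, and the margins report how far the
    interval bounds stay from the segment ends — how much clearance the
    animals kept from the lit borders.
    """
    (x0, y0), (x1, y1) = axis_segment
    axis = np.array([x1 - x0, y1 - y0], dtype=float)
    length = float(np.hypot(*axis))
    if length == 0:
        raise ValueError("degenerate axis segment")
    unit = axis / length
    coords = np.concatenate(
        [(tr.head_mm - np.array([x0, y0])) @ unit for tr in tracks])
    if coords.size < 30:
        raise ValueError("need at least 30 pooled positions")
    mean = float(coords.mean())
    sd = float(coords.std(ddof=1))
    degenerate = sd == 0.0
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    edges = np.arange(0.0, length + bin_mm, bin_mm)
    counts, edges = np.histogram(coords, bins=edges)
    return GaussianPositionFit(
        mean_mm=mean, sd_mm=sd, ci95_mm=(lo, hi),
        margin_mm=(lo - 0.0, length - hi),
        hist_counts=counts, bin_edges_mm=edges, n=coords.size,
        degenerate=degenerate)


# ---------------------------------------------------------------------------
# statistics


def t_statistics(sample_a: Sequence[float], mu_or_sample_b,
                 mode: str = "one_sample",
                 equal_var: bool = False) -> tuple[float, float, float]:
    """Student t test: ``(t, df, two-tailed p)``.

    One-sample against a population mean, or two-sample (Welch by default).
    Degenerate zero-variance one-sample input follows the convention
    p -> 0 when the mean differs from mu and p = 1 when it equals mu.
    """
    a = np.asarray(sample_a, dtype=float)
    if a.size < 2:
        raise ValueError("need n >= 2")
    if mode == "one_sample":
        mu = float(mu_or_sample_b)
        if a.std(ddof=1) == 0:
            if a.mean() == mu:
                return 0.0, float(a.size - 1), 1.0
            return float(np.sign(a.mean() - mu) * np.inf), float(a.size - 1), 0.0
        res = stats.ttest_1samp(a, popmean=mu)
        return float(res.statistic), float(res.df), float(res.pvalue)
    if mode == "two_sample":
        b = np.asarray(mu_or_sample_b, dtype=float)
        if b.size < 2:
            raise ValueError("need n >= 2 per sample")
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        return float(res.statistic), float(res.df), float(res.pvalue)
    raise ValueError("mode must be 'one_sample' or 'two_sample'")
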