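"""Spectral, radiometric, geometric and temporal characterisation of a
display used as an optogenetic light source.

A flat-panel display is an array of red/green/blue sub-pixel emitters behind
a cover glass.  Whether it can drive a given channelrhodopsin depends on
(i) the overlap between sub-pixel emission spectra and the opsin action
spectrum, (ii) the irradiance each channel delivers at full drive and how it
scales with the 0-255 drive value, (iii) how far light spreads laterally on
its way through the cover glass (spatial resolution), and (iv) how fast the
panel switches.  This module provides those four computations on simple
array-backed containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "AngularProfile",
    "ChannelModel",
    "DisplayModel",
    "IntensityTrace",
    "spectral_overlap",
    "channel_power_density",
    "effective_drive",
    "lateral_spread",
    "rise_fall_times",
]


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum carries no power (all-zero intensities)."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled wavelength/intensity curve in relative units.

    Used both for display sub-pixel emission and for opsin action spectra.
    Outside its sampled support the spectrum is taken to be zero.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or i.ndim != 1 or w.size != i.size:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if w.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")
        if not np.any(i > 0):
            raise ValueError("degenerate spectrum: all intensities are zero")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "intensities", i)

    def interpolate(self, grid_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid_nm``; zero outside the support."""
        return np.interp(grid_nm, self.wavelengths_nm, self.intensities, left=0.0, right=0.0)

    def normalised_to_peak(self) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, self.intensities / self.intensities.max())

    @classmethod
    def gaussian(cls, peak_nm: float, sigma_nm: float,
                 lo_nm: float = 350.0, hi_nm: float = 750.0,
                 step_nm: float = 1.0) -> "Spectrum":
        """Synthetic Gaussian band, a stand-in for unpublished measured curves."""
        w = np.arange(lo_nm, hi_nm + 0.5 * step_nm, step_nm)
        return cls(w, np.exp(-0.5 * ((w - peak_nm) / sigma_nm) ** 2))


@dataclass(frozen=True)
class AngularProfile:
    """Relative radiant intensity I(theta) of an area emitter.

    Angles in degrees from the surface normal, on [0, 90].  The flux emitted
    into [theta, theta+dtheta] is proportional to I(theta) sin(theta) dtheta.
    """

    angles_deg: np.ndarray
    radiant_intensity: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=float)
        r = np.asarray(self.radiant_intensity, dtype=float)
        if a.size != r.size or a.ndim != 1:
            raise ValueError("angles and intensities must be 1-D and equal length")
        if not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing")
        if a[0] != 0.0:
            raise ValueError("profile must include theta = 0")
        if a[-1] > 90.0 or np.any(a < 0):
            raise ValueError("angles must lie in [0, 90] degrees")
        if np.any(r < 0):
            raise ValueError("radiant intensity must be non-negative")
        if not np.any(r > 0):
            raise ValueError("degenerate angular profile")
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "radiant_intensity", r)

    @classmethod
    def lambertian(cls, n_points: int = 9001) -> "AngularProfile":
        """I(theta) = cos(theta), the textbook flat-panel emission profile.

        Sampled densely (0.01 deg default) so that downstream quadrature is
        limited by the integration step, not by linear interpolation of cos.
        """
        a = np.linspace(0.0, 90.0, n_points)
        return cls(a, np.cos(np.radians(a)))

    @classmethod
    def forward_only(cls) -> "AngularProfile":
        """All flux at normal incidence (idealised collimated emitter)."""
        return cls(np.array([0.0, 0.5, 90.0]), np.array([1.0, 0.0, 0.0]))


def _default_transfer(gamma: float) -> Callable[[np.ndarray], np.ndarray]:
    def transfer(drive):
        return (np.asarray(drive, dtype=float) / 255.0) ** gamma
    return transfer


@dataclass
class ChannelModel:
    """One display primary: emission spectrum, peak irradiance, transfer curve.

    ``max_power_density`` is the irradiance in µW/mm² at the specimen plane
    for drive value 255.  The drive->output relation of consumer panels is
    strongly nonlinear; by default a gamma power law ``(d/255)**gamma`` with
    the display-industry standard gamma 2.2 is used, or a measured lookup
    table ``(drive, fraction of max)`` may be supplied.
    """

    name: str
    emission: Spectrum
    max_power_density: float
    transfer_gamma: float = 2.2
    transfer_lut: Sequence[tuple[float, float]] | None = None

    def __post_init__(self):
        if self.name not in ("red", "green", "blue"):
            raise ValueError("channel name must be red, green or blue")
        if self.max_power_density <= 0:
            raise ValueError("max_power_density must be positive")
        if self.transfer_lut is not None:
            lut = np.asarray(self.transfer_lut, dtype=float)
            d, f = lut[:, 0], lut[:, 1]
            if not np.all(np.diff(d) > 0):
                raise ValueError("LUT drive values must be strictly increasing")
            if np.any(np.diff(f) < 0):
                raise ValueError("LUT transfer must be monotone non-decreasing")
            if d[0] != 0 or d[-1] != 255 or f[0] != 0 or abs(f[-1] - 1) > 1e-12:
                raise ValueError("LUT must map 0 -> 0 and 255 -> 1")
            self._lut = (d, f)
        elif self.transfer_gamma <= 0:
            raise ValueError("gamma must be positive")

    def transfer(self, drive) -> np.ndarray | float:
        """Fraction of max output at integer drive value(s) in 0-255."""
        if self.transfer_lut is not None:
            d, f = self._lut
            return np.interp(drive, d, f)
        return _default_transfer(self.transfer_gamma)(drive)


@dataclass
class DisplayModel:
    """Physical and photometric description of one display."""

    channels: dict[str, ChannelModel]
    glass_thickness_mm: float
    angular: AngularProfile
    refresh_hz: float = 60.0
    subpixel_size_mm: tuple[float, float] = (0.041, 0.012)
    pixel_pitch_mm: float = 0.05
    black_residual_uw_mm2: float = 0.0  # metadata; black frames render as zero

    def __post_init__(self):
        missing = {"red", "green", "blue"} - set(self.channels)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")
        if not (0.1 < self.glass_thickness_mm < 5):
            raise ValueError("glass thickness out of plausible range (0.1, 5) mm")
        if self.refresh_hz < 24:
            raise ValueError("refresh rate below 24 Hz")


@dataclass(frozen=True)
class IntensityTrace:
    """A photodiode/oscilloscope-style intensity-versus-time record."""

    times_s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if t.size != i.size or t.size < 3:
            raise ValueError("trace needs >= 3 aligned samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensity must be non-negative")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensity", i)


# ---------------------------------------------------------------------------
# operations


def spectral_overlap(emission: Spectrum, action: Spectrum) -> float:
    """Fraction of emitted power usable by an opsin.

    The action spectrum is rescaled to peak 1 and the emission-weighted mean
    activation ``integral(E * A_hat) / integral(E)`` is returned.  1.0 means
    every emitted photon falls where the opsin is maximally sensitive; 0.0
    means the spectra are disjoint.
    """
    if not np.any(emission.intensities > 0):  # unreachable via constructor
        raise DegenerateSpectrumError("degenerate spectrum")
    grid = np.union1d(emission.wavelengths_nm, action.wavelengths_nm)
    e = emission.interpolate(grid)
    a = action.normalised_to_peak().interpolate(grid)
    total = np.trapezoid(e, grid)
    if total <= 0:
        raise DegenerateSpectrumError("degenerate spectrum")
    return float(np.trapezoid(e * a, grid) / total)


def channel_power_density(channel: ChannelModel, drive: int) -> float:
    """Irradiance (µW/mm²) of one channel at an integer drive value 0-255."""
    if not 0 <= drive <= 255:
        raise ValueError(f"drive value {drive} outside [0, 255]")
    return float(channel.max_power_density * channel.transfer(drive))


def effective_drive(display: DisplayModel, rgb: tuple[int, int, int],
                    action: Spectrum) -> float:
    """Opsin-weighted irradiance (µW/mm²) of an RGB colour on a display.

    Sums, over the three channels, the channel irradiance at its drive value
    weighted by the spectral overlap of that channel with the action
    spectrum.  Additive over channels by construction.
    """
    total = 0.0
    for name, value in zip(("red", "green", "blue"), rgb):
        ch = display.channels[name]
        if value > 0:
            total += channel_power_density(ch, value) * spectral_overlap(ch.emission, action)
        else:
            channel_power_density(ch, value)  # still range-checks the drive
    return total


def _refract(theta_air_rad: np.ndarray, n: float) -> np.ndarray:
    return np.arcsin(np.clip(np.sin(theta_air_rad) / n, 0.0, 1.0))


def lateral_spread(angular: AngularProfile, glass_thickness_mm: float,
                   containment: float = 0.95,
                   refractive_index: float | None = None,
                   n_quad: int = 100001) -> float:
    """Containment radius of light from a point emitter under cover glass.

    Smallest lateral radius r (mm) at the top of the glass such that a
    fraction ``containment`` of the emitted flux lands within r of the
    emitter axis.  A ray at polar angle theta travels laterally
    ``t * tan(theta)``; with a refractive index n the in-glass angle obeys
    sin(theta_glass) = sin(theta_air)/n.  Flux is weighted by
    I(theta) sin(theta) dtheta.  For a Lambertian profile without refraction
    the closed form is ``t * tan(arcsin(sqrt(c)))``.
    """
    if not 0 < containment < 1:
        if containment >= 1 and angular.angles_deg[-1] >= 90.0:
            raise ValueError("unbounded spread: containment >= 1 with emission at 90 deg")
        raise ValueError("containment must lie in (0, 1)")
    if glass_thickness_mm <= 0:
        raise ValueError("glass thickness must be positive")

    support = angular.angles_deg[angular.radiant_intensity > 0]
    if support.max() == 0.0:  # all flux on the normal: no lateral spread
        return 0.0

    th_max = np.radians(angular.angles_deg[-1])
    theta = np.linspace(0.0, th_max, n_quad)
    inten = np.interp(np.degrees(theta), angular.angles_deg, angular.radiant_intensity)
    w = inten * np.sin(theta)
    cdf = np.concatenate(([0.0], np.cumsum((w[1:] + w[:-1]) * 0.5 * np.diff(theta))))
    if cdf[-1] <= 0:
        raise ValueError("degenerate angular profile")
    cdf /= cdf[-1]
    # lateral radius is monotone in theta, so the containment radius is the
    # radius at the containment quantile of the angular flux distribution
    theta_c = float(np.interp(containment, cdf, theta))
    if refractive_index is not None:
        theta_c = float(_refract(np.array(theta_c), refractive_index))
    return glass_thickness_mm * float(np.tan(theta_c))


def rise_fall_times(trace: IntensityTrace, on_time_s: float, off_time_s: float,
                    rise_frac: float = 0.9, fall_frac: float = 0.1,
                    convention: str = "commanded") -> tuple[float, float]:
    """Switching times of a display from a photodiode trace.

    Rise time: delay from the commanded ON instant until the intensity first
    exceeds ``rise_frac`` (90%) of the plateau.  Fall time: delay from the
    commanded OFF instant until it first drops below ``fall_frac`` (10%).
    With ``convention="10-90"`` the rise is instead measured between the 10%
    and 90% crossings (and the fall between 90% and 10%).

    Plateau and baseline levels are estimated from the trace itself: the
    baseline from samples before ``on_time_s``, the plateau from the last
    quarter of the ON interval.  Crossing instants are linearly interpolated
    between samples.
    """
    if convention not in ("commanded", "10-90"):
        raise ValueError("convention must be 'commanded' or '10-90'")
    t, y = trace.times_s, trace.intensity
    if not (t[0] <= on_time_s < off_time_s <= t[-1]):
        raise ValueError("trace must span both transitions")

    pre = y[t < on_time_s]
    baseline = float(pre.mean()) if pre.size else 0.0
    on_mask = (t >= on_time_s) & (t < off_time_s)
    on_t = t[on_mask]
    plateau_window = on_t[0] + 0.75 * (on_t[-1] - on_t[0])
    plateau = float(y[on_mask & (t >= plateau_window)].mean())
    if plateau <= baseline:
        raise ValueError("incomplete transition: no plateau above baseline")

    def level(frac):
        return baseline + frac * (plateau - baseline)

    def first_crossing(t0, upward, frac):
        thr = level(frac)
        sel = t >= t0
        ts, ys = t[sel], y[sel]
        hit = ys >= thr if upward else ys <= thr
        if not hit.any():
            raise ValueError("incomplete transition: threshold never crossed")
        k = int(np.argmax(hit))
        if k == 0:
            return float(ts[0])
        # interpolate the crossing between samples k-1 and k
        y0, y1 = ys[k - 1], ys[k]
        if y1 == y0:
            return float(ts[k])
        return float(ts[k - 1] + (thr - y0) / (y1 - y0) * (ts[k] - ts[k - 1]))

    if convention == "commanded":
        rise = first_crossing(on_time_s, True, rise_frac) - on_time_s
        fall = first_crossing(off_time_s, False, fall_frac) - off_time_s
    else:
        rise = first_crossing(on_time_s, True, rise_frac) - first_crossing(
            on_time_s, True, fall_frac)
        fall = first_crossing(off_time_s, False, fall_frac) - first_crossing(
            off_time_s, False, rise_frac)
    return max(rise, 0.0), max(fall, 0.0)
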