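"""Bundled display and opsin presets.

The Honor 8 preset carries the published scalar characterisation of that
panel: per-channel peak irradiance 1.8 µW/mm² (blue) and 2.1 µW/mm² (green
and red), 0.68 mm cover glass, 60 Hz refresh, 41 µm x 12 µm sub-pixels and
a black-state residual of 5.3e-3 µW/mm².  The *curves* (sub-pixel emission
spectra, opsin action spectra, measured angular profile) were never
published, so synthetic Gaussian stand-ins with field-typical peak
wavelengths are used; the angular profile defaults to Lambertian.  Numbers
that depend only on the scalars are exact; numbers that depend on the curves
are model numbers.
"""

from __future__ import annotations

from .photometry import AngularProfile, ChannelModel, DisplayModel, Spectrum

__all__ = ["honor8_display", "action_spectrum", "flat_action_spectrum", "OPSIN_PEAKS_NM"]

# (peak nm, sigma nm) of synthetic Gaussian action spectra; peaks follow the
# published maxima of each opsin, widths are typical of rhodopsin bands
OPSIN_PEAKS_NM = {
    "cschrimson": (590.0, 45.0),
    "chr2xxl": (460.0, 35.0),
    "gtacr1": (515.0, 40.0),
    "gtacr2": (470.0, 30.0),
}

# synthetic sub-pixel emission bands (peak nm, sigma nm) for an LCD panel
_CHANNEL_BANDS = {
    "red": (610.0, 12.0),
    "green": (535.0, 15.0),
    "blue": (455.0, 10.0),
}

_CHANNEL_MAX_UW_MM2 = {"red": 2.1, "green": 2.1, "blue": 1.8}


def honor8_display(angular: AngularProfile | None = None) -> DisplayModel:
    """The Honor 8 LCD panel as an optogenetic light source.

    Synthetic emission spectra (Gaussian bands); published scalar values.
    """
    channels = {
        name: ChannelModel(
            name=name,
            emission=Spectrum.gaussian(*_CHANNEL_BANDS[name]),
            max_power_density=_CHANNEL_MAX_UW_MM2[name],
        )
        for name in ("red", "green", "blue")
    }
    return DisplayModel(
        channels=channels,
        glass_thickness_mm=0.68,
        angular=angular if angular is not None else AngularProfile.lambertian(),
        refresh_hz=60.0,
        subpixel_size_mm=(0.041, 0.012),
        pixel_pitch_mm=0.05,
        black_residual_uw_mm2=5.3e-3,
    )


def action_spectrum(opsin: str) -> Spectrum:
    """Synthetic Gaussian action spectrum for a named channelrhodopsin."""
    try:
        peak, sigma = OPSIN_PEAKS_NM[opsin.lower()]
    except KeyError:
        raise KeyError(
            f"unknown opsin {opsin!r}; choose from {sorted(OPSIN_PEAKS_NM)}") from None
    return Spectrum.gaussian(peak, sigma)


def flat_action_spectrum(lo_nm: float = 350.0, hi_nm: float = 750.0) -> Spectrum:
    """Uniform sensitivity across the visible band (overlap 1 per channel)."""
    import numpy as np

    w = np.arange(lo_nm, hi_nm + 0.5, 1.0)
    return Spectrum(w, np.ones_like(w))
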