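"""Readers and writers for the package's plain-text interchange formats.

Formats:

* spectra — two-column text (wavelength_nm, intensity), ``#`` comments;
* tracks — CSV with header ``animal_id,time_s,head_x_mm,head_y_mm`` and
  optional ``tail_x_mm,tail_y_mm`` and ``rolling`` columns, one row per
  sample, '.' decimal, UTF-8;
* protocols and display models — YAML mappings;
* pattern masks — grayscale PNG, nonzero = lit.

Every writer's output is re-readable by the matching reader (round-trip
contract).  Malformed inputs raise :class:`ValidationError` naming the
offending file and row/key.  A JSON run manifest recording inputs, seed and
package versions can be attached to any output directory.
"""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .photometry import AngularProfile, ChannelModel, DisplayModel, Spectrum
from .stimulus import Protocol, StimulusStep, SyncMarker

__all__ = [
    "ValidationError",
    "read_spectrum",
    "write_spectrum",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_protocol",
    "write_protocol",
    "read_mask_png",
    "write_mask_png",
    "read_display_config",
    "write_display_config",
    "write_run_manifest",
]


class ValidationError(ValueError):
    """Malformed input file; the message names the file and row/key."""


# ---------------------------------------------------------------------------
# spectra


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    wavelengths, intensities = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValidationError(f"{path}: line {lineno}: expected 2 columns")
        try:
            wavelengths.append(float(parts[0]))
            intensities.append(float(parts[1]))
        except ValueError:
            raise ValidationError(f"{path}: line {lineno}: non-numeric value") from None
    try:
        return Spectrum(np.array(wavelengths), np.array(intensities))
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_spectrum(spectrum: Spectrum, path, comment: str | None = None) -> Path:
    path = Path(path)
    lines = []
    if comment:
        lines.extend(f"# {c}" for c in comment.splitlines())
    lines.append("# wavelength_nm intensity")
    lines.extend(f"{w:.6g} {i:.8g}" for w, i in
                 zip(spectrum.wavelengths_nm, spectrum.intensities))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# tracks


_TRACK_REQUIRED = ["animal_id", "time_s", "head_x_mm", "head_y_mm"]


def write_tracks_csv(tracks: Sequence, path) -> Path:
    from .metrics import Track  # noqa: F401  (type of the elements)

    path = Path(path)
    frames = []
    for tr in tracks:
        df = pd.DataFrame({
            "animal_id": tr.animal_id,
            "time_s": tr.times_s,
            "head_x_mm": tr.head_mm[:, 0],
            "head_y_mm": tr.head_mm[:, 1],
        })
        if tr.tail_mm is not None:
            df["tail_x_mm"] = tr.tail_mm[:, 0]
            df["tail_y_mm"] = tr.tail_mm[:, 1]
        if tr.rolling is not None:
            df["rolling"] = tr.rolling.astype(int)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    return path


def read_tracks_csv(path) -> list:
    from .metrics import Track

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: unreadable CSV ({exc})") from None
    missing = [c for c in _TRACK_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if col in ("animal_id",):
            continue
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: row {bad.index[0] + 2}: non-numeric value in {col!r}")
    has_tail = {"tail_x_mm", "tail_y_mm"} <= set(df.columns)
    has_roll = "rolling" in df.columns
    tracks = []
    for animal, g in df.groupby("animal_id", sort=False):
        try:
            tracks.append(Track(
                animal_id=str(animal),
                times_s=g["time_s"].to_numpy(float),
                head_mm=g[["head_x_mm", "head_y_mm"]].to_numpy(float),
                tail_mm=g[["tail_x_mm", "tail_y_mm"]].to_numpy(float) if has_tail else None,
                rolling=g["rolling"].to_numpy(float).astype(bool) if has_roll else None,
            ))
        except ValueError as exc:
            raise ValidationError(f"{path}: animal {animal!r}: {exc}") from None
    if not tracks:
        raise ValidationError(f"{path}: no track rows")
    return tracks


# ---------------------------------------------------------------------------
# protocols


def _step_to_dict(step: StimulusStep) -> dict:
    d = {
        "duration_s": float(step.duration_s),
        "pattern": step.pattern,
        "rgb": [int(v) for v in step.rgb],
        "sync_marker": bool(step.sync_marker),
    }
    if step.geometry:
        d["geometry"] = {k: float(v) for k, v in step.geometry.items()}
    if tuple(step.position_mm) != (0.0, 0.0):
        d["position_mm"] = [float(v) for v in step.position_mm]
    if tuple(step.velocity_mm_s) != (0.0, 0.0):
        d["velocity_mm_s"] = [float(v) for v in step.velocity_mm_s]
    return d


def write_protocol(protocol: Protocol, path, mask_paths: dict | None = None) -> Path:
    """Serialise a protocol to YAML.

    Image-pattern steps have their masks written as sibling PNG files
    (named ``<stem>_mask<i>.png`` unless ``mask_paths`` maps step index to
    a filename) and referenced by relative path.
    """
    path = Path(path)
    doc = {
        "arena_mm": [float(v) for v in protocol.arena_mm],
        "mm_per_px": float(protocol.mm_per_px),
        "steps": [],
    }
    if protocol.sync_marker is not None:
        doc["sync_marker"] = {
            "centre_mm": [float(v) for v in protocol.sync_marker.centre_mm],
            "diameter_mm": float(protocol.sync_marker.diameter_mm),
        }
    for i, step in enumerate(protocol.steps):
        d = _step_to_dict(step)
        if step.pattern == "image":
            name = (mask_paths or {}).get(i, f"{path.stem}_mask{i}.png")
            write_mask_png(step.image_mask, path.parent / name)
            d["image"] = name
        doc["steps"].append(d)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_protocol(path) -> Protocol:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: invalid YAML ({exc})") from None
    if not isinstance(doc, dict) or "steps" not in doc:
        raise ValidationError(f"{path}: missing key 'steps'")
    steps = []
    for i, d in enumerate(doc["steps"]):
        try:
            mask = None
            if d.get("image"):
                mask = read_mask_png(path.parent / d["image"])
            steps.append(StimulusStep(
                duration_s=float(d["duration_s"]),
                pattern=d.get("pattern", "full_field"),
                rgb=tuple(d.get("rgb", (255, 255, 255))),
                geometry=d.get("geometry", {}) or {},
                position_mm=tuple(d.get("position_mm", (0.0, 0.0))),
                velocity_mm_s=tuple(d.get("velocity_mm_s", (0.0, 0.0))),
                image_mask=mask,
                sync_marker=bool(d.get("sync_marker", True)),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: steps[{i}]: {exc}") from None
    sync = None
    if "sync_marker" in doc and isinstance(doc["sync_marker"], dict):
        sync = SyncMarker(centre_mm=tuple(doc["sync_marker"]["centre_mm"]),
                          diameter_mm=float(doc["sync_marker"].get("diameter_mm", 2.0)))
    try:
        return Protocol(steps=steps,
                        arena_mm=tuple(doc.get("arena_mm", (60.0, 40.0))),
                        mm_per_px=float(doc.get("mm_per_px", 0.5)),
                        sync_marker=sync)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# masks


def write_mask_png(mask: np.ndarray, path) -> Path:
    path = Path(path)
    arr = np.asarray(mask)
    if arr.dtype != np.uint8:
        arr = (np.asarray(arr) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)
    return path


def read_mask_png(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


# ---------------------------------------------------------------------------
# display models


def write_display_config(display: DisplayModel, path,
                         spectra_dir: str = ".") -> Path:
    """Serialise a display model to YAML + sibling spectrum files."""
    path = Path(path)
    doc = {
        "glass_thickness_mm": display.glass_thickness_mm,
        "refresh_hz": display.refresh_hz,
        "subpixel_size_mm": list(display.subpixel_size_mm),
        "pixel_pitch_mm": display.pixel_pitch_mm,
        "black_residual_uw_mm2": display.black_residual_uw_mm2,
        "channels": {},
    }
    for name, ch in display.channels.items():
        fname = f"{path.stem}_{name}.txt"
        write_spectrum(ch.emission, path.parent / Path(spectra_dir) / fname)
        doc["channels"][name] = {
            "spectrum_file": str(Path(spectra_dir) / fname),
            "max_power_density_uw_mm2": ch.max_power_density,
            "gamma": ch.transfer_gamma,
        }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_display_config(path, angular: AngularProfile | None = None) -> DisplayModel:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: invalid YAML ({exc})") from None
    if "channels" not in doc:
        raise ValidationError(f"{path}: missing key 'channels'")
    missing = [n for n in ("red", "green", "blue") if n not in doc["channels"]]
    if missing:
        raise ValidationError(f"{path}: channels: missing key(s) {missing}")
    channels = {}
    for name in ("red", "green", "blue"):
        c = doc["channels"][name]
        try:
            channels[name] = ChannelModel(
                name=name,
                emission=read_spectrum(path.parent / c["spectrum_file"]),
                max_power_density=float(c["max_power_density_uw_mm2"]),
                transfer_gamma=float(c.get("gamma", 2.2)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: channels.{name}: {exc}") from None
    try:
        return DisplayModel(
            channels=channels,
            glass_thickness_mm=float(doc["glass_thickness_mm"]),
            angular=angular if angular is not None else AngularProfile.lambertian(),
            refresh_hz=float(doc.get("refresh_hz", 60.0)),
            subpixel_size_mm=tuple(doc.get("subpixel_size_mm", (0.041, 0.012))),
            pixel_pitch_mm=float(doc.get("pixel_pitch_mm", 0.05)),
            black_residual_uw_mm2=float(doc.get("black_residual_uw_mm2", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# run manifest


def write_run_manifest(out_dir, inputs: dict, seed: int | None = None) -> Path:
    """Record inputs, seed, versions and a timestamp for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = {
        "package": "optoscreen",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
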