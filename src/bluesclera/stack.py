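"""Bracketed exposure stacks and their on-disk representation.

An :class:`ExposureStack` holds the raw input of the colorimetric pipeline:
an ordered series of RGB frames of the same scene taken at strictly
increasing exposure times, together with those times.  Frames are kept in
memory as linear-light floats in [0, 1]; the acquisition bit depth is
retained only for saturation handling and file export.

All synthesis and analysis happen in linear light.  Files are written as
16-bit PNGs with a ``"colorspace": "linear"`` declaration in the JSON
manifest; 8-bit inputs without such a declaration are assumed sRGB-encoded
and pass through the inverse transfer function at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ExposureStack",
    "srgb_to_linear",
    "linear_to_srgb",
    "save_stack",
    "load_stack",
]


def srgb_to_linear(v: np.ndarray) -> np.ndarray:
    """Inverse sRGB transfer function (input and output in [0, 1])."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(v: np.ndarray) -> np.ndarray:
    """Forward sRGB transfer function (input and output in [0, 1])."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


@dataclass(frozen=True)
class ExposureStack:
    """Bracketed RGB frames of one scene.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W, 3)
        Linear-light pixel values in [0, 1].
    exposure_times : ndarray, shape (n_frames,)
        Strictly increasing positive exposure times in seconds.
    bit_depth : int
        Acquisition depth, 8 or 16.
    """

    frames: np.ndarray
    exposure_times: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.exposure_times, dtype=float)
        if frames.ndim != 4 or frames.shape[-1] != 3 or frames.shape[0] < 1:
            raise ValueError("frames must have shape (n_frames, H, W, 3) with n_frames >= 1")
        if times.shape != (frames.shape[0],):
            raise ValueError("need exactly one exposure time per frame")
        if np.any(times <= 0):
            raise ValueError("exposure times must be positive")
        if np.any(np.diff(times) <= 0):
            raise ValueError("exposure times must be strictly increasing")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "exposure_times", times)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def save_stack(stack: ExposureStack, directory: str | Path, prefix: str = "frame") -> Path:
    """Write a stack as 16-bit linear TIFFs plus a JSON manifest.

    Returns the manifest path.  Quantisation to 16 bits is the only loss.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for k in range(stack.n_frames):
        name = f"{prefix}_{k:02d}.tif"
        data = np.clip(stack.frames[k], 0.0, 1.0)
        iio.imwrite(directory / name, np.round(data * 65535).astype(np.uint16))
        entries.append({"file": name, "exposure_time_s": float(stack.exposure_times[k])})
    manifest = {
        "frames": entries,
        "bit_depth": 16,
        "colorspace": "linear",
    }
    path = directory / "stack_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_stack(manifest_path: str | Path) -> ExposureStack:
    """Read a stack written by :func:`save_stack` (or a compatible manifest).

    8-bit files in a manifest without ``"colorspace": "linear"`` are decoded
    through the inverse sRGB transfer; 16-bit linear files pass through.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    linear = manifest.get("colorspace", "srgb") == "linear"
    frames, times = [], []
    for entry in manifest["frames"]:
        raw = iio.imread(manifest_path.parent / entry["file"])
        if raw.dtype == np.uint16:
            v = raw.astype(float) / 65535.0
        elif raw.dtype == np.uint8:
            v = raw.astype(float) / 255.0
        else:
            v = raw.astype(float)
        if not linear:
            v = srgb_to_linear(v)
        frames.append(v)
        times.append(entry["exposure_time_s"])
    return ExposureStack(
        frames=np.stack(frames), exposure_times=np.asarray(times),
        bit_depth=int(manifest.get("bit_depth", 16)),
    )
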