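"""Frame/mask readers and writers plus YAML configuration helpers.

Frame sequences are directories of PNG/TIFF files consumed in
lexicographic order; masks are PNG with foreground stored as 255.  Common
video containers are decoded to frames through imageio when a suitable
plugin is available.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import InvalidArgumentError

__all__ = [
    "read_frames",
    "write_frames",
    "read_masks",
    "write_masks",
    "load_yaml",
    "save_yaml",
]

_FRAME_EXTS = (".png", ".tif", ".tiff")
_VIDEO_EXTS = (".mp4", ".avi", ".mov", ".mkv")


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return np.asarray(img)


def read_frames(path) -> list[np.ndarray]:
    """Read a frame directory (sorted PNG/TIFF) or a video container."""
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise InvalidArgumentError(f"no PNG/TIFF frames in {p}")
        return [_to_gray(iio.imread(f)) for f in files]
    if p.suffix.lower() in _VIDEO_EXTS:
        try:
            return [_to_gray(f) for f in iio.imiter(p)]
        except Exception as exc:  # plugin-dependent
            raise InvalidArgumentError(
                f"cannot decode {p}: {exc}; extract frames to a PNG directory instead"
            ) from exc
    raise InvalidArgumentError(f"{p} is neither a frame directory nor a known video container")


def write_frames(path, frames, prefix: str = "frame") -> list[Path]:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    out = []
    for i, frame in enumerate(frames):
        f = p / f"{prefix}_{i:05d}.png"
        iio.imwrite(f, np.asarray(frame, dtype=np.uint8))
        out.append(f)
    return out


def read_masks(path) -> list[np.ndarray]:
    """Read a directory of binary PNG masks (any nonzero pixel = foreground)."""
    return [np.asarray(m) > 0 for m in read_frames(path)]


def write_masks(path, masks, prefix: str = "mask") -> list[Path]:
    return write_frames(
        path, [np.asarray(m, dtype=bool).astype(np.uint8) * 255 for m in masks], prefix
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def save_yaml(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
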