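"""Pixel-level fusion of the two segmentation routes plus morphology.

The background-subtraction mask (motion evidence) and the network mask
(appearance evidence) are combined with a per-pixel bitwise operation —
OR by default, so the network can fill the false-negative holes motion
detection leaves inside dwelling targets — and the fused mask is then
cleaned with a configurable morphological sequence (default: opening with
a 3x3 ellipse to remove speckle, closing with a 5x5 ellipse to seal small
holes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError

__all__ = ["FusionConfig", "fuse_masks", "refine_morphology", "structuring_element"]

_OPS = ("open", "close", "erode", "dilate")


@dataclass
class FusionConfig:
    """Bitwise mode and ordered morphology sequence."""

    mode: str = "or"
    morphology: list[tuple[str, str, int]] = field(
        default_factory=lambda: [("open", "ellipse", 3), ("close", "ellipse", 5)]
    )

    def __post_init__(self) -> None:
        if self.mode not in ("or", "and"):
            raise InvalidArgumentError("fusion mode must be 'or' or 'and'")
        for op, shape, size in self.morphology:
            if op not in _OPS:
                raise InvalidArgumentError(f"unknown morphology op {op!r}")
            if shape not in ("ellipse", "rect"):
                raise InvalidArgumentError(f"unknown structuring element {shape!r}")
            if size < 1 or size % 2 == 0:
                raise InvalidArgumentError("structuring element sizes must be odd and >= 1")


def structuring_element(shape: str, size: int) -> np.ndarray:
    """Odd-sized binary footprint: filled ellipse (disc) or full rectangle."""
    if size < 1 or size % 2 == 0:
        raise InvalidArgumentError("size must be odd and >= 1")
    if shape == "rect":
        return np.ones((size, size), dtype=bool)
    if shape == "ellipse":
        r = size // 2
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        if r == 0:
            return np.ones((1, 1), dtype=bool)
        return (yy / r) ** 2 + (xx / r) ** 2 <= 1.0 + 1e-9
    raise InvalidArgumentError(f"unknown structuring element {shape!r}")


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool and not np.isin(np.unique(m), (0, 1, 255)).all():
        raise InvalidArgumentError(f"{name} must be binary")
    return m.astype(bool)


def fuse_masks(mask_a: np.ndarray, mask_b: np.ndarray, mode: str = "or") -> np.ndarray:
    """Per-pixel OR (default) or AND of two binary masks of equal shape."""
    a = _as_binary(mask_a, "mask_a")
    b = _as_binary(mask_b, "mask_b")
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mode == "or":
        return a | b
    if mode == "and":
        return a & b
    raise InvalidArgumentError("fusion mode must be 'or' or 'and'")


def refine_morphology(mask: np.ndarray, config: FusionConfig | None = None) -> np.ndarray:
    """Apply the configured morphology sequence; output binary, same shape."""
    config = config or FusionConfig()
    out = _as_binary(mask, "mask")
    # Outside the frame counts as foreground for erosion and background for
    # dilation, so opening stays anti-extensive and closing extensive right
    # up to the border.
    erode = lambda m, se: ndimage.binary_erosion(m, structure=se, border_value=1)
    dilate = lambda m, se: ndimage.binary_dilation(m, structure=se, border_value=0)
    for op, shape, size in config.morphology:
        se = structuring_element(shape, size)
        if op == "open":
            out = dilate(erode(out, se), se)
        elif op == "close":
            out = erode(dilate(out, se), se)
        elif op == "erode":
            out = erode(out, se)
        else:
            out = dilate(out, se)
    return out
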