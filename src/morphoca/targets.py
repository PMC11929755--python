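"""Synthetic target morphologies and PNG target I/O.

The generator draws a small family of lizard-like body plans on a square
RGBA canvas: a full-legged lizard (head disc, tapered body, curved tail,
four leg lobes, dark dorsal spots), a small-legged variant, a legless
variant ("snake", the lizard silhouette with the leg lobes removed), a
recoloured legless variant, and a compact spotted disc ("ladybug"
analogue). Silhouettes are binary in alpha, the head points up (the
angle-0 anterior convention), and all variants share canvas size and
centring so a model can be retrained across them without re-gridding.

Targets are used premultiplied (RGB scaled by alpha): since generated
alpha is exactly 0 or 1 and RGB is zero outside the body, generated
images are already premultiplied; loaded PNGs are premultiplied on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from PIL import Image

__all__ = ["BodyPlanSpec", "VARIANTS", "make_target", "load_target", "save_target", "premultiply"]


# body / spot colours per palette; chosen only for pixel-level
# distinguishability between variants
PALETTES = {
    "lizard": ((0.35, 0.62, 0.30), (0.10, 0.28, 0.10)),
    "yellow": ((0.88, 0.76, 0.18), (0.45, 0.36, 0.05)),
    "ladybug": ((0.82, 0.10, 0.10), (0.05, 0.05, 0.05)),
}

VARIANTS = ("lizard", "lizard_small_legs", "legless", "legless_recolored", "compact")

_VARIANT_DEFAULTS = {
    # (leg_scale, palette, compact body?)
    "lizard": (1.0, "lizard", False),
    "lizard_small_legs": (0.45, "lizard", False),
    "legless": (0.0, "lizard", False),
    "legless_recolored": (0.0, "yellow", False),
    "compact": (0.0, "ladybug", True),
}


@dataclass
class BodyPlanSpec:
    """Recipe for one synthetic target morphology."""

    variant: str = "lizard"
    size: int = 56
    leg_scale: Optional[float] = None  # default resolved from the variant
    palette: Optional[str] = None

    def __post_init__(self):
        if self.variant not in _VARIANT_DEFAULTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.size < 24:
            raise ValueError("target size must be at least 24 pixels")
        leg, pal, _ = _VARIANT_DEFAULTS[self.variant]
        if self.leg_scale is None:
            self.leg_scale = leg
        if not (0.0 <= self.leg_scale <= 1.0):
            raise ValueError("leg_scale must lie in [0, 1]")
        if self.palette is None:
            self.palette = pal
        if self.palette not in PALETTES:
            raise ValueError(f"unknown palette {self.palette!r}")


def _coords(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalised coordinates: x rightward, y downward, both in ~[-1, 1]."""
    half = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    return (cc - half) / half, (rr - half) / half


def _disc(x, y, cx, cy, rx, ry=None):
    ry = rx if ry is None else ry
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def _lizard_base(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Head + tapered trunk + curved tail silhouette (no legs)."""
    sil = _disc(x, y, 0.0, -0.48, 0.20)  # head
    trunk = (y >= -0.50) & (y <= 0.34)
    half_width = 0.21 - 0.11 * (y + 0.50) / 0.84  # tapers toward the tail
    sil |= trunk & (np.abs(x) <= half_width)
    # tail: discs of shrinking radius stamped along a rightward-curving arc
    for t in np.linspace(0.0, 1.0, 40):
        cx = 0.33 * t * t
        cy = 0.34 + 0.36 * t
        sil |= _disc(x, y, cx, cy, 0.085 * (1.0 - 0.75 * t) + 0.015)
    return sil


def _leg_lobes(x: np.ndarray, y: np.ndarray, leg_scale: float) -> np.ndarray:
    lobes = np.zeros_like(x, dtype=bool)
    if leg_scale <= 0.0:
        return lobes
    for side in (-1.0, 1.0):
        for cy, base in ((-0.26, 0.205), (0.18, 0.135)):
            cx = side * (base + 0.16 * leg_scale)
            lobes |= _disc(x, y, cx, cy, 0.06 + 0.13 * leg_scale, 0.055 + 0.05 * leg_scale)
    return lobes


def _dorsal_spots(x: np.ndarray, y: np.ndarray, compact: bool) -> np.ndarray:
    spots = np.zeros_like(x, dtype=bool)
    if compact:
        centres = [(-0.14, -0.12), (0.14, -0.12), (-0.16, 0.16), (0.16, 0.16), (0.0, 0.03)]
        r = 0.075
    else:
        centres = [(0.0, -0.20), (0.0, 0.0), (0.0, 0.18)]
        r = 0.06
    for cx, cy in centres:
        spots |= _disc(x, y, cx, cy, r)
    return spots


def make_target(spec: BodyPlanSpec) -> np.ndarray:
    """Render a body-plan spec to a float RGBA image in [0, 1].

    Alpha is exactly binary; RGB is zero outside the silhouette, so the
    result is premultiplied by construction.
    """
    x, y = _coords(spec.size)
    _, _, compact = _VARIANT_DEFAULTS[spec.variant]
    if compact:
        sil = _disc(x, y, 0.0, 0.02, 0.40, 0.44) | _disc(x, y, 0.0, -0.44, 0.14)
    else:
        sil = _lizard_base(x, y) | _leg_lobes(x, y, spec.leg_scale)
    body_rgb, spot_rgb = PALETTES[spec.palette]
    spots = _dorsal_spots(x, y, compact) & sil

    img = np.zeros((spec.size, spec.size, 4), dtype=np.float32)
    for ch in range(3):
        img[..., ch] = np.where(spots, spot_rgb[ch], body_rgb[ch]) * sil
    img[..., 3] = sil.astype(np.float32)
    return img


def premultiply(image: np.ndarray) -> np.ndarray:
    """Scale RGB by alpha so transparent regions carry no colour signal."""
    out = image.astype(np.float32).copy()
    out[..., :3] *= out[..., 3:4]
    return out


def load_target(path) -> np.ndarray:
    """Read an RGBA PNG into a premultiplied float array in [0, 1]."""
    with Image.open(path) as im:
        if "A" not in im.getbands():
            raise ValueError(f"{path}: target must carry an alpha channel")
        arr = np.asarray(im.convert("RGBA"), dtype=np.float32) / 255.0
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"{path}: target must be square, got {arr.shape[0]}x{arr.shape[1]} pixels"
        )
    return premultiply(arr)


def save_target(image: np.ndarray, path) -> None:
    """Write a float RGBA array in [0, 1] as an 8-bit RGBA PNG."""
    if image.ndim != 3 or image.shape[-1] != 4:
        raise ValueError("expected an (H, W, 4) RGBA array")
    data = np.clip(np.asarray(image, dtype=np.float32), 0.0, 1.0)
    Image.fromarray(np.round(data * 255.0).astype(np.uint8), mode="RGBA").save(path)
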