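"""Maternal environment: the two organizer gradient channels.

The environment mimics the two organising centres of maternal factors
that establish the embryonic anterior-posterior axis: channel 0 is a
radially decaying bump at the anterior organizer, channel 1 the same at
the posterior one. Cells read these channels but can never write them,
so the axis they define is an external datum the developing pattern must
respect — which is what makes rotation-invariant growth possible.

Conventions: row 0 is the top of the grid, angles are measured
counter-clockwise, and at angle 0 the anterior organizer sits above the
grid centre (head up).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage

from .config import ModelConfig

__all__ = ["make_environment", "rotate_field"]


def _bump(height: int, width: int, centre: tuple[float, float], radius: float) -> np.ndarray:
    """Cosine-tapered radial bump: 1 at the centre, 0 beyond `radius`."""
    rr, cc = np.mgrid[0:height, 0:width]
    d = np.hypot(rr - centre[0], cc - centre[1])
    return np.clip(np.cos(math.pi * d / (2.0 * radius)), 0.0, 1.0).astype(np.float32)


def make_environment(
    height: int,
    width: int,
    angle: float = 0.0,
    organizer_offset: Optional[float] = None,
    decay_radius: Optional[float] = None,
    config: Optional[ModelConfig] = None,
) -> np.ndarray:
    """Build the (H, W, 2) environment field at a given orientation.

    The organizers sit at the grid centre displaced by
    ``organizer_offset * min(H, W) / 2`` along the axis direction:
    anterior opposite to, posterior along, the angle-rotated "down"
    direction (angle 0 puts the anterior organizer straight above the
    centre). Each channel is a cosine-tapered radial gradient with value
    exactly 1 at its organizer.
    """
    if height < 3 or width < 3:
        raise ValueError("environment grid must be at least 3x3")
    config = config or ModelConfig()
    if organizer_offset is None:
        organizer_offset = config.organizer_offset
    if decay_radius is None:
        decay_radius = config.decay_radius_frac * min(height, width) / 2.0
    if decay_radius <= 0:
        raise ValueError("decay_radius must be positive")

    cr, cc = (height - 1) / 2.0, (width - 1) / 2.0
    d = organizer_offset * min(height, width) / 2.0
    # counter-clockwise angle, row axis points down: angle 0 -> anterior up
    dr, dc = -d * math.cos(angle), -d * math.sin(angle)
    anterior = (cr + dr, cc + dc)
    posterior = (cr - dr, cc - dc)
    for name, (r, c) in (("anterior", anterior), ("posterior", posterior)):
        if not (0 <= r <= height - 1 and 0 <= c <= width - 1):
            raise ValueError(f"{name} organizer at ({r:.1f}, {c:.1f}) falls outside the grid")

    env = np.stack(
        [
            _bump(height, width, anterior, decay_radius),
            _bump(height, width, posterior, decay_radius),
        ],
        axis=-1,
    )
    # snap each organizer pixel to the exact channel maximum of 1
    env[round(anterior[0]), round(anterior[1]), 0] = 1.0
    env[round(posterior[0]), round(posterior[1]), 1] = 1.0
    return env


def rotate_field(field: np.ndarray, angle: float) -> np.ndarray:
    """Rotate an (H, W[, C]) field counter-clockwise about the grid centre.

    Quarter-turn multiples are exact array rotations; other angles use
    bilinear interpolation with zero fill outside the frame.
    """
    quarter = angle / (math.pi / 2.0)
    if abs(quarter - round(quarter)) < 1e-9:
        return np.rot90(field, k=round(quarter) % 4, axes=(0, 1)).copy()
    return ndimage.rotate(
        field,
        math.degrees(angle),
        axes=(1, 0),
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
    ).astype(field.dtype, copy=False)
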