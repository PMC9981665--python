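"""Minimum-image helpers for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np

__all__ = ["minimum_image", "fold", "minimum_image_distance"]


def minimum_image(delta: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Map displacement vectors into the nearest-image convention.

    Every component of the result lies in [-L/2, L/2).
    """
    delta = np.asarray(delta, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    return delta - lengths * np.round(delta / lengths)


def fold(positions: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Wrap positions into the primary cell [0, L).

    Guards against the floating-point edge case where ``np.mod`` of a tiny
    negative value rounds up to exactly L (which periodic KD-trees reject).
    """
    positions = np.asarray(positions, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    out = np.mod(positions, lengths)
    return np.where(out >= lengths, 0.0, out)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances |b - a| (broadcasting over leading axes)."""
    d = minimum_image(np.asarray(b, float) - np.asarray(a, float), lengths)
    return np.sqrt(np.sum(d * d, axis=-1))
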