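"""Packaged 5x7 digit glyph atlas.

One fixed bitmap font is used both to burn ``mm:ss`` timestamps into
synthetic frames and as the template set for timestamp recovery by
normalized cross-correlation. Keeping render and recognition on the same
atlas makes the OCR stage dependency-free and exactly testable.
"""
from __future__ import annotations

import numpy as np

_GLYPH_ROWS: dict[str, tuple[str, ...]] = {
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00110", "01000", "10000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    ":": ("00000", "00100", "00100", "00000", "00100", "00100", "00000"),
}

GLYPH_H, GLYPH_W = 7, 5
#: one column of padding between consecutive glyphs
GLYPH_PITCH = GLYPH_W + 1


def glyph_bitmap(ch: str) -> np.ndarray:
    """Return the 7x5 float {0,1} bitmap of one atlas character."""
    rows = _GLYPH_ROWS[ch]
    return np.array([[float(c) for c in r] for r in rows])


def atlas() -> dict[str, np.ndarray]:
    """The full digit+colon template set."""
    return {ch: glyph_bitmap(ch) for ch in _GLYPH_ROWS}


def render_text(text: str, scale: int = 2, intensity: float = 1.0) -> np.ndarray:
    """Rasterize *text* with the atlas at integer *scale* (nearest-neighbour).

    Returns a float array in [0, intensity], height ``7*scale``.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    cols = []
    pad = np.zeros((GLYPH_H, 1))
    for i, ch in enumerate(text):
        if i:
            cols.append(pad)
        cols.append(glyph_bitmap(ch))
    strip = np.hstack(cols) * intensity
    return np.kron(strip, np.ones((scale, scale)))


def stamp_text(image: np.ndarray, text: str, origin: tuple[int, int],
               scale: int = 2, intensity: float = 1.0) -> np.ndarray:
    """Burn *text* into a copy of *image* with its top-left at *origin* (row, col)."""
    out = image.copy()
    patch = render_text(text, scale=scale, intensity=intensity)
    r, c = origin
    h, w = patch.shape
    if r < 0 or c < 0 or r + h > out.shape[0] or c + w > out.shape[1]:
        raise ValueError("timestamp overlay does not fit inside the image")
    region = out[r:r + h, c:c + w]
    out[r:r + h, c:c + w] = np.maximum(region, patch)
    return out
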