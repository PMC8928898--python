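"""5x7 bitmap glyphs for the tag digits 1-8.

The simulator stamps these onto rendered tag discs and the classical tag
classifier correlates candidate patches against the same shapes.  Keeping one
canonical bitmap per digit makes the digit-reading problem well posed without
shipping font files.
"""

from __future__ import annotations

import numpy as np

_ROWS = {
    1: ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    2: ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    3: ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    4: ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    5: ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    6: ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    7: ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    8: ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
}

GLYPH_SHAPE = (7, 5)

# correlation templates are compared at this resolution
DIGIT_TEMPLATE_SHAPE = (14, 10)

_TEMPLATE_CACHE: dict[int, np.ndarray] | None = None


def glyph_bitmap(digit: int) -> np.ndarray:
    """Boolean (7, 5) bitmap for a digit in [1, 8]."""
    rows = _ROWS[digit]
    return np.array([[c == "1" for c in row] for row in rows], dtype=bool)


def glyph_image(digit: int, scale: int = 2) -> np.ndarray:
    """Integer-upscaled bitmap, shape (7*scale, 5*scale)."""
    return np.kron(glyph_bitmap(digit), np.ones((scale, scale), dtype=bool))


def digit_templates() -> dict[int, np.ndarray]:
    """Zero-mean, unit-norm correlation templates, one flat vector per digit."""
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        sy = DIGIT_TEMPLATE_SHAPE[0] // GLYPH_SHAPE[0]
        sx = DIGIT_TEMPLATE_SHAPE[1] // GLYPH_SHAPE[1]
        cache: dict[int, np.ndarray] = {}
        for digit in _ROWS:
            img = np.kron(glyph_bitmap(digit), np.ones((sy, sx))).astype(float)
            vec = img.ravel() - img.mean()
            cache[digit] = vec / np.linalg.norm(vec)
        _TEMPLATE_CACHE = cache
    return _TEMPLATE_CACHE
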