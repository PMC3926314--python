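"""Eight-pattern compass edge strengths and their pointwise maximum.

Each edge strength ES1..ES8 is a weighted sum of the 3×3 neighbourhood of a
pixel of the attribute image, with one coefficient pattern per candidate
edge orientation (horizontal, vertical, half-plane offsets and the two
diagonals). All patterns have zero coefficient sum, so a constant input
produces zero response everywhere. The local maximum edge strength (LMES)
at a pixel is the largest magnitude among the eight responses; magnitudes
are used because edge polarity (dark-to-light vs light-to-dark) is
irrelevant for boundary detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .attribute import AttributeImage

__all__ = ["EDGE_KERNELS", "EdgeStrengthSet", "compute_edge_strengths", "compute_lmes"]

#: 3×3 coefficient patterns for ES1..ES8, row index = x (top to bottom),
#: column index = y (left to right).
EDGE_KERNELS = np.array(
    [
        [[1, 2, 1], [0, 0, 0], [-1, -2, -1]],   # ES1: horizontal step
        [[1, 0, -1], [2, 0, -2], [1, 0, -1]],   # ES2: vertical step
        [[1, 2, 1], [-1, -2, -1], [0, 0, 0]],   # ES3: horizontal, upper half
        [[0, 0, 0], [1, 2, 1], [-1, -2, -1]],   # ES4: horizontal, lower half
        [[1, -1, 0], [2, -2, 0], [1, -1, 0]],   # ES5: vertical, left half
        [[0, 1, -1], [0, 2, -2], [0, 1, -1]],   # ES6: vertical, right half
        [[2, 1, 0], [1, 0, -1], [0, -1, -2]],   # ES7: diagonal ↘
        [[0, 1, 2], [-1, 0, 1], [-2, -1, 0]],   # ES8: diagonal ↙
    ],
    dtype=float,
)

_NDI_MODES = {"reflect": "reflect", "nearest": "nearest"}


@dataclass
class EdgeStrengthSet:
    """The eight signed edge-strength maps and their absolute maximum."""

    es: np.ndarray      # (8, M, N), signed responses
    lmes: np.ndarray    # (M, N), max |ES_k|, ≥ 0

    def __post_init__(self) -> None:
        es = np.asarray(self.es, dtype=float)
        if es.ndim != 3 or es.shape[0] != 8:
            raise ValueError(f"expected es of shape (8, M, N), got {es.shape}")
        lmes = np.asarray(self.lmes, dtype=float)
        if lmes.shape != es.shape[1:]:
            raise ValueError(
                f"lmes shape {lmes.shape} does not match es maps {es.shape[1:]}"
            )
        self.es = es
        self.lmes = lmes


def compute_edge_strengths(ia, border_mode: str = "reflect") -> EdgeStrengthSet:
    """Correlate an attribute image with the eight 3×3 patterns.

    Parameters
    ----------
    ia : AttributeImage or 2-D array, at least 3×3
    border_mode : str
        "reflect" (edge-inclusive, consistent with the attribute stage)
        or "nearest".
    """
    values = ia.values if isinstance(ia, AttributeImage) else np.asarray(ia, dtype=float)
    if values.ndim != 2 or min(values.shape) < 3:
        raise ValueError(f"input must be at least 3×3, got shape {values.shape}")
    if border_mode not in _NDI_MODES:
        raise ValueError(f"border_mode must be one of {tuple(_NDI_MODES)}")
    mode = _NDI_MODES[border_mode]
    es = np.stack(
        [ndimage.correlate(values, k, mode=mode) for k in EDGE_KERNELS]
    )
    return EdgeStrengthSet(es=es, lmes=compute_lmes(es))


def compute_lmes(es) -> np.ndarray:
    """Pointwise maximum of the absolute edge strengths.

    Accepts an :class:`EdgeStrengthSet`, an (8, M, N) array, or a sequence
    of eight equal-shaped maps.
    """
    if isinstance(es, EdgeStrengthSet):
        arr = es.es
    else:
        maps = [np.asarray(m, dtype=float) for m in es]
        if len(maps) != 8:
            raise ValueError(f"expected eight edge-strength maps, got {len(maps)}")
        shape = maps[0].shape
        if any(m.shape != shape for m in maps):
            raise ValueError("edge-strength maps must share one shape")
        arr = np.stack(maps)
    return np.abs(arr).max(axis=0)
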