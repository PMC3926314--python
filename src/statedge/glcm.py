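"""Windowed gray-level co-occurrence matrices and their scalar texture features.

A co-occurrence matrix Cooc(i, j) counts how often a pixel with gray level i
has a neighbour with gray level j at a fixed spatial relation R(d, θ), with
the distance d in pixels and the orientation θ quantized to 45° steps. The
matrix is indexed 0..Nc where Nc is the maximum gray level of the window it
was computed from, so its size adapts to the local dynamic range.

Four scalar features are derived from the normalized matrix p(i, j):

* ``dm``   — diagonal moment, Σ sqrt(½·|i−j|·p(i,j)): mass away from the
  diagonal, i.e. local gray-level transitions.
* ``direc`` — directivity, Σ p(i,i): the fraction of equal-valued pairs.
* ``ener`` — energy, Σ p(i,j)²: uniformity of the pair distribution
  (1 for a constant window).
* ``odm``  — opposite differential moment, Σ p(i,j)/(1+(i−j)²): a local
  homogeneity measure.
* ``var``  — an extension: the variance of the first pair coordinate,
  Σ (i−μ)²·p(i,j) with μ = Σ i·p(i,j).

Directional features are usually averaged over the four orientations
(0°, 45°, 90°, 135°), which sweeps 180° at the same distance and gives a
degree of rotational invariance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ANGLES",
    "FEATURE_NAMES",
    "SpatialRelation",
    "CooccurrenceMatrix",
    "canonical_feature",
    "counted_offsets",
    "compute_glcm",
    "normalize_glcm",
    "glcm_feature",
    "averaged_feature",
]

ANGLES = (0, 45, 90, 135)

#: Accepted feature names (lowercase). "var" is an extension without a
#: closed-form reference in the original feature list.
FEATURE_NAMES = ("dm", "direc", "ener", "odm", "var")


def canonical_feature(name: str) -> str:
    """Normalize a feature name; raises ValueError for unknown names."""
    key = str(name).strip().lower()
    if key == "var_ext":
        key = "var"
    if key not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}")
    return key


@dataclass(frozen=True)
class SpatialRelation:
    """The spatial relation R(d, θ) between the two pixels of a pair.

    Parameters
    ----------
    distance : int
        Pixel spacing d ≥ 1 between the pair members (default 1).
    angle : int
        Orientation θ versus the horizontal, one of 0, 45, 90, 135 degrees.
    """

    distance: int = 1
    angle: int = 0

    def __post_init__(self) -> None:
        if int(self.distance) != self.distance or self.distance < 1:
            raise ValueError(f"distance must be a positive integer, got {self.distance}")
        if self.angle not in ANGLES:
            raise ValueError(f"angle must be one of {ANGLES}, got {self.angle}")

    @property
    def primary_offset(self) -> tuple[int, int]:
        """(row, column) offset of the neighbour for the primary orientation.

        Sweeping 180°: (0, d) for 0°, (−d, d) for 45°, (−d, 0) for 90°,
        (−d, −d) for 135°.
        """
        d = int(self.distance)
        return {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}[self.angle]


def counted_offsets(relation: SpatialRelation, symmetric: bool) -> list[tuple[int, int]]:
    """The neighbour offsets actually counted for a relation.

    The diagonal orientations (45°, 135°) count both opposite offsets by
    definition; for 0° and 90° the reversed offset (equivalently, the
    transposed pairs) is added only when ``symmetric`` is requested.
    """
    dr, dc = relation.primary_offset
    if relation.angle in (45, 135) or symmetric:
        return [(dr, dc), (-dr, -dc)]
    return [(dr, dc)]


@dataclass
class CooccurrenceMatrix:
    """Square pair-frequency table for one window and one spatial relation.

    ``table[i, j]`` is the (possibly normalized) frequency of the gray-level
    pair (i, j); indices run 0..Nc where Nc is the window maximum.
    """

    table: np.ndarray
    relation: SpatialRelation
    pair_count: int
    normalized: bool = False

    @property
    def nc(self) -> int:
        """Top gray-level index of the table."""
        return self.table.shape[0] - 1


def _offset_slices(shape: tuple[int, int], dr: int, dc: int):
    """Slices selecting first elements and their (dr, dc) neighbours."""
    h, w = shape
    a = (slice(max(0, -dr), h - max(0, dr)), slice(max(0, -dc), w - max(0, dc)))
    b = (slice(max(0, dr), h - max(0, -dr)), slice(max(0, dc), w - max(0, -dc)))
    return a, b


def compute_glcm(
    window: np.ndarray,
    relation: SpatialRelation = SpatialRelation(),
    symmetric: bool = True,
) -> CooccurrenceMatrix:
    """Count gray-level pair frequencies at the given spatial relation.

    Parameters
    ----------
    window : 2-D integer array
        Gray levels in [0, 255].
    relation : SpatialRelation
        Distance and orientation of the counted pairs.
    symmetric : bool
        For 0° and 90°, also count the transposed pairs so the table is
        orientation-symmetric like the diagonal directions. No effect at
        45°/135°, which always count both orientations.

    Returns
    -------
    CooccurrenceMatrix
        Unnormalized counts; ``pair_count`` is the total number of counted
        in-window pairs.
    """
    w = np.asarray(window)
    if w.ndim != 2 or w.size == 0:
        raise ValueError("window must be a non-empty 2-D array")
    if not np.issubdtype(w.dtype, np.integer):
        if np.issubdtype(w.dtype, np.bool_):
            w = w.astype(np.intp)
        else:
            raise ValueError("window values must be integers")
    if w.min() < 0 or w.max() > 255:
        raise ValueError("window values must lie in [0, 255]")
    w = w.astype(np.intp)
    d = relation.distance
    if d >= w.shape[0] or d >= w.shape[1]:
        raise ValueError(
            f"offset exceeds window: d={d} for window shape {w.shape}"
        )
    nc = int(w.max())
    table = np.zeros((nc + 1, nc + 1), dtype=np.int64)
    for dr, dc in counted_offsets(relation, symmetric):
        sa, sb = _offset_slices(w.shape, dr, dc)
        a = w[sa]
        b = w[sb]
        if a.size == 0:
            raise ValueError(f"offset exceeds window: ({dr}, {dc}) for shape {w.shape}")
        np.add.at(table, (a.ravel(), b.ravel()), 1)
    return CooccurrenceMatrix(
        table=table,
        relation=relation,
        pair_count=int(table.sum()),
        normalized=False,
    )


def normalize_glcm(m: CooccurrenceMatrix) -> CooccurrenceMatrix:
    """Divide the counts by the pair count so entries sum to one.

    Idempotent: an already-normalized matrix is returned unchanged.
    """
    if m.normalized:
        return m
    if m.pair_count <= 0:
        raise ValueError("no pixel pairs at this offset")
    return replace(m, table=m.table / m.pair_count, normalized=True)


def glcm_feature(m: CooccurrenceMatrix, name: str, raw: bool = False) -> float:
    """Evaluate one scalar texture feature on a co-occurrence matrix.

    The matrix must be normalized unless ``raw=True``, which evaluates the
    same formulas directly on counts (this makes energy and homogeneity
    scale with the window area and is kept only for the literal reading).
    """
    name = canonical_feature(name)
    if not m.normalized and not raw:
        raise ValueError(
            "feature evaluation requires a normalized matrix "
            "(pass raw=True to operate on counts)"
        )
    p = np.asarray(m.table, dtype=float)
    idx = np.arange(p.shape[0], dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    if name == "dm":
        return float(np.sqrt(0.5 * np.abs(i - j) * p).sum())
    if name == "direc":
        return float(np.trace(p))
    if name == "ener":
        return float((p * p).sum())
    if name == "odm":
        return float((p / (1.0 + (i - j) ** 2)).sum())
    # var: variance of the first pair coordinate
    mu = float((i * p).sum())
    return float(((i - mu) ** 2 * p).sum())


def averaged_feature(
    window: np.ndarray,
    name: str,
    distance: int = 1,
    symmetric: bool = True,
) -> float:
    """Mean of a feature over the four directional co-occurrence matrices.

    This is the quantity assigned to the window's center pixel when building
    an attribute image.
    """
    name = canonical_feature(name)
    vals = []
    for angle in ANGLES:
        m = compute_glcm(window, SpatialRelation(distance, angle), symmetric=symmetric)
        vals.append(glcm_feature(normalize_glcm(m), name))
    return float(np.mean(vals))
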