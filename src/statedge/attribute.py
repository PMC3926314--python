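"""Attribute images: per-pixel windowed co-occurrence features.

The attribute image Ia assigns each pixel the four-direction average of one
co-occurrence feature, computed on the t×t window centered there. The scan
covers every pixel; the image border is reflect-padded so Ia has the same
M×N extent as its source channel.

Two engines produce identical values:

* ``"naive"`` — literal per-pixel re-computation through
  :func:`statedge.glcm.averaged_feature`; the reference path, quadratic in
  window count and used for verification.
* ``"vectorized"`` — encodes each in-window pixel pair as an integer code
  ``first*256 + second`` and evaluates the features from per-window code
  multisets with sliding-window views. Linear features (direc, odm, var)
  are means over the code axis; energy and the diagonal moment need the
  per-cell counts, recovered by sorting the codes and measuring run
  lengths (Σ r² over runs gives the energy numerator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .glcm import (
    ANGLES,
    SpatialRelation,
    averaged_feature,
    canonical_feature,
    counted_offsets,
)
from .image_io import GrayChannel

__all__ = ["DetectorConfig", "AttributeImage", "compute_attribute_image"]

_PAD_MODES = {"reflect": "symmetric", "nearest": "edge"}

_CODE_BASE = 256  # gray levels fit in one byte, so a pair fits in 16 bits


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the edge detector shared by all pipeline stages.

    Parameters
    ----------
    feature : str
        Co-occurrence feature for the attribute image ("dm", "direc",
        "ener", "odm" or "var"). Default "ener".
    window_size : int
        Odd sliding-window side t ≥ 3. Default 5: the smallest window with
        stable four-direction statistics at d = 1 that keeps the attribute
        image sharp at cell boundaries.
    distance : int
        Pair distance d ≥ 1, d < t. Default 1.
    symmetric : bool
        Orientation-symmetric co-occurrence tables for 0°/90° (the
        diagonals always are). Default True.
    border_mode : str
        "reflect" (edge-inclusive mirror, default) or "nearest".
    levels : int or None
        Optional global quantization to this many gray levels before the
        co-occurrence step (a speed/robustness option); None (default)
        keeps the full 0..255 range with the matrix size following each
        window's maximum.
    bins : int
        Top bin index L of the edge-strength histogram handed to the
        threshold selector. Default 255 (8-bit convention).
    """

    feature: str = "ener"
    window_size: int = 5
    distance: int = 1
    symmetric: bool = True
    border_mode: str = "reflect"
    levels: int | None = None
    bins: int = 255

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature", canonical_feature(self.feature))
        t = self.window_size
        if t < 3 or t % 2 == 0:
            raise ValueError(f"window_size must be an odd integer ≥ 3, got {t}")
        if self.distance < 1 or self.distance >= t:
            raise ValueError(
                f"distance must satisfy 1 ≤ d < window_size, got d={self.distance}, t={t}"
            )
        if self.border_mode not in _PAD_MODES:
            raise ValueError(
                f"border_mode must be one of {tuple(_PAD_MODES)}, got {self.border_mode!r}"
            )
        if self.levels is not None and self.levels < 2:
            raise ValueError(f"levels must be ≥ 2, got {self.levels}")
        if self.bins < 2:
            raise ValueError(f"bins must be ≥ 2, got {self.bins}")


@dataclass
class AttributeImage:
    """Per-pixel map of one averaged co-occurrence feature."""

    values: np.ndarray
    feature: str
    window_size: int
    distance: int
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"attribute image must be 2-D, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("attribute image contains non-finite values")
        self.values = v


def _quantize(values: np.ndarray, levels: int | None) -> np.ndarray:
    if levels is None:
        return values
    return (values.astype(np.int64) * levels // 256).astype(values.dtype)


def _pad(values: np.ndarray, half: int, border_mode: str) -> np.ndarray:
    return np.pad(values, half, mode=_PAD_MODES[border_mode])


def _offset_code_windows(padded: np.ndarray, dr: int, dc: int, t: int,
                         out_shape: tuple[int, int]) -> np.ndarray:
    """Pair codes of one offset, grouped per sliding window.

    Returns an (M, N, k) array whose last axis lists the codes of the pairs
    with both members inside the t×t window centered at each pixel.
    """
    h, w = padded.shape
    a = padded[max(0, -dr): h - max(0, dr), max(0, -dc): w - max(0, dc)]
    b = padded[max(0, dr): h - max(0, -dr), max(0, dc): w - max(0, -dc)]
    code = a.astype(np.int32) * _CODE_BASE + b.astype(np.int32)
    view = sliding_window_view(code, (t - abs(dr), t - abs(dc)))
    m, n = out_shape
    return view.reshape(m, n, -1)


def _feature_from_codes(codes: np.ndarray, name: str) -> np.ndarray:
    """Evaluate one feature per window from its pair-code multiset."""
    k = codes.shape[-1]
    if name in ("direc", "odm", "var"):
        a = codes // _CODE_BASE
        b = codes % _CODE_BASE
        if name == "direc":
            return (a == b).mean(axis=-1)
        if name == "odm":
            diff = (a - b).astype(np.int64)
            return (1.0 / (1.0 + diff * diff)).sum(axis=-1) / k
        af = a.astype(float)
        mu = af.mean(axis=-1)
        return (af * af).mean(axis=-1) - mu * mu

    # ener / dm need per-cell counts: sort codes, then measure runs.
    s = np.sort(codes, axis=-1)
    idx = np.arange(k)
    neq = s[..., 1:] != s[..., :-1]
    head = np.ones(s.shape[:-1] + (1,), dtype=bool)
    is_start = np.concatenate([head, neq], axis=-1)
    start_idx = np.maximum.accumulate(np.where(is_start, idx, 0), axis=-1)
    if name == "ener":
        # sum over runs of r² == sum over elements of (2·pos_in_run + 1)
        pos = idx - start_idx
        return (2 * pos + 1).sum(axis=-1) / float(k * k)
    # dm: one contribution sqrt(½·|i−j|·count/k) per distinct cell
    is_end = np.concatenate([neq, head], axis=-1)
    run_len = idx - start_idx + 1
    abs_diff = np.abs(s // _CODE_BASE - s % _CODE_BASE)
    contrib = np.sqrt(0.5 * abs_diff * run_len / float(k))
    return np.where(is_end, contrib, 0.0).sum(axis=-1)


def _vectorized(values: np.ndarray, cfg: DetectorConfig) -> np.ndarray:
    t = cfg.window_size
    half = t // 2
    padded = _pad(values, half, cfg.border_mode)
    out_shape = values.shape
    name = cfg.feature
    acc = np.zeros(out_shape, dtype=float)
    for angle in ANGLES:
        rel = SpatialRelation(cfg.distance, angle)
        parts = [
            _offset_code_windows(padded, dr, dc, t, out_shape)
            for dr, dc in counted_offsets(rel, cfg.symmetric)
        ]
        codes = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=-1)
        acc += _feature_from_codes(codes, name)
    return acc / len(ANGLES)


def _naive(values: np.ndarray, cfg: DetectorConfig) -> np.ndarray:
    t = cfg.window_size
    half = t // 2
    padded = _pad(values, half, cfg.border_mode)
    m, n = values.shape
    out = np.empty((m, n), dtype=float)
    for x in range(m):
        for y in range(n):
            out[x, y] = averaged_feature(
                padded[x: x + t, y: y + t],
                cfg.feature,
                distance=cfg.distance,
                symmetric=cfg.symmetric,
            )
    return out


def compute_attribute_image(
    channel,
    cfg: DetectorConfig | None = None,
    engine: str = "auto",
) -> AttributeImage:
    """Slide a t×t window over a channel and map each pixel to its feature.

    Parameters
    ----------
    channel : GrayChannel or 2-D integer array
        Source gray levels 0..255.
    cfg : DetectorConfig
        Feature, window size, distance, symmetry, border and quantization.
    engine : str
        "auto"/"vectorized" for the fast path, "naive" for the literal
        per-pixel reference; both produce the same values.
    """
    cfg = cfg or DetectorConfig()
    values = channel.pixels if isinstance(channel, GrayChannel) else np.asarray(channel)
    if values.ndim != 2:
        raise ValueError(f"channel must be 2-D, got shape {values.shape}")
    m, n = values.shape
    if cfg.window_size >= min(m, n):
        raise ValueError(
            f"window larger than image: t={cfg.window_size} for {m}×{n}"
        )
    values = _quantize(values, cfg.levels)
    if engine in ("auto", "vectorized"):
        out = _vectorized(values, cfg)
    elif engine == "naive":
        out = _naive(values, cfg)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return AttributeImage(
        values=out,
        feature=cfg.feature,
        window_size=cfg.window_size,
        distance=cfg.distance,
        border_mode=cfg.border_mode,
    )
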