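"""Reading RGB microscopy images, channel handling, and edge-map output.

All modules share one coordinate convention: row-major, 0-based, x = row
(top to bottom), y = column (left to right). Images are 8-bit per channel;
anything else is linearly rescaled to 0..255 on read, since every
downstream formula assumes gray levels in that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RgbImage",
    "GrayChannel",
    "EdgeMap",
    "read_rgb_image",
    "split_channels",
    "write_edge_outputs",
]


@dataclass
class RgbImage:
    """An M×N×3 image with 8-bit intensities per primitive color.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (M, N, 3)
        Gray levels 0..255, channel order R, G, B.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an M×N×3 array, got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(
                f"image must be at least 3×3 pixels, got {px.shape[0]}×{px.shape[1]}"
            )
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValueError("intensities must be integers in [0, 255]")
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        """M, the number of rows."""
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        """N, the number of columns."""
        return self.pixels.shape[1]


@dataclass
class GrayChannel:
    """One primitive-color plane of an :class:`RgbImage`."""

    pixels: np.ndarray
    channel_label: str = "R"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected an M×N array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer) or px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must be integers in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.channel_label not in ("R", "G", "B"):
            raise ValueError(f"channel_label must be R, G or B, got {self.channel_label!r}")


@dataclass
class EdgeMap:
    """Binary edge mask: 1 = edge pixel, 0 = non-edge."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"expected an M×N mask, got shape {m.shape}")
        if m.dtype == bool:
            m = m.astype(np.uint8)
        vals = np.unique(m)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("edge mask values must be 0 or 1")
        self.mask = m.astype(np.uint8)

    @property
    def edge_pixel_count(self) -> int:
        return int(self.mask.sum())


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Rescale an arbitrary-dtype raster to 8-bit gray levels 0..255."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        # full-range integer division: 65535 // 257 == 255
        return (arr // 257).astype(np.uint8)
    if arr.dtype == np.bool_:
        return arr.astype(np.uint8) * 255
    if np.issubdtype(arr.dtype, np.floating):
        lo, hi = float(arr.min()), float(arr.max())
        if 0.0 <= lo and hi <= 1.0:
            return np.round(arr * 255.0).astype(np.uint8)
        if hi == lo:
            return np.zeros(arr.shape, np.uint8)
        return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        lo, hi = int(arr.min()), int(arr.max())
        if 0 <= lo and hi <= 255:
            return arr.astype(np.uint8)
        if hi == lo:
            return np.zeros(arr.shape, np.uint8)
        return ((arr.astype(np.int64) - lo) * 255 // (hi - lo)).astype(np.uint8)
    raise ValueError(f"unsupported pixel dtype {arr.dtype}")


def read_rgb_image(path) -> RgbImage:
    """Read a PNG/TIFF/JPEG raster as an 8-bit RGB image.

    Grayscale inputs are replicated into three identical channels; alpha
    channels are dropped; non-8-bit data is linearly rescaled to 0..255
    (16-bit by integer division of the full range).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    return RgbImage(_to_uint8(arr))


def split_channels(img: RgbImage) -> tuple[GrayChannel, GrayChannel, GrayChannel]:
    """Split an RGB image into its R, G and B planes (in that order)."""
    return tuple(
        GrayChannel(img.pixels[..., k].copy(), label)
        for k, label in enumerate("RGB")
    )


def write_edge_outputs(edges: EdgeMap, original: RgbImage, out_dir, stem: str = "edges"):
    """Write a 0/255 mask PNG and a white-on-original overlay PNG.

    Returns ``(mask_path, overlay_path)``.
    """
    if edges.mask.shape != original.pixels.shape[:2]:
        raise ValueError(
            f"edge map shape {edges.mask.shape} does not match image "
            f"shape {original.pixels.shape[:2]}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_path = out_dir / f"{stem}_mask.png"
    overlay_path = out_dir / f"{stem}_overlay.png"
    iio.imwrite(mask_path, (edges.mask * 255).astype(np.uint8))
    overlay = original.pixels.copy()
    overlay[edges.mask.astype(bool)] = (255, 255, 255)
    iio.imwrite(overlay_path, overlay)
    return mask_path, overlay_path
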