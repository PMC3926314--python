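"""Synthetic test images with exact ground truth.

The generators emulate the test material of the method's intended use:
two-region color images with a known closed boundary, cell-like images of
non-overlapping stained blobs on a lighter background, and salt-and-pepper
impulse corruption of a stated density D (affecting ≈ D·M·N pixels).

Default colors follow an immunohistochemistry-like palette — dark
red/brown cells, fg = (150, 40, 60), on a pale background,
bg = (230, 210, 220) — giving per-channel contrasts of 80/170/160 gray
levels. Every generator is deterministic for a fixed seed, and the
ground-truth masks are never touched by the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import EdgeMap, RgbImage

__all__ = [
    "DEFAULT_FG",
    "DEFAULT_BG",
    "inner_boundary",
    "generate_two_region_image",
    "generate_cell_like_image",
    "add_salt_pepper",
]

DEFAULT_FG = (150, 40, 60)
DEFAULT_BG = (230, 210, 220)


def _check_color(c, name: str) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if arr.shape != (3,) or (arr < 0).any() or (arr > 255).any():
        raise ValueError(f"{name} must be an RGB triple in [0, 255]³, got {c!r}")
    return arr


def inner_boundary(region: np.ndarray) -> np.ndarray:
    """1-pixel inner boundary: region pixels with a 4-neighbour outside.

    Pixels beyond the canvas count as outside the region.
    """
    r = np.asarray(region).astype(bool)
    padded = np.pad(r, 1, constant_values=False)
    neighbours_inside = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return (r & ~neighbours_inside).astype(np.uint8)


def _finalize(rgb: np.ndarray, region: np.ndarray, noise: float, seed: int,
              per_channel: bool):
    img = RgbImage(np.clip(np.round(rgb), 0, 255).astype(np.uint8))
    if noise > 0:
        img = add_salt_pepper(img, noise, seed=seed, per_channel=per_channel)
    edges = EdgeMap(inner_boundary(region))
    return img, region.astype(np.uint8), edges


def generate_two_region_image(
    height: int = 256,
    width: int = 256,
    shape: str = "circle",
    center: tuple[float, float] | None = None,
    radius: float = 60.0,
    rect: tuple[int, int, int, int] | None = None,
    fg=DEFAULT_FG,
    bg=DEFAULT_BG,
    noise: float = 0.0,
    seed: int = 0,
    per_channel_noise: bool = False,
):
    """A foreground shape on a uniform background, with ground truth.

    Parameters
    ----------
    shape : str
        "circle" (uses ``center``/``radius``) or "rectangle" (uses
        ``rect = (row0, col0, row1, col1)``, exclusive stop).
    noise : float
        Salt-and-pepper density D in [0, 1); applied to the image only.
    seed : int
        Seed for the noise generator; the geometry is deterministic.

    Returns
    -------
    (RgbImage, region mask uint8, EdgeMap)
        The region mask marks the foreground shape; the edge map is its
        1-pixel 4-connected inner boundary.
    """
    if height < 3 or width < 3:
        raise ValueError("canvas must be at least 3×3")
    fg = _check_color(fg, "fg")
    bg = _check_color(bg, "bg")
    if shape == "circle":
        if radius <= 0:
            raise ValueError(f"radius must be positive, got {radius}")
        cx, cy = center if center is not None else ((height - 1) / 2, (width - 1) / 2)
        if cx - radius < 0 or cx + radius > height - 1 or cy - radius < 0 or cy + radius > width - 1:
            raise ValueError("circle extends outside the canvas")
        xx, yy = np.mgrid[0:height, 0:width]
        region = ((xx - cx) ** 2 + (yy - cy) ** 2) <= radius**2
    elif shape == "rectangle":
        if rect is None:
            raise ValueError("rectangle shape needs rect=(row0, col0, row1, col1)")
        r0, c0, r1, c1 = rect
        if not (0 <= r0 < r1 <= height and 0 <= c0 < c1 <= width):
            raise ValueError(f"rectangle {rect} outside the {height}×{width} canvas")
        region = np.zeros((height, width), dtype=bool)
        region[r0:r1, c0:c1] = True
    else:
        raise ValueError(f"unknown shape {shape!r}")
    rgb = np.where(region[..., None], fg, bg)
    return _finalize(rgb, region, noise, seed, per_channel_noise)


def add_salt_pepper(img: RgbImage, density: float, seed: int = 0,
                    per_channel: bool = False) -> RgbImage:
    """Corrupt ≈ density·M·N pixels to pure black or white (½ each).

    Each pixel position is corrupted independently with probability
    ``density``; by default a corrupted pixel turns black or white across
    all three channels jointly (``per_channel=True`` draws the impulse
    independently per channel instead).
    """
    if not 0 <= density < 1:
        raise ValueError(f"density must lie in [0, 1), got {density}")
    if density == 0:
        return img
    rng = np.random.default_rng(seed)
    px = img.pixels.copy()
    m, n = px.shape[:2]
    if per_channel:
        hit = rng.random((m, n, 3)) < density
        white = rng.random((m, n, 3)) < 0.5
        px[hit & white] = 255
        px[hit & ~white] = 0
    else:
        hit = rng.random((m, n)) < density
        white = rng.random((m, n)) < 0.5
        px[hit & white] = (255, 255, 255)
        px[hit & ~white] = (0, 0, 0)
    return RgbImage(px)


@dataclass
class _Blob:
    cx: float
    cy: float
    ax: float
    ay: float
    phi: float


def generate_cell_like_image(
    height: int = 256,
    width: int = 256,
    n_cells: int = 8,
    radius_range: tuple[float, float] = (12.0, 26.0),
    fg=DEFAULT_FG,
    bg=DEFAULT_BG,
    noise: float = 0.0,
    seed: int = 0,
    per_channel_noise: bool = False,
    max_tries: int = 500,
):
    """Non-overlapping elliptical blobs with smooth intensity falloff.

    Blob color runs from full foreground at the center to halfway between
    foreground and background at the rim, so the boundary keeps half the
    nominal contrast. Placement is rejection-sampled with a 2-pixel gap
    between blobs; a RuntimeError is raised if ``n_cells`` cannot be
    placed within ``max_tries`` draws per blob.

    Returns ``(RgbImage, region mask uint8, EdgeMap)``; the region mask
    has exactly ``n_cells`` 4-connected components.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be ≥ 1, got {n_cells}")
    lo, hi = radius_range
    if not 2 <= lo <= hi:
        raise ValueError(f"radius_range must satisfy 2 ≤ lo ≤ hi, got {radius_range}")
    if hi * 2 + 4 > min(height, width):
        raise ValueError("largest blob does not fit the canvas")
    fg = _check_color(fg, "fg")
    bg = _check_color(bg, "bg")
    rng = np.random.default_rng(seed)
    blobs: list[_Blob] = []
    gap = 2.0
    for _ in range(n_cells):
        placed = False
        for _attempt in range(max_tries):
            ax = rng.uniform(lo, hi)
            ay = rng.uniform(lo, hi)
            rmax = max(ax, ay)
            cx = rng.uniform(rmax + 1, height - 2 - rmax)
            cy = rng.uniform(rmax + 1, width - 2 - rmax)
            phi = rng.uniform(0, np.pi)
            ok = all(
                np.hypot(cx - b.cx, cy - b.cy) > rmax + max(b.ax, b.ay) + gap
                for b in blobs
            )
            if ok:
                blobs.append(_Blob(cx, cy, ax, ay, phi))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping blobs in "
                f"{height}×{width} after {max_tries} tries each"
            )
    xx, yy = np.mgrid[0:height, 0:width]
    rgb = np.tile(bg, (height, width, 1)).astype(float)
    region = np.zeros((height, width), dtype=bool)
    for b in blobs:
        dx = xx - b.cx
        dy = yy - b.cy
        u = (dx * np.cos(b.phi) + dy * np.sin(b.phi)) / b.ax
        v = (-dx * np.sin(b.phi) + dy * np.cos(b.phi)) / b.ay
        rho2 = u * u + v * v
        inside = rho2 <= 1.0
        region |= inside
        # falloff 1 → 0.5 from center to rim keeps boundary contrast
        weight = 0.5 + 0.5 * (1.0 - rho2[inside])
        rgb[inside] = bg + (fg - bg) * weight[:, None]
    return _finalize(rgb, region, noise, seed, per_channel_noise)
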