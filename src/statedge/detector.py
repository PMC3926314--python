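"""End-to-end color edge detector.

Pipeline per primitive color: attribute image → eight edge strengths →
LMES → histogram → automatic threshold → binary channel map. The three
channel maps are fused by a logical OR: a pixel is an edge in the final
map iff at least one color component classifies it as an edge. No
thinning, gap filling or other post-processing is applied afterwards.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .attribute import DetectorConfig, compute_attribute_image
from .edge_strength import compute_edge_strengths
from .image_io import EdgeMap, RgbImage, split_channels
from .threshold import OtsuResult, lmes_histogram, otsu_threshold

__all__ = [
    "ChannelEdgeMap",
    "DetectionResult",
    "binarize_channel",
    "fuse_channels",
    "detect_color_edges",
]


@dataclass
class ChannelEdgeMap:
    """Binary edge decision of one color component.

    ``mask`` is 1 exactly where the channel's LMES is ≥ the threshold
    (all zero for a degenerate, constant-strength channel).
    """

    mask: np.ndarray
    channel_label: str
    threshold: float
    otsu: OtsuResult

    @property
    def edge_pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class DetectionResult:
    """Fused edge map plus the per-channel decisions that produced it."""

    fused: EdgeMap
    channels: tuple[ChannelEdgeMap, ...]
    config: DetectorConfig
    intermediates: dict | None = None

    def summary(self) -> dict:
        """JSON-serializable run summary: config, thresholds, edge counts."""
        return {
            "config": asdict(self.config),
            "image_shape": list(self.fused.mask.shape),
            "channels": {
                c.channel_label: {
                    "threshold": c.threshold,
                    "t_star": c.otsu.t_star,
                    "degenerate": c.otsu.degenerate,
                    "edge_pixels": c.edge_pixel_count,
                }
                for c in self.channels
            },
            "fused_edge_pixels": self.fused.edge_pixel_count,
        }


def binarize_channel(lmes: np.ndarray, otsu: OtsuResult, label: str = "R") -> ChannelEdgeMap:
    """Classify a channel's pixels into edge (LMES ≥ T) and non-edge."""
    arr = np.asarray(lmes, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"LMES map must be 2-D, got shape {arr.shape}")
    if otsu.degenerate:
        mask = np.zeros(arr.shape, dtype=np.uint8)
    else:
        mask = (arr >= otsu.threshold).astype(np.uint8)
    return ChannelEdgeMap(mask=mask, channel_label=label, threshold=otsu.threshold, otsu=otsu)


def fuse_channels(er: ChannelEdgeMap, eg: ChannelEdgeMap, eb: ChannelEdgeMap) -> EdgeMap:
    """OR-fuse the three channel maps: edge iff edge in ≥ 1 component."""
    shapes = {er.mask.shape, eg.mask.shape, eb.mask.shape}
    if len(shapes) != 1:
        raise ValueError(f"channel masks must share one shape, got {shapes}")
    fused = (er.mask.astype(bool) | eg.mask.astype(bool) | eb.mask.astype(bool))
    provenance = {
        f"T_{c.channel_label}": c.threshold for c in (er, eg, eb)
    }
    return EdgeMap(mask=fused.astype(np.uint8), provenance=provenance)


def detect_color_edges(
    img,
    cfg: DetectorConfig | None = None,
    keep_intermediates: bool = False,
    engine: str = "auto",
) -> DetectionResult:
    """Run the full detector on an RGB image.

    Parameters
    ----------
    img : RgbImage or (M, N, 3) uint8 array
    cfg : DetectorConfig, optional
        Defaults: feature "ener", t = 5, d = 1, symmetric tables,
        reflect borders, 255 histogram bins.
    keep_intermediates : bool
        Retain per-channel attribute images, edge strengths and
        histograms on the result.
    engine : str
        Attribute-image engine ("auto", "vectorized" or "naive").

    The computation is deterministic: fixed input and config give
    byte-identical outputs.
    """
    cfg = cfg or DetectorConfig()
    if not isinstance(img, RgbImage):
        img = RgbImage(np.asarray(img))
    per_channel = []
    intermediates: dict | None = {} if keep_intermediates else None
    for channel in split_channels(img):
        try:
            ia = compute_attribute_image(channel, cfg, engine=engine)
            ess = compute_edge_strengths(ia.values, border_mode=cfg.border_mode)
            hist = lmes_histogram(ess.lmes, cfg.bins)
            otsu = otsu_threshold(hist)
        except ValueError as exc:
            raise ValueError(f"channel {channel.channel_label}: {exc}") from exc
        per_channel.append(binarize_channel(ess.lmes, otsu, channel.channel_label))
        if intermediates is not None:
            intermediates[channel.channel_label] = {
                "attribute": ia,
                "edge_strengths": ess,
                "histogram": hist,
            }
    fused = fuse_channels(*per_channel)
    return DetectionResult(
        fused=fused,
        channels=tuple(per_channel),
        config=cfg,
        intermediates=intermediates,
    )
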