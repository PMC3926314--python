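"""Segmentation evaluation: sensitivity and classification probabilities.

Three statistics compare a binary prediction against a reference labeling
R = R₁ ∪ R₂ (R₁ the cells/edge class, R₂ the background):

* Sen(%) = N_pcc / (N·M) · 100 — the fraction of pixels whose predicted
  label equals the reference label (both classes count).
* P_C = N₁C / N₁r — probability that an R₁ pixel is marked as R₁.
* P_f = N₁f / N₂r — probability that an R₂ pixel is marked as R₁.

Thin edge references punish 1-pixel localization offsets under exact
matching, so P_C/P_f accept an optional tolerance radius: an R₁ pixel
counts as detected if a predicted pixel lies within that Euclidean
distance, and a predicted pixel counts as false only if it is farther
than the tolerance from every R₁ pixel. Tolerance 0 (the default)
reduces to exact pixelwise recall and false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import EdgeMap

__all__ = [
    "EvaluationReport",
    "segmentation_sensitivity",
    "classification_probabilities",
    "evaluate_edge_maps",
]


@dataclass
class EvaluationReport:
    """Evaluation statistics with the underlying pixel counts."""

    sen_percent: float
    pc: float
    pf: float
    npcc: int
    n1r: int
    n2r: int
    n1c: int
    n1f: int
    tolerance: float = 0.0

    def to_dict(self) -> dict:
        return {
            "sen_percent": self.sen_percent,
            "pc": self.pc,
            "pf": self.pf,
            "npcc": self.npcc,
            "n1r": self.n1r,
            "n2r": self.n2r,
            "n1c": self.n1c,
            "n1f": self.n1f,
            "tolerance": self.tolerance,
        }

    def summary(self) -> str:
        lines = [
            "segmentation evaluation",
            "-----------------------",
            f"Sen(%)      {self.sen_percent:8.2f}   (Npcc = {self.npcc})",
            f"Pc          {self.pc:8.4f}   (N1c = {self.n1c} / N1r = {self.n1r})",
            f"Pf          {self.pf:8.4f}   (N1f = {self.n1f} / N2r = {self.n2r})",
            f"tolerance   {self.tolerance:8.1f}   px",
        ]
        return "\n".join(lines)


def _as_binary(arr) -> np.ndarray:
    if isinstance(arr, EdgeMap):
        arr = arr.mask
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {a.shape}")
    return a > 0


def segmentation_sensitivity(pred, ref) -> float:
    """Sen(%): percentage of pixels with matching labels in both classes."""
    p = _as_binary(pred)
    r = _as_binary(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    npcc = int((p == r).sum())
    return 100.0 * npcc / p.size


def classification_probabilities(pred, ref_r1, tolerance: float = 0.0):
    """P_C and P_f of a prediction against the reference R₁ mask.

    Returns ``(pc, pf, counts)`` with ``counts`` holding N1c, N1f, N1r and
    N2r. ``tolerance`` is the Euclidean match radius in pixels (0 = exact).
    """
    p = _as_binary(pred)
    r = _as_binary(ref_r1)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    if tolerance < 0:
        raise ValueError(f"tolerance must be ≥ 0, got {tolerance}")
    n1r = int(r.sum())
    n2r = int(r.size - n1r)
    if n1r == 0 or n2r == 0:
        raise ValueError("degenerate reference: one class is empty")
    if tolerance == 0:
        n1c = int((p & r).sum())
        n1f = int((p & ~r).sum())
    else:
        if p.any():
            dist_to_pred = ndimage.distance_transform_edt(~p)
            n1c = int((dist_to_pred[r] <= tolerance).sum())
        else:
            n1c = 0
        dist_to_ref = ndimage.distance_transform_edt(~r)
        n1f = int((dist_to_ref[p] > tolerance).sum())
    pc = n1c / n1r
    pf = n1f / n2r
    counts = {"n1c": n1c, "n1f": n1f, "n1r": n1r, "n2r": n2r}
    return pc, pf, counts


def evaluate_edge_maps(pred, ref, tolerance: float = 0.0) -> EvaluationReport:
    """Full report: Sen(%) plus P_C/P_f with the given match tolerance."""
    p = _as_binary(pred)
    r = _as_binary(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    npcc = int((p == r).sum())
    pc, pf, counts = classification_probabilities(p, r, tolerance)
    return EvaluationReport(
        sen_percent=100.0 * npcc / p.size,
        pc=pc,
        pf=pf,
        npcc=npcc,
        tolerance=float(tolerance),
        **counts,
    )
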