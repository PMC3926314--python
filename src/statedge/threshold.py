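"""Automatic threshold selection on the edge-strength histogram (Otsu).

The LMES map is real-valued; its values are linearly rescaled so that 0
maps to bin 0 and the maximum maps to bin L (floor binning), giving the
integer histogram f_0..f_L the classic between-class-variance criterion
expects. For every candidate split t the two classes {0..t} and {t+1..L}
get weights w1, w2 and means μ1, μ2, and the selected t* maximizes

    σB²(t) = w1(μ1 − μT)² + w2(μ2 − μT)²  =  w1·w2·(μ1 − μ2)².

Candidates where either class is empty are excluded. Because σB² can be
exactly constant over runs of empty bins, the argmax is decided with exact
rational arithmetic (σB² ∝ (S1·c2 − S2·c1)²/(c1·c2) with integer cumulative
counts c and index sums S), making the smallest-t tie-break deterministic
regardless of floating-point summation order. The decision threshold in
raw units is the lower edge of bin t*+1, so "edge ⇔ LMES ≥ T" selects
exactly the pixels binned above t*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = ["LmesHistogram", "OtsuResult", "lmes_histogram", "otsu_threshold"]

logger = logging.getLogger(__name__)


@dataclass
class LmesHistogram:
    """Integer histogram of a rescaled LMES map.

    ``counts[i]`` is the number of pixels in bin i, i = 0..L; ``vmax`` is
    the raw LMES value mapped to the top bin (the map maximum).
    """

    counts: np.ndarray
    vmax: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("histogram needs at least two bins")
        if (c < 0).any():
            raise ValueError("histogram counts must be nonnegative")
        self.counts = c.astype(np.int64)
        self.vmax = float(self.vmax)

    @property
    def top_bin(self) -> int:
        """L, the top bin index."""
        return self.counts.size - 1

    @property
    def n(self) -> int:
        """Total pixel count."""
        return int(self.counts.sum())

    def raw_value(self, b: float) -> float:
        """Raw LMES value at the lower edge of bin b."""
        if self.vmax == 0.0:
            return 0.0
        return float(b) * self.vmax / self.top_bin


@dataclass
class OtsuResult:
    """Selected threshold and the class statistics justifying it.

    ``t_star`` is the selected bin index, ``threshold`` the decision value
    in raw LMES units ("edge ⇔ LMES ≥ threshold"), ``sigma_b`` the
    between-class variance per candidate t (NaN where a class is empty),
    and ``w1/w2/mu1/mu2/mu_t`` the statistics at t*. ``degenerate`` marks
    histograms with a single occupied bin, for which no split exists and
    the threshold is placed above the maximum (no edge pixels).
    """

    t_star: int
    threshold: float
    sigma_b: np.ndarray
    w1: float
    w2: float
    mu1: float
    mu2: float
    mu_t: float
    degenerate: bool = False


def lmes_histogram(lmes: np.ndarray, bins: int = 255) -> LmesHistogram:
    """Bin a nonnegative real map into bins 0..L with L = ``bins``.

    Values are rescaled so 0 maps to bin 0 and the map maximum to bin L;
    bin b then covers the raw interval [b·vmax/L, (b+1)·vmax/L).
    """
    arr = np.asarray(lmes, dtype=float)
    if bins < 2:
        raise ValueError(f"bins must be ≥ 2, got {bins}")
    if arr.size == 0:
        raise ValueError("empty LMES map")
    if not np.isfinite(arr).all() or (arr < 0).any():
        raise ValueError("LMES values must be finite and ≥ 0")
    vmax = float(arr.max())
    if vmax == 0.0:
        counts = np.zeros(bins + 1, dtype=np.int64)
        counts[0] = arr.size
        return LmesHistogram(counts=counts, vmax=0.0)
    b = np.floor(arr / vmax * bins).astype(np.int64)
    counts = np.bincount(b.ravel(), minlength=bins + 1)
    return LmesHistogram(counts=counts, vmax=vmax)


def _exact_argmax(counts: np.ndarray) -> int | None:
    """Smallest t maximizing σB², compared as exact rationals.

    σB²(t) = (S1·c2 − S2·c1)² / (N²·c1·c2) with c1/c2 the class counts and
    S1/S2 the class index sums; the constant N² is dropped.
    """
    total = int(counts.sum())
    s_total = int((np.arange(counts.size) * counts).sum())
    c1 = 0
    s1 = 0
    best_t: int | None = None
    best_val = Fraction(-1)
    for t in range(counts.size - 1):
        c1 += int(counts[t])
        s1 += t * int(counts[t])
        c2 = total - c1
        if c1 == 0 or c2 == 0:
            continue
        s2 = s_total - s1
        num = s1 * c2 - s2 * c1
        val = Fraction(num * num, c1 * c2)
        if val > best_val:
            best_val = val
            best_t = t
    return best_t


def otsu_threshold(h: LmesHistogram) -> OtsuResult:
    """Select the split maximizing between-class variance.

    Returns the smallest maximizing bin index (deterministic tie-break,
    favouring sensitivity) and the decision threshold in raw LMES units.
    A single occupied bin yields a degenerate result with the threshold
    above the map maximum and a logged warning.
    """
    counts = h.counts
    n = h.n
    if n <= 0:
        raise ValueError("empty histogram")
    idx = np.arange(counts.size, dtype=float)
    p = counts / n
    w1 = np.cumsum(p)
    c1 = np.cumsum(counts)
    mu_cum = np.cumsum(idx * p)
    mu_t = float(mu_cum[-1])
    w2 = 1.0 - w1
    valid = (c1 > 0) & (c1 < n)
    sigma = np.full(counts.size, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = mu_cum / w1
        mu2 = (mu_t - mu_cum) / w2
        sig = w1 * (mu1 - mu_t) ** 2 + w2 * (mu2 - mu_t) ** 2
    sigma[valid] = sig[valid]

    t_star = _exact_argmax(counts)
    if t_star is None:
        logger.warning(
            "degenerate LMES histogram (single occupied bin): "
            "declaring zero edge pixels"
        )
        return OtsuResult(
            t_star=0,
            threshold=h.vmax + 1.0,
            sigma_b=sigma,
            w1=1.0,
            w2=0.0,
            mu1=mu_t,
            mu2=0.0,
            mu_t=mu_t,
            degenerate=True,
        )
    return OtsuResult(
        t_star=int(t_star),
        threshold=h.raw_value(t_star + 1),
        sigma_b=sigma,
        w1=float(w1[t_star]),
        w2=float(w2[t_star]),
        mu1=float(mu1[t_star]),
        mu2=float(mu2[t_star]),
        mu_t=mu_t,
        degenerate=False,
    )
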