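"""Independent brute-force oracles used across the test suite.

Everything here is written from the definitions, deliberately avoiding the
package's vectorized code paths: explicit python loops over pixels, pairs
and histogram bins, and exact rational arithmetic where ties matter.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

#: unit neighbour offsets (row, col) per orientation, scaled by the distance
UNIT_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(window, distance, angle, symmetric):
    """Pair-frequency table by literal enumeration of all pixel pairs."""
    w = np.asarray(window)
    nc = int(w.max())
    tab = np.zeros((nc + 1, nc + 1), dtype=np.int64)
    ur, uc = UNIT_OFFSETS[angle]
    offsets = [(ur * distance, uc * distance)]
    if angle in (45, 135) or symmetric:
        offsets.append((-ur * distance, -uc * distance))
    h, wd = w.shape
    for dr, dc in offsets:
        for x in range(h):
            for y in range(wd):
                x2, y2 = x + dr, y + dc
                if 0 <= x2 < h and 0 <= y2 < wd:
                    tab[w[x, y], w[x2, y2]] += 1
    return tab


def feature_double_loop(p, name):
    """Scalar feature by an explicit double loop over matrix cells."""
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    mu = 0.0
    if name == "var":
        for i in range(n):
            for j in range(n):
                mu += i * p[i, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            if name == "dm":
                total += (0.5 * abs(i - j) * v) ** 0.5
            elif name == "direc":
                total += v if i == j else 0.0
            elif name == "ener":
                total += v * v
            elif name == "odm":
                total += v / (1 + (i - j) ** 2)
            else:
                total += (i - mu) ** 2 * v
    return total


def edge_strength_oracle(ia):
    """ES1..ES8 on interior pixels by literal index arithmetic.

    Returns an (8, M, N) array, NaN on the 1-pixel border.
    """
    a = np.asarray(ia, dtype=float)
    m, n = a.shape
    out = np.full((8, m, n), np.nan)
    for x in range(1, m - 1):
        for y in range(1, n - 1):
            out[0, x, y] = (a[x-1, y-1] + 2*a[x-1, y] + a[x-1, y+1]
                            - a[x+1, y-1] - 2*a[x+1, y] - a[x+1, y+1])
            out[1, x, y] = (a[x-1, y-1] - a[x-1, y+1] + 2*a[x, y-1]
                            - 2*a[x, y+1] + a[x+1, y-1] - a[x+1, y+1])
            out[2, x, y] = (a[x-1, y-1] + 2*a[x-1, y] + a[x-1, y+1]
                            - a[x, y-1] - 2*a[x, y] - a[x, y+1])
            out[3, x, y] = (a[x, y-1] + 2*a[x, y] + a[x, y+1]
                            - a[x+1, y-1] - 2*a[x+1, y] - a[x+1, y+1])
            out[4, x, y] = (a[x-1, y-1] - a[x-1, y] + 2*a[x, y-1]
                            - 2*a[x, y] + a[x+1, y-1] - a[x+1, y])
            out[5, x, y] = (a[x-1, y] - a[x-1, y+1] + 2*a[x, y]
                            - 2*a[x, y+1] + a[x+1, y] - a[x+1, y+1])
            out[6, x, y] = (2*a[x-1, y-1] + a[x-1, y] + a[x, y-1]
                            - a[x, y+1] - a[x+1, y] - 2*a[x+1, y+1])
            out[7, x, y] = (a[x-1, y] + 2*a[x-1, y+1] - a[x, y-1]
                            + a[x, y+1] - 2*a[x+1, y-1] - a[x+1, y])
    return out


def otsu_bruteforce(counts):
    """Smallest t maximizing w1(μ1−μT)² + w2(μ2−μT)², exact rationals."""
    counts = [int(c) for c in counts]
    top = len(counts) - 1
    total = sum(counts)
    mu_t = Fraction(sum(i * c for i, c in enumerate(counts)), total)
    best_t = None
    best_val = Fraction(-1)
    c1 = 0
    s1 = 0
    for t in range(top + 1):
        c1 += counts[t]
        s1 += t * counts[t]
        c2 = total - c1
        if c1 == 0 or c2 == 0:
            continue
        w1 = Fraction(c1, total)
        w2 = Fraction(c2, total)
        mu1 = Fraction(s1, c1)
        mu2 = Fraction(sum(i * c for i, c in enumerate(counts)) - s1, c2)
        val = w1 * (mu1 - mu_t) ** 2 + w2 * (mu2 - mu_t) ** 2
        if val > best_val:
            best_val = val
            best_t = t
    return best_t


def confusion_oracle(pred, ref):
    """Pixelwise confusion counts by explicit enumeration (tolerance 0)."""
    p = np.asarray(pred) > 0
    r = np.asarray(ref) > 0
    npcc = n1r = n2r = n1c = n1f = 0
    for x in range(p.shape[0]):
        for y in range(p.shape[1]):
            if p[x, y] == r[x, y]:
                npcc += 1
            if r[x, y]:
                n1r += 1
                if p[x, y]:
                    n1c += 1
            else:
                n2r += 1
                if p[x, y]:
                    n1f += 1
    return {"npcc": npcc, "n1r": n1r, "n2r": n2r, "n1c": n1c, "n1f": n1f}
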