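"""Independent naive-loop reference implementations.

Everything here is written directly from the method definitions with plain
Python loops — no code is shared with the package's vectorized paths, so
agreement between the two is a meaningful check.  The boundary rule is the
same contract the package documents: symmetric (mirror-with-edge) padding.
"""

from __future__ import annotations

import math

import numpy as np


def pad(img: np.ndarray, p: int) -> np.ndarray:
    return np.pad(np.asarray(img, dtype=float), p, mode="symmetric") if p else np.asarray(img, float)


def naive_gaussian_kernel(radius: int, std: float) -> np.ndarray:
    n = 2 * radius + 1
    k = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if math.isinf(std):
                k[i, j] = 1.0
            else:
                k[i, j] = math.exp(-((j - radius) ** 2 + (i - radius) ** 2) / (2 * std**2))
    return k / k.sum()


def naive_patch_distance(q, a, b, r, kern) -> float:
    """Weighted SSD of patches at padded coordinates a, b."""
    total = 0.0
    for u in range(-r, r + 1):
        for v in range(-r, r + 1):
            diff = q[a[0] + u, a[1] + v] - q[b[0] + u, b[1] + v]
            total += kern[u + r, v + r] * diff * diff
    return total


def naive_nlm(img, search_radius, patch_radius, kernel_std, kappa, noise_var=0.0):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    s, r = search_radius, patch_radius
    kern = naive_gaussian_kernel(r, kernel_std)
    p = s + r
    q = pad(img, p)
    out = np.empty_like(img)
    for row in range(h):
        for col in range(w):
            ci = (row + p, col + p)
            raw, vals = [], []
            wself = 0.0
            for dy in range(-s, s + 1):
                for dx in range(-s, s + 1):
                    if dy == 0 and dx == 0:
                        continue
                    d2 = naive_patch_distance(q, ci, (ci[0] + dy, ci[1] + dx), r, kern)
                    d2 = max(d2 - 2.0 * noise_var, 0.0)
                    wgt = math.exp(-d2 / kappa**2)
                    wself = max(wself, wgt)
                    raw.append(wgt)
                    vals.append(q[ci[0] + dy, ci[1] + dx])
            raw.append(wself)
            vals.append(img[row, col])
            beta = sum(raw)
            out[row, col] = sum(wg * v for wg, v in zip(raw, vals)) / beta
    return out


def naive_prefilter(img, radius, std):
    img = np.asarray(img, dtype=float)
    if radius == 0:
        return img.copy()
    kern = naive_gaussian_kernel(radius, std)
    q = pad(img, radius)
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            acc = 0.0
            for u in range(2 * radius + 1):
                for v in range(2 * radius + 1):
                    acc += kern[u, v] * q[i + u, j + v]
            out[i, j] = acc
    return out


def naive_neighborhood_gradient(pref, row, col, r):
    """Mean central-difference gradient over the patch at (possibly out-of-image)
    coordinates, defined on the symmetrically padded prefiltered image."""
    pref = np.asarray(pref, dtype=float)
    margin = max(abs(row) if row < 0 else row - pref.shape[0] + 1, 0)
    margin = max(
        margin, max(abs(col) if col < 0 else col - pref.shape[1] + 1, 0)
    )
    p = margin + r + 1
    q = pad(pref, p)
    gx = gy = 0.0
    n = (2 * r + 1) ** 2
    for u in range(-r, r + 1):
        for v in range(-r, r + 1):
            y, x = row + u + p, col + v + p
            gx += (q[y, x + 1] - q[y, x - 1]) / 2.0
            gy += (q[y + 1, x] - q[y - 1, x]) / 2.0
    return gx / n, gy / n


def naive_angle(g1, g2) -> float:
    n1 = math.hypot(*g1)
    n2 = math.hypot(*g2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    cross = g1[0] * g2[1] - g1[1] * g2[0]
    dot = g1[0] * g2[0] + g1[1] * g2[1]
    return math.atan2(abs(cross), dot)


def naive_onlm(
    img,
    search_radius,
    patch_radius,
    kernel_std,
    prefilter_radius,
    prefilter_std,
    kappa2,
    tau,
    alpha,
    c,
    aggregate="raw",
    noise_var=0.0,
):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    s, r = search_radius, patch_radius
    kern = naive_gaussian_kernel(r, kernel_std)
    pref = naive_prefilter(img, prefilter_radius, prefilter_std)
    p = s + r
    q = pad(img, p)
    qk = pad(pref, p)
    qa = q if aggregate == "raw" else qk
    grads = {}
    for row in range(-s, h + s):
        for col in range(-s, w + s):
            grads[(row, col)] = naive_neighborhood_gradient(pref, row, col, r)
    out = np.empty_like(img)
    for row in range(h):
        for col in range(w):
            ci = (row + p, col + p)
            # adaptive bandwidth: mean prefiltered-patch distance over the
            # whole window (center included, its distance is 0), uncorrected
            total = 0.0
            for dy in range(-s, s + 1):
                for dx in range(-s, s + 1):
                    total += naive_patch_distance(qk, ci, (ci[0] + dy, ci[1] + dx), r, kern)
            k1sq = alpha * total / (2 * s + 1) ** 2 + c
            gi = grads[(row, col)]
            raw, vals = [], []
            wself = 0.0
            for dy in range(-s, s + 1):
                for dx in range(-s, s + 1):
                    if dy == 0 and dx == 0:
                        continue
                    cj = (ci[0] + dy, ci[1] + dx)
                    d2k = naive_patch_distance(qk, ci, cj, r, kern)
                    d2 = naive_patch_distance(q, ci, cj, r, kern)
                    if noise_var > 0:
                        d2k = max(d2k - 2.0 * noise_var, 0.0)
                        d2 = max(d2 - 2.0 * noise_var, 0.0)
                    ang = naive_angle(gi, grads[(row + dy, col + dx)])
                    wgt = math.exp(-d2k / k1sq - d2 / kappa2**2 - ang / tau**2)
                    wself = max(wself, wgt)
                    raw.append(wgt)
                    vals.append(qa[cj[0], cj[1]])
            raw.append(wself)
            vals.append(qa[ci[0], ci[1]])
            beta = sum(raw)
            out[row, col] = sum(wg * v for wg, v in zip(raw, vals)) / beta
    return out


def naive_bilateral(img, radius, spatial_std, range_std):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    q = pad(img, radius)
    out = np.empty_like(img)
    for row in range(h):
        for col in range(w):
            num = den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    pj = q[row + radius + dy, col + radius + dx]
                    wgt = math.exp(-(dy * dy + dx * dx) / (2 * spatial_std**2))
                    if not math.isinf(range_std):
                        wgt *= math.exp(-((img[row, col] - pj) ** 2) / (2 * range_std**2))
                    num += wgt * pj
                    den += wgt
            out[row, col] = num / den
    return out
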