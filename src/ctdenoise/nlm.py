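"""Classic non-local means (NLM) denoising.

Each output pixel is a convex combination of the pixels in its search
window; the weight of a candidate pixel decays exponentially with the
Gaussian-weighted squared distance between the two similarity patches,
``w = exp(-d2 / kappa**2)``.  The center pixel does not compare against
itself (that would always win); instead its raw weight is set to the
maximum raw weight among the other candidates before normalization, the
standard self-weight rule.

Boundary rule: the image is padded symmetrically (mirror including the edge
pixel), so patches and search windows of border pixels are always defined;
candidates that fall outside the image take their mirrored values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .kernels import bias_corrected_distance, gaussian_kernel_1d, pad_image

__all__ = ["NLMParams", "WeightMap", "nlm_weights", "nlm_denoise"]


@dataclass(frozen=True)
class NLMParams:
    """Tuning parameters of classic NLM on the 0-255 intensity scale.

    ``kernel_std=None`` resolves to ``patch_radius / 2`` (or 1.0 for a
    degenerate 1x1 patch); ``kappa=numpy.inf`` is the flat-weight limit in
    which the filter becomes a plain search-window mean.  ``noise_var`` is
    the per-pixel noise variance used for bias correction of the patch
    distances; 0 disables the correction.
    """

    search_radius: int = 10
    patch_radius: int = 3
    kernel_std: float | None = None
    kappa: float = 10.0
    noise_var: float = 0.0

    def __post_init__(self) -> None:
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be >= 0")
        if self.search_radius < self.patch_radius:
            raise ValueError("search_radius must be >= patch_radius")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")
        if self.kernel_std is not None and not np.isinf(self.kernel_std):
            if self.kernel_std <= 0:
                raise ValueError("kernel_std must be positive")

    @property
    def resolved_kernel_std(self) -> float:
        if self.kernel_std is not None:
            return self.kernel_std
        return self.patch_radius / 2.0 if self.patch_radius > 0 else 1.0


@dataclass(frozen=True)
class WeightMap:
    """Normalized similarity weights of one target pixel over its search window.

    ``weights[s + dy, s + dx]`` is ``z(i, i + (dy, dx))`` for offsets in
    ``[-s, s]``; the map sums to 1 and every entry lies in [0, 1].  ``beta``
    is the normalizer (the sum of raw weights).
    """

    center: tuple[int, int]
    weights: np.ndarray
    beta: float


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def _kernel_correlate_valid(sq_diff: np.ndarray, g1: np.ndarray, r: int) -> np.ndarray:
    """Separable kernel-weighted patch sum of a squared-difference field.

    ``sq_diff`` covers the image region plus an ``r`` margin; the returned
    map is the Gaussian-kernel correlation evaluated at the image pixels
    (the 'valid' interior, no boundary effects).
    """
    if r == 0:
        return sq_diff
    tmp = correlate1d(sq_diff, g1, axis=0, mode="nearest")
    tmp = correlate1d(tmp, g1, axis=1, mode="nearest")
    return tmp[r:-r, r:-r]


def _search_offsets(search_radius: int):
    for dy in range(-search_radius, search_radius + 1):
        for dx in range(-search_radius, search_radius + 1):
            yield dy, dx


def offset_distance_map(
    padded: np.ndarray,
    shape: tuple[int, int],
    search_radius: int,
    patch_radius: int,
    g1: np.ndarray,
    offset: tuple[int, int],
) -> np.ndarray:
    """d2(i, i+offset) for every image pixel i, from a (s+r)-padded image."""
    h, w = shape
    s, r = search_radius, patch_radius
    dy, dx = offset
    base = padded[s : s + h + 2 * r, s : s + w + 2 * r]
    shifted = padded[s + dy : s + dy + h + 2 * r, s + dx : s + dx + w + 2 * r]
    return _kernel_correlate_valid((base - shifted) ** 2, g1, r)


def nlm_weights(image: np.ndarray, i: tuple[int, int], params: NLMParams) -> WeightMap:
    """Similarity weights of pixel ``i`` over its search window.

    Reference (per-pixel) computation; :func:`nlm_denoise` reproduces the
    same weights vectorized over all pixels.
    """
    img = _check_image(image)
    row, col = int(i[0]), int(i[1])
    if not (0 <= row < img.shape[0] and 0 <= col < img.shape[1]):
        raise ValueError(f"pixel {i} outside image of shape {img.shape}")
    s, r = params.search_radius, params.patch_radius
    g1 = gaussian_kernel_1d(r, params.resolved_kernel_std)
    kern = np.outer(g1, g1)
    pad = s + r
    q = pad_image(img, pad)
    ksq = params.kappa**2
    n = 2 * s + 1
    raw = np.empty((n, n))
    pr, pc = row + pad, col + pad
    patch_i = q[pr - r : pr + r + 1, pc - r : pc + r + 1]
    for dy, dx in _search_offsets(s):
        if dy == 0 and dx == 0:
            continue
        jr, jc = pr + dy, pc + dx
        patch_j = q[jr - r : jr + r + 1, jc - r : jc + r + 1]
        d2 = float(np.sum(kern * (patch_i - patch_j) ** 2))
        d2 = bias_corrected_distance(d2, params.noise_var)
        raw[s + dy, s + dx] = np.exp(-d2 / ksq)
    if s > 0:
        center_mask = np.ones((n, n), dtype=bool)
        center_mask[s, s] = False
        raw[s, s] = raw[center_mask].max()
    else:
        raw[s, s] = 1.0
    beta = float(raw.sum())
    return WeightMap(center=(row, col), weights=raw / beta, beta=beta)


def nlm_denoise(image: np.ndarray, params: NLMParams | None = None) -> np.ndarray:
    """Denoise a 2-D image with classic non-local means.

    Every output pixel is the weighted average of the (mirror-padded)
    search-window pixels under the weights of :func:`nlm_weights`, so the
    output lies within the per-window min/max of the input.
    """
    params = params or NLMParams()
    img = _check_image(image)
    h, w = img.shape
    s, r = params.search_radius, params.patch_radius
    if s == 0:
        return img.copy()
    g1 = gaussian_kernel_1d(r, params.resolved_kernel_std)
    pad = s + r
    q = pad_image(img, pad)
    ksq = params.kappa**2
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    wmax = np.zeros((h, w))
    for dy, dx in _search_offsets(s):
        if dy == 0 and dx == 0:
            continue
        d2 = offset_distance_map(q, (h, w), s, r, g1, (dy, dx))
        if params.noise_var > 0:
            d2 = np.maximum(d2 - 2.0 * params.noise_var, 0.0)
        wgt = np.exp(-d2 / ksq)
        np.maximum(wmax, wgt, out=wmax)
        pj = q[pad + dy : pad + dy + h, pad + dx : pad + dx + w]
        num += wgt * pj
        den += wgt
    num += wmax * img
    den += wmax
    return num / den
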