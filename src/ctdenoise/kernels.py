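"""Gaussian kernels and Gaussian-weighted patch distances.

This is the shared machinery of the non-local means family: a normalized
Gaussian kernel ``K_r`` defines how much each offset inside a similarity
patch contributes to the squared-difference sum, and the resulting weighted
patch distance is the similarity measure every weight function is built on.

Because the kernel is normalized to unit sum, the weighted distance needs no
further division by the patch area: the two conventions (unit-sum kernel vs
dividing an unnormalized sum by ``(2r+1)^2``) differ only by a constant that
is absorbed into the filtering bandwidth ``kappa``.  All bandwidths in this
package are on the unit-sum-kernel scale.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gaussian_kernel",
    "gaussian_kernel_1d",
    "weighted_patch_distance",
    "bias_corrected_distance",
]


def gaussian_kernel_1d(radius: int, std: float) -> np.ndarray:
    """Normalized 1-D Gaussian profile of length ``2*radius + 1``.

    ``std=numpy.inf`` is an explicit flat-kernel sentinel (all entries equal).
    The outer product of this profile with itself equals
    :func:`gaussian_kernel` exactly, which the separable fast paths rely on.
    """
    radius = int(radius)
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if not np.isinf(std) and std <= 0:
        raise ValueError(f"std must be positive (or inf), got {std}")
    t = np.arange(-radius, radius + 1, dtype=float)
    if np.isinf(std):
        g = np.ones_like(t)
    else:
        g = np.exp(-(t**2) / (2.0 * std**2))
    return g / g.sum()


def gaussian_kernel(radius: int, std: float) -> np.ndarray:
    """Normalized ``(2r+1) x (2r+1)`` Gaussian weight grid.

    Entry at offset ``(di, dj)`` from the center is proportional to
    ``exp(-(di**2 + dj**2) / (2*std**2))``; entries are divided by their
    total so the grid sums to exactly 1.
    """
    g = gaussian_kernel_1d(radius, std)
    k = np.outer(g, g)
    return k / k.sum()


def pad_image(image: np.ndarray, pad: int) -> np.ndarray:
    """Symmetric (mirror-with-edge) padding, the boundary rule used package-wide."""
    if pad == 0:
        return np.asarray(image, dtype=float)
    return np.pad(np.asarray(image, dtype=float), pad, mode="symmetric")


def weighted_patch_distance(
    image: np.ndarray,
    center_a: tuple[int, int],
    center_b: tuple[int, int],
    kernel: np.ndarray,
) -> float:
    """Kernel-weighted sum of squared differences between two patches.

    Patches are the ``(2r+1) x (2r+1)`` neighborhoods of the two centers,
    extracted from the symmetrically padded image so border centers are
    valid.  With a unit-sum kernel the result is the mean squared patch
    difference under the kernel measure; it is symmetric in its two centers,
    nonnegative, and scales as ``s**2`` when intensities scale by ``s``.
    """
    image = np.asarray(image, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    r = (kernel.shape[0] - 1) // 2
    if kernel.shape != (2 * r + 1, 2 * r + 1):
        raise ValueError(f"kernel must be square odd-sized, got {kernel.shape}")
    if r > min(image.shape):
        raise ValueError(
            f"kernel radius {r} exceeds image extent {image.shape} under symmetric padding"
        )
    padded = pad_image(image, r)
    ar, ac = (int(center_a[0]) + r, int(center_a[1]) + r)
    br, bc = (int(center_b[0]) + r, int(center_b[1]) + r)
    pa = padded[ar - r : ar + r + 1, ac - r : ac + r + 1]
    pb = padded[br - r : br + r + 1, bc - r : bc + r + 1]
    return float(np.sum(kernel * (pa - pb) ** 2))


def bias_corrected_distance(d2: float, noise_var: float) -> float:
    """Remove the additive noise bias ``2*noise_var`` from a squared patch distance.

    On a noisy image the expected squared patch distance exceeds the clean
    one by twice the per-pixel noise variance; subtracting it recovers an
    estimate of the clean distance.  Negative results are clamped to 0 (a
    squared distance cannot be negative).  ``noise_var=0`` is the identity.
    """
    if noise_var < 0:
        raise ValueError(f"noise_var must be >= 0, got {noise_var}")
    return max(float(d2) - 2.0 * float(noise_var), 0.0)
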