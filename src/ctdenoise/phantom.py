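"""Synthetic CT-like phantoms and their corruption model.

A phantom is a piecewise-constant 2-D image built from ellipses and annuli
(a crude axial-CT look: a bright bone-like ring around soft-tissue-level
interior structures).  Corruption adds i.i.d. zero-mean Gaussian noise and
optional straight-line streaks — additive line profiles emulating the
linear bright/dark bands of low-dose CT reconstructions, not sinogram-domain
physics.  Noise is applied first, clipping to [0, 255] last, so estimates
of the noise level should use mid-gray regions away from saturation.

Everything is deterministic given the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Ellipse",
    "Annulus",
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom",
    "corrupt",
    "default_phantom_spec",
    "default_noise_spec",
]


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse: center (row, col), semi-axes (a, b), rotation in radians.

    ``a`` runs along the rotated column direction, ``b`` along the rotated
    row direction; ``rotation`` is counterclockwise in the (col, row) plane.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    intensity: float
    rotation: float = 0.0


@dataclass(frozen=True)
class Annulus:
    """Elliptical ring: inside the outer ellipse but outside the inner one."""

    center: tuple[float, float]
    outer_axes: tuple[float, float]
    inner_axes: tuple[float, float]
    intensity: float
    rotation: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Square piecewise-constant phantom: later objects paint over earlier ones."""

    size: int = 128
    objects: tuple = ()
    background: float = 20.0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("size must be >= 16")
        if not 0 <= self.background <= 255:
            raise ValueError("background must be in [0, 255]")
        for obj in self.objects:
            if not 0 <= obj.intensity <= 255:
                raise ValueError(f"object intensity {obj.intensity} outside [0, 255]")
            axes = obj.outer_axes if isinstance(obj, Annulus) else obj.axes
            reach = max(axes)
            cr, cc = obj.center
            if (
                cr - reach < 0
                or cc - reach < 0
                or cr + reach > self.size - 1
                or cc + reach > self.size - 1
            ):
                raise ValueError(f"object {obj} extends outside the {self.size}px image")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level, streak-artifact layout and the RNG seed."""

    sigma: float = 20.0
    streaks: int = 0
    streak_amplitude: float = 40.0
    streak_width: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.streaks < 0:
            raise ValueError("streaks must be >= 0")
        if self.streak_width <= 0:
            raise ValueError("streak_width must be > 0")


def _ellipse_mask(
    rr: np.ndarray,
    cc: np.ndarray,
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation: float,
) -> np.ndarray:
    dr = rr - center[0]
    dc = cc - center[1]
    cos, sin = np.cos(rotation), np.sin(rotation)
    u = cos * dc + sin * dr
    v = -sin * dc + cos * dr
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the spec: each pixel takes the topmost covering object's intensity."""
    img = np.full((spec.size, spec.size), float(spec.background))
    rr, cc = np.meshgrid(
        np.arange(spec.size, dtype=float), np.arange(spec.size, dtype=float), indexing="ij"
    )
    for obj in spec.objects:
        if isinstance(obj, Annulus):
            mask = _ellipse_mask(rr, cc, obj.center, obj.outer_axes, obj.rotation)
            mask &= ~_ellipse_mask(rr, cc, obj.center, obj.inner_axes, obj.rotation)
        else:
            mask = _ellipse_mask(rr, cc, obj.center, obj.axes, obj.rotation)
        img[mask] = obj.intensity
    return img


def corrupt(image: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Add seeded Gaussian noise, superimpose streaks, then clip to [0, 255].

    Each streak is a straight band of the given width through a uniformly
    random point at a uniformly random angle, with a uniform ±amplitude
    offset.  Identical (image, spec) pairs give bit-identical outputs.
    """
    img = np.asarray(image, dtype=float)
    rng = np.random.default_rng(noise.seed)
    out = img.copy()
    if noise.sigma > 0:
        out += rng.normal(0.0, noise.sigma, size=img.shape)
    if noise.streaks > 0:
        h, w = img.shape
        rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
        for _ in range(noise.streaks):
            theta = rng.uniform(0.0, np.pi)
            p0r = rng.uniform(0.0, h - 1.0)
            p0c = rng.uniform(0.0, w - 1.0)
            amp = rng.uniform(-noise.streak_amplitude, noise.streak_amplitude)
            # distance from the line through (p0r, p0c) with direction (cos, sin)
            dist = np.abs(-np.sin(theta) * (cc - p0c) + np.cos(theta) * (rr - p0r))
            out[dist <= noise.streak_width / 2.0] += amp
    if noise.sigma > 0 or noise.streaks > 0:
        np.clip(out, 0.0, 255.0, out=out)
    return out


def default_phantom_spec() -> PhantomSpec:
    """The shipped 128x128 benchmark phantom.

    A bright skull-like annulus around a soft-tissue interior with one
    hyperdense and one hypodense inclusion, on a near-air background —
    fixed so benchmark runs are comparable across sessions.
    """
    return PhantomSpec(
        size=128,
        background=20.0,
        objects=(
            Ellipse(center=(64.0, 64.0), axes=(44.0, 52.0), intensity=90.0),
            Annulus(
                center=(64.0, 64.0),
                outer_axes=(44.0, 52.0),
                inner_axes=(38.0, 46.0),
                intensity=230.0,
            ),
            Ellipse(center=(50.0, 52.0), axes=(8.0, 8.0), intensity=150.0),
            Ellipse(center=(80.0, 72.0), axes=(6.0, 6.0), intensity=40.0),
        ),
    )


def default_noise_spec() -> NoiseSpec:
    """The shipped benchmark corruption: sigma=20 Gaussian noise, five streaks."""
    return NoiseSpec(sigma=20.0, streaks=5, streak_amplitude=40.0, streak_width=2.0, seed=0)


def with_seed(noise: NoiseSpec, seed: int) -> NoiseSpec:
    """Copy of ``noise`` with a different seed (replicate generation helper)."""
    return replace(noise, seed=seed)
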