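"""Synthetic inputs: canonical angle maps, stripe images, an orientation
estimator, and particle rendering.

Everything here is generated programmatically so the full pipeline — field
construction, simulation, rendering, and orientation re-estimation — can be
exercised without any external fingerprint data.  The estimator is a plain
structure-tensor method: ridge orientation is the eigenvector of the smaller
eigenvalue of the Gaussian-smoothed gradient outer product (perpendicular to
the dominant gradient), returned mod π.

Image arrays follow the package-wide convention: pixel [i, j] sits at the
domain point ((i+½)/n0, (j+½)/n1), axis 0 = x, axis 1 = y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dynamics import ParticleState
from .orientation_fields import (AngleGrid, HomogeneousField, PiecewiseField,
                                 SingularField, SingularPoint, normalize_angle)

__all__ = [
    "RidgeImage",
    "make_angle_map",
    "make_field",
    "stripe_image",
    "estimate_orientation",
    "render_particles",
    "orientation_agreement",
]


@dataclass
class RidgeImage:
    """Grayscale stripe image with known period and orientation."""

    pixels: np.ndarray
    wavelength: float
    orientation: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


def make_field(kind: str, chi: float = 0.2, **kw):
    """Canonical orientation fields used throughout the tests and CLI.

    Kinds: ``parallel`` (theta0), ``single_core`` / ``single_delta`` (zeta),
    ``core_plus_delta`` (zeta1 = core, zeta2 = delta), ``two_region``
    (theta0 left half, theta1 right half).
    """
    if kind == "parallel":
        return HomogeneousField(kw.get("theta0", np.pi / 2), chi=chi)
    if kind == "single_core":
        return SingularField([SingularPoint(tuple(kw.get("zeta", (0.5, 0.5))), "core")],
                             chi=chi)
    if kind == "single_delta":
        return SingularField([SingularPoint(tuple(kw.get("zeta", (0.5, 0.5))), "delta")],
                             chi=chi)
    if kind == "core_plus_delta":
        return SingularField([
            SingularPoint(tuple(kw.get("zeta1", (0.35, 0.6))), "core"),
            SingularPoint(tuple(kw.get("zeta2", (0.65, 0.35))), "delta"),
        ], chi=chi)
    if kind == "two_region":
        t0 = kw.get("theta0", np.pi / 2)
        t1 = kw.get("theta1", 0.0)
        return PiecewiseField([((0.0, 0.5, 0.0, 1.0), t0)], fallback=t1, chi=chi)
    raise ValueError(f"unknown field kind {kind!r}")


def _cell_centers(resolution: int):
    c = (np.arange(resolution) + 0.5) / resolution
    gx, gy = np.meshgrid(c, c, indexing="ij")
    return np.stack([gx, gy], axis=-1)


def make_angle_map(kind: str, resolution: int = 128, chi: float = 0.2,
                   **kw) -> AngleGrid:
    """Sample a canonical field onto an AngleGrid at cell centers."""
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    field = make_field(kind, chi=chi, **kw)
    pts = _cell_centers(resolution)
    angles = field.angle_at(pts.reshape(-1, 2)).reshape(resolution, resolution)
    return AngleGrid(angles)


def stripe_image(wavelength: float, orientation: float,
                 resolution: int = 256) -> RidgeImage:
    """Sinusoidal stripe pattern: ½(1 + cos(2π (x·n)/λ)), n ⟂ stripes."""
    if not 0.0 < wavelength <= 0.5:
        raise ValueError("wavelength must lie in (0, 0.5]")
    pts = _cell_centers(resolution)
    n = np.array([-np.sin(orientation), np.cos(orientation)])
    phase = (pts @ n) / wavelength
    pixels = 0.5 * (1.0 + np.cos(2.0 * np.pi * phase))
    return RidgeImage(pixels, wavelength, float(normalize_angle(orientation)))


def estimate_orientation(pixels, smoothing_scale: float = 2.0,
                         mask_rel_tol: float = 1e-6) -> AngleGrid:
    """Structure-tensor ridge-orientation estimate of a grayscale image.

    Central-difference gradients are formed, their per-pixel outer products
    smoothed by a Gaussian of ``smoothing_scale`` pixels, and the ridge
    orientation taken as the eigenvector of the SMALLER eigenvalue of the
    smoothed tensor (perpendicular to the dominant gradient direction),
    reduced mod π.  Pixels whose tensor trace falls below ``mask_rel_tol``
    times the maximum trace (e.g. constant regions) are masked out.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or min(pixels.shape) < 16:
        raise ValueError("image must be 2-D and at least 16x16")
    gx, gy = np.gradient(pixels)
    jxx = ndimage.gaussian_filter(gx * gx, smoothing_scale)
    jxy = ndimage.gaussian_filter(gx * gy, smoothing_scale)
    jyy = ndimage.gaussian_filter(gy * gy, smoothing_scale)
    # dominant-gradient direction, then rotate by pi/2 for the ridge direction
    theta_grad = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    angles = normalize_angle(theta_grad + 0.5 * np.pi)
    trace = jxx + jyy
    mask = trace > mask_rel_tol * max(trace.max(), np.finfo(float).tiny)
    return AngleGrid(angles, mask)


def render_particles(state: ParticleState, resolution: int = 256,
                     splat_radius: float = 0.004) -> np.ndarray:
    """Deposit a Gaussian splat per particle with torus wrapping.

    ``splat_radius`` is the Gaussian sigma in domain units.  The image is
    normalized to [0, 1] (all-zero if the state is empty of mass).
    """
    if splat_radius <= 0:
        raise ValueError("splat_radius must be positive")
    positions = state.positions if hasattr(state, "positions") \
        else np.asarray(state, dtype=float).reshape(-1, 2)
    img = np.zeros((resolution, resolution))
    sigma_px = splat_radius * resolution
    half = max(1, int(np.ceil(4.0 * sigma_px)))
    offs = np.arange(-half, half + 1)
    oi, oj = np.meshgrid(offs, offs, indexing="ij")
    for x, y in positions:
        ci = x * resolution - 0.5
        cj = y * resolution - 0.5
        i0 = int(np.round(ci))
        j0 = int(np.round(cj))
        di = (i0 + oi) - ci
        dj = (j0 + oj) - cj
        stamp = np.exp(-(di * di + dj * dj) / (2.0 * sigma_px ** 2))
        np.add.at(img, (np.mod(i0 + oi, resolution), np.mod(j0 + oj, resolution)),
                  stamp)
    peak = img.max()
    if peak > 0:
        img /= peak
    return img


def orientation_agreement(field, state, resolution: int = 256,
                          splat_radius: float = 0.004,
                          smoothing_scale: float = 4.0,
                          tolerance: float = 0.15):
    """Fraction of image cells where a rendered pattern matches a field.

    Renders the particle state, re-estimates the local ridge orientation via
    the structure tensor, and compares it (mod π) with the input field at the
    cell centers, over the estimator's valid mask.  The operational check
    that simulated particles align along the lines of smallest stress.
    Returns (fraction_within_tolerance, angular_error_grid, estimate).
    """
    img = render_particles(state, resolution, splat_radius)
    est = estimate_orientation(img, smoothing_scale)
    pts = _cell_centers(resolution).reshape(-1, 2)
    ref = field.angle_at(pts).reshape(resolution, resolution)
    diff = np.mod(est.angles - ref, np.pi)
    diff = np.minimum(diff, np.pi - diff)
    valid = est.valid
    frac = float((diff[valid] <= tolerance).mean())
    return frac, np.where(valid, diff, np.nan), est
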