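"""Stress-field orientation: direction of smallest stress s(x) on [0,1)².

The epidermal stress field enters the particle model only through an
unoriented unit line field s(x) (defined mod π), its perpendicular l(x) and
the anisotropy tensor

    T(x) = chi s(x) ⊗ s(x) + l(x) ⊗ l(x),   chi in [0, 1].

Fields may be spatially homogeneous, generated by the singular points of a
quadratic differential (cores and deltas, the two singular-point types of
fingerprint orientation fields), piecewise homogeneous over rectangular
regions, or sampled on a regular angle grid loaded from CSV.

Angles are radians in [0, π), measured from the horizontal axis, so that
s = (cos θ, sin θ).  Arrays indexed [i, j] map to the domain point
((i+½)/n0, (j+½)/n1): axis 0 is x, axis 1 is y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "SingularPoint",
    "AngleGrid",
    "OrientationField",
    "HomogeneousField",
    "SingularField",
    "PiecewiseField",
    "SampledField",
    "FieldDomainError",
    "SingularPointError",
    "delta_orientation",
    "core_orientation",
    "composite_orientation",
    "frame_at",
    "tensor_at",
    "grid_lookup",
    "fill_missing_orientations",
]


class FieldDomainError(ValueError):
    """Evaluation at a masked or undefined field location."""


class SingularPointError(ValueError):
    """Evaluation exactly at a singular point of the field."""


def normalize_angle(theta):
    """Reduce angles to the line-field range [0, π)."""
    return np.mod(theta, np.pi)


@dataclass(frozen=True)
class SingularPoint:
    """A core (single line ending) or delta (three-line junction) at ``position``."""

    position: tuple
    kind: str  # "core" | "delta"

    def __post_init__(self) -> None:
        if self.kind not in ("core", "delta"):
            raise ValueError("kind must be 'core' or 'delta'")
        x, y = self.position
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError("singular point must lie in the unit square")


def _args(x, zeta):
    """Principal argument of x - zeta read as a complex number."""
    x = np.asarray(x, dtype=float)
    dx = x[..., 0] - zeta[0]
    dy = x[..., 1] - zeta[1]
    if np.any((dx == 0.0) & (dy == 0.0)):
        raise SingularPointError(f"evaluation at singular point {zeta}")
    return np.arctan2(dy, dx)


def delta_orientation(x, zeta):
    """Line angle of a delta (quadratic differential z dz² > 0): (−arg(x−ζ)/2) mod π."""
    return normalize_angle(-0.5 * _args(x, zeta))


def core_orientation(x, zeta):
    """Line angle of a core (dz²/z > 0): (+arg(x−ζ)/2) mod π."""
    return normalize_angle(0.5 * _args(x, zeta))


def composite_orientation(x, points: Sequence[SingularPoint]):
    """Line angle of the field φ(z) = Π(z−ζ_delta)/Π(z−ζ_core), φ dz² > 0.

    The positivity condition gives the additive rule
    θ = ½ (Σ_cores arg(x−ζ) − Σ_deltas arg(x−ζ)) mod π, which reduces to
    delta_orientation / core_orientation for a single singular point.
    """
    if not points:
        raise ValueError("need at least one singular point")
    x = np.asarray(x, dtype=float)
    total = np.zeros(x.shape[:-1])
    for p in points:
        a = _args(x, p.position)
        total = total + (a if p.kind == "core" else -a)
    return normalize_angle(0.5 * total)


@dataclass
class AngleGrid:
    """Sampled orientation angles over the unit square.

    ``angles[i, j]`` is the line angle (radians, [0, π)) at the cell center
    ((i+½)/rows, (j+½)/cols).  ``mask`` flags valid cells (all valid if None).
    """

    angles: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.angles = normalize_angle(np.asarray(self.angles, dtype=float))
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.angles.shape:
                raise ValueError("mask shape must equal angle shape")

    @property
    def shape(self):
        return self.angles.shape

    @property
    def valid(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.angles.shape, dtype=bool)
        return self.mask


def grid_lookup(grid: AngleGrid, x, mode: str = "bilinear"):
    """Angle of a sampled grid at point(s) x, periodic in both directions.

    ``nearest`` returns the closest valid cell's angle.  ``bilinear``
    interpolates the doubled-angle embedding (cos 2θ, sin 2θ) component-wise
    and halves the recovered argument, so averaging is wraparound-correct
    across the π seam.  Invalid cells contribute zero weight; a fully invalid
    neighborhood raises FieldDomainError.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    pts = np.atleast_2d(x)
    rows, cols = grid.shape
    valid = grid.valid
    fi = pts[:, 0] * rows - 0.5
    fj = pts[:, 1] * cols - 0.5
    if mode == "nearest":
        i = np.mod(np.round(fi).astype(int), rows)
        j = np.mod(np.round(fj).astype(int), cols)
        if grid.mask is not None and not np.all(valid[i, j]):
            bad = ~valid[i, j]
            i[bad], j[bad] = _nearest_valid(grid, pts[bad])
        out = grid.angles[i, j]
    elif mode == "bilinear":
        i0 = np.floor(fi).astype(int)
        j0 = np.floor(fj).astype(int)
        ti = fi - i0
        tj = fj - j0
        c2 = np.cos(2.0 * grid.angles)
        s2 = np.sin(2.0 * grid.angles)
        num_c = np.zeros(len(pts))
        num_s = np.zeros(len(pts))
        wtot = np.zeros(len(pts))
        for di, dj, w in (
            (0, 0, (1 - ti) * (1 - tj)),
            (1, 0, ti * (1 - tj)),
            (0, 1, (1 - ti) * tj),
            (1, 1, ti * tj),
        ):
            ii = np.mod(i0 + di, rows)
            jj = np.mod(j0 + dj, cols)
            wv = w * valid[ii, jj]
            num_c += wv * c2[ii, jj]
            num_s += wv * s2[ii, jj]
            wtot += wv
        dead = wtot <= 0.0
        if np.any(dead):
            raise FieldDomainError("all-invalid bilinear neighborhood")
        out = normalize_angle(0.5 * np.arctan2(num_s, num_c))
    else:
        raise ValueError("mode must be 'nearest' or 'bilinear'")
    return out[0] if scalar else out


def _nearest_valid(grid: AngleGrid, pts):
    """Indices of the nearest valid cell for each point (brute force)."""
    rows, cols = grid.shape
    vi, vj = np.nonzero(grid.valid)
    if len(vi) == 0:
        raise FieldDomainError("grid has no valid cells")
    cx = (vi + 0.5) / rows
    cy = (vj + 0.5) / cols
    dx = pts[:, 0:1] - cx[None, :]
    dy = pts[:, 1:2] - cy[None, :]
    dx -= np.floor(dx + 0.5)
    dy -= np.floor(dy + 0.5)
    k = np.argmin(dx * dx + dy * dy, axis=1)
    return vi[k], vj[k]


def fill_missing_orientations(grid: AngleGrid) -> AngleGrid:
    """Fill masked cells by harmonic extension of the doubled-angle embedding.

    Solves the discrete Laplace equation (4-neighbor stencil, Neumann edges)
    for (cos 2θ, sin 2θ) on the invalid cells with valid cells as Dirichlet
    data, then recovers θ.  Valid cells are returned unchanged.
    """
    valid = grid.valid
    if not valid.any():
        raise FieldDomainError("cannot fill a grid with no valid cells")
    if valid.all():
        return AngleGrid(grid.angles.copy(), np.ones(grid.shape, dtype=bool))
    rows, cols = grid.shape
    c2 = np.cos(2.0 * grid.angles)
    s2 = np.sin(2.0 * grid.angles)
    unknown = ~valid
    idx = -np.ones(grid.shape, dtype=int)
    idx[unknown] = np.arange(unknown.sum())
    n = unknown.sum()
    A = sp.lil_matrix((n, n))
    b_c = np.zeros(n)
    b_s = np.zeros(n)
    ui, uj = np.nonzero(unknown)
    for k, (i, j) in enumerate(zip(ui, uj)):
        deg = 0
        for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if not (0 <= ni < rows and 0 <= nj < cols):
                continue  # Neumann: absent neighbor drops out
            deg += 1
            if valid[ni, nj]:
                b_c[k] += c2[ni, nj]
                b_s[k] += s2[ni, nj]
            else:
                A[k, idx[ni, nj]] = -1.0
        A[k, k] = deg
    A = A.tocsr()
    xc = spla.spsolve(A, b_c)
    xs = spla.spsolve(A, b_s)
    angles = grid.angles.copy()
    angles[unknown] = normalize_angle(0.5 * np.arctan2(xs[idx[unknown]], xc[idx[unknown]]))
    return AngleGrid(angles, np.ones(grid.shape, dtype=bool))


# ---------------------------------------------------------------------------
# field representations


class OrientationField:
    """Base class: a line field θ(x) with anisotropy parameter chi."""

    def __init__(self, chi: float = 0.2) -> None:
        if not 0.0 <= chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")
        self.chi = chi

    def angle_at(self, x):
        """Line angle(s) in [0, π) at point(s) x; vectorized."""
        raise NotImplementedError


class HomogeneousField(OrientationField):
    """Spatially constant orientation θ0."""

    def __init__(self, theta0: float, chi: float = 0.2) -> None:
        super().__init__(chi)
        self.theta0 = float(normalize_angle(theta0))

    def angle_at(self, x):
        x = np.asarray(x, dtype=float)
        return np.full(x.shape[:-1], self.theta0)


class SingularField(OrientationField):
    """Field generated by core/delta singular points of a quadratic differential."""

    def __init__(self, points: Sequence[SingularPoint], chi: float = 0.2) -> None:
        super().__init__(chi)
        self.points = list(points)

    def angle_at(self, x):
        return composite_orientation(x, self.points)


class PiecewiseField(OrientationField):
    """Piecewise-homogeneous field over axis-aligned rectangular regions.

    ``regions`` is a list of ((x0, x1, y0, y1), theta) entries scanned in
    order; the first containing rectangle wins, and a fallback angle applies
    where no region matches.
    """

    def __init__(self, regions, fallback: float = 0.0, chi: float = 0.2) -> None:
        super().__init__(chi)
        self.regions = [((float(a), float(b), float(c), float(d)),
                         float(normalize_angle(t)))
                        for (a, b, c, d), t in regions]
        self.fallback = float(normalize_angle(fallback))

    def angle_at(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape[:-1], self.fallback)
        unset = np.ones(x.shape[:-1], dtype=bool)
        for (x0, x1, y0, y1), theta in self.regions:
            inside = ((x[..., 0] >= x0) & (x[..., 0] < x1)
                      & (x[..., 1] >= y0) & (x[..., 1] < y1) & unset)
            out[inside] = theta
            unset &= ~inside
        return out


class SampledField(OrientationField):
    """Field evaluated from an AngleGrid by nearest or bilinear lookup."""

    def __init__(self, grid: AngleGrid, mode: str = "bilinear",
                 chi: float = 0.2) -> None:
        super().__init__(chi)
        self.grid = grid
        self.mode = mode

    def angle_at(self, x):
        return grid_lookup(self.grid, x, self.mode)


def frame_at(field: OrientationField, x):
    """Orthonormal frame (s, l) at x: s = (cos θ, sin θ), l = s rotated +π/2.

    Vectorized: for x of shape (N, 2) returns two (N, 2) arrays.
    """
    theta = field.angle_at(x)
    c, s = np.cos(theta), np.sin(theta)
    s_vec = np.stack([c, s], axis=-1)
    l_vec = np.stack([-s, c], axis=-1)
    return s_vec, l_vec


def tensor_at(field: OrientationField, x):
    """Stress tensor T(x) = chi s⊗s + l⊗l; eigenpairs (chi, s) and (1, l)."""
    s_vec, l_vec = frame_at(field, x)
    return (field.chi * s_vec[..., :, None] * s_vec[..., None, :]
            + l_vec[..., :, None] * l_vec[..., None, :])
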