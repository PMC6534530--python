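"""Time integration of the interacting-particle system on the unit torus.

N particles x_j ∈ [0,1)² evolve by

    dx_j/dt = (1/N) Σ_{k≠j} F(x_j − x_k, T(x_j)),

with displacements taken in the minimum-image convention (componentwise in
[−0.5, 0.5)) and forces hard-truncated at the model cutoff.  A brute-force
O(N²) right-hand side serves as the reference; a cell-list variant searches
only the 3×3 periodic cell neighborhood and must agree to rounding error.
Integrators: explicit Euler (default, Δt = 0.2) and fixed-step
Dormand–Prince 5(4).  Stationarity is monitored by the statistic
τ = Σ_j ‖x_j(t+Δt) − x_j(t)‖_1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .force_models import ForceModel, axis_coefficients
from .orientation_fields import OrientationField, frame_at

__all__ = [
    "ParticleState",
    "SimConfig",
    "CellGrid",
    "min_image_displacement",
    "rhs_velocities",
    "rhs_velocities_celllist",
    "step",
    "integrate",
    "tau_metric",
    "uniform_random_init",
    "circle_init",
]


def wrap(x):
    """Map coordinates to the half-open fundamental domain [0, 1)."""
    return np.mod(x, 1.0)


@dataclass
class ParticleState:
    """Positions of N particles on the torus at a simulation time."""

    positions: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = wrap(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if len(self.positions) < 1:
            raise ValueError("need at least one particle")

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class SimConfig:
    """Integration settings.

    With ``adaptive`` set, explicit Euler steps use
    dt_k = min(dt, max_move / max_j |v_j|, 1/lambda): ``dt`` becomes a
    step-size cap, ``max_move`` bounds the per-step particle displacement,
    and lambda is a cheap force-sum Jacobian bound keeping the step inside
    the Euler stability region.  Steady states are fixed points of the
    Euler map for any step size, so this mode reaches stationary patterns
    of the (very slow) dynamics in far fewer steps; transients are then
    not time-accurate.  ``t_end`` optionally stops the run once simulated
    time reaches it.
    """

    dt: float = 0.2
    n_steps: int = 2000
    integrator: str = "euler"  # "euler" | "rk_dopri"
    seed: int = 0
    snapshot_every: int = 0  # 0: keep only initial and final states
    converge_tol: Optional[float] = None  # stop when tau drops below this
    adaptive: bool = False
    max_move: float = 0.002
    t_end: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if self.integrator not in ("euler", "rk_dopri"):
            raise ValueError("integrator must be 'euler' or 'rk_dopri'")
        if self.adaptive and self.integrator != "euler":
            raise ValueError("adaptive stepping is Euler-only")
        if self.max_move <= 0:
            raise ValueError("max_move must be positive")


@dataclass
class CellGrid:
    """Uniform spatial hash; cell edge 1/cells_per_side must cover the cutoff."""

    cells_per_side: int

    def __post_init__(self) -> None:
        if self.cells_per_side < 1:
            raise ValueError("cells_per_side must be >= 1")

    @classmethod
    def for_model(cls, model: ForceModel) -> "CellGrid":
        """Largest grid whose cell edge still covers the effective force range."""
        return cls(max(1, int(np.floor(1.0 / model.effective_range))))

    def cell_index(self, positions) -> np.ndarray:
        m = self.cells_per_side
        ij = np.floor(positions * m).astype(int)
        ij = np.clip(ij, 0, m - 1)
        return ij[:, 0] * m + ij[:, 1]


def min_image_displacement(a, b):
    """Shortest torus displacement a − b, componentwise in [−0.5, 0.5)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return d - np.floor(d + 0.5)


def _pair_velocity_sum(disp, s_vec, l_vec, model: ForceModel,
                       stiffness: Optional[list] = None):
    """Sum of forces over the trailing pair axis.

    disp: (N, M, 2) displacements x_j − x_k (already minimum-image);
    s_vec, l_vec: (N, 2) frames at x_j.  Returns (N, 2) force sums.
    Self-pairs (zero displacement) contribute nothing since F(0) = 0.
    If ``stiffness`` is a list, appends max_j Σ_k (|f_s| + |f_l|), a cheap
    bound on the force-sum Jacobian used for adaptive step-size control.
    """
    n = disp.shape[0]
    ds = model.eta * disp
    r = np.hypot(ds[..., 0], ds[..., 1])
    inside = (r > 0.0) & (r < model.cutoff_radius)
    i_idx, _ = np.nonzero(inside)
    dsm = ds[inside]
    f_s, f_l = axis_coefficients(model, r[inside])
    si, li = s_vec[i_idx], l_vec[i_idx]
    ps = f_s * (dsm * si).sum(axis=1)
    pl = f_l * (dsm * li).sum(axis=1)
    contrib = ps[:, None] * si + pl[:, None] * li
    out = np.empty((n, 2))
    out[:, 0] = np.bincount(i_idx, weights=contrib[:, 0], minlength=n)
    out[:, 1] = np.bincount(i_idx, weights=contrib[:, 1], minlength=n)
    if stiffness is not None:
        w = np.bincount(i_idx, weights=np.abs(f_s) + np.abs(f_l), minlength=n)
        stiffness.append(float(w.max()) if len(w) else 0.0)
    return out


def rhs_velocities(state: ParticleState, field: OrientationField,
                   model: ForceModel,
                   stiffness: Optional[list] = None) -> np.ndarray:
    """Velocities (1/N) Σ_{k≠j} F(d_jk, T(x_j)); brute-force O(N²) reference."""
    x = state.positions
    n = state.n
    if n < 2:
        if stiffness is not None:
            stiffness.append(0.0)
        return np.zeros_like(x)
    disp = min_image_displacement(x[:, None, :], x[None, :, :])
    s_vec, l_vec = frame_at(field, x)
    return _pair_velocity_sum(disp, s_vec, l_vec, model, stiffness) / n


def rhs_velocities_celllist(state: ParticleState, field: OrientationField,
                            model: ForceModel,
                            grid: Optional[CellGrid] = None,
                            stiffness: Optional[list] = None) -> np.ndarray:
    """Cell-list right-hand side; identical contract to :func:`rhs_velocities`.

    Only particles in the same or one of the 8 periodically-adjacent cells
    are examined, valid because the cell edge is at least the effective
    force range cutoff_radius / eta.  Backed by a compiled kernel; the
    vectorized numpy path stays as the reference implementation and the two
    agree to rounding error.
    """
    from ._kernels import allpairs_rhs, cell_rhs, pack_model
    if grid is None:
        grid = CellGrid.for_model(model)
    m = grid.cells_per_side
    if 1.0 / m < model.effective_range - 1e-12:
        raise ValueError("cell edge smaller than the effective force range")
    x = np.ascontiguousarray(state.positions)
    n = state.n
    if n < 2:
        if stiffness is not None:
            stiffness.append(0.0)
        return np.zeros_like(x)
    s_all, l_all = frame_at(field, x)
    s_all = np.ascontiguousarray(s_all)
    l_all = np.ascontiguousarray(l_all)
    code, par = pack_model(model)
    if m < 3:  # every cell is its own neighbor: plain pair loop
        v, wmax = allpairs_rhs(x, s_all, l_all, model.eta,
                               model.cutoff_radius, code, par)
    else:
        ij = np.clip(np.floor(x * m).astype(np.int64), 0, m - 1)
        cell = ij[:, 0] * m + ij[:, 1]
        order = np.argsort(cell, kind="stable")
        starts = np.zeros(m * m + 1, dtype=np.int64)
        starts[1:] = np.cumsum(np.bincount(cell, minlength=m * m))
        v, wmax = cell_rhs(x, s_all, l_all, model.eta, model.cutoff_radius,
                           code, par, order, starts,
                           np.ascontiguousarray(ij[:, 0]),
                           np.ascontiguousarray(ij[:, 1]), m)
    if stiffness is not None:
        stiffness.append(float(wmax))
    return v / n


def _rhs_celllist_numpy(state: ParticleState, field: OrientationField,
                        model: ForceModel,
                        grid: Optional[CellGrid] = None,
                        stiffness: Optional[list] = None) -> np.ndarray:
    """Pure-numpy cell-list right-hand side (padded neighbor table).

    Kept as an independent reference for the compiled kernel.
    """
    if grid is None:
        grid = CellGrid.for_model(model)
    m = grid.cells_per_side
    if 1.0 / m < model.effective_range - 1e-12:
        raise ValueError("cell edge smaller than the effective force range")
    x = state.positions
    n = state.n
    v = np.zeros_like(x)
    if n < 2:
        if stiffness is not None:
            stiffness.append(0.0)
        return v
    if m < 3:
        return rhs_velocities(state, field, model, stiffness)
    s_all, l_all = frame_at(field, x)
    cell = grid.cell_index(x)
    order = np.argsort(cell, kind="stable")
    counts = np.bincount(cell, minlength=m * m)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    kmax = int(counts.max())
    members = np.full((m * m, kmax), -1, dtype=int)
    rank = np.arange(n) - starts[cell[order]]
    members[cell[order], rank] = order
    ci, cj = cell // m, cell % m
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    neigh_cells = np.stack([((ci + di) % m) * m + (cj + dj) % m
                            for di, dj in offsets], axis=1)
    cand = members[neigh_cells].reshape(n, -1)
    present = cand >= 0
    cand = np.where(present, cand, 0)
    disp = min_image_displacement(x[:, None, :], x[cand])
    ds = model.eta * disp
    r = np.hypot(ds[..., 0], ds[..., 1])
    inside = present & (r > 0.0) & (r < model.cutoff_radius)
    i_idx, _ = np.nonzero(inside)
    dsm = ds[inside]
    f_s, f_l = axis_coefficients(model, r[inside])
    si, li = s_all[i_idx], l_all[i_idx]
    ps = f_s * (dsm * si).sum(axis=1)
    pl = f_l * (dsm * li).sum(axis=1)
    contrib = ps[:, None] * si + pl[:, None] * li
    v[:, 0] = np.bincount(i_idx, weights=contrib[:, 0], minlength=n)
    v[:, 1] = np.bincount(i_idx, weights=contrib[:, 1], minlength=n)
    if stiffness is not None:
        w = np.bincount(i_idx, weights=np.abs(f_s) + np.abs(f_l), minlength=n)
        stiffness.append(float(w.max()) if len(w) else 0.0)
    return v / n


# Dormand-Prince 5(4) tableau; the 5th-order weights are used for the update.
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = [
    [],
    [1 / 5],
    [3 / 40, 9 / 40],
    [44 / 45, -56 / 15, 32 / 9],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
]
_DP_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])


def step(state: ParticleState, field: OrientationField, model: ForceModel,
         cfg: SimConfig, use_celllist: bool = False,
         grid: Optional[CellGrid] = None) -> ParticleState:
    """Advance one time step of size cfg.dt and wrap onto the torus."""
    rhs = (lambda s: rhs_velocities_celllist(s, field, model, grid)) \
        if use_celllist else (lambda s: rhs_velocities(s, field, model))
    x = state.positions
    dt = cfg.dt
    if cfg.integrator == "euler":
        if cfg.adaptive:
            stiff: list = []
            v = (rhs_velocities_celllist(state, field, model, grid, stiff)
                 if use_celllist else
                 rhs_velocities(state, field, model, stiff))
            vmax = float(np.abs(v).max())
            if vmax > 0:
                dt = min(dt, cfg.max_move / vmax)
            # keep dt inside the Euler stability region: the row-sum bound
            # lambda ~ 4 * max_j sum_k (|f_s|+|f_l|) / N over-estimates the
            # Jacobian, so dt <= 1/lambda leaves a comfortable margin
            lam = 4.0 * stiff[0] / state.n if stiff and stiff[0] > 0 else 0.0
            if lam > 0:
                dt = min(dt, 1.0 / lam)
            xn = x + dt * v
        else:
            xn = x + dt * rhs(state)
    else:  # fixed-step Dormand-Prince 5(4), 5th-order solution
        ks = []
        for i in range(7):
            xi = x.copy()
            for a, k in zip(_DP_A[i], ks):
                xi = xi + dt * a * k
            ks.append(rhs(ParticleState(xi, state.time + _DP_C[i] * dt)))
        xn = x + dt * sum(b * k for b, k in zip(_DP_B, ks))
    return ParticleState(wrap(xn), state.time + dt)


def tau_metric(prev: ParticleState, next_: ParticleState) -> float:
    """τ = Σ_j ‖x_j(t+Δt) − x_j(t)‖_1 with minimum-image displacements.

    Seam crossings (0.999 → 0.001) therefore count by their short torus
    distance, keeping the convergence statistic free of wrap spikes.
    """
    if prev.n != next_.n:
        raise ValueError("snapshots have different particle counts")
    d = min_image_displacement(next_.positions, prev.positions)
    return float(np.abs(d).sum())


def integrate(init: ParticleState, field: OrientationField, model: ForceModel,
              cfg: SimConfig, use_celllist: bool = False,
              tau_out: Optional[list] = None,
              ) -> Tuple[List[ParticleState], ParticleState]:
    """Run up to cfg.n_steps steps, stopping early once τ < converge_tol.

    Returns (snapshots, final_state); snapshots always include the initial
    state and, if snapshot_every > 0, every snapshot_every-th step.
    If ``tau_out`` is a list, the per-step τ values are appended to it.
    Deterministic for a given initial state and config.
    """
    grid = CellGrid.for_model(model) if use_celllist else None
    snapshots = [init]
    state = init
    for k in range(1, cfg.n_steps + 1):
        new = step(state, field, model, cfg, use_celllist, grid)
        tau = tau_metric(state, new)
        if tau_out is not None:
            tau_out.append(tau)
        state = new
        if cfg.snapshot_every and k % cfg.snapshot_every == 0:
            snapshots.append(state)
        if cfg.converge_tol is not None and tau < cfg.converge_tol:
            break
        if cfg.t_end is not None and state.time >= cfg.t_end:
            break
    if snapshots[-1] is not state:
        snapshots.append(state)
    return snapshots, state


def uniform_random_init(n: int, seed: int) -> ParticleState:
    """N particles uniformly distributed on the torus, reproducible from seed."""
    if n < 1:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(seed)
    return ParticleState(rng.random((n, 2)), 0.0)


def circle_init(n: int, center=(0.5, 0.5), radius: float = 0.005) -> ParticleState:
    """N particles equiangularly distributed on a circle, wrapped to the torus."""
    if n < 1:
        raise ValueError("need at least one particle")
    phi = 2.0 * np.pi * np.arange(n) / n
    pts = np.asarray(center, dtype=float) + radius * np.stack(
        [np.cos(phi), np.sin(phi)], axis=1)
    return ParticleState(wrap(pts), 0.0)
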