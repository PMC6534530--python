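"""Numba-compiled pair-interaction kernels.

The compiled cell-list kernel is the production right-hand side for large
runs; the vectorized numpy implementations in :mod:`dynamics` remain the
reference path, and the test suite asserts agreement between the two to
1e-12 per component.  Coefficient formulas are duplicated here in scalar
form — any change to :mod:`force_models` must be mirrored.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .force_models import (ForceModel, KCParams, OscillatorParams,
                           PiecewiseParams, _kc_mix)

# family codes for the jit dispatch
KC = 0
PIECEWISE = 1
OSCILLATOR = 2


def pack_model(model: ForceModel):
    """Encode a ForceModel as (code, float-parameter vector) for the kernel."""
    p = model.params
    if isinstance(p, OscillatorParams):
        par = np.array([p.c, p.c_s, p.c_l, p.e_s1, p.e_s2, p.e_l1, p.e_l2,
                        p.a_s, p.a_l])
        return OSCILLATOR, par
    if isinstance(p, PiecewiseParams):
        b = p.base
        fc1 = float(_kc_mix(p.c1, b, 1.0))
        fc2 = float(_kc_mix(p.c2, b, 1.0))
        par = np.array([b.alpha, b.beta, b.gamma, b.e_A, b.e_R, b.chi,
                        p.c1, p.c2, fc1, fc2])
        return PIECEWISE, par
    assert isinstance(p, KCParams)
    # attraction prefactors along s and l (delta_scale folded in; the
    # adapted family fixes the l prefactor at 0.3 and keeps chi along s)
    if model.family == "kc_adapted":
        a_s, a_l = p.chi, 0.3
    else:
        a_s, a_l = p.chi * p.delta_scale, p.delta_scale
    par = np.array([p.alpha, p.beta, p.gamma, p.e_A, p.e_R, a_s, a_l])
    return KC, par


@njit(cache=False, inline="always")
def _coeffs(code, par, r):
    """Scalar (f_s, f_l) before cutoff; must mirror axis_coefficients."""
    if code == KC:
        alpha, beta, gamma, e_a, e_r, a_s, a_l = (par[0], par[1], par[2],
                                                  par[3], par[4], par[5],
                                                  par[6])
        fr = (alpha * r * r + beta) * np.exp(-e_r * r)
        fa = -gamma * r * np.exp(-e_a * r)
        return a_s * fa + fr, a_l * fa + fr
    if code == PIECEWISE:
        alpha, beta, gamma, e_a, e_r, chi = (par[0], par[1], par[2], par[3],
                                             par[4], par[5])
        c1, c2, fc1, fc2 = par[6], par[7], par[8], par[9]
        fr = (alpha * r * r + beta) * np.exp(-e_r * r)
        fa = -gamma * r * np.exp(-e_a * r)
        f_s = chi * fa + fr
        f1 = fa + fr
        if r < c1:
            f_l = f1
        elif r > c2:
            f_l = -f1
        else:
            f_l = fc1 + (r - c1) / (c2 - c1) * (-fc2 - fc1)
        return f_s, f_l
    # oscillator
    c, c_s, c_l, e_s1, e_s2, e_l1, e_l2, a_s, a_l = (
        par[0], par[1], par[2], par[3], par[4], par[5], par[6], par[7], par[8])
    f_s = c * np.exp(e_s1 * r) + c_s * np.sin(np.pi * r / a_s) * np.exp(e_s2 * r)
    f_l = (c * np.cos(np.pi * r / a_l) * np.exp(e_l1 * r)
           + c_l * np.sin(np.pi * r / a_l) * np.exp(e_l2 * r))
    return f_s, f_l


@njit(cache=False)
def cell_rhs(x, s_vec, l_vec, eta, cutoff, code, par,
             order, starts, cell_i, cell_j, m):
    """Cell-list force sums with periodic 3x3 neighborhood search.

    order/starts: particles sorted by cell index with CSR-style offsets.
    Returns (velocities*N, max_j sum_k |f_s|+|f_l|).
    """
    n = x.shape[0]
    v = np.zeros((n, 2))
    wmax = 0.0
    for j in range(n):
        ci = cell_i[j]
        cj = cell_j[j]
        wj = 0.0
        for di in range(-1, 2):
            for dj in range(-1, 2):
                c = ((ci + di) % m) * m + (cj + dj) % m
                for idx in range(starts[c], starts[c + 1]):
                    k = order[idx]
                    if k == j:
                        continue
                    dx = x[j, 0] - x[k, 0]
                    dx -= np.floor(dx + 0.5)
                    dy = x[j, 1] - x[k, 1]
                    dy -= np.floor(dy + 0.5)
                    dxs = eta * dx
                    dys = eta * dy
                    r = np.sqrt(dxs * dxs + dys * dys)
                    if r <= 0.0 or r >= cutoff:
                        continue
                    f_s, f_l = _coeffs(code, par, r)
                    ps = s_vec[j, 0] * dxs + s_vec[j, 1] * dys
                    pl = l_vec[j, 0] * dxs + l_vec[j, 1] * dys
                    v[j, 0] += f_s * ps * s_vec[j, 0] + f_l * pl * l_vec[j, 0]
                    v[j, 1] += f_s * ps * s_vec[j, 1] + f_l * pl * l_vec[j, 1]
                    wj += abs(f_s) + abs(f_l)
        if wj > wmax:
            wmax = wj
    return v, wmax


@njit(cache=False)
def allpairs_rhs(x, s_vec, l_vec, eta, cutoff, code, par):
    """All-pairs force sums; used when the cutoff spans most of the torus."""
    n = x.shape[0]
    v = np.zeros((n, 2))
    wmax = 0.0
    for j in range(n):
        wj = 0.0
        for k in range(n):
            if k == j:
                continue
            dx = x[j, 0] - x[k, 0]
            dx -= np.floor(dx + 0.5)
            dy = x[j, 1] - x[k, 1]
            dy -= np.floor(dy + 0.5)
            dxs = eta * dx
            dys = eta * dy
            r = np.sqrt(dxs * dxs + dys * dys)
            if r <= 0.0 or r >= cutoff:
                continue
            f_s, f_l = _coeffs(code, par, r)
            ps = s_vec[j, 0] * dxs + s_vec[j, 1] * dys
            pl = l_vec[j, 0] * dxs + l_vec[j, 1] * dys
            v[j, 0] += f_s * ps * s_vec[j, 0] + f_l * pl * l_vec[j, 0]
            v[j, 1] += f_s * ps * s_vec[j, 1] + f_l * pl * l_vec[j, 1]
            wj += abs(f_s) + abs(f_l)
        if wj > wmax:
            wmax = wj
    return v, wmax
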