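"""Anisotropic pair-interaction forces between Merkel cells.

The force a cell at ``x_k`` exerts on a cell at ``x_j`` acts along the local
frame of the epidermal stress field,

    F(d, T(x_j)) = f_s(|d|) (s·d) s + f_l(|d|) (l·d) l,

where ``d = x_j - x_k``, ``s`` is the unit direction of smallest stress and
``l`` the perpendicular direction of largest stress.  Several coefficient
families are provided:

* ``kc_original`` / ``kc_reparam`` — the Kücken–Champod exponential
  repulsion/attraction kernels, f_s = χ·δ·f_A + f_R and f_l = δ·f_A + f_R
  (δ a global attraction scale, 1 by default);
* ``kc_adapted`` — the same kernels with the attraction along l damped by a
  fixed factor 0.3 (f_l = 0.3 f_A + f_R) while f_s keeps χ f_A + f_R;
* ``piecewise`` — f_l sign-flipped beyond an outer cutoff c2 with a linear
  bridge on [c1, c2], making the long-range tail attractive;
* ``oscillator`` — damped-harmonic-oscillator ansatz coefficients.

All families are hard-truncated: every force component is exactly zero for
separations at or beyond ``cutoff_radius``.  A rescaling factor ``eta``
evaluates the force at ``eta * d`` (coefficients AND projections), shrinking
the stationary ridge spacing for eta > 1 and enlarging it for eta < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KCParams",
    "OscillatorParams",
    "PiecewiseParams",
    "ForceModel",
    "PRESETS",
    "make_preset",
    "repulsion_coefficient",
    "attraction_coefficient",
    "oscillator_coefficients",
    "piecewise_coefficients",
    "axis_coefficients",
    "pair_force",
]

FAMILIES = ("kc_original", "kc_adapted", "kc_reparam", "piecewise", "oscillator")


class ForceConfigError(ValueError):
    """Raised for inconsistent force-model configuration."""


@dataclass(frozen=True)
class KCParams:
    """Parameters of the exponential repulsion/attraction kernels.

    f_R(r) = (alpha r^2 + beta) exp(-e_R r)   (repulsion, >= 0)
    f_A(r) = -gamma r exp(-e_A r)             (attraction, <= 0)

    ``chi`` in [0, 1] sets the anisotropy of the stress tensor; ``delta_scale``
    multiplies the attraction kernel globally (the delta-sweep dial).
    """

    alpha: float = 270.0
    beta: float = 0.1
    gamma: float = 35.0
    e_A: float = 95.0
    e_R: float = 100.0
    chi: float = 0.2
    delta_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "e_A", "e_R"):
            if getattr(self, name) < 0:
                raise ForceConfigError(f"{name} must be nonnegative")
        if not 0.0 <= self.chi <= 1.0:
            raise ForceConfigError("chi must lie in [0, 1]")
        if not 0.0 <= self.delta_scale <= 1.0:
            raise ForceConfigError("delta_scale must lie in [0, 1]")


@dataclass(frozen=True)
class OscillatorParams:
    """Damped-harmonic-oscillator coefficient parameters.

    f_s(r) = c exp(e_s1 r) + c_s sin(pi r / a_s) exp(e_s2 r)
    f_l(r) = c cos(pi r / a_l) exp(e_l1 r) + c_l sin(pi r / a_l) exp(e_l2 r)
    """

    c: float = 0.1
    c_s: float = -0.05
    c_l: float = 0.005
    e_s1: float = -65.0
    e_s2: float = -100.0
    e_l1: float = -160.0
    e_l2: float = -40.0
    a_s: float = 0.03
    a_l: float = 0.022

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ForceConfigError("c must be positive")
        if not (abs(self.c) > abs(self.c_s) and abs(self.c) > abs(self.c_l)):
            raise ForceConfigError("|c| must dominate |c_s| and |c_l|")
        if not (self.e_s1 < 0 and self.e_s2 < 0 and self.e_l1 < 0 and self.e_l2 < 0):
            raise ForceConfigError("decay rates must be negative")
        if not (self.a_s > 0 and self.a_l > 0):
            raise ForceConfigError("oscillation half-periods must be positive")


@dataclass(frozen=True)
class PiecewiseParams:
    """KC kernels with the l-coefficient sign-flipped beyond c2.

    f_l = f(r, 1) below c1, -f(r, 1) above c2, linearly bridged on [c1, c2],
    where f(r, chi) = chi f_A(r) + f_R(r).  f_s = f(r, chi) throughout.
    """

    base: KCParams = field(default_factory=KCParams)
    c1: float = 0.06
    c2: float = 0.07

    def __post_init__(self) -> None:
        if not 0.0 < self.c1 < self.c2:
            raise ForceConfigError("need 0 < c1 < c2")


@dataclass(frozen=True)
class ForceModel:
    """A named coefficient family with its cutoff and rescaling factor."""

    family: str = "kc_original"
    params: object = field(default_factory=KCParams)
    cutoff_radius: float = 0.5
    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ForceConfigError(f"unknown force family {self.family!r}")
        expected = OscillatorParams if self.family == "oscillator" else (
            PiecewiseParams if self.family == "piecewise" else KCParams
        )
        if not isinstance(self.params, expected):
            raise ForceConfigError(
                f"family {self.family!r} requires {expected.__name__}, "
                f"got {type(self.params).__name__}"
            )
        if not 0.0 < self.cutoff_radius <= 0.5:
            raise ForceConfigError("cutoff_radius must lie in (0, 0.5]")
        if self.eta <= 0:
            raise ForceConfigError("eta must be positive")

    @property
    def chi(self) -> float:
        if isinstance(self.params, OscillatorParams):
            return 1.0
        p = self.params.base if isinstance(self.params, PiecewiseParams) else self.params
        return p.chi

    @property
    def effective_range(self) -> float:
        """Separation beyond which the force vanishes: cutoff_radius / eta."""
        return self.cutoff_radius / self.eta


# ---------------------------------------------------------------------------
# coefficient functions


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be nonnegative")
    return r


def repulsion_coefficient(r, p: KCParams):
    """f_R(r) = (alpha r^2 + beta) exp(-e_R r)."""
    r = _check_r(r)
    return (p.alpha * r * r + p.beta) * np.exp(-p.e_R * r)


def attraction_coefficient(r, p: KCParams):
    """f_A(r) = -gamma r exp(-e_A r); nonpositive everywhere."""
    r = _check_r(r)
    return -p.gamma * r * np.exp(-p.e_A * r)


def oscillator_coefficients(r, p: OscillatorParams):
    """Damped-oscillator coefficient pair (f_s, f_l) before cutoff."""
    r = _check_r(r)
    f_s = p.c * np.exp(p.e_s1 * r) + p.c_s * np.sin(np.pi * r / p.a_s) * np.exp(p.e_s2 * r)
    f_l = (p.c * np.cos(np.pi * r / p.a_l) * np.exp(p.e_l1 * r)
           + p.c_l * np.sin(np.pi * r / p.a_l) * np.exp(p.e_l2 * r))
    return f_s, f_l


def _kc_mix(r, p: KCParams, chi: float):
    """f(r, chi) = chi f_A(r) + f_R(r)."""
    return chi * attraction_coefficient(r, p) + repulsion_coefficient(r, p)


def piecewise_coefficients(r, p: PiecewiseParams):
    """Sign-flipped-tail coefficient pair (f_s, f_l) before cutoff."""
    r = _check_r(r)
    base = p.base
    f_s = _kc_mix(r, base, base.chi)
    f1 = _kc_mix(r, base, 1.0)
    fc1 = float(_kc_mix(p.c1, base, 1.0))
    fc2 = float(_kc_mix(p.c2, base, 1.0))
    bridge = fc1 + (r - p.c1) / (p.c2 - p.c1) * (-fc2 - fc1)
    f_l = np.where(r < p.c1, f1, np.where(r > p.c2, -f1, bridge))
    return f_s, f_l


def axis_coefficients(model: ForceModel, r):
    """Coefficient pair (f_s, f_l) of the assembled force at separation r.

    Dispatches on the model family and applies the hard cutoff last: both
    components are exactly zero for r >= cutoff_radius.  Vectorized in r.
    ``r`` is the separation at which the force is evaluated (already
    eta-scaled by the caller where applicable).
    """
    r = _check_r(r)
    p = model.params
    if model.family in ("kc_original", "kc_reparam"):
        fa = p.delta_scale * attraction_coefficient(r, p)
        fr = repulsion_coefficient(r, p)
        f_s = p.chi * fa + fr
        f_l = fa + fr
    elif model.family == "kc_adapted":
        fa = attraction_coefficient(r, p)
        fr = repulsion_coefficient(r, p)
        f_s = p.chi * fa + fr
        f_l = 0.3 * fa + fr
    elif model.family == "piecewise":
        f_s, f_l = piecewise_coefficients(r, p)
    elif model.family == "oscillator":
        f_s, f_l = oscillator_coefficients(r, p)
    else:  # pragma: no cover - guarded in __post_init__
        raise ForceConfigError(f"unknown force family {model.family!r}")
    inside = r < model.cutoff_radius
    return np.where(inside, f_s, 0.0), np.where(inside, f_l, 0.0)


def pair_force(d, s_vec, l_vec, model: ForceModel):
    """Force on the particle at x_j from one at x_k, d = x_j - x_k.

    Evaluates F(eta*d, T): coefficients at r = eta|d|, projections of eta*d
    onto the orthonormal local frame (s_vec, l_vec).  Returns the zero vector
    whenever eta|d| >= cutoff_radius.  Antisymmetric: F(-d) = -F(d).
    """
    d = np.asarray(d, dtype=float)
    s_vec = np.asarray(s_vec, dtype=float)
    l_vec = np.asarray(l_vec, dtype=float)
    if not (np.isclose(s_vec @ s_vec, 1.0, atol=1e-10)
            and np.isclose(l_vec @ l_vec, 1.0, atol=1e-10)
            and np.isclose(s_vec @ l_vec, 0.0, atol=1e-10)):
        raise ValueError("(s_vec, l_vec) must be an orthonormal frame")
    ds = model.eta * d
    r = float(np.hypot(ds[0], ds[1]))
    if r >= model.cutoff_radius:
        return np.zeros(2)
    f_s, f_l = axis_coefficients(model, r)
    return f_s * (s_vec @ ds) * s_vec + f_l * (l_vec @ ds) * l_vec


# ---------------------------------------------------------------------------
# named presets

_KC2012 = KCParams(alpha=270.0, beta=0.1, gamma=35.0, e_A=95.0, e_R=100.0, chi=0.2)
_KC_REPARAM = replace(_KC2012, gamma=10.5)

PRESETS = {
    "kc2012": ("kc_original", _KC2012),
    "kc-adapted": ("kc_adapted", _KC2012),
    "kc-reparam": ("kc_reparam", _KC_REPARAM),
    "piecewise": ("piecewise", PiecewiseParams(base=_KC_REPARAM, c1=0.06, c2=0.07)),
    "oscillator2014": ("oscillator", OscillatorParams()),
}


def make_preset(name: str, cutoff_radius: float = 0.5, eta: float = 1.0,
                **overrides) -> ForceModel:
    """Build a ForceModel from a named preset, optionally overriding params."""
    if name not in PRESETS:
        raise ForceConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    family, params = PRESETS[name]
    if overrides:
        if family == "piecewise":
            base_overrides = {k: v for k, v in overrides.items()
                              if k in KCParams.__dataclass_fields__}
            pw_overrides = {k: v for k, v in overrides.items() if k in ("c1", "c2")}
            unknown = set(overrides) - set(base_overrides) - set(pw_overrides)
            if unknown:
                raise ForceConfigError(f"unknown parameter overrides {sorted(unknown)}")
            params = replace(params, base=replace(params.base, **base_overrides),
                             **pw_overrides)
        else:
            params = replace(params, **overrides)
    return ForceModel(family=family, params=params,
                      cutoff_radius=cutoff_radius, eta=eta)
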