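"""Configuration files, snapshot CSVs, angle-grid CSVs and run manifests.

Text formats throughout: snapshots are CSV with columns
(time, particle_id, x, y) at full double precision; angle grids are CSV
matrices of radians with an optional companion {0,1} mask; manifests are
JSON and contain everything needed to reproduce a run bit-for-bit.
JSON is the canonical config format; YAML is accepted on input.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import ParticleState, SimConfig
from .force_models import (KCParams, OscillatorParams, PiecewiseParams,
                           ForceModel, PRESETS, make_preset)
from .orientation_fields import AngleGrid

__all__ = [
    "ConfigError",
    "load_config",
    "force_model_from_config",
    "sim_config_from_config",
    "write_snapshot",
    "read_snapshot",
    "write_angle_grid",
    "read_angle_grid",
    "write_manifest",
    "write_image_png",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


_FORCE_KEYS = {"family", "preset", "parameters", "cutoff_radius", "eta"}
_SIM_KEYS = {"dt", "n_steps", "integrator", "seed", "snapshot_every",
             "converge_tol"}
_TOP_KEYS = {"force", "simulation", "field"}

_PARAM_CLASSES = {
    "kc_original": KCParams,
    "kc_adapted": KCParams,
    "kc_reparam": KCParams,
    "piecewise": PiecewiseParams,
    "oscillator": OscillatorParams,
}


def load_config(path) -> dict:
    """Load and validate a JSON or YAML configuration file.

    Returns a dict with resolved ``force`` (a ForceModel) and ``simulation``
    (a SimConfig) entries plus the raw ``field`` section if present.
    Unknown keys are rejected with an error naming the offending key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    force = force_model_from_config(raw.get("force", {}))
    sim = sim_config_from_config(raw.get("simulation", {}))
    return {"force": force, "simulation": sim, "field": raw.get("field")}


def force_model_from_config(section: dict) -> ForceModel:
    """Build a ForceModel from a config section (preset or explicit parameters)."""
    unknown = set(section) - _FORCE_KEYS
    if unknown:
        raise ConfigError(f"unknown force config key(s): {sorted(unknown)}")
    cutoff = float(section.get("cutoff_radius", 0.5))
    eta = float(section.get("eta", 1.0))
    preset = section.get("preset")
    params = section.get("parameters")
    family = section.get("family")
    if preset is not None:
        if params is not None:
            raise ConfigError("give either 'preset' or explicit 'parameters', not both")
        if family is not None and family != PRESETS.get(preset, (None,))[0]:
            raise ConfigError(f"family {family!r} conflicts with preset {preset!r}")
        return make_preset(preset, cutoff_radius=cutoff, eta=eta)
    if family is None:
        family = "kc_original"
    cls = _PARAM_CLASSES.get(family)
    if cls is None:
        raise ConfigError(f"unknown force family {family!r}")
    params = dict(params or {})
    try:
        if cls is PiecewiseParams:
            base = KCParams(**{k: v for k, v in params.items()
                               if k not in ("c1", "c2")})
            p = PiecewiseParams(base=base,
                                **{k: v for k, v in params.items() if k in ("c1", "c2")})
        else:
            p = cls(**params)
    except TypeError as exc:
        raise ConfigError(f"bad force parameters: {exc}") from exc
    return ForceModel(family=family, params=p, cutoff_radius=cutoff, eta=eta)


def sim_config_from_config(section: dict) -> SimConfig:
    unknown = set(section) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
    return SimConfig(**section)


# ---------------------------------------------------------------------------
# snapshots


def write_snapshot(state: ParticleState, path) -> None:
    """CSV with header (time, particle_id, x, y), 17 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time,particle_id,x,y\n")
        for i, (x, y) in enumerate(state.positions):
            fh.write(f"{state.time:.17g},{i},{x:.17g},{y:.17g}\n")


def read_snapshot(path) -> ParticleState:
    """Read a snapshot CSV; out-of-domain coordinates are wrapped with a warning."""
    path = Path(path)
    times, pts = [], []
    with path.open() as fh:
        header = fh.readline().strip()
        if header.split(",") != ["time", "particle_id", "x", "y"]:
            raise ValueError(f"{path}: unexpected snapshot header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                t, _, x, y = (float(parts[0]), int(parts[1]),
                              float(parts[2]), float(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            times.append(t)
            pts.append((x, y))
    pts = np.asarray(pts, dtype=float)
    if np.any((pts < 0.0) | (pts >= 1.0)):
        warnings.warn("snapshot coordinates outside [0,1) were wrapped")
    return ParticleState(pts, times[0] if times else 0.0)


# ---------------------------------------------------------------------------
# angle grids


def write_angle_grid(grid: AngleGrid, path, mask_path=None) -> None:
    """Plain-text CSV matrix of radians; optional companion {0,1} mask CSV."""
    np.savetxt(path, grid.angles, delimiter=",", fmt="%.17g")
    if mask_path is not None:
        np.savetxt(mask_path, grid.valid.astype(int), delimiter=",", fmt="%d")


def read_angle_grid(path, mask_path=None) -> AngleGrid:
    angles = np.atleast_2d(np.loadtxt(path, delimiter=","))
    mask = None
    if mask_path is not None:
        mask = np.atleast_2d(np.loadtxt(mask_path, delimiter=",")).astype(bool)
    return AngleGrid(angles, mask)


# ---------------------------------------------------------------------------
# manifests and images


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path, *, force: ForceModel, sim: SimConfig, field_spec=None,
                   n_particles=None, tau_trace=None, extra=None) -> None:
    """JSON run manifest: full configuration echo sufficient for reproduction."""
    doc = {
        "ridgesim_version": __version__,
        "force": {"family": force.family, "cutoff_radius": force.cutoff_radius,
                  "eta": force.eta, "parameters": _jsonable(force.params)},
        "simulation": _jsonable(sim),
        "field": _jsonable(field_spec),
        "n_particles": n_particles,
        "tau_trace": _jsonable(tau_trace),
    }
    if extra:
        doc.update(_jsonable(extra))
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_image_png(pixels: np.ndarray, path) -> None:
    """8-bit grayscale PNG; transposed/flipped so x is horizontal, y points up."""
    import imageio.v3 as iio
    img = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    disp = np.flipud(img.T)  # axis0=x, axis1=y -> raster rows top-to-bottom
    iio.imwrite(Path(path), (disp * 255).astype(np.uint8))
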