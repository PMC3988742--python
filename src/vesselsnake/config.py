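"""Run configuration: one YAML document drives a whole reproducible run.

The document has fixed sections (phantom / io / gmm / scale / shape /
energy) with defaults; unknown keys anywhere are rejected with the offending
path named, and a resolved config round-trips losslessly.  All randomness in
a run flows from the single top-level ``seed``.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .evolution import EnergyParams
from .intensity_model import ScaleParams
from .phantoms import PhantomSpec
from .shape_prior import ProfileSampler

DEFAULTS = {
    "seed": 0,
    "baseline_mode": False,
    "phantom": {
        "shape": [128, 128],
        "geometry": "straight",
        "vessel_radius": 4.0,
        "bifurcation_angle": 60.0,
        "blob_radius": None,
        "blob_gap": 0.0,
        "intensity_background": 0.0,
        "intensity_vessel": 100.0,
        "intensity_blob": None,
        "noise_sigma": 25.0,
        "fade_to": 0.1,
        "n_modes": 1,
    },
    "io": {"image": None, "seed_mask": None, "truth": None, "outdir": None},
    "gmm": {"n_components": 3, "seed": None, "blood_index": None},
    "scale": {"min": 4.0, "max": 10.0, "tau": 1.0},
    "shape": {"R_factor": 2.0, "n_directions": 36, "interp_order": 1},
    "energy": {
        "lambda": 0.4,
        "mu": 0.2,
        "dt": 0.5,
        "max_iters": 500,
        "epsilon": 1.5,
        "convergence_tol": 1.0e-3,
        "reinit_every": 10,
        "force_clip": 10.0,
        "intensity_force": "pointwise",
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        here = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict):
            if val is None:
                continue
            if not isinstance(val, dict):
                raise ConfigError(f"config section {here!r} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


class RunConfig:
    """Resolved, validated configuration for one experiment run."""

    def __init__(self, data: dict = None):
        self.data = _merge(DEFAULTS, data or {})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        return cls(loaded)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.data, sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        canonical = json.dumps(self.data, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    # ---- typed views -----------------------------------------------------
    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def phantom_spec(self) -> PhantomSpec:
        p = self.data["phantom"]
        return PhantomSpec(
            shape=tuple(p["shape"]),
            geometry=p["geometry"],
            vessel_radius=p["vessel_radius"],
            bifurcation_angle=p["bifurcation_angle"],
            blob_radius=p["blob_radius"],
            blob_gap=p["blob_gap"],
            intensity_background=p["intensity_background"],
            intensity_vessel=p["intensity_vessel"],
            intensity_blob=p["intensity_blob"],
            noise_sigma=p["noise_sigma"],
            fade_to=p["fade_to"],
            n_modes=p["n_modes"],
            rng_seed=self.seed,
        )

    def scale_params(self) -> ScaleParams:
        s = self.data["scale"]
        return ScaleParams(min_scale=s["min"], max_scale=s["max"], tau=s["tau"])

    def energy_params(self) -> EnergyParams:
        e = self.data["energy"]
        baseline = bool(self.data["baseline_mode"])
        return EnergyParams(
            lambda_shape=0.0 if baseline else e["lambda"],
            mu_smooth=e["mu"],
            dt=e["dt"],
            max_iters=e["max_iters"],
            epsilon_heaviside=e["epsilon"],
            convergence_tol=e["convergence_tol"],
            reinit_every=e["reinit_every"],
            force_clip=e["force_clip"],
            intensity_force=e["intensity_force"],
            adaptive_scale=not baseline,
        )

    def sampler(self, max_vessel_radius: float = None) -> ProfileSampler:
        sh = self.data["shape"]
        if max_vessel_radius is None:
            max_vessel_radius = self.data["phantom"]["vessel_radius"]
        return ProfileSampler(
            R=sh["R_factor"] * max_vessel_radius,
            n_directions=sh["n_directions"],
            interp_order=sh["interp_order"],
        )

    def gmm_seed(self) -> int:
        g = self.data["gmm"]
        return self.seed if g["seed"] is None else int(g["seed"])
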