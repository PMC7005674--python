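"""Declarative run configuration for the simulator (YAML key/value, validated).

Example::

    seed: 7
    binding:
      on_rate: 0.1
      off_components: [[0.4, 0.3], [0.35, 3.0], [0.25, 12.0]]
    illumination: {t_on_ms: 100, t_off_ms: 0.3, n_frames: 1991}
    photophysics: {bleach_rate: 0.0}
    optics: {image_size: [128, 128], psf_sigma: 1.3, background_level: 100}
    movie: {n_molecules: 50, binder_emission: 3000, locator_emission: 2000}

Validation is performed by the dataclass invariants in :mod:`smtirfkit.simkit`;
unknown keys raise immediately so typos cannot silently change a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simkit import BindingModel, IlluminationScheme, OpticsModel, PhotophysicsModel

__all__ = ["SimulationConfig", "load_sim_config"]


@dataclass
class SimulationConfig:
    binding: BindingModel
    illumination: IlluminationScheme
    photophysics: PhotophysicsModel
    optics: OpticsModel
    n_molecules: int = 50
    binder_emission: float = 3000.0
    locator_emission: float = 2000.0
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _build(cls, section: dict, name: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise ValueError(f"invalid key in '{name}' section: {exc}") from exc


def load_sim_config(path: str | Path) -> SimulationConfig:
    """Load and validate a simulation configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"seed", "binding", "illumination", "photophysics", "optics", "movie"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    binding_raw = dict(raw.get("binding", {}))
    if "off_components" in binding_raw:
        binding_raw["off_components"] = tuple(tuple(c) for c in binding_raw["off_components"])
    optics_raw = dict(raw.get("optics", {}))
    if "image_size" in optics_raw:
        optics_raw["image_size"] = tuple(optics_raw["image_size"])
    if "drift_per_frame" in optics_raw:
        optics_raw["drift_per_frame"] = tuple(optics_raw["drift_per_frame"])
    if "channel_transform" in optics_raw:
        optics_raw["channel_transform"] = tuple(tuple(r) for r in optics_raw["channel_transform"])
    movie = dict(raw.get("movie", {}))
    unknown_movie = set(movie) - {"n_molecules", "binder_emission", "locator_emission"}
    if unknown_movie:
        raise ValueError(f"unknown keys in 'movie' section: {sorted(unknown_movie)}")

    return SimulationConfig(
        binding=_build(BindingModel, binding_raw, "binding"),
        illumination=_build(IlluminationScheme, dict(raw.get("illumination", {})), "illumination"),
        photophysics=_build(PhotophysicsModel, dict(raw.get("photophysics", {})), "photophysics"),
        optics=_build(OpticsModel, optics_raw, "optics"),
        n_molecules=int(movie.get("n_molecules", 50)),
        binder_emission=float(movie.get("binder_emission", 3000.0)),
        locator_emission=float(movie.get("locator_emission", 2000.0)),
        seed=int(raw.get("seed", 0)),
    )
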