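"""Pipeline configuration: TOML loading, validation, defaults, hashing.

Every parameter has an embedded default; a config file overrides them
section by section.  Unknown keys are rejected before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from halocount.simgen import OpticsConfig
from halocount.spotfinder import SpotConfig
from halocount.undercount import UndercountConfig, DEFAULT_LAMBDA_GRID

DEFAULTS: dict = {
    "rng_seed": 0,
    "newborn_max_length_um": 3.5,
    "optics": {
        "pixel_size": 0.16,
        "psf_sigma": 0.084,
        "z_spacing": 0.2,
        "n_planes": 5,
        "defocus_scale": 0.5,
        "photons_per_molecule": 2000.0,
        "background_level": 100.0,
        "read_noise_sd": 2.0,
        "autofluorescence_level": 50.0,
        "shot_noise": True,
    },
    "segmentation": {
        "min_area": 50,
        "smoothing_sigma": 1.0,
        "disk_radius": 2,
        "erosion_extra": 1,
        "exclusions": [],
    },
    "spots": {
        "window": 6,
        "noise_size": 1.0,
        "feature_size": 7,
        "threshold_k": 3.0,
        "crop_shape": [30, 35],
    },
    "photobleach": {
        "aperture_radius": 3,
        "bg_annulus": [5, 8],
        "min_step": 50.0,
        "penalty": 3.0,
    },
    "undercount": {
        "eps": 0.25,
        "lambda_grid": list(DEFAULT_LAMBDA_GRID),
        "n_cells_per_lambda": 10000,
        "radius": 0.5,
        "length_distribution_name": "lognormal",
        "length_distribution_params": {"mean": 2.5, "sigma": 0.15},
    },
}


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


def _merge_validated(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in override:
            oval = override[key]
            if isinstance(dval, dict):
                if not isinstance(oval, dict):
                    raise ConfigError(f"section {path + key!r} must be a table")
                # free-form distribution parameters are passed through
                if key == "length_distribution_params":
                    out[key] = dict(oval)
                else:
                    out[key] = _merge_validated(dval, oval, path + key + ".")
            else:
                out[key] = oval
        else:
            out[key] = dval if not isinstance(dval, dict) else dict(dval)
    unknown = set(override) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


@dataclass
class PipelineConfig:
    """Validated parameters for every pipeline stage."""

    rng_seed: int = 0
    newborn_max_length_um: float = 3.5
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    segmentation: dict = field(default_factory=lambda: dict(DEFAULTS["segmentation"]))
    spots: SpotConfig = field(default_factory=SpotConfig)
    photobleach: dict = field(default_factory=lambda: dict(DEFAULTS["photobleach"]))
    undercount: UndercountConfig = field(default_factory=UndercountConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        merged = _merge_validated(DEFAULTS, raw)
        if merged["newborn_max_length_um"] <= 0:
            raise ConfigError("newborn_max_length_um must be positive")
        pb = merged["photobleach"]
        if pb["min_step"] <= 0:
            raise ConfigError("photobleach.min_step must be positive")
        uc = merged["undercount"]
        try:
            optics = OpticsConfig(**merged["optics"])
            spots_kw = dict(merged["spots"])
            spots_kw["crop_shape"] = tuple(spots_kw["crop_shape"])
            spots = SpotConfig(**spots_kw)
            undercount = UndercountConfig(
                eps=uc["eps"],
                lambda_grid=tuple(uc["lambda_grid"]),
                n_cells_per_lambda=uc["n_cells_per_lambda"],
                radius=uc["radius"],
                length_distribution=(
                    uc["length_distribution_name"],
                    dict(uc["length_distribution_params"]),
                ),
                rng_seed=merged["rng_seed"],
            )
        except ValueError as e:
            raise ConfigError(str(e)) from e
        return cls(
            rng_seed=int(merged["rng_seed"]),
            newborn_max_length_um=float(merged["newborn_max_length_um"]),
            optics=optics,
            segmentation=merged["segmentation"],
            spots=spots,
            photobleach=pb,
            undercount=undercount,
        )

    @classmethod
    def from_toml(cls, path: str | Path | None) -> "PipelineConfig":
        if path is None:
            return cls.from_dict({})
        raw = tomllib.loads(Path(path).read_text())
        return cls.from_dict(raw)

    def as_dict(self) -> dict:
        from dataclasses import asdict

        d = {
            "rng_seed": self.rng_seed,
            "newborn_max_length_um": self.newborn_max_length_um,
            "optics": asdict(self.optics),
            "segmentation": dict(self.segmentation),
            "spots": {**asdict(self.spots), "crop_shape": list(self.spots.crop_shape)},
            "photobleach": dict(self.photobleach),
            "undercount": {
                "eps": self.undercount.eps,
                "lambda_grid": list(self.undercount.lambda_grid),
                "n_cells_per_lambda": self.undercount.n_cells_per_lambda,
                "radius": self.undercount.radius,
                "length_distribution_name": self.undercount.length_distribution[0],
                "length_distribution_params": dict(self.undercount.length_distribution[1]),
            },
        }
        return d

    def hash(self) -> str:
        """Stable short hash of the full parameter set, for provenance."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _toml_value(v) -> str:
    import numbers

    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, numbers.Integral):
        return repr(int(v))
    if isinstance(v, numbers.Real):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def dumps_toml(d: dict, prefix: str = "") -> str:
    """Serialise a nested dict of plain values to TOML text."""
    lines = []
    for k, v in d.items():
        if not isinstance(v, dict):
            lines.append(f"{k} = {_toml_value(v)}")
    for k, v in d.items():
        if isinstance(v, dict):
            name = f"{prefix}{k}"
            lines.append(f"\n[{name}]")
            lines.append(dumps_toml(v, prefix=name + "."))
    return "\n".join(lines)


def default_config_toml() -> str:
    """The embedded defaults as a ready-to-edit TOML document."""
    return dumps_toml(DEFAULTS) + "\n"
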