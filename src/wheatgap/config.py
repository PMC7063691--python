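"""YAML configuration loading and validation for pipeline runs.

A run config names the sites (presets or site YAML files), the base cultivar,
the trait search ranges and the run scale.  Example::

    sites: [temperate_CW, hot_dry_SW]
    years: 100        # harvested seasons per evaluation
    n_starts: 25
    n_candidates: 16
    patience: 20
    max_gen: 200
    seed: 1
    outdir: results
    reduced: false    # true -> 10 years, 3 starts, max_gen 50
    cultivar: reference           # or path to a cultivar YAML
    trait_ranges: default         # or path to a ranges YAML

A cultivar YAML holds a ``traits`` block (a_max, s_g, p_h, p_p, g_f, r_u,
w_ss), an optional ``stress`` block (hsgnt, hsgnr, dsgnt, dsgns, dsgnr_max)
and an optional ``physiology`` block (rue, k_ext, t_base, grains_per_g,
max_grain_wt, labile_frac).  A site YAML holds the SiteClimateParams fields.
A ranges YAML maps each trait name to [lower, upper].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .crop import CultivarParams, StressParams, TRAIT_NAMES
from .optimize import DEFAULT_TRAIT_RANGES, TraitRanges
from .weather import SiteClimateParams, preset_names, site_preset

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "load_cultivar",
    "load_trait_ranges",
    "load_site",
    "save_cultivar",
]

REDUCED_SCALE = dict(years=10, n_starts=3, max_gen=50)


class ConfigError(ValueError):
    """A configuration problem, naming the offending field."""


@dataclass(frozen=True)
class RunConfig:
    sites: tuple[str, ...]
    cultivar: str = "reference"
    trait_ranges: str = "default"
    years: int = 100
    n_starts: int = 25
    n_candidates: int = 16
    patience: int = 20
    max_gen: int = 200
    seed: int = 1
    outdir: str = "results"
    reduced: bool = False

    def __post_init__(self) -> None:
        if not self.sites:
            raise ConfigError("sites: at least one site is required")
        if self.years < 2:
            raise ConfigError(
                "years: must be >= 2 (the CV-of-yield stability filter is "
                "undefined on a single season)"
            )
        if self.n_candidates < 1:
            raise ConfigError("n_candidates: must be >= 1")
        if self.n_starts < 1:
            raise ConfigError("n_starts: must be >= 1")

    def effective(self) -> "RunConfig":
        """Apply the reduced-scale overrides if requested."""
        if not self.reduced:
            return self
        return replace(self, **REDUCED_SCALE)


_RUN_FIELDS = {f for f in RunConfig.__dataclass_fields__}


def _read_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration, applying defaults."""
    data = _read_yaml(path)
    unknown = set(data) - _RUN_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "sites" in data:
        data["sites"] = tuple(data["sites"])
    cfg = RunConfig(**data)
    for site in cfg.sites:
        if site not in preset_names() and not Path(site).exists():
            raise ConfigError(
                f"{path}: sites: {site!r} is neither a preset "
                f"({', '.join(preset_names())}) nor an existing file"
            )
    for name, label in ((cfg.cultivar, "cultivar"), (cfg.trait_ranges, "trait_ranges")):
        builtin = "reference" if label == "cultivar" else "default"
        if name != builtin and not Path(name).exists():
            raise ConfigError(f"{path}: {label}: file not found: {name}")
    return cfg


def load_site(name_or_path: str) -> SiteClimateParams:
    if name_or_path in preset_names():
        return site_preset(name_or_path)
    data = _read_yaml(name_or_path)
    try:
        return SiteClimateParams(
            site_id=data.get("site_id", Path(name_or_path).stem),
            latitude=float(data["latitude"]),
            monthly_tmin_mean=np.asarray(data["monthly_tmin_mean"], float),
            monthly_tmax_mean=np.asarray(data["monthly_tmax_mean"], float),
            monthly_t_sd=np.asarray(data["monthly_t_sd"], float),
            monthly_rad_mean=np.asarray(data["monthly_rad_mean"], float),
            p_wet_given_wet=np.asarray(data["p_wet_given_wet"], float),
            p_wet_given_dry=np.asarray(data["p_wet_given_dry"], float),
            wet_day_precip_mean=np.asarray(data["wet_day_precip_mean"], float),
            sowing_doy=int(data["sowing_doy"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{name_or_path}: missing site field {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{name_or_path}: {exc}") from exc


def load_cultivar(name_or_path: str) -> CultivarParams:
    if name_or_path == "reference":
        return CultivarParams()
    data = _read_yaml(name_or_path)
    kwargs: dict = {"name": data.get("name", Path(name_or_path).stem)}
    traits = data.get("traits", {})
    unknown = set(traits) - set(TRAIT_NAMES)
    if unknown:
        raise ConfigError(
            f"{name_or_path}: traits: unknown names {sorted(unknown)}; "
            f"legal trait names are {list(TRAIT_NAMES)}"
        )
    kwargs.update({k: float(v) for k, v in traits.items()})
    if "stress" in data:
        try:
            kwargs["stress"] = StressParams(**{
                k: float(v) for k, v in data["stress"].items()
            })
        except TypeError as exc:
            raise ConfigError(f"{name_or_path}: stress: {exc}") from exc
    kwargs.update({k: float(v) for k, v in data.get("physiology", {}).items()})
    try:
        return CultivarParams(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name_or_path}: {exc}") from exc


def save_cultivar(cv: CultivarParams, path: str | Path) -> None:
    """Write a cultivar back out in the config schema (re-simulatable)."""
    data = {
        "name": cv.name,
        "traits": {t: float(getattr(cv, t)) for t in TRAIT_NAMES},
        "stress": {
            "hsgnt": cv.stress.hsgnt, "hsgnr": cv.stress.hsgnr,
            "dsgnt": cv.stress.dsgnt, "dsgns": cv.stress.dsgns,
            "dsgnr_max": cv.stress.dsgnr_max,
        },
        "physiology": {
            "rue": cv.rue, "k_ext": cv.k_ext, "t_base": cv.t_base,
            "grains_per_g": cv.grains_per_g, "max_grain_wt": cv.max_grain_wt,
            "labile_frac": cv.labile_frac,
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_trait_ranges(name_or_path: str) -> TraitRanges:
    if name_or_path == "default":
        return DEFAULT_TRAIT_RANGES
    data = _read_yaml(name_or_path)
    try:
        return TraitRanges.from_dict(data)
    except ValueError as exc:
        raise ConfigError(f"{name_or_path}: {exc}") from exc
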