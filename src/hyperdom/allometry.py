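"""Height and aboveground-biomass allometry.

Stem biomass composes three published pieces of allometry:

* a per-region Weibull height–diameter model ``H = a(1 - exp(-b D^c))``,
* the moist-forest dicot model ``AGB = coef * rho * D^2 * H`` (kg), and
* a palm (monocot) power law ``ln AGB = ln_intercept + ln_slope * ln D``
  that uses diameter only.

Coefficient values live in a versioned YAML config
(:data:`DEFAULT_CONFIG_PATH`); every results file records the config used.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "HeightModel",
    "AllometryConfig",
    "load_allometry_config",
    "default_allometry_config",
    "estimate_height",
    "agb_dicot",
    "agb_palm",
    "stem_biomass_kg",
    "stem_biomass_Mg",
]

DEFAULT_CONFIG_PATH = importlib.resources.files("hyperdom") / "data" / "allometry.yaml"

KG_PER_MG = 1000.0


@dataclasses.dataclass(frozen=True)
class HeightModel:
    """Per-region Weibull height parameters ``{region: (a, b, c)}``.

    ``a`` (m) is the asymptotic height; ``b`` and ``c`` shape the approach.
    """

    params: dict

    def __post_init__(self):
        for region, (a, b, c) in self.params.items():
            if not (a > 0 and b > 0 and c > 0):
                raise ValueError(
                    f"height parameters for {region!r} must be positive, "
                    f"got {(a, b, c)}"
                )

    def height(self, d_cm, region: str):
        if region not in self.params:
            raise KeyError(f"no height parameters for region {region!r}")
        a, b, c = self.params[region]
        d = np.asarray(d_cm, dtype=float)
        if np.any(d <= 0):
            raise ValueError("diameter must be positive")
        h = a * (1.0 - np.exp(-b * d**c))
        return float(h) if np.isscalar(d_cm) else h


@dataclasses.dataclass(frozen=True)
class AllometryConfig:
    """Allometry coefficients.  Units: D cm, rho g cm^-3, H m, AGB kg."""

    dicot_coef: float
    palm_ln_intercept: float
    palm_ln_slope: float
    height: HeightModel
    version: int | str = "unversioned"

    def __post_init__(self):
        if not self.dicot_coef > 0:
            raise ValueError("dicot_coef must be positive")

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "dicot_coef": self.dicot_coef,
            "height": {
                r: {"a": p[0], "b": p[1], "c": p[2]}
                for r, p in self.height.params.items()
            },
            "palm": {
                "ln_intercept": self.palm_ln_intercept,
                "ln_slope": self.palm_ln_slope,
            },
        }


def load_allometry_config(path=None) -> AllometryConfig:
    """Load an AllometryConfig from YAML (package default when *path* is None)."""
    if path is None:
        text = DEFAULT_CONFIG_PATH.read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    height = HeightModel(
        {r: (p["a"], p["b"], p["c"]) for r, p in raw["height"].items()}
    )
    return AllometryConfig(
        dicot_coef=float(raw["dicot_coef"]),
        palm_ln_intercept=float(raw["palm"]["ln_intercept"]),
        palm_ln_slope=float(raw["palm"]["ln_slope"]),
        height=height,
        version=raw.get("version", "unversioned"),
    )


def default_allometry_config() -> AllometryConfig:
    return load_allometry_config(None)


def estimate_height(d_cm, region: str, height_model: HeightModel):
    """Modeled tree height (m) from diameter via the region's Weibull fit."""
    return height_model.height(d_cm, region)


def agb_dicot(d_cm, rho, height_m, config: AllometryConfig):
    """Dicot aboveground biomass (kg): ``coef * rho * D^2 * H``."""
    d = np.asarray(d_cm, dtype=float)
    r = np.asarray(rho, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(d <= 0) or np.any(r <= 0) or np.any(h <= 0):
        raise ValueError("diameter, wood density and height must be positive")
    out = config.dicot_coef * r * d**2 * h
    return float(out) if out.ndim == 0 else out


def agb_palm(d_cm, config: AllometryConfig):
    """Palm aboveground biomass (kg) from diameter only (log-log power law)."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = np.exp(config.palm_ln_intercept + config.palm_ln_slope * np.log(d))
    return float(out) if out.ndim == 0 else out


def stem_biomass_kg(d_cm, rho, region, is_monocot, config: AllometryConfig):
    """Route one stem (or arrays of stems) to the palm or dicot model; kg.

    Monocots use diameter only; dicots use modeled height for the stem's
    region and its assigned wood density.
    """
    if np.isscalar(d_cm):
        if is_monocot:
            return agb_palm(d_cm, config)
        h = estimate_height(d_cm, region, config.height)
        return agb_dicot(d_cm, rho, h, config)
    d = np.asarray(d_cm, dtype=float)
    mono = np.asarray(is_monocot, dtype=bool)
    out = np.empty_like(d)
    if mono.any():
        out[mono] = agb_palm(d[mono], config)
    dic = ~mono
    if dic.any():
        region_arr = np.asarray(region, dtype=object)
        rho_arr = np.asarray(rho, dtype=float)
        h = np.empty(dic.sum())
        sub_regions = region_arr[dic]
        sub_d = d[dic]
        for reg in np.unique(sub_regions.astype(str)):
            m = sub_regions == reg
            h[m] = estimate_height(sub_d[m], reg, config.height)
        out[dic] = agb_dicot(sub_d, rho_arr[dic], h, config)
    return out


def stem_biomass_Mg(d_cm, rho, region, is_monocot, config: AllometryConfig):
    """As :func:`stem_biomass_kg`, converted to Mg."""
    out = stem_biomass_kg(d_cm, rho, region, is_monocot, config)
    return out / KG_PER_MG if not np.isscalar(out) else out / KG_PER_MG
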