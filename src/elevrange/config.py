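"""Configuration objects for the synthetic study system and the pipeline.

The defaults of :class:`SyntheticConfig` describe the study system the
package emulates: a Himalayan valley transect of 96 vegetation plots on
1,800-5,400 m a.s.l., ~545 vascular plant species labelled by life form
(woody/herbaceous) and biogeographical affinity (temperate/tropical/
cosmopolitan), six mini weather stations at fixed elevations, and a
human population surface with towns at 2,700 and 4,200 m.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = ["ConfigError", "SyntheticConfig", "STATION_ELEVATIONS"]


class ConfigError(ValueError):
    """Raised when a configuration field violates its contract."""


#: Elevations (m a.s.l.) of the six valley weather stations.
STATION_ELEVATIONS: tuple[float, ...] = (2457.0, 2792.0, 3368.0, 3740.0, 4140.0, 5230.0)

# Species counts of the surveyed flora: 545 recorded species of which
# 158 woody / 387 herbaceous, and 337 temperate / 112 tropical /
# 96 with no clear distribution centre.
_LIFE_FORM_DEFAULT = {"woody": 158 / 545, "herbaceous": 387 / 545}
_AFFINITY_DEFAULT = {
    "temperate": 337 / 545,
    "tropical": 112 / 545,
    "cosmopolitan": 96 / 545,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic community / environment generator.

    Range geometry uses a midpoint parameterisation: each species draws a
    midpoint uniformly on the domain and a latent range size
    ``max(0, a + b * (midpoint - domain_low) + noise)``; the occupied
    interval is (optionally) truncated to the domain. ``rapoport_slope_b``
    is therefore the planted range-size-per-metre-of-elevation slope that
    downstream regressions should recover.
    """

    # --- elevational domain and sampling design -------------------------
    domain_low: float = 1800.0    # m a.s.l.
    domain_high: float = 5400.0   # m a.s.l.
    n_plots: int = 96
    plot_jitter_sd: float = 0.0   # m; 0 = exact even grid
    n_species: int = 545

    # --- range geometry --------------------------------------------------
    base_range_a: float = 400.0        # m, latent range size at domain_low
    rapoport_slope_b: float = 0.35     # m of range per m of midpoint elevation
    range_noise_sd: float = 300.0      # m
    truncate_to_domain: bool = True
    detection_prob: float = 0.9        # per (species, plot) Bernoulli
    #: optional map group label -> slope b, overriding rapoport_slope_b for
    #: species carrying that life-form or affinity label
    group_slopes: Mapping[str, float] | None = None
    life_form_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_LIFE_FORM_DEFAULT)
    )
    affinity_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_AFFINITY_DEFAULT)
    )

    # --- station climate -------------------------------------------------
    t0_sea_level_c: float = 22.0       # °C, sea-level annual mean
    lapse_rate: float = 5.5            # K per km
    seasonal_amplitude: float = 10.0   # K, peak deviation of monthly means
    temp_noise_sd: float = 0.3         # K
    precip_base: float = 1500.0        # mm/yr at 0 m
    precip_gradient: float = -0.15     # mm/yr per m of elevation
    precip_noise_sd: float = 4.0       # mm per month
    n_years: int = 3
    first_year: int = 2016
    station_elevations: Sequence[float] = STATION_ELEVATIONS

    # --- disturbance and palaeoclimate scenario --------------------------
    pop_centers: Sequence[tuple[float, float]] = ((2700.0, 2000.0), (4200.0, 1500.0))
    n_minor_villages: int = 8
    minor_village_pop: float = 150.0
    n_lgm_models: int = 3
    lgm_warming_low: float = 5.0       # °C warming since LGM at domain_low
    lgm_warming_high: float = 3.0      # °C at domain_high
    lgm_wetting_low: float = 300.0     # mm/yr wetting since LGM at domain_low
    lgm_wetting_high: float = 120.0    # mm/yr at domain_high
    lgm_model_sd_t: float = 0.4        # °C between-model spread
    lgm_model_sd_p: float = 25.0       # mm between-model spread

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.domain_low < self.domain_high:
            raise ConfigError(
                f"domain_low ({self.domain_low}) must be < domain_high ({self.domain_high})"
            )
        if self.n_plots < 2:
            raise ConfigError(f"n_plots must be >= 2, got {self.n_plots}")
        if self.n_species < 1:
            raise ConfigError(f"n_species must be >= 1, got {self.n_species}")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ConfigError(f"detection_prob must lie in [0, 1], got {self.detection_prob}")
        for name in ("life_form_proportions", "affinity_proportions"):
            props = getattr(self, name)
            if not props:
                raise ConfigError(f"{name} must be non-empty")
            if any(p < 0 for p in props.values()):
                raise ConfigError(f"{name} has a negative fraction")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {sum(props.values())!r}")
        if self.range_noise_sd < 0:
            raise ConfigError(f"range_noise_sd must be >= 0, got {self.range_noise_sd}")
        if self.plot_jitter_sd < 0:
            raise ConfigError(f"plot_jitter_sd must be >= 0, got {self.plot_jitter_sd}")
        if not self.pop_centers:
            raise ConfigError("pop_centers must be non-empty")
        for elev, pop in self.pop_centers:
            if not self.domain_low <= elev <= self.domain_high:
                raise ConfigError(
                    f"pop_centers elevation {elev} outside domain "
                    f"[{self.domain_low}, {self.domain_high}]"
                )
            if pop < 0:
                raise ConfigError(f"pop_centers population must be >= 0, got {pop}")
        if self.n_years < 1:
            raise ConfigError(f"n_years must be >= 1, got {self.n_years}")
        if self.n_lgm_models < 1:
            raise ConfigError(f"n_lgm_models must be >= 1, got {self.n_lgm_models}")
        if len(set(self.station_elevations)) < 2:
            raise ConfigError("station_elevations needs >= 2 distinct elevations")

    # --- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["station_elevations"] = list(self.station_elevations)
        d["pop_centers"] = [list(c) for c in self.pop_centers]
        if self.group_slopes is not None:
            d["group_slopes"] = dict(self.group_slopes)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        kwargs = dict(data)
        if "pop_centers" in kwargs:
            kwargs["pop_centers"] = tuple(tuple(c) for c in kwargs["pop_centers"])
        if "station_elevations" in kwargs:
            kwargs["station_elevations"] = tuple(kwargs["station_elevations"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load from a YAML or JSON file holding the fields of this class."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def replace(self, **changes) -> "SyntheticConfig":
        return dataclasses.replace(self, **changes)

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
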