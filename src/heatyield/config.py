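"""Configuration for the synthetic station-weather and yield-panel generator."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any

import yaml


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate a US Corn-Belt-like station network over a 40-year
    record: a May-September daily-maximum temperature series with seasonal
    cycle and day-to-day persistence, rainfall whose recent occurrence
    raises the wet-bulb temperature (so humid-heat days tend to follow
    rain), and county corn yields with a technology trend, a planted dry
    heat sensitivity of -2 Bu/acre per dry-heat day, and no humid-heat
    sensitivity.
    """

    seed: int = 0
    n_stations: int = 50
    n_counties: int = 50
    years: tuple[int, int] = (1980, 2019)
    base_period: tuple[int, int] = (1981, 2010)
    season: tuple[int, ...] = (5, 6, 7, 8, 9)

    # daily-maximum temperature model (deg C)
    temp_mean_c: float = 29.0
    temp_seasonal_amplitude: float = 5.0
    temp_ar1: float = 0.7
    temp_noise_sd: float = 3.0

    # precipitation occurrence chain + amounts
    rain_prob_wet_after_wet: float = 0.3
    rain_prob_wet_after_dry: float = 0.3
    rain_mean_mm: float = 8.0

    # wet-bulb depression: Twmax = Tmax - max(0, d0 + noise - coupling * precip3)
    wetbulb_depression_mean: float = 6.0
    wetbulb_depression_sd: float = 1.5
    humidity_rain_coupling: float = 0.25   # deg C of Twmax elevation per mm in prior 3 days

    # yield panel (Bu/acre)
    beta1_true: float = -2.0               # per dry-heat day
    beta2_true: float = 0.0                # per humid-heat day
    beta1_true_irrigated: float = 0.0
    beta2_true_irrigated: float = 0.0
    yield_trend: float = 1.5               # per year
    yield_intercept: float = 120.0
    yield_noise_sd: float = 8.0
    county_offset_sd: float = 10.0
    irrigated_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.base_period = tuple(int(y) for y in self.base_period)
        self.season = tuple(int(m) for m in self.season)
        self.validate()

    def validate(self) -> None:
        def bad(name: str, why: str) -> ConfigError:
            return ConfigError(f"invalid config field {name!r}: {why}")

        if self.seed < 0:
            raise bad("seed", "must be non-negative")
        if self.n_stations < 1:
            raise bad("n_stations", "must be >= 1")
        if not 1 <= self.n_counties <= self.n_stations:
            raise bad("n_counties", "must satisfy 1 <= n_counties <= n_stations")
        if self.years[0] > self.years[1]:
            raise bad("years", "start after end")
        if self.base_period[0] > self.base_period[1]:
            raise bad("base_period", "start after end")
        if not set(self.season) <= set(range(1, 13)) or not self.season:
            raise bad("season", "months must be in 1..12")
        for name in ("rain_prob_wet_after_wet", "rain_prob_wet_after_dry",
                     "irrigated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise bad(name, "probability must be in [0, 1]")
        if not 0.0 <= self.temp_ar1 < 1.0:
            raise bad("temp_ar1", "must be in [0, 1)")
        for name in ("temp_noise_sd", "temp_seasonal_amplitude", "rain_mean_mm",
                     "wetbulb_depression_sd", "yield_noise_sd", "county_offset_sd"):
            if getattr(self, name) < 0:
                raise bad(name, "must be non-negative")
        if self.humidity_rain_coupling < 0:
            raise bad("humidity_rain_coupling", "must be non-negative")

    def replace(self, **changes: Any) -> "SyntheticConfig":
        data = asdict(self)
        data.update(changes)
        return SyntheticConfig(**data)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"invalid config field(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineConfig:
    """Full pipeline settings: generator conditions plus analysis knobs."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    level: float = 0.95
    season_name: str = "MJJAS"
    crop: str = "corn"
    hourly_csv: str | None = None   # optional real-data hourly ingest path

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        syn = data.pop("synthetic", {})
        known = {f.name for f in fields(cls)} - {"synthetic"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"invalid config section(s)/field(s): {sorted(unknown)}")
        return cls(synthetic=SyntheticConfig.from_dict(syn), **data)

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict(),
            "level": self.level,
            "season_name": self.season_name,
            "crop": self.crop,
            "hourly_csv": self.hourly_csv,
        }


def load_config(path: str) -> PipelineConfig:
    """Read a YAML config file (nested sections mirror the dataclass fields)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return PipelineConfig.from_dict(data)


def dump_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
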