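"""Run configuration: schema, defaults, the parameter ledger and YAML I/O.

The ledger drives the Monte Carlo propagation.  Each entry is a
:class:`ParameterSpec` with a distribution law (normal, lognormal or fixed),
truncation bounds enforced by resampling, and a scope:

* ``global`` -- one draw per iteration (populations, thresholds, rations,
  production scalings, stratum fractions);
* ``per_water_mass`` -- an independent draw in every water mass (the two
  patchiness intensity parameters), reflecting environmental heterogeneity;
* ``per_block`` -- one draw per coarse biomass block, scaling the cells of
  the block proportionally.

Point values default to literature-style means; the little auk density
threshold is lognormal (its reported uncertainty is strongly right-skewed),
with the log-scale sigma back-solved from a 95% interval of 7.8-22.2 g m^-3
around a median of 13.7 g m^-3.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import ConfigError, InputError

#: log-scale sd of the auk threshold: ln(22.2/7.8) / (2 * 1.96)
AUK_THRESHOLD_SIGMA_LOG = math.log(22.2 / 7.8) / (2 * 1.959963984540054)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Model):
    nx: int = 76
    ny: int = 76
    cell_side_km: float = 20.0


class SyntheticConfig(_Model):
    land_fraction: float = 0.02
    n_islands: int = 8
    margin_km: float = 200.0
    mean_density_gm2: float = 33.2
    cv_spatial: float = 0.8
    correlation_length_km: float = 200.0
    block_size_cells: int = 5
    n_colonies: int = 8
    total_pairs: float = 4.8e6

    @field_validator("land_fraction")
    @classmethod
    def _land(cls, v: float) -> float:
        if not 0 <= v < 0.5:
            raise ValueError("land_fraction must be in [0, 0.5)")
        return v


class NicheConfig(_Model):
    strata: list[int]
    threshold_gm3: float
    ration_g_day: float


class NichesConfig(_Model):
    bowhead: NicheConfig = NicheConfig(strata=[1, 2, 3], threshold_gm3=9.4, ration_g_day=1.413e6)
    little_auk: NicheConfig = NicheConfig(strata=[1], threshold_gm3=13.7, ration_g_day=294.0)
    foraging_radius_km: float = 150.0
    season_days: int = 92


class ScenarioConfig(_Model):
    nb17: float = 50_000.0
    nb21: float = 343.0
    na21_pairs: float = 4.8e6


class ProductionConfig(_Model):
    pb_ratio: float = 3.8
    season_fraction: float = 0.43
    copepod_to_meso: float = 1.0
    stratum_fractions: list[float] = [0.45, 0.35, 0.20]


class PatchinessConfig(_Model):
    phi_mean: float = 0.084
    phi_sd: float = 0.005
    p_mean: float = 0.415
    p_sd: float = 0.05


class ParameterOverride(_Model):
    """Optional per-parameter override of the default ledger entry."""

    name: str
    dist: Optional[Literal["normal", "lognormal", "fixed"]] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None

    @field_validator("sd")
    @classmethod
    def _sd(cls, v, info):
        if v is not None and v < 0:
            raise ValueError(f"sd must be >= 0 (parameter {info.data.get('name')!r})")
        return v


class RuntimeConfig(_Model):
    iters: int = 10_000
    seed: int = 0
    workers: int = 1


class PathsConfig(_Model):
    fixtures: Optional[str] = None
    output: Optional[str] = None


class RunConfig(_Model):
    grid: GridConfig = GridConfig()
    synthetic: SyntheticConfig = SyntheticConfig()
    niches: NichesConfig = NichesConfig()
    scenario: ScenarioConfig = ScenarioConfig()
    production: ProductionConfig = ProductionConfig()
    patchiness: PatchinessConfig = PatchinessConfig()
    parameters: list[ParameterOverride] = []
    runtime: RuntimeConfig = RuntimeConfig()
    paths: PathsConfig = PathsConfig()


class ParameterSpec(BaseModel):
    """One entry of the Monte Carlo parameter ledger.

    For ``lognormal`` entries ``mean`` is the median (point value) and
    ``sd`` the log-scale sigma.  ``fixed`` entries carry no sd.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    dist: Literal["normal", "lognormal", "fixed"]
    mean: float
    sd: float = 0.0
    lower: float = -math.inf
    upper: float = math.inf
    scope: Literal["global", "per_water_mass", "per_block"] = "global"

    @field_validator("sd")
    @classmethod
    def _sd(cls, v: float) -> float:
        if v < 0:
            raise ValueError("sd must be >= 0")
        return v

    def model_post_init(self, _ctx) -> None:
        if self.lower > self.upper:
            raise ValueError(f"parameter {self.name!r}: lower > upper")
        if self.dist == "fixed" and self.sd != 0:
            raise ValueError(f"fixed parameter {self.name!r} must not carry an sd")
        if not self.lower <= self.mean <= self.upper:
            raise ValueError(f"parameter {self.name!r}: mean outside truncation bounds")

    @property
    def point_value(self) -> float:
        return self.mean

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the (truncated) distribution; truncation by resampling."""
        if self.dist == "fixed" or self.sd == 0:
            return self.mean if size is None else np.full(size, self.mean)

        def _draw(n):
            if self.dist == "normal":
                return rng.normal(self.mean, self.sd, size=n)
            return np.exp(rng.normal(math.log(self.mean), self.sd, size=n))

        n = 1 if size is None else int(np.prod(size))
        out = _draw(n)
        for _ in range(1000):
            bad = (out < self.lower) | (out > self.upper)
            if not bad.any():
                break
            out[bad] = _draw(int(bad.sum()))
        else:
            out = np.clip(out, self.lower, self.upper)
        if size is None:
            return float(out[0])
        return out.reshape(size)


def default_ledger(config: RunConfig) -> dict[str, ParameterSpec]:
    """Build the parameter ledger from a run configuration.

    Default dispersions are literature-scale: populations carry their
    reported SDs, rations and production scalings ~10% relative SDs, the
    whale threshold sd 1 g m^-3 and the auk threshold a lognormal spread
    matching its reported 95% interval.  Season length and foraging radius
    are fixed.  ``parameters`` overrides replace fields by name.
    """
    sc, ni, pr, pa = config.scenario, config.niches, config.production, config.patchiness
    f1, f2, f3 = pr.stratum_fractions
    specs = [
        ParameterSpec(name="na21_pairs", dist="normal", mean=sc.na21_pairs, sd=3e5, lower=0.0),
        ParameterSpec(name="nb17", dist="normal", mean=sc.nb17, sd=2500.0, lower=0.0),
        ParameterSpec(name="nb21", dist="normal", mean=sc.nb21, sd=50.0, lower=0.0),
        ParameterSpec(
            name="threshold_bowhead_gm3", dist="normal",
            mean=ni.bowhead.threshold_gm3, sd=1.0, lower=1e-6,
        ),
        ParameterSpec(
            name="threshold_auk_gm3", dist="lognormal",
            mean=ni.little_auk.threshold_gm3, sd=AUK_THRESHOLD_SIGMA_LOG, lower=1e-6,
        ),
        ParameterSpec(
            name="ration_bowhead_g_day", dist="normal",
            mean=ni.bowhead.ration_g_day, sd=0.1 * ni.bowhead.ration_g_day, lower=1e-6,
        ),
        ParameterSpec(
            name="ration_auk_g_day", dist="normal",
            mean=ni.little_auk.ration_g_day, sd=0.1 * ni.little_auk.ration_g_day, lower=1e-6,
        ),
        ParameterSpec(name="pb_ratio", dist="normal", mean=pr.pb_ratio, sd=0.5, lower=1e-6),
        ParameterSpec(
            name="season_fraction", dist="normal",
            mean=pr.season_fraction, sd=0.05, lower=1e-6, upper=1.0,
        ),
        ParameterSpec(
            name="copepod_to_meso", dist="normal",
            mean=pr.copepod_to_meso, sd=0.05, lower=1e-6,
        ),
        ParameterSpec(name="stratum_f1", dist="normal", mean=f1, sd=0.04, lower=0.0),
        ParameterSpec(name="stratum_f2", dist="normal", mean=f2, sd=0.04, lower=0.0),
        ParameterSpec(name="stratum_f3", dist="normal", mean=f3, sd=0.03, lower=0.0),
        ParameterSpec(
            name="phi", dist="normal", mean=pa.phi_mean, sd=pa.phi_sd,
            lower=1e-6, upper=1.0 - 1e-6, scope="per_water_mass",
        ),
        ParameterSpec(
            name="p", dist="normal", mean=pa.p_mean, sd=pa.p_sd,
            lower=1e-6, upper=1.0, scope="per_water_mass",
        ),
        ParameterSpec(name="biomass_block", dist="normal", mean=1.0, sd=1.0,
                      lower=0.0, scope="per_block"),
        ParameterSpec(name="season_days", dist="fixed", mean=float(ni.season_days)),
        ParameterSpec(name="foraging_radius_km", dist="fixed", mean=ni.foraging_radius_km),
    ]
    ledger = {s.name: s for s in specs}
    for ov in config.parameters:
        if ov.name not in ledger:
            raise ConfigError(f"parameter override names unknown parameter {ov.name!r}")
        base = ledger[ov.name].model_dump()
        for fld in ("dist", "mean", "sd", "lower", "upper"):
            val = getattr(ov, fld)
            if val is not None:
                base[fld] = val
        try:
            ledger[ov.name] = ParameterSpec(**base)
        except ValidationError as exc:
            raise ConfigError(f"invalid override for parameter {ov.name!r}: {exc}") from exc
    return ledger


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective configuration (defaults applied) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
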