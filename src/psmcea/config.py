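"""Model configuration: schema, validation, loading and run manifests.

The configuration mirrors the published input-parameter table of the analysis
row for row: every uncertain quantity is a :class:`Param` carrying its
base-case value, deterministic-sensitivity bounds, and the probability
distribution used in probabilistic sensitivity analysis.  Survival
coefficients are grouped per arm/endpoint in :class:`SurvivalBlock` objects
with their variance-covariance matrices.

Unknown keys are rejected (``extra="forbid"`` everywhere), so a typo in a
YAML file fails loudly at load time rather than silently running defaults.
"""

from __future__ import annotations

import hashlib
import json
import time
from importlib import resources
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Param",
    "SurvivalBlock",
    "DrugUnit",
    "Component",
    "Strategy",
    "Settings",
    "AEEntry",
    "DeathDisutility",
    "ModelConfig",
    "RunManifest",
    "load_config",
    "save_config",
    "config_hash",
]

STRATEGY_NAMES = ("EC+mFOLFOX6", "EC", "SOC")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class Param(_Model):
    """One uncertain scalar input.

    ``value`` is the base case; ``low``/``high`` are the deterministic
    sensitivity bounds (95% CI when published, otherwise +/-10% is imputed);
    ``dist`` names the PSA distribution.  Gamma distributions are stored as
    (shape, scale = value/shape) so that the distribution mean reproduces the
    base-case value exactly; normal standard errors are back-calculated from
    the 95% CI as (high - low)/(2 * 1.96).
    """

    value: float
    dist: Literal["fixed", "normal", "beta", "gamma", "uniform"] = "fixed"
    low: float | None = None
    high: float | None = None
    alpha: float | None = None
    beta: float | None = None
    shape: float | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.dist == "beta" and (self.alpha is None or self.beta is None):
            raise ValueError("beta parameter needs alpha and beta")
        if self.dist == "beta" and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError("beta alpha/beta must be positive")
        if self.dist == "gamma":
            if self.shape is None or self.shape <= 0:
                raise ValueError("gamma parameter needs a positive shape")
            if self.value < 0:
                raise ValueError("gamma-distributed value must be non-negative")
        if self.dist == "uniform" and (self.low is None or self.high is None
                                       or not self.low < self.high):
            raise ValueError("uniform parameter needs low < high")
        if self.dist == "normal" and (self.low is None or self.high is None):
            raise ValueError("normal parameter needs CI bounds")
        return self

    def dsa_bounds(self) -> tuple[float, float]:
        if self.low is not None and self.high is not None:
            return float(self.low), float(self.high)
        return 0.9 * self.value, 1.1 * self.value

    @property
    def gamma_scale(self) -> float:
        return self.value / self.shape

    @property
    def normal_se(self) -> float:
        return (self.high - self.low) / (2.0 * 1.959963984540054)

    def sample(self, rng: np.random.Generator, n: int | None = None):
        """Draw from the PSA distribution (fixed parameters return the value)."""
        if self.dist == "fixed":
            return self.value if n is None else np.full(n, self.value)
        if self.dist == "normal":
            return rng.normal(self.value, self.normal_se, size=n)
        if self.dist == "beta":
            return rng.beta(self.alpha, self.beta, size=n)
        if self.dist == "gamma":
            if self.value == 0:
                return 0.0 if n is None else np.zeros(n)
            return rng.gamma(self.shape, self.gamma_scale, size=n)
        if self.dist == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        raise AssertionError(self.dist)


def fixed(value: float) -> Param:
    return Param(value=value, dist="fixed")


class SurvivalBlock(_Model):
    """Estimation-scale coefficients of one arm/endpoint extrapolation model
    with multivariate-normal uncertainty."""

    family: str
    coef_names: list[str]
    coefs: list[float]
    low: list[float]
    high: list[float]
    vcov: list[list[float]]

    @model_validator(mode="after")
    def _check(self):
        k = len(self.coefs)
        if not (len(self.coef_names) == len(self.low) == len(self.high) == k):
            raise ValueError("survival block arrays must have equal length")
        V = np.asarray(self.vcov, dtype=float)
        if V.shape != (k, k):
            raise ValueError("vcov dimension must equal the coefficient count")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("vcov must be symmetric")
        if np.min(np.linalg.eigvalsh(V)) < -1e-10:
            raise ValueError("vcov must be positive semi-definite")
        return self

    def vcov_array(self) -> np.ndarray:
        return np.asarray(self.vcov, dtype=float)


class DrugUnit(_Model):
    unit_mg: float = Field(gt=0)
    cost: Param  # dollars per unit


class Component(_Model):
    """One drug within a regimen, with dosing rule and administration events."""

    drug: str
    dose_rule: Literal["fixed", "per-m2", "per-kg"]
    dose_mg: float = Field(ge=0)  # mg per administration (or per day)
    schedule: Literal["per-day", "per-2-week"]
    rdi: str | None = None  # key into ModelConfig.rdi
    admin_events: dict[str, int] = Field(default_factory=dict)
    fraction: float = Field(default=1.0, ge=0.0, le=1.0)


class AEEntry(_Model):
    """Grade >=3 adverse event: one-off management cost and 1-week disutility."""

    cost: Param
    disutility: Param
    duration_weeks: float = 1.0


class DeathDisutility(_Model):
    """Utility decrement applied over a window of days before death."""

    window_days: tuple[float, float]
    decrement: Param


class Strategy(_Model):
    components: list[Component]
    ae_incidence: dict[str, Param] = Field(default_factory=dict)
    survival: dict[Literal["os", "pfs"], SurvivalBlock]

    @model_validator(mode="after")
    def _check(self):
        if set(self.survival) != {"os", "pfs"}:
            raise ValueError("strategy needs both 'os' and 'pfs' survival blocks")
        return self


class Settings(_Model):
    """General model settings (cohort, horizon, discounting, engine knobs)."""

    body_surface_area: Param  # m^2
    weight_kg: Param
    horizon_years: Param
    discount_rate: Param  # annual
    baseline_age: float = 61.0
    male_proportion: float = 0.5
    wtp_per_qaly: float = 150_000.0
    days_per_month: float = 30.4375
    days_per_year: float = 365.25
    cycle_days: float = 7.0
    # utility handling: "constant" applies the state utilities each cycle
    # (numerically what re-deriving the population-norm multiplier every cycle
    # yields); "aging-multiplier" fixes the multiplier at baseline and lets
    # utilities decline with the population norm as the cohort ages.
    utility_mode: Literal["constant", "aging-multiplier"] = "constant"
    include_ae_effects: bool = True
    include_death_disutility: bool = True
    death_disutility_scale: float = 0.0625
    scan_interval_weeks: float = 6.0
    consultation_interval_weeks: float = 2.0
    end_of_life_multiplier: float = 1.0
    apply_rdi: bool = True
    risk_table_interval_months: float = 6.0  # grid used when rendering curves

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 <= self.discount_rate.value <= 0.06:
            raise ValueError("discount rate outside the documented 0-6% range")
        if self.horizon_years.value <= 0:
            raise ValueError("horizon must be positive")
        return self

    @property
    def weeks_per_year(self) -> float:
        return self.days_per_year / self.cycle_days


class ModelConfig(_Model):
    """Complete machine-readable input set for the three-strategy model."""

    schema_name: Literal["psmcea-v1"] = "psmcea-v1"
    settings: Settings
    drugs: dict[str, DrugUnit]
    rdi: dict[str, Param]
    admin_costs: dict[str, Param]
    monitoring_costs: dict[str, Param]  # braf_test, scan, consultation
    utilities: dict[Literal["pfs", "pd"], Param]
    ae_catalog: dict[str, AEEntry]
    death_disutilities: list[DeathDisutility]
    subsequent_cost_per_week: Param
    end_of_life_cost: Param
    strategies: dict[str, Strategy]
    seed: int = 20260210

    @model_validator(mode="after")
    def _check(self):
        for name, strat in self.strategies.items():
            for comp in strat.components:
                if comp.drug not in self.drugs:
                    raise ValueError(f"strategy '{name}': unknown drug '{comp.drug}'")
                if comp.rdi is not None and comp.rdi not in self.rdi:
                    raise ValueError(f"strategy '{name}': unknown RDI key '{comp.rdi}'")
                for ev in comp.admin_events:
                    if ev not in self.admin_costs:
                        raise ValueError(
                            f"strategy '{name}': unknown administration event '{ev}'")
            for ae in strat.ae_incidence:
                if ae not in self.ae_catalog:
                    raise ValueError(f"strategy '{name}': unknown AE '{ae}'")
        for key in ("braf_test", "scan", "consultation"):
            if key not in self.monitoring_costs:
                raise ValueError(f"monitoring_costs missing '{key}'")
        for p in self._all_params():
            if p.dist == "gamma" and p.value < 0:
                raise ValueError("negative cost input")
        return self

    # -- traversal helpers ---------------------------------------------------

    def _all_params(self):
        yield from (self.settings.body_surface_area, self.settings.weight_kg,
                    self.settings.horizon_years, self.settings.discount_rate)
        for d in self.drugs.values():
            yield d.cost
        yield from self.rdi.values()
        yield from self.admin_costs.values()
        yield from self.monitoring_costs.values()
        yield from self.utilities.values()
        for ae in self.ae_catalog.values():
            yield ae.cost
            yield ae.disutility
        for dd in self.death_disutilities:
            yield dd.decrement
        yield self.subsequent_cost_per_week
        yield self.end_of_life_cost
        for strat in self.strategies.values():
            yield from strat.ae_incidence.values()

    def named_params(self):
        """(dotted-name, Param) pairs for every scalar uncertain input."""
        out = [
            ("settings.body_surface_area", self.settings.body_surface_area),
            ("settings.weight_kg", self.settings.weight_kg),
            ("settings.horizon_years", self.settings.horizon_years),
            ("settings.discount_rate", self.settings.discount_rate),
        ]
        out += [(f"drugs.{k}.cost", v.cost) for k, v in self.drugs.items()]
        out += [(f"rdi.{k}", v) for k, v in self.rdi.items()]
        out += [(f"admin_costs.{k}", v) for k, v in self.admin_costs.items()]
        out += [(f"monitoring_costs.{k}", v) for k, v in self.monitoring_costs.items()]
        out += [(f"utilities.{k}", v) for k, v in self.utilities.items()]
        for k, ae in self.ae_catalog.items():
            out += [(f"ae_catalog.{k}.cost", ae.cost),
                    (f"ae_catalog.{k}.disutility", ae.disutility)]
        for i, dd in enumerate(self.death_disutilities):
            out.append((f"death_disutilities.{i}.decrement", dd.decrement))
        out += [("subsequent_cost_per_week", self.subsequent_cost_per_week),
                ("end_of_life_cost", self.end_of_life_cost)]
        for s, strat in self.strategies.items():
            out += [(f"strategies.{s}.ae_incidence.{k}", v)
                    for k, v in strat.ae_incidence.items()]
        return out

    def get_param(self, dotted: str) -> Param:
        for name, p in self.named_params():
            if name == dotted:
                return p
        raise KeyError(dotted)

    def with_param_value(self, dotted: str, value: float) -> "ModelConfig":
        """Return a deep copy with one scalar input replaced."""
        data = self.model_dump(mode="python")
        node = data
        parts = dotted.split(".")
        for part in parts[:-1]:
            node = node[int(part)] if isinstance(node, list) else node[part]
        leaf = parts[-1]
        target = node[int(leaf)] if isinstance(node, list) else node[leaf]
        if isinstance(target, dict) and "value" in target:
            target["value"] = float(value)
        else:  # plain scalar setting
            node[leaf] = float(value)
        return ModelConfig.model_validate(data)


# ---------------------------------------------------------------------------
# IO and manifests
# ---------------------------------------------------------------------------


def load_config(path) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ModelConfig.model_validate(data)


def load_default_config() -> ModelConfig:
    """The base-case input set shipped with the package."""
    text = resources.files("psmcea").joinpath("data/base_case.yaml").read_text()
    return ModelConfig.model_validate(yaml.safe_load(text))


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


def config_hash(config: ModelConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class RunManifest(_Model):
    """Provenance record emitted once per pipeline run."""

    config_hash: str
    package_version: str = "0.1.0"
    seed: int
    timestamp: float = Field(default_factory=time.time)
    warnings: list[str] = Field(default_factory=list)

    @classmethod
    def for_run(cls, config: ModelConfig, seed: int | None = None) -> "RunManifest":
        return cls(config_hash=config_hash(config),
                   seed=config.seed if seed is None else seed)

    def add(self, message: str) -> None:
        self.warnings.append(message)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(mode="json"), fh, indent=2)
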