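"""Synthetic trial-arm data and digitized-curve artifacts.

Real inputs to the pipeline are survival-curve coordinates read off published
Kaplan-Meier plots together with number-at-risk tables.  This module makes
the whole pipeline runnable and testable without any external download: it
simulates subject-level event/censoring times from a chosen parametric family
(the same families used for extrapolation) and renders exactly the artifact a
graph digitizer would produce - the KM step function plus a risk table.

Censoring is the minimum of an administrative cutoff and an exponential
dropout time (constant monthly rate), independent of the event process, which
is the simplest mechanism consistent with the independent-censoring
assumption of the product-limit estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import FAMILIES
from .config import load_default_config, ModelConfig

__all__ = ["ArmSpec", "PseudoIPD", "DigitizedCurve", "simulate_arm",
           "render_km_artifacts", "base_case_fixture"]


@dataclass(frozen=True)
class ArmSpec:
    """Ground-truth description of one simulated trial arm/endpoint.

    ``true_params`` are on the natural scale, times in months.
    """

    label: str
    endpoint: str  # "PFS" | "OS"
    family: str
    true_params: tuple[float, ...]
    n_subjects: int
    cutoff_months: float = np.inf
    dropout_rate_per_month: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family '{self.family}'")
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        if not self.cutoff_months >= 0:
            raise ValueError("cutoff must be non-negative")
        if self.dropout_rate_per_month < 0:
            raise ValueError("dropout rate must be non-negative")
        fam = FAMILIES[self.family]
        if len(self.true_params) != len(fam.param_names):
            raise ValueError(
                f"{self.family} needs {len(fam.param_names)} parameters")
        for name, value, link in zip(fam.param_names, self.true_params, fam.links):
            if link == "log" and not value > 0:
                raise ValueError(f"parameter '{name}' must be positive")


@dataclass
class PseudoIPD:
    """Per-subject (time, event) records for one arm/endpoint."""

    times: np.ndarray
    events: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.size == 0:
            raise ValueError("PseudoIPD needs at least one record")
        if np.any(~np.isfinite(self.times)) or np.any(self.times < 0):
            raise ValueError("times must be finite and non-negative")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self):
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events,
                             "arm": self.arm, "endpoint": self.endpoint})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path)
        arm = str(df["arm"].iloc[0]) if "arm" in df else ""
        endpoint = str(df["endpoint"].iloc[0]) if "endpoint" in df else ""
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), arm, endpoint)


@dataclass
class DigitizedCurve:
    """A KM step function as a digitizer would deliver it, plus a risk table."""

    arm: str
    endpoint: str
    times: np.ndarray  # step-point times, months, starting at 0
    survival: np.ndarray  # step-point survival, starting at 1
    risk_times: np.ndarray
    n_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.times[0] != 0 or self.survival[0] != 1.0:
            raise ValueError("curve must start at (0, 1)")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((self.survival < -1e-12) | (self.survival > 1 + 1e-12)):
            raise ValueError("survival must lie in [0, 1]")
        if np.any(np.diff(self.n_risk) > 0):
            raise ValueError("numbers at risk must be non-increasing")
        if self.risk_times[0] != 0:
            raise ValueError("risk table must start at time 0")

    def to_csv(self, coords_path, risk_path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.survival}).to_csv(
            coords_path, index=False)
        pd.DataFrame({"time": self.risk_times, "n_risk": self.n_risk}).to_csv(
            risk_path, index=False)

    @classmethod
    def from_csv(cls, coords_path, risk_path, arm="", endpoint="") -> "DigitizedCurve":
        c = pd.read_csv(coords_path)
        r = pd.read_csv(risk_path)
        return cls(arm, endpoint, c["time"].to_numpy(), c["survival"].to_numpy(),
                   r["time"].to_numpy(), r["n_risk"].to_numpy())


def simulate_arm(spec: ArmSpec) -> PseudoIPD:
    """Simulate right-censored subject records for one arm/endpoint.

    The observed time is the minimum of the latent event time (drawn from the
    arm's family), an exponential dropout time and the administrative cutoff;
    the event indicator is 1 iff the latent event time is that minimum.
    Bit-reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fam = FAMILIES[spec.family]
    latent = fam.sample(rng, spec.n_subjects, *spec.true_params)
    censor = np.full(spec.n_subjects, float(spec.cutoff_months))
    if spec.dropout_rate_per_month > 0:
        dropout = rng.exponential(1.0 / spec.dropout_rate_per_month,
                                  size=spec.n_subjects)
        censor = np.minimum(censor, dropout)
    times = np.minimum(latent, censor)
    events = (latent <= censor).astype(int)
    return PseudoIPD(times, events, arm=spec.label, endpoint=spec.endpoint)


def render_km_artifacts(ipd: PseudoIPD, risk_times,
                        jitter_sd: float = 0.0, seed: int = 0) -> DigitizedCurve:
    """Render the digitizer artifact for an arm: exact KM step coordinates at
    the event times plus true numbers at risk at ``risk_times``.

    ``jitter_sd`` optionally adds Gaussian noise to the survival ordinates to
    emulate digitization error (monotonicity is restored afterwards).
    """
    risk_times = np.asarray(risk_times, dtype=float)
    if risk_times.size == 0 or risk_times[0] != 0:
        raise ValueError("risk_times must start at 0")
    if np.any(np.diff(risk_times) <= 0):
        raise ValueError("risk_times must be strictly increasing")

    order = np.argsort(ipd.times, kind="stable")
    t_sorted = ipd.times[order]
    e_sorted = ipd.events[order]

    # product-limit estimate with tied events handled per time point
    step_t = [0.0]
    step_s = [1.0]
    n_at_risk = len(ipd)
    s = 1.0
    for t in np.unique(t_sorted[e_sorted == 1]):
        at_t = t_sorted == t
        d = int(np.sum(e_sorted[at_t]))
        n_i = int(np.sum(t_sorted >= t))
        s *= 1.0 - d / n_i
        step_t.append(float(t))
        step_s.append(s)
        n_at_risk = n_i - d
    step_t = np.asarray(step_t)
    step_s = np.asarray(step_s)

    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = step_s + rng.normal(0.0, jitter_sd, size=step_s.size)
        noisy[0] = 1.0
        step_s = np.minimum.accumulate(np.clip(noisy, 0.0, 1.0))

    n_risk = np.array([int(np.sum(ipd.times >= rt)) for rt in risk_times])
    return DigitizedCurve(ipd.arm, ipd.endpoint, step_t, step_s,
                          risk_times, n_risk)


def base_case_fixture() -> ModelConfig:
    """The complete published base-case parameter set as a validated config."""
    return load_default_config()


def trial_arm_specs(config: ModelConfig | None = None, n_subjects: int = 300,
                    cutoff_months: float = 36.0,
                    dropout_rate_per_month: float = 0.003,
                    seed: int = 11) -> list[ArmSpec]:
    """Arm specifications emulating the trial read-out under the base-case
    extrapolation models (used to exercise reconstruction and refitting)."""
    config = config or base_case_fixture()
    specs = []
    for i, (name, strat) in enumerate(config.strategies.items()):
        for j, endpoint in enumerate(("pfs", "os")):
            block = strat.survival[endpoint]
            fam = FAMILIES[block.family]
            natural = fam.to_natural(block.coefs)
            specs.append(ArmSpec(
                label=name, endpoint=endpoint.upper(), family=block.family,
                true_params=natural, n_subjects=n_subjects,
                cutoff_months=cutoff_months,
                dropout_rate_per_month=dropout_rate_per_month,
                seed=seed + 10 * i + j,
            ))
    return specs
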