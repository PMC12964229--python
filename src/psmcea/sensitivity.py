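"""Deterministic and probabilistic sensitivity analysis, acceptability
curves, expected value of perfect information, and scenario analyses.

The probabilistic analysis jointly resamples every uncertain input from its
assigned distribution (beta for probabilities/utilities, gamma for costs,
normal for cohort measurements) and the six survival-coefficient pairs from
their multivariate normals via Cholesky factorization, then pushes each draw
through the full partitioned-survival engine for all three strategies.
Structural settings sampled as uniform in deterministic analysis (time
horizon, discount rate) are held at base case in the probabilistic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .engine import run_all, run_strategy
from .evaluate import compare
from .reconstruct import km_estimate, reconstruct_ipd
from .survival import (fit_parametric, fit_spline, model_average,
                       survival_function, FAMILIES)
from .synthetic import render_km_artifacts, simulate_arm, trial_arm_specs

__all__ = [
    "cholesky_sample", "sample_all", "PSASamples", "run_psa", "ceac", "evpi",
    "one_way_dsa", "two_way_price_map", "run_scenarios", "make_trial_ipd",
]


# ---------------------------------------------------------------------------
# correlated and independent sampling
# ---------------------------------------------------------------------------


def cholesky_sample(mean, vcov, n: int, rng, *, jitter: float = 1e-10,
                    max_tries: int = 6) -> np.ndarray:
    """Draws from N(mean, vcov) as mean + L z with L L^T = vcov.

    A matrix that is symmetric but numerically indefinite is repaired by the
    smallest diagonal jitter (powers of ten) that makes the factorization
    succeed; a genuinely non-PSD matrix raises.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    mean = np.asarray(mean, dtype=float)
    V = np.asarray(vcov, dtype=float)
    if V.shape != (mean.size, mean.size):
        raise ValueError("vcov shape does not match the mean vector")
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("vcov must be symmetric")
    eps = 0.0
    for _ in range(max_tries):
        try:
            L = np.linalg.cholesky(V + eps * np.eye(mean.size))
            break
        except np.linalg.LinAlgError:
            eps = jitter if eps == 0.0 else eps * 10.0
    else:
        raise np.linalg.LinAlgError("variance-covariance matrix is not repairable")
    z = rng.standard_normal((n, mean.size))
    return mean + z @ L.T


def sample_all(config: ModelConfig, rng, *, max_attempts: int = 100) -> ModelConfig:
    """One coherent random draw of the whole input set.

    Returns a deep copy of the configuration with every distributed scalar
    replaced by a draw (values violating hard bounds are redrawn) and each
    survival block's coefficients replaced by one multivariate-normal draw.
    Horizon and discount rate stay at base case (structural settings).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    draw = config.model_copy(deep=True)
    for name, p in draw.named_params():
        if p.dist in ("fixed", "uniform"):
            continue
        lo, hi = (0.0, 1.0) if p.dist == "beta" else (0.0, np.inf)
        for _ in range(max_attempts):
            v = float(p.sample(rng))
            if lo <= v <= hi:
                p.value = v
                break
        else:
            raise RuntimeError(f"could not draw '{name}' within bounds")
    for strat in draw.strategies.values():
        for block in strat.survival.values():
            sampled = cholesky_sample(block.coefs, block.vcov_array(), 1, rng)[0]
            block.coefs = [float(c) for c in sampled]
    return draw


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSASamples:
    """Per-iteration costs and QALYs for all strategies."""

    strategies: tuple[str, ...]
    costs: np.ndarray   # (n, n_strategies)
    qalys: np.ndarray
    wtp: float
    seed: int
    n_failures: int = 0
    failure_messages: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.costs.shape[0])

    def nmb(self, wtp: float | None = None) -> np.ndarray:
        lam = self.wtp if wtp is None else wtp
        return self.qalys * lam - self.costs

    def deltas(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        ia, ib = self.strategies.index(a), self.strategies.index(b)
        return (self.costs[:, ia] - self.costs[:, ib],
                self.qalys[:, ia] - self.qalys[:, ib])

    def summary(self, a: str, b: str) -> dict:
        """Means and 2.5/97.5 percentile intervals for the pair a vs b.

        The ICER interval is the percentile interval of the iteration-wise
        ratio; ratios are unstable when the QALY increment crosses zero, in
        which case interpret the CEAC instead.
        """
        dc, dq = self.deltas(a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            icers = dc / dq
        pct = lambda x: tuple(np.percentile(x, [2.5, 97.5]))  # noqa: E731
        return {
            "pair": f"{a} vs {b}",
            "mean_delta_cost": float(np.mean(dc)), "ci_delta_cost": pct(dc),
            "mean_delta_qaly": float(np.mean(dq)), "ci_delta_qaly": pct(dq),
            "mean_icer": float(np.mean(dc) / np.mean(dq)),
            "ci_icer": pct(icers[np.isfinite(icers)]),
        }

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for j, s in enumerate(self.strategies):
            cols[f"cost_{s}"] = self.costs[:, j]
            cols[f"qaly_{s}"] = self.qalys[:, j]
        return pd.DataFrame(cols)


def run_psa(config: ModelConfig, n: int = 5000, seed: int | None = None,
            max_failure_fraction: float = 0.01) -> PSASamples:
    """n Monte-Carlo iterations of the full model; reproducible for a fixed
    seed (per-iteration substreams spawned from the master seed)."""
    if n <= 0:
        raise ValueError("need a positive iteration count")
    seed = config.seed if seed is None else int(seed)
    names = tuple(config.strategies)
    streams = np.random.SeedSequence(seed).spawn(n)
    costs = np.empty((n, len(names)))
    qalys = np.empty((n, len(names)))
    ok = np.ones(n, dtype=bool)
    messages = []
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        try:
            draw = sample_all(config, rng)
            results = run_all(draw)
            for j, s in enumerate(names):
                costs[i, j] = results[s].total_cost
                qalys[i, j] = results[s].total_qalys
        except Exception as exc:  # recorded, excluded, never silent
            ok[i] = False
            if len(messages) < 20:
                messages.append(f"iteration {i}: {exc!r}")
    n_fail = int(np.sum(~ok))
    if n_fail > max_failure_fraction * n:
        raise RuntimeError(
            f"{n_fail}/{n} PSA iterations failed; first errors: {messages[:3]}")
    return PSASamples(strategies=names, costs=costs[ok], qalys=qalys[ok],
                      wtp=config.settings.wtp_per_qaly, seed=seed,
                      n_failures=n_fail, failure_messages=messages)


def ceac(samples: PSASamples, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves: for each willingness-to-pay,
    the fraction of iterations in which each strategy has maximal net
    monetary benefit (ties resolved in favour of the cheaper strategy)."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size < 2:
        raise ValueError("need at least two willingness-to-pay values")
    if samples.n == 0:
        raise ValueError("empty PSA samples")
    rows = []
    # stable tie-break: sort strategy columns by cost within iteration via
    # argmax over nmb - tiny*cost
    for lam in wtp_grid:
        nmb = samples.qalys * lam - samples.costs
        tie_break = nmb - 1e-9 * samples.costs
        best = np.argmax(tie_break, axis=1)
        probs = np.bincount(best, minlength=len(samples.strategies)) / samples.n
        rows.append([lam, *probs])
    return pd.DataFrame(rows, columns=["wtp", *samples.strategies])


def evpi(samples: PSASamples, wtp: float | None = None) -> float:
    """Per-person expected value of perfect information:
    mean(max_s NMB_s) - max_s(mean NMB_s)."""
    if samples.n == 0:
        raise ValueError("empty PSA samples")
    nmb = samples.nmb(wtp)
    value = float(np.mean(np.max(nmb, axis=1)) - np.max(np.mean(nmb, axis=0)))
    # non-negative by construction; clip float-accumulation dust
    return max(value, 0.0)


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------


def _with_survival_coef(config: ModelConfig, strategy: str, endpoint: str,
                        index: int, value: float) -> ModelConfig:
    out = config.model_copy(deep=True)
    out.strategies[strategy].survival[endpoint].coefs[index] = float(value)
    return out


def _pair_icer(config: ModelConfig, pair: tuple[str, str]) -> float:
    a = run_strategy(pair[0], config)
    b = run_strategy(pair[1], config)
    cmpr = compare(a, b, config.settings.wtp_per_qaly)
    if cmpr.icer is not None:
        return cmpr.icer
    return -np.inf if cmpr.dominance == "dominant" else np.inf


def one_way_dsa(config: ModelConfig, pair: tuple[str, str],
                include_survival: bool = True) -> pd.DataFrame:
    """Tornado entries: the pairwise ICER with each input at its lower and
    upper deterministic bound (95% CI, or +/-10% where no CI is published),
    all else at base case; sorted by absolute ICER swing."""
    base = _pair_icer(config, pair)
    rows = []
    for name, p in config.named_params():
        lo, hi = p.dsa_bounds()
        icer_lo = _pair_icer(config.with_param_value(name, lo), pair)
        icer_hi = _pair_icer(config.with_param_value(name, hi), pair)
        rows.append((name, lo, hi, icer_lo, icer_hi))
    if include_survival:
        for sname in pair:
            strat = config.strategies[sname]
            for endpoint, block in strat.survival.items():
                for i, cname in enumerate(block.coef_names):
                    icer_lo = _pair_icer(
                        _with_survival_coef(config, sname, endpoint, i,
                                            block.low[i]), pair)
                    icer_hi = _pair_icer(
                        _with_survival_coef(config, sname, endpoint, i,
                                            block.high[i]), pair)
                    rows.append((f"strategies.{sname}.survival.{endpoint}.{cname}",
                                 block.low[i], block.high[i], icer_lo, icer_hi))
    df = pd.DataFrame(rows, columns=["parameter", "low", "high",
                                     "icer_low", "icer_high"])
    df["base_icer"] = base
    finite = df[["icer_low", "icer_high"]].replace([np.inf, -np.inf], np.nan)
    df["swing"] = (finite.max(axis=1) - finite.min(axis=1)).abs()
    return df.sort_values("swing", ascending=False, ignore_index=True)


def two_way_price_map(config: ModelConfig, drug_a: str = "encorafenib",
                      drug_b: str = "cetuximab",
                      fractions_a=None, fractions_b=None) -> pd.DataFrame:
    """Preferred strategy (maximal NMB at the configured willingness-to-pay)
    over a grid of price fractions for two drugs (1.0 = current price)."""
    fractions_a = np.linspace(0, 1, 11) if fractions_a is None else np.asarray(fractions_a)
    fractions_b = np.linspace(0, 1, 11) if fractions_b is None else np.asarray(fractions_b)
    if np.any(fractions_a < 0) or np.any(fractions_b < 0):
        raise ValueError("price fractions must be non-negative")
    base_a = config.drugs[drug_a].cost.value
    base_b = config.drugs[drug_b].cost.value
    lam = config.settings.wtp_per_qaly
    rows = []
    for fa in fractions_a:
        for fb in fractions_b:
            cfg = config.with_param_value(f"drugs.{drug_a}.cost", base_a * fa)
            cfg = cfg.with_param_value(f"drugs.{drug_b}.cost", base_b * fb)
            results = run_all(cfg)
            nmbs = {s: r.total_qalys * lam - r.total_cost
                    for s, r in results.items()}
            best = max(nmbs, key=lambda s: (nmbs[s], -results[s].total_cost))
            rows.append((fa, fb, best))
    return pd.DataFrame(rows, columns=[f"fraction_{drug_a}",
                                       f"fraction_{drug_b}", "preferred"])


# ---------------------------------------------------------------------------
# scenario analyses
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("spline", "aic-average", "bic-average",
                  "progression-utilities-only", "no-rdi")


def make_trial_ipd(config: ModelConfig, n_subjects: int = 300,
                   seed: int = 11) -> dict:
    """Pseudo-IPD per (strategy, endpoint) produced by the full synthetic
    pipeline: simulate arms under the base-case extrapolations, render the
    digitized-curve artifacts, then reconstruct."""
    out = {}
    for spec in trial_arm_specs(config, n_subjects=n_subjects, seed=seed):
        ipd_true = simulate_arm(spec)
        grid = np.arange(0.0, spec.cutoff_months + 1e-9,
                         config.settings.risk_table_interval_months)
        curve = render_km_artifacts(ipd_true, grid)
        out[(spec.label, spec.endpoint.lower())] = reconstruct_ipd(curve)
    return out


def _refit_survival(ipd_map: dict, config: ModelConfig, mode: str,
                    spline_knots: int = 2, seed: int = 20260101) -> dict:
    fns = {}
    for sname in config.strategies:
        fns[sname] = {}
        for endpoint in ("os", "pfs"):
            ipd = ipd_map[(sname, endpoint)]
            if mode == "spline":
                fit = fit_spline(ipd.times, ipd.events, spline_knots, seed=seed)
                fns[sname][endpoint] = survival_function(fit)
            else:
                fits = []
                for fam in FAMILIES:
                    try:
                        f = fit_parametric(ipd.times, ipd.events, fam, seed=seed)
                    except ValueError:
                        continue
                    if f.converged and np.isfinite(f.loglik):
                        fits.append(f)
                criterion = "AIC" if mode == "aic-average" else "BIC"
                fns[sname][endpoint] = model_average(fits, criterion)
    return fns


def run_scenarios(config: ModelConfig, ipd_map: dict | None = None,
                  scenarios=SCENARIO_NAMES, seed: int = 20260101) -> pd.DataFrame:
    """Re-run the model end-to-end under each scenario.

    Scenarios 1-3 (spline / AIC-averaged / BIC-averaged extrapolation)
    require pseudo-IPD for refitting (``ipd_map`` keyed by (strategy,
    endpoint)); scenario 4 restricts utilities to the progression-based
    health states (no adverse-event or time-to-death decrements); scenario 5
    removes the relative-dose-intensity adjustment.  Returns a tidy table of
    strategy totals and pairwise ICERs per scenario.
    """
    refit_needed = {"spline", "aic-average", "bic-average"} & set(scenarios)
    if refit_needed and ipd_map is None:
        raise ValueError(
            "scenarios 1-3 need pseudo-IPD for refitting; pass ipd_map "
            "(see make_trial_ipd)")
    lam = config.settings.wtp_per_qaly
    rows = []
    for scen in scenarios:
        cfg = config
        fns = None
        if scen in ("spline", "aic-average", "bic-average"):
            fns = _refit_survival(ipd_map, config, scen, seed=seed)
        elif scen == "progression-utilities-only":
            cfg = config.model_copy(deep=True)
            cfg.settings.include_ae_effects = False
            cfg.settings.include_death_disutility = False
        elif scen == "no-rdi":
            cfg = config.model_copy(deep=True)
            cfg.settings.apply_rdi = False
        else:
            raise ValueError(f"unknown scenario '{scen}'")
        results = run_all(cfg, survival_fns=fns)
        for s, r in results.items():
            rows.append({"scenario": scen, "kind": "strategy", "name": s,
                         "cost": r.total_cost, "qaly": r.total_qalys,
                         "ly": r.total_lys, "icer": np.nan})
        pairs = [("EC+mFOLFOX6", "EC"), ("EC+mFOLFOX6", "SOC"), ("EC", "SOC")]
        for a, b in pairs:
            if a in results and b in results:
                c = compare(results[a], results[b], lam)
                rows.append({"scenario": scen, "kind": "pair",
                             "name": f"{a} vs {b}",
                             "cost": c.delta_cost, "qaly": c.delta_qaly,
                             "ly": c.delta_ly,
                             "icer": c.icer if c.icer is not None else np.nan})
    return pd.DataFrame(rows)
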