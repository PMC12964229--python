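"""Parametric survival families, maximum-likelihood fitting, flexible splines
and information-criterion model averaging.

All fitted models carry their coefficients on the *estimation scale*: strictly
positive parameters (rates, shapes, scales) are stored as logarithms, while
location-type parameters (a log-normal ``meanlog``, a Gompertz ``shape``, the
generalized-gamma ``mu`` and ``Q``) are stored untransformed.  This is the
convention used by mainstream survival software for reporting coefficient
vectors together with a variance-covariance matrix, and it is the scale on
which multivariate-normal uncertainty propagation is performed downstream.

Supported families
------------------
exponential, weibull, gompertz, llogis (log-logistic), lnorm (log-normal),
gamma, gengamma (generalized gamma, stable (mu, sigma, Q) parameterization),
and Royston-Parmar restricted cubic splines on the log cumulative-hazard
scale with 0-3 internal knots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "FAMILIES",
    "SurvivalFit",
    "SurvivalFunction",
    "evaluate_survival",
    "fit_parametric",
    "fit_spline",
    "model_average",
    "median_survival",
    "NotReached",
]


# ---------------------------------------------------------------------------
# family definitions (natural-scale survival / density / sampling)
# ---------------------------------------------------------------------------

_EPS = 1e-300


def _llogis_sf(t, scale, shape):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.where(t > 0, (t / scale) ** shape, 0.0)
    return 1.0 / (1.0 + z)


def _llogis_logpdf(t, scale, shape):
    lt = np.log(t)
    z = shape * (lt - np.log(scale))
    return np.log(shape) - lt + z - 2.0 * np.logaddexp(0.0, z)


def _gompertz_sf(t, shape, rate):
    # shape may be negative (decreasing hazard; improper distribution)
    t = np.asarray(t, dtype=float)
    if abs(shape) < 1e-12:
        return np.exp(-rate * t)
    return np.exp(-rate / shape * np.expm1(shape * t))


def _gompertz_logpdf(t, shape, rate):
    if abs(shape) < 1e-12:
        return np.log(rate) - rate * t
    return np.log(rate) + shape * t - rate / shape * np.expm1(shape * t)


def _gompertz_sample(rng, n, shape, rate):
    u = rng.uniform(size=n)
    if abs(shape) < 1e-12:
        return -np.log(u) / rate
    arg = 1.0 - shape * np.log(u) / rate
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(arg > 0, np.log(np.maximum(arg, _EPS)) / shape, np.inf)
    return t


def _gengamma_sf(t, mu, sigma, Q):
    """Survival of the stable generalized gamma (Prentice)."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    w = (np.log(t[pos]) - mu) / sigma
    if abs(Q) < 1e-8:
        out[pos] = stats.norm.sf(w)
    else:
        a = Q ** -2
        expnu = a * np.exp(np.clip(Q * w, -700, 700))
        if Q > 0:
            out[pos] = special.gammaincc(a, expnu)
        else:
            out[pos] = special.gammainc(a, expnu)
    return out


def _gengamma_logpdf(t, mu, sigma, Q):
    lt = np.log(t)
    w = (lt - mu) / sigma
    if abs(Q) < 1e-8:
        return stats.norm.logpdf(w) - np.log(sigma) - lt
    a = Q ** -2
    qw = np.clip(Q * w, -700, 700)
    return (
        np.log(abs(Q))
        - np.log(sigma)
        - lt
        - special.gammaln(a)
        + a * (np.log(a) + qw)
        - a * np.exp(qw)
    )


def _gengamma_sample(rng, n, mu, sigma, Q):
    if abs(Q) < 1e-8:
        return np.exp(mu + sigma * rng.standard_normal(n))
    a = Q ** -2
    g = rng.gamma(a, size=n)
    return np.exp(mu + sigma * (np.log(Q * Q * g) / Q))


@dataclass(frozen=True)
class Family:
    """A parametric time-to-event family.

    ``links`` maps each coefficient to the transform from estimation scale to
    natural scale: ``"log"`` (exponentiate) or ``"identity"``.
    """

    name: str
    param_names: tuple[str, ...]
    links: tuple[str, ...]
    sf: Callable
    logpdf: Callable
    sample: Callable
    init: Callable  # (times, events) -> natural-scale starting values

    def to_natural(self, coefs: Sequence[float]) -> tuple[float, ...]:
        return tuple(
            float(np.exp(c)) if link == "log" else float(c)
            for c, link in zip(coefs, self.links)
        )

    def to_estimation(self, natural: Sequence[float]) -> tuple[float, ...]:
        return tuple(
            float(np.log(v)) if link == "log" else float(v)
            for v, link in zip(natural, self.links)
        )


def _mean_logt(times, events):
    t = np.asarray(times, float)
    t = t[t > 0]
    return float(np.mean(np.log(t))) if t.size else 0.0


FAMILIES: dict[str, Family] = {
    "exponential": Family(
        "exponential", ("rate",), ("log",),
        sf=lambda t, rate: np.exp(-rate * np.asarray(t, float)),
        logpdf=lambda t, rate: np.log(rate) - rate * t,
        sample=lambda rng, n, rate: rng.exponential(1.0 / rate, size=n),
        init=lambda t, e: (max(np.sum(e), 1) / max(np.sum(t), 1e-9),),
    ),
    "weibull": Family(
        "weibull", ("shape", "scale"), ("log", "log"),
        sf=lambda t, shape, scale: np.exp(-((np.asarray(t, float) / scale) ** shape)),
        logpdf=lambda t, shape, scale: (
            np.log(shape) - np.log(scale)
            + (shape - 1) * (np.log(t) - np.log(scale))
            - (t / scale) ** shape
        ),
        sample=lambda rng, n, shape, scale: scale * rng.weibull(shape, size=n),
        init=lambda t, e: (1.0, float(np.mean(t[t > 0])) if np.any(t > 0) else 1.0),
    ),
    "gompertz": Family(
        "gompertz", ("shape", "rate"), ("identity", "log"),
        sf=_gompertz_sf,
        logpdf=_gompertz_logpdf,
        sample=_gompertz_sample,
        init=lambda t, e: (0.001, max(np.sum(e), 1) / max(np.sum(t), 1e-9)),
    ),
    "llogis": Family(
        "llogis", ("scale", "shape"), ("log", "log"),
        sf=_llogis_sf,
        logpdf=_llogis_logpdf,
        sample=lambda rng, n, scale, shape: scale
        * (lambda u: (u / (1 - u)) ** (1.0 / shape))(rng.uniform(size=n)),
        init=lambda t, e: (float(np.median(t[t > 0])) if np.any(t > 0) else 1.0, 1.5),
    ),
    "lnorm": Family(
        "lnorm", ("meanlog", "sdlog"), ("identity", "log"),
        sf=lambda t, meanlog, sdlog: stats.norm.sf(
            (np.log(np.maximum(np.asarray(t, float), _EPS)) - meanlog) / sdlog
        ) * (np.asarray(t, float) > 0) + (np.asarray(t, float) <= 0) * 1.0,
        logpdf=lambda t, meanlog, sdlog: stats.norm.logpdf(
            (np.log(t) - meanlog) / sdlog
        ) - np.log(sdlog) - np.log(t),
        sample=lambda rng, n, meanlog, sdlog: np.exp(
            meanlog + sdlog * rng.standard_normal(n)
        ),
        init=lambda t, e: (_mean_logt(t, e), 1.0),
    ),
    "gamma": Family(
        "gamma", ("rate", "shape"), ("log", "log"),
        sf=lambda t, rate, shape: special.gammaincc(shape, rate * np.asarray(t, float)),
        logpdf=lambda t, rate, shape: (
            shape * np.log(rate) - special.gammaln(shape)
            + (shape - 1) * np.log(t) - rate * t
        ),
        sample=lambda rng, n, rate, shape: rng.gamma(shape, 1.0 / rate, size=n),
        init=lambda t, e: (
            max(np.sum(e), 1) / max(np.sum(t), 1e-9), 1.0,
        ),
    ),
    "gengamma": Family(
        "gengamma", ("mu", "sigma", "Q"), ("identity", "log", "identity"),
        sf=_gengamma_sf,
        logpdf=_gengamma_logpdf,
        sample=_gengamma_sample,
        init=lambda t, e: (_mean_logt(t, e), 1.0, 0.5),
    ),
}


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------


class NotReached:
    """Sentinel for a median (or other quantile) not reached in the horizon."""

    def __repr__(self):  # pragma: no cover
        return "NotReached"

    def __eq__(self, other):
        return isinstance(other, NotReached)

    def __hash__(self):
        return hash("NotReached")


NOT_REACHED = NotReached()


@dataclass
class SurvivalFit:
    """A fitted time-to-event model on the estimation scale."""

    family: str
    coef_names: tuple[str, ...]
    coefs: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_subjects: int
    n_events: int
    converged: bool = True
    diagnostic: str = ""
    knots: np.ndarray | None = None  # spline families only (log-time scale)
    data_id: int | None = None  # identity token of the fitting data

    @property
    def n_params(self) -> int:
        return len(self.coefs)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        # n = number of subjects (documented convention)
        return self.n_params * np.log(self.n_subjects) - 2.0 * self.loglik

    def sf(self, t) -> np.ndarray:
        return evaluate_survival(self, t)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "coef_names": list(self.coef_names),
            "coefs": self.coefs.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_subjects": self.n_subjects,
            "n_events": self.n_events,
            "converged": self.converged,
        }
        if self.knots is not None:
            d["knots"] = self.knots.tolist()
        return d


@dataclass
class SurvivalFunction:
    """A callable survival curve S(t) with provenance.

    ``t`` is in months; values are probabilities in [0, 1].
    """

    fn: Callable[[np.ndarray], np.ndarray]
    provenance: str = "single"
    components: list = field(default_factory=list)
    weights: np.ndarray | None = None

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival requested at negative time")
        return np.clip(self.fn(t), 0.0, 1.0)


def from_coefficients(family: str, coefs: Sequence[float],
                      coef_names: Sequence[str] | None = None,
                      vcov: np.ndarray | None = None,
                      n_subjects: int = 0, n_events: int = 0) -> SurvivalFit:
    """Build a :class:`SurvivalFit` from externally supplied coefficients
    (e.g. a published table of estimation-scale estimates)."""
    fam = _get_family(family)
    coefs = np.asarray(coefs, dtype=float)
    if len(coefs) != len(fam.param_names):
        raise ValueError(
            f"{family} expects {len(fam.param_names)} coefficients, got {len(coefs)}"
        )
    k = len(coefs)
    return SurvivalFit(
        family=family,
        coef_names=tuple(coef_names or fam.param_names),
        coefs=coefs,
        vcov=np.zeros((k, k)) if vcov is None else np.asarray(vcov, float),
        loglik=np.nan,
        n_subjects=n_subjects,
        n_events=n_events,
    )


def _get_family(name: str) -> Family:
    if name not in FAMILIES:
        raise ValueError(
            f"unknown survival family '{name}'; known: {sorted(FAMILIES)} "
            f"and spline-k1/2/3"
        )
    return FAMILIES[name]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_survival(fit: SurvivalFit, t) -> np.ndarray:
    """Evaluate S(t) (t in months) for a fitted or table-specified model."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival requested at negative time")
    if fit.family.startswith("spline"):
        return _spline_sf(t, fit.coefs, fit.knots)
    fam = _get_family(fit.family)
    natural = fam.to_natural(fit.coefs)
    return np.clip(fam.sf(t, *natural), 0.0, 1.0)


def survival_function(fit: SurvivalFit) -> SurvivalFunction:
    return SurvivalFunction(fn=lambda t: evaluate_survival(fit, t),
                            provenance=f"single:{fit.family}",
                            components=[fit])


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


def _neg_loglik(fam: Family, coefs, times, events):
    natural = fam.to_natural(coefs)
    t_ev = times[events == 1]
    t_cn = times[events == 0]
    with np.errstate(all="ignore"):
        ll = 0.0
        if t_ev.size:
            lp = fam.logpdf(t_ev, *natural)
            if not np.all(np.isfinite(lp)):
                return np.inf
            ll += np.sum(lp)
        if t_cn.size:
            s = fam.sf(t_cn, *natural)
            s = np.clip(s, _EPS, 1.0)
            ll += np.sum(np.log(s))
    return -ll if np.isfinite(ll) else np.inf


def _fit_mle(nll, x0, n_restarts=3, seed=20260101, scale=0.3):
    """Quasi-Newton minimisation with fixed-seed random restarts."""
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.asarray(x0, float)]
    starts += [x0 + scale * rng.standard_normal(len(x0)) for _ in range(n_restarts)]
    for s in starts:
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore", RuntimeWarning)
                res = optimize.minimize(nll, s, method="BFGS",
                                        options={"maxiter": 500, "gtol": 1e-7})
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res
    return best


def _vcov_from_hessian(nll, x):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess1(np.asarray(x, float), nll)
        vcov = np.linalg.inv(hess)
        # symmetrize; a valid covariance has a non-negative diagonal
        vcov = 0.5 * (vcov + vcov.T)
        if np.any(np.diag(vcov) < 0):
            raise np.linalg.LinAlgError("negative variance")
        return vcov, True
    except np.linalg.LinAlgError:
        k = len(x)
        return np.full((k, k), np.nan), False


def fit_parametric(times, events, family: str, *, seed: int = 20260101) -> SurvivalFit:
    """Fit one of the seven standard families by right-censored ML.

    Parameters
    ----------
    times, events:
        Event/censoring times (months) and event indicators (1 = event).
    family:
        One of ``exponential, weibull, gompertz, llogis, lnorm, gamma,
        gengamma``.

    Returns a :class:`SurvivalFit` with estimation-scale coefficients and the
    inverse observed-information variance-covariance matrix.  Non-convergence
    is flagged on the result, never silent.
    """
    fam = _get_family(family)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty data")
    n_events = int(np.sum(events))
    if n_events == 0:
        raise ValueError("cannot fit a parametric model to all-censored data")

    x0 = np.asarray(fam.to_estimation(fam.init(times, events)), dtype=float)
    nll = lambda c: _neg_loglik(fam, c, times, events)  # noqa: E731
    res = _fit_mle(nll, x0, seed=seed)
    if res is None or not np.isfinite(res.fun):
        return SurvivalFit(family, fam.param_names,
                           x0, np.full((len(x0),) * 2, np.nan),
                           -np.inf, times.size, n_events,
                           converged=False, diagnostic="optimizer failure",
                           data_id=_data_token(times, events))
    vcov, ok = _vcov_from_hessian(nll, res.x)
    converged = bool(res.success or res.status == 2) and ok
    return SurvivalFit(
        family=family,
        coef_names=fam.param_names,
        coefs=np.asarray(res.x, float),
        vcov=vcov,
        loglik=-float(res.fun),
        n_subjects=int(times.size),
        n_events=n_events,
        converged=converged,
        diagnostic="" if converged else str(getattr(res, "message", "")),
        data_id=_data_token(times, events),
    )


def _data_token(times, events) -> int:
    return hash((np.round(np.asarray(times, float), 10).tobytes(),
                 np.asarray(events, int).tobytes()))


# ---------------------------------------------------------------------------
# Royston-Parmar restricted cubic splines on log cumulative hazard
# ---------------------------------------------------------------------------


def _rcs_basis(x, knots):
    """Natural cubic spline basis v_j(x) for internal knots (boundary = first
    and last entries of ``knots``)."""
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    internal = knots[1:-1]
    cols = [np.ones_like(x), x]
    for kj in internal:
        lam = (kmax - kj) / (kmax - kmin)
        vj = (np.maximum(x - kj, 0) ** 3
              - lam * np.maximum(x - kmin, 0) ** 3
              - (1 - lam) * np.maximum(x - kmax, 0) ** 3)
        cols.append(vj)
    return np.column_stack(cols)


def _rcs_basis_deriv(x, knots):
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    internal = knots[1:-1]
    cols = [np.zeros_like(x), np.ones_like(x)]
    for kj in internal:
        lam = (kmax - kj) / (kmax - kmin)
        vj = 3 * (np.maximum(x - kj, 0) ** 2
                  - lam * np.maximum(x - kmin, 0) ** 2
                  - (1 - lam) * np.maximum(x - kmax, 0) ** 2)
        cols.append(vj)
    return np.column_stack(cols)


def _spline_sf(t, gammas, knots):
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t, dtype=float)
    pos = t > 0
    if np.any(pos):
        x = np.log(t[pos])
        eta = _rcs_basis(x, knots) @ gammas
        out[pos] = np.exp(-np.exp(np.clip(eta, -700, 700)))
    return out


def _spline_nll(gammas, x_ev, x_cn, knots):
    # log h(t) = eta'(x) - x + eta ... with H = exp(eta), x = log t
    with np.errstate(all="ignore"):
        ll = 0.0
        if x_ev.size:
            B = _rcs_basis(x_ev, knots)
            Bd = _rcs_basis_deriv(x_ev, knots)
            eta = B @ gammas
            deta = Bd @ gammas
            if np.any(deta <= 0):
                return np.inf
            ll += np.sum(np.log(deta) - x_ev + eta - np.exp(np.clip(eta, -700, 700)))
        if x_cn.size:
            eta = _rcs_basis(x_cn, knots) @ gammas
            ll -= np.sum(np.exp(np.clip(eta, -700, 700)))
    return -ll if np.isfinite(ll) else np.inf


def fit_spline(times, events, knots: int, *, seed: int = 20260101) -> SurvivalFit:
    """Fit a flexible spline model with ``knots`` internal knots (0-3).

    The baseline is a restricted cubic spline in log time on the log
    cumulative-hazard scale; internal knots sit at event-time quantiles and
    boundary knots at the extreme event times (the 0-knot model is exactly a
    Weibull reparameterization).
    """
    if knots not in (0, 1, 2, 3):
        raise ValueError("knots must be 0, 1, 2 or 3")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    t_ev = times[events == 1]
    if t_ev.size == 0:
        raise ValueError("cannot fit a spline model to all-censored data")
    distinct = np.unique(t_ev[t_ev > 0])
    if distinct.size <= knots + 2:
        raise ValueError(
            f"need more than {knots + 2} distinct event times for {knots} knots"
        )
    x_ev = np.log(t_ev[t_ev > 0])
    x_cn = np.log(np.maximum(times[events == 0], _EPS))
    x_cn = x_cn[np.isfinite(x_cn) & (times[events == 0] > 0)]

    qs = np.linspace(0, 1, knots + 2)
    knot_pos = np.quantile(x_ev, qs)
    if np.unique(knot_pos).size != knot_pos.size:
        raise ValueError("degenerate knot placement: duplicated knot locations")

    # Weibull-equivalent start
    wb = fit_parametric(times, events, "weibull", seed=seed)
    shape, scale = FAMILIES["weibull"].to_natural(wb.coefs)
    x0 = np.zeros(knots + 2)
    x0[0] = -shape * np.log(scale)
    x0[1] = shape

    nll = lambda g: _spline_nll(g, x_ev, x_cn, knot_pos)  # noqa: E731
    res = _fit_mle(nll, x0, seed=seed, scale=0.1)
    vcov, ok = _vcov_from_hessian(nll, res.x)
    names = tuple(["gamma0", "gamma1"] + [f"s{j}" for j in range(1, knots + 1)])
    return SurvivalFit(
        family=f"spline-k{knots}",
        coef_names=names,
        coefs=np.asarray(res.x, float),
        vcov=vcov,
        loglik=-float(res.fun),
        n_subjects=int(times.size),
        n_events=int(np.sum(events)),
        converged=bool(res.success or res.status == 2) and ok,
        diagnostic="" if ok else "singular information matrix",
        knots=knot_pos,
        data_id=_data_token(times, events),
    )


# ---------------------------------------------------------------------------
# model averaging and summaries
# ---------------------------------------------------------------------------


def ic_weights(ics: Sequence[float]) -> np.ndarray:
    """exp(-Delta_i/2) weights from a vector of information criteria."""
    ics = np.asarray(ics, dtype=float)
    delta = ics - np.min(ics)
    w = np.exp(-delta / 2.0)
    return w / np.sum(w)


def model_average(fits: Sequence[SurvivalFit], criterion: str = "AIC") -> SurvivalFunction:
    """Information-criterion weighted average survival across candidate fits.

    Weights are ``exp(-Delta_i/2)`` normalized, with Delta the AIC or BIC
    difference from the best model; the averaged curve is the weighted mean of
    the component survival functions.
    """
    if len(fits) < 2:
        raise ValueError("model averaging needs at least two fits")
    ids = {f.data_id for f in fits if f.data_id is not None}
    if len(ids) > 1:
        raise ValueError("cannot average fits obtained from different data")
    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    ics = [f.aic if criterion == "AIC" else f.bic for f in fits]
    w = ic_weights(ics)
    fits = list(fits)

    def fn(t):
        return np.sum([wi * evaluate_survival(f, t) for wi, f in zip(w, fits)], axis=0)

    return SurvivalFunction(fn=fn, provenance=f"{criterion}-average",
                            components=fits, weights=w)


def median_survival(fn: SurvivalFunction | SurvivalFit, horizon_months: float = 1200.0,
                    tol: float = 1e-6):
    """Median survival time in months by bracketed root search of S(t) = 0.5.

    Returns :data:`NOT_REACHED` when the curve never crosses 0.5 within the
    search horizon.
    """
    s = fn.sf if isinstance(fn, SurvivalFit) else fn
    if float(s(np.asarray([horizon_months]))[0]) > 0.5:
        return NOT_REACHED
    lo, hi = 0.0, horizon_months
    f = lambda t: float(s(np.asarray([t]))[0]) - 0.5  # noqa: E731
    return float(optimize.brentq(f, lo, hi, xtol=tol))
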