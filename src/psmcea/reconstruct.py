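"""Pseudo-IPD reconstruction from digitized survival curves (Guyot), the
product-limit estimator with Greenwood variance, and log(-log) proportional-
hazards diagnostics.

The reconstruction inverts the Kaplan-Meier estimator: given the digitized
step coordinates and the published number-at-risk table, integer event and
censoring counts are allocated within each risk interval so that (a) the KM
curve of the reconstructed records tracks the digitized coordinates and
(b) the implied number at risk matches the published table at every risk
time.  Censoring within an interval is spread uniformly, the stated
assumption when exact censor times are unknown.  Counts that would go
negative under digitization noise are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import DigitizedCurve, PseudoIPD

__all__ = ["reconstruct_ipd", "km_estimate", "KMEstimate",
           "loglog_curve", "detect_crossing"]


def reconstruct_ipd(curve: DigitizedCurve, max_iter: int = 200) -> PseudoIPD:
    """Reconstruct subject-level records from a digitized curve + risk table.

    The output subject count equals the first risk-table entry exactly.
    """
    t = np.asarray(curve.times, dtype=float)
    s = np.clip(np.asarray(curve.survival, dtype=float), 0.0, 1.0)
    rt = np.asarray(curve.risk_times, dtype=float)
    nr = np.asarray(curve.n_risk, dtype=int)
    if rt.size < 2:
        raise ValueError("need at least two risk-table entries")
    if np.any(np.diff(nr) > 0):
        raise ValueError("risk counts increase over time")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("survival increases over time")

    # coordinate index ranges per risk interval; a final open-ended interval
    # covers coordinates at/after the last risk time
    bounds = list(rt) + [np.inf]
    intervals = []
    for i in range(len(rt)):
        idx = np.where((t >= bounds[i]) & (t < bounds[i + 1]))[0]
        intervals.append(idx)

    event_times: list[float] = []
    censor_times: list[float] = []

    n_hat = int(nr[0])
    s_last_event = 1.0  # KM value at the most recent reconstructed event

    def run_interval(idx, c_total, n_start, s_last, t_end, commit):
        """Allocate c_total censorings uniformly over the interval and derive
        event counts at each digitized step; returns state at interval end."""
        n = n_start
        sl = s_last
        if c_total > 0:
            t_start = t[idx[0]] if idx.size else t_end
            span_end = t_end if np.isfinite(t_end) else (t[idx[-1]] if idx.size else t_start)
            cts = t_start + (np.arange(1, c_total + 1) / (c_total + 1)) * max(
                span_end - t_start, 0.0)
        else:
            cts = np.empty(0)
        for j, k in enumerate(idx):
            if sl > 0:
                d = int(round(n * (1.0 - s[k] / sl)))
            else:
                d = 0
            d = min(max(d, 0), n)
            if d > 0 and n > 0:
                sl = sl * (1.0 - d / n)
            if commit and d > 0:
                event_times.extend([float(t[k])] * d)
            n -= d
            upper = t[idx[j + 1]] if j + 1 < idx.size else t_end
            c_here = int(np.sum((cts >= t[k]) & (cts < upper))) if c_total else 0
            c_here = min(c_here, n)
            if commit and c_here > 0:
                lo = float(t[k])
                hi = float(upper) if np.isfinite(upper) else float(t[k])
                censor_times.extend(
                    (lo + (np.arange(1, c_here + 1) / (c_here + 1)) * (hi - lo)).tolist())
            n -= c_here
        return n, sl

    for i in range(len(rt) - 1):
        idx = intervals[i]
        target = int(nr[i + 1])
        c_total = 0
        prev = None
        for _ in range(max_iter):
            n_end, _ = run_interval(idx, c_total, n_hat, s_last_event,
                                    rt[i + 1], commit=False)
            gap = n_end - target
            if gap == 0 or c_total == prev:
                break
            prev = c_total
            c_total = int(np.clip(c_total + gap, 0, n_hat))
        n_hat, s_last_event = run_interval(idx, c_total, n_hat, s_last_event,
                                           rt[i + 1], commit=True)

    # after the last published risk time: events only, then administrative
    # censoring of the remainder at the last observed coordinate
    idx = intervals[-1]
    n_hat, s_last_event = run_interval(idx, 0, n_hat, s_last_event,
                                       np.inf, commit=True)
    if n_hat > 0:
        t_end = float(t[idx[-1]]) if idx.size else float(max(t[-1], rt[-1]))
        censor_times.extend([t_end] * n_hat)

    times = np.concatenate([np.asarray(event_times, float),
                            np.asarray(censor_times, float)])
    events = np.concatenate([np.ones(len(event_times), dtype=int),
                             np.zeros(len(censor_times), dtype=int)])
    order = np.argsort(times, kind="stable")
    return PseudoIPD(times[order], events[order], curve.arm, curve.endpoint)


# ---------------------------------------------------------------------------
# Kaplan-Meier with Greenwood variance
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    """Product-limit estimate with Greenwood standard errors.

    Arrays are aligned over the distinct event times (time 0 included with
    S=1, SE=0); ``n_risk``/``n_events`` give the risk set and event count at
    each time.
    """

    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])

    def se_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.se[max(i, 0)])

    @property
    def max_time(self) -> float:
        return float(self.times[-1])


def km_estimate(ipd: PseudoIPD) -> KMEstimate:
    """Kaplan-Meier estimate with Greenwood variance
    Var(S(t)) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i)),
    ties at a time point processed together."""
    t = ipd.times
    e = ipd.events
    uniq = np.unique(t[e == 1])
    times = [0.0]
    surv = [1.0]
    se = [0.0]
    n_risk = [len(ipd)]
    n_ev = [0]
    s = 1.0
    gw = 0.0  # Greenwood cumulative sum
    for ti in uniq:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum(e[t == ti]))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            gw += d_i / (n_i * (n_i - d_i))
            se_i = s * np.sqrt(gw)
        else:
            se_i = 0.0  # curve hits zero; Greenwood variance degenerates
        times.append(float(ti))
        surv.append(s)
        se.append(float(se_i))
        n_risk.append(n_i)
        n_ev.append(d_i)
    return KMEstimate(np.asarray(times), np.asarray(surv), np.asarray(se),
                      np.asarray(n_risk), np.asarray(n_ev),
                      ipd.arm, ipd.endpoint)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics
# ---------------------------------------------------------------------------


def loglog_curve(km: KMEstimate) -> np.ndarray:
    """(log t, log(-log S(t))) series over points with S strictly in (0, 1).

    Returns an array of shape (m, 2); raises if fewer than two usable points.
    """
    mask = (km.survival > 0.0) & (km.survival < 1.0) & (km.times > 0.0)
    if int(np.sum(mask)) < 2:
        raise ValueError("fewer than two usable points for a log(-log) curve")
    x = np.log(km.times[mask])
    y = np.log(-np.log(km.survival[mask]))
    return np.column_stack([x, y])


def detect_crossing(series_a: np.ndarray, series_b: np.ndarray) -> bool:
    """Whether two log(-log) survival series intersect over common support.

    Both series are interpolated onto the shared log-time range; a sign
    change of their difference (beyond interpolation jitter) flags crossing.
    """
    a, b = np.asarray(series_a, float), np.asarray(series_b, float)
    lo = max(a[0, 0], b[0, 0])
    hi = min(a[-1, 0], b[-1, 0])
    if hi <= lo:
        return False
    grid = np.linspace(lo, hi, 200)
    fa = np.interp(grid, a[:, 0], a[:, 1])
    fb = np.interp(grid, b[:, 0], b[:, 1])
    diff = fa - fb
    tol = 1e-9
    return bool(np.any(diff > tol) and np.any(diff < -tol))
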