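"""Pairwise economic outcomes (ICER, INHB, INMB) and survival-probability
number needed to treat with Altman-style confidence intervals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import StrategyResult
from .reconstruct import KMEstimate
from .survival import SurvivalFunction

__all__ = ["PairwiseComparison", "NNTResult", "compare", "nnt_at_time"]

DOMINANT = "dominant"          # more QALYs at lower cost
DOMINATED = "dominated"        # fewer (or equal) QALYs at higher cost


@dataclass
class PairwiseComparison:
    """Incremental outcomes of an intervention against a comparator at
    willingness-to-pay lambda ($/QALY)."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    wtp: float
    icer: float | None          # $/QALY; None when tagged
    icer_per_ly: float | None
    dominance: str | None       # "dominant" | "dominated" | None
    inhb: float                 # QALYs: dQ - dC/lambda
    inmb: float                 # $: dQ*lambda - dC


def compare(a: StrategyResult, b: StrategyResult, wtp: float) -> PairwiseComparison:
    """Incremental comparison of strategy ``a`` (intervention) vs ``b``.

    The ICER is computed from unrounded totals; it is replaced by a dominance
    tag when the QALY increment is non-positive (dominated if also costlier)
    or when the intervention saves money while gaining QALYs (dominant).
    """
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    dc = a.total_cost - b.total_cost
    dq = a.total_qalys - b.total_qalys
    dly = a.total_lys - b.total_lys
    dominance = None
    icer = icer_ly = None
    if dq > 0 and dc < 0:
        dominance = DOMINANT
    elif dq <= 0 and dc >= 0 and not (dq == 0 and dc == 0):
        dominance = DOMINATED
    elif dq != 0:
        icer = dc / dq
    if dly != 0 and dominance is None:
        icer_ly = dc / dly
    return PairwiseComparison(
        intervention=a.name, comparator=b.name,
        delta_cost=dc, delta_ly=dly, delta_qaly=dq, wtp=wtp,
        icer=icer, icer_per_ly=icer_ly, dominance=dominance,
        inhb=dq - dc / wtp, inmb=dq * wtp - dc,
    )


@dataclass
class NNTResult:
    """Number needed to treat at a fixed time point.

    ``nnt`` is the signed reciprocal of the survival difference (negative
    when the comparator is favoured); the confidence bounds are reciprocals
    of the difference CI bounds.  When the difference CI spans zero the
    interval is the Altman NNTB-to-infinity-to-NNTH form, rendered with the
    signed-notation bounds and flagged by ``ci_spans_zero``.
    """

    time_months: float
    s1: float
    s2: float
    delta: float
    se_delta: float | None
    nnt: float
    ci_low: float | None
    ci_high: float | None
    ci_spans_zero: bool = False


def _surv_and_se(curve, t: float) -> tuple[float, float | None]:
    if isinstance(curve, KMEstimate):
        if t > curve.max_time:
            raise ValueError(f"t={t} beyond the curve's observed support")
        return curve.survival_at(t), curve.se_at(t)
    if isinstance(curve, SurvivalFunction) or callable(curve):
        return float(np.asarray(curve(np.asarray([t])))[0]), None
    raise TypeError("curve must be a KMEstimate or SurvivalFunction")


def nnt_at_time(curve1, curve2, t_months: float, z: float = 1.959963984540054
                ) -> NNTResult:
    """NNT = 1 / (S1(t) - S2(t)) with a Greenwood-based CI when both inputs
    are Kaplan-Meier estimates (SE(d) = sqrt(SE1^2 + SE2^2)); parametric
    curves give a point estimate only."""
    s1, se1 = _surv_and_se(curve1, t_months)
    s2, se2 = _surv_and_se(curve2, t_months)
    delta = s1 - s2
    nnt = np.inf if delta == 0 else 1.0 / delta
    se = None
    lo = hi = None
    spans = False
    if se1 is not None and se2 is not None:
        se = float(np.hypot(se1, se2))
        d_lo, d_hi = delta - z * se, delta + z * se
        spans = d_lo < 0 < d_hi
        # reciprocals preserve the printed sign convention; when the delta CI
        # spans zero the bounds are NNTB (from d_hi) and NNTH (from d_lo)
        lo = np.inf if d_hi == 0 else 1.0 / d_hi
        hi = np.inf if d_lo == 0 else 1.0 / d_lo
    return NNTResult(time_months=t_months, s1=s1, s2=s2, delta=delta,
                     se_delta=se, nnt=float(nnt), ci_low=lo, ci_high=hi,
                     ci_spans_zero=spans)
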