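"""Value attribution for a combination regimen under imperfect information.

Allocates the combination's incremental QALYs (vs the common comparator)
between the backbone regimen and the add-on component.  The scheme is
price-independent: it uses only incremental QALYs and the willingness-to-pay
threshold.  With the remainder R = dQ_combo - dQ_backbone:

* balanced market power  - the backbone keeps its standalone increment,
  the add-on receives the whole remainder R;
* imbalanced market power - the backbone additionally captures a share of
  the remainder (half, by default), reflecting asymmetric bargaining.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AttributionResult", "attribute"]

SCENARIOS = ("unallocated", "balanced", "imbalanced")


@dataclass
class AttributionResult:
    scenario: str
    dq_combo: float           # combination vs comparator, QALYs
    dq_backbone: float        # backbone alone vs comparator, QALYs
    wtp: float
    backbone_qalys: float
    addon_qalys: float
    backbone_value: float     # dollars = QALYs * wtp
    addon_value: float
    backbone_share: float     # fraction of dq_combo
    addon_share: float
    flagged: bool = False     # inputs violated dq_combo >= dq_backbone >= 0

    @property
    def total_value(self) -> float:
        return self.dq_combo * self.wtp


def attribute(dq_combo: float, dq_backbone: float, wtp: float,
              scenario: str = "balanced",
              imbalance_split: float = 0.5) -> AttributionResult:
    """Allocate the combination's incremental value between components.

    ``imbalance_split`` is the share of the remainder the backbone captures
    in the imbalanced scenario (0.5 = an even split of the add-on's
    remainder).  ``unallocated`` reports totals only (everything on the
    combination, nothing attributed to the backbone beyond its standalone
    increment).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario '{scenario}'; choose from {SCENARIOS}")
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    if not 0.0 <= imbalance_split <= 1.0:
        raise ValueError("imbalance_split must lie in [0, 1]")
    flagged = not (dq_combo >= dq_backbone >= 0)

    remainder = dq_combo - dq_backbone
    if scenario == "balanced":
        backbone = dq_backbone
    elif scenario == "imbalanced":
        backbone = dq_backbone + imbalance_split * remainder
    else:  # unallocated: totals only
        backbone = dq_backbone
    addon = dq_combo - backbone

    denom = dq_combo if dq_combo != 0 else float("nan")
    return AttributionResult(
        scenario=scenario, dq_combo=dq_combo, dq_backbone=dq_backbone,
        wtp=wtp,
        backbone_qalys=backbone, addon_qalys=addon,
        backbone_value=backbone * wtp, addon_value=addon * wtp,
        backbone_share=backbone / denom, addon_share=addon / denom,
        flagged=flagged,
    )
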