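# psmcea

A partitioned-survival cost-effectiveness model of first-line therapy for
**BRAF V600E-mutant metastatic colorectal cancer**, comparing encorafenib +
cetuximab with mFOLFOX6 chemotherapy (`EC+mFOLFOX6`), encorafenib + cetuximab
alone (`EC`), and investigator's-choice chemotherapy (`SOC`) from a US payer
perspective — together with the supporting methodology as a reusable,
tested library:

- **Synthetic trial data**: simulate right-censored arms from any supported
  family and render the "digitized curve + number-at-risk table" artifact a
  graph digitizer produces (`psmcea.synthetic`);
- **Pseudo-IPD reconstruction** from digitized Kaplan–Meier curves (the
  Guyot inversion), product-limit estimation with Greenwood variance, and
  log(−log) proportional-hazards diagnostics (`psmcea.reconstruct`);
- **Survival extrapolation**: seven standard parametric families
  (exponential, Weibull, Gompertz, log-logistic, log-normal, gamma,
  generalized gamma) plus Royston–Parmar splines with 1–3 knots, AIC/BIC
  model averaging with weights `w_i ∝ exp(−Δ_i/2)` (`psmcea.survival`);
- **Economic engine**: a three-state partitioned survival model
  (`PFS(t)`, `PD(t) = OS(t) − PFS(t)`, `1 − OS(t)`) on weekly cycles with
  half-cycle correction, six cost categories, age-adjustable utilities,
  adverse-event and time-to-death disutilities, 3 % annual discounting
  (`psmcea.engine`);
- **Decision outcomes**: ICER, INHB `= ΔQ − ΔC/λ`, INMB `= ΔQ·λ − ΔC`, and
  number needed to treat `NNT = 1/(S₁(t) − S₂(t))` with Altman/Greenwood
  confidence intervals (`psmcea.evaluate`);
- **Uncertainty**: one- and two-way deterministic sensitivity analysis,
  probabilistic sensitivity analysis with Cholesky-correlated survival
  coefficient draws, acceptability curves, per-person EVPI
  `= E[max_s NMB_s] − max_s E[NMB_s]`, and five scenario analyses
  (`psmcea.sensitivity`);
- **Value attribution** for combination regimens under balanced/imbalanced
  market power, a pure function of incremental QALYs and the threshold
  (`psmcea.attribution`).

Every input of the published base case — survival coefficients with their
variance–covariance matrices, unit costs, adverse-event incidences,
disutilities, utilities and general settings — ships as a validated YAML
fixture (`psmcea.base_case_fixture()`), so the whole analysis reruns from a
clean install with no downloads.

## Worked example

```python
import psmcea
from psmcea import compare

config = psmcea.base_case_fixture()
results = psmcea.run_all(config)
c = compare(results["EC+mFOLFOX6"], results["SOC"],
            config.settings.wtp_per_qaly)
print(f"dC ${c.delta_cost:,.0f}  dQALY {c.delta_qaly:.3f}  "
      f"ICER ${c.icer:,.0f}/QALY")
```

prints

```
dC $695,622  dQALY 1.390  ICER $500,462/QALY
```

i.e. adding the targeted combination in first line buys 1.39
quality-adjusted life-years over chemotherapy at ≈ $696k — an ICER of
≈ $500k per QALY, more than three times the $150,000/QALY willingness-to-pay
threshold, so chemotherapy remains the cost-effective option. The
`examples/` directory walks through each capability (base case,
reconstruction, extrapolation, PSA/tornado/price maps, NNT and value
attribution, scenarios) with commented output.

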