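# Methods

## Model structure

The model is an area-under-the-curve partitioned survival model (PSM) with
three mutually exclusive states: progression-free (PFS), progressed disease
(PD) and death. State occupancy is read directly off the arm-specific
survival curves rather than derived from transition probabilities:
`pfs(t) = S_PFS(t)`, `pd(t) = max(S_OS(t) − S_PFS(t), 0)`,
`dead(t) = 1 − S_OS(t)`. The PD clamp is counted and surfaced as a warning
when it affects more than 20 % of cycle boundaries, since persistent
PFS > OS indicates incompatible curves rather than digitization noise.

Cycles are one week long; boundaries sit at `k` weeks for
`k = 0 … floor(horizon_years · 365.25 / 7)` (1,565 cycles over the 30-year
base-case horizon). Occupancy between boundaries uses trapezoidal half-cycle
correction (the mean of adjacent boundary values). Calendar conversions use
30.4375 days/month and 365.25/7 ≈ 52.18 weeks/year throughout; the 52.18
convention is load-bearing — it is what reproduces the published
adverse-event disutility cell (0.00116 QALY) where division by 52 does not.
Discounting is `(1 + r)^(−t)` in years at an annual rate of 3 %, applied at
cycle midpoints for flows and at the event cycle for per-event costs;
one-off model-initiation items (adverse-event cost and disutility, the
one-time mutation test) are undiscounted at `t = 0`.

## Survival inputs and extrapolation

The base case evaluates closed-form survival functions from published
coefficient tables: log-logistic OS and PFS for both
encorafenib-plus-cetuximab arms, log-normal PFS and gamma OS for the
chemotherapy arm. Coefficients are carried on the *estimation scale* —
logarithms for strictly positive parameters (log-logistic scale/shape,
gamma rate/shape, log-normal sdlog), identity for location parameters —
because exponentiating the printed values reproduces the trial medians
(e.g. `exp(3.32) ≈ 27.7` months against a 30.3-month observed OS median),
whereas a natural-scale reading does not. Multivariate-normal uncertainty
is defined on this scale with the published variance–covariance matrices,
which guarantees positive natural-scale parameters in every probabilistic
draw.

The refitting pipeline (used by the scenario analyses and available
generally) estimates any of seven families by right-censored maximum
likelihood: quasi-Newton (BFGS) on the estimation scale with three
fixed-seed random restarts — the Gompertz and generalized-gamma likelihoods
can be multimodal on small samples — and the variance–covariance matrix
taken as the inverse observed information (numerical Hessian).
Non-convergence is flagged on the fit object, never silent. The generalized
gamma uses the stable (mu, sigma, Q) parameterization to avoid the overflow
pathologies of the shape–rate form. Flexible models are Royston–Parmar
restricted cubic splines on the log cumulative-hazard scale in log time,
with internal knots at event-time quantiles and boundary knots at the
extreme event times; the 0-knot model is exactly a Weibull
reparameterization, which the tests exploit as an identity check. Model
averaging weights candidate fits by `exp(−Δ_i/2)` on AIC or BIC; BIC's
sample size is the number of subjects (one documented convention, applied
consistently). Medians and other quantiles come from bracketed root search
with a 1e-6 month tolerance; a curve that never crosses the target within
the 100-year search horizon reports "not reached".

## Pseudo-IPD reconstruction

Subject-level records are rebuilt from digitized step coordinates plus the
number-at-risk table by inverting the Kaplan–Meier estimator: within each
risk interval, integer censoring counts are spread uniformly (the stated
assumption when exact censor times are unknown) and adjusted iteratively
until the implied number at risk matches the published table at the next
risk time; event counts at each digitized step follow from the survival
ratio to the running product-limit estimate, clamped at zero when
digitization noise implies a negative count. After the last published risk
time no further censoring is assumed and the remaining cohort is
administratively censored at the final coordinate. The reconstruction
returns exactly the initial number at risk and, with full risk reporting at
every event time, reproduces the source Kaplan–Meier curve exactly; with a
6-monthly risk grid and n = 300 it tracks the source within 0.02 survival
probability (tested). Greenwood's formula supplies the variance of the
product-limit estimate; the proportional-hazards diagnostic transforms the
curve to `(log t, log(−log S))` and flags crossing of two arms' series over
their common support.

## Synthetic trial data

Because the real inputs are digitized published curves, the package
generates its own: latent event times drawn from any supported family,
censored by the minimum of an administrative cutoff and an exponential
dropout time (constant monthly rate, independent of the event process — the
simplest mechanism consistent with the independent-censoring assumption of
the product-limit estimator). The default trial emulation uses 300 subjects
per arm, a 36-month administrative cutoff and 0.3 %/month dropout — a
plausible phase-3 read-out for this disease setting — with risk tables on a
6-month grid (the reporting interval is not fixed by the source material
and is exposed as a setting). What the generator does **not** emulate:
digitizer measurement error beyond optional Gaussian jitter, reporting
granularity of published curves, interval censoring, or dependence between
censoring and prognosis. Passing round-trip tests therefore demonstrates
correctness of the reconstruction algebra, not robustness to real
digitization artifacts.

## Costs

Six categories accrue per strategy, all in July-2025 US dollars as given by
the input table (no further inflation step):

- **Drug acquisition** — dose rules per component (fixed mg/day, per m²
  with BSA 1.97 m², per kg with weight 83.35 kg), fractional per-mg pricing
  without vial rounding, times the published relative dose intensity
  (encorafenib 91.7 %, cetuximab 94.2 %); accrues on PFS occupancy
  (treatment to progression, no stopping rule).
- **Administration** — per-administration event maps (first-hour infusion,
  additional hour, IV push, prolonged >8 h infusion, additional sequential
  infusion) at fee-schedule unit costs, on PFS occupancy.
- **Monitoring** — radiographic assessment every 6 weeks and consultation
  every 2 weeks during PFS, plus a one-time mutation test at entry. The
  6-week scan interval matches the trial's radiographic assessment schedule
  and reproduces the published monitoring cells across all three arms to
  about 5 %.
- **Adverse events** — grade ≥3 events with ≥5 % incidence in any arm;
  `Σ incidence × unit cost` as a one-off at model initiation.
- **Subsequent treatment** — a weekly rate on PD occupancy.
- **End of life** — a per-death unit cost at the death cycle. The published
  per-arm end-of-life totals exceed the unit cost itself, which discounted
  expected one-off costs cannot do; an unstated extra step is suspected in
  the source. The engine exposes an end-of-life multiplier (default 1.0,
  i.e. no attempt to match that cell) and the cell is excluded from the
  reproduction checks; the residual effect on total costs is under 1 %.

The chemotherapy comparator is investigator's choice in the source trial
and its composition is not published. It is modelled as mFOLFOX6 with
bevacizumab 5 mg/kg every 2 weeks in a configurable fraction of patients
(default 0.80, calibrated so that comparator drug acquisition reproduces
the published cell; bevacizumab adds no separately billed administration
event since it is given within the same infusion encounter).

## Utilities

State utilities are 0.80 (PFS) and 0.73 (PD). The source derives
multipliers (0.973, 0.888) against the age/sex general-population norm of
0.822 (Ara–Brazier regression, age 61, 50 % male) and describes updating
them each cycle; the published per-arm QALY/life-year ratios equal
0.80 and 0.73 to four decimals in all six cells, i.e. numerically the
multiplier was re-derived each cycle and the pipeline collapses to constant
state utilities. The default mode (`constant`) therefore applies the state
utilities directly — reproducing the published table — while
`aging-multiplier` mode fixes the baseline multiplier and lets utilities
decline with the population norm as the cohort ages (the regression is
evaluated with age capped at 100, its supported range).

Adverse-event disutilities apply once at model initiation as
`Σ incidence × decrement × (1 week / 52.18 weeks)`, reflecting the
assumption that severity resolves within about a week. Time-to-death
disutilities apply per new death as
`Σ decrement_p × window_p / 365.25 × scale`: the face-value sum of the
published decrements over their 30/60/90-day windows is 0.0452 QALY per
death, roughly 16× the published per-arm cells (~0.0028 per discounted
death). The mapping the source used is unstated; the engine implements the
stated formula with a configurable scale whose default (1/16 = 0.0625)
reproduces the magnitude implied by the published table. Setting the scale
to 1.0 recovers the face-value formula; the choice moves total QALYs by
about 1.5 % and the affected cell is excluded from the reproduction checks.

## Uncertainty analysis

**Deterministic.** Each input moves to its published 95 % CI bounds (±10 %
where no interval is published), all else at base case, and the pairwise
ICER is recorded; survival coefficients vary marginally to their printed
limits. Entries are ranked by absolute ICER swing. The two-way price map
scales two drugs' unit costs over a fraction grid and reports the
NMB-maximal strategy at each point.

**Probabilistic.** 5,000 iterations; beta draws for probabilities,
utilities and dose intensities, gamma for costs (shape 384.16 — a 5.1 %
coefficient of variation — with scale = mean/shape, since the printed
2-decimal scale values are rounded), normal for cohort measurements with
the standard error back-calculated as (UL − LL)/(2·1.96), and one
multivariate-normal draw per survival block via Cholesky factorization
(near-indefinite matrices are repaired by minimal diagonal jitter;
genuinely non-PSD matrices raise). Time horizon and discount rate — the
two inputs the source assigns uniform ranges — are treated as structural
and held at base case in the probabilistic analysis, following standard
practice of varying methodological settings deterministically only.
Iterations are seeded from per-iteration substreams spawned off the master
seed, so results are reproducible and order-independent. Hard bound
violations (e.g. a probability above 1) trigger a resample capped at 100
attempts; failed iterations are recorded and excluded, and more than 1 %
failures aborts the run. Acceptability curves report the fraction of
iterations in which each strategy's net monetary benefit is maximal (ties
break toward the cheaper strategy); EVPI is
`mean(max_s NMB_s) − max_s(mean NMB_s)` per person, clipped at zero against
floating-point dust. ICER intervals are 2.5/97.5 percentiles of the
iteration-wise ratio; these are unstable when the QALY increment crosses
zero, and the acceptability curve is the better summary in that regime.

**Scenarios.** (1) spline extrapolation, (2) AIC-weighted and (3)
BIC-weighted model averages — all three refit from pseudo-IPD produced by
the full synthetic pipeline (simulate → render → reconstruct), since the
source's spline coefficients are not published and these scenarios are
exercised structurally; (4) progression-based utilities only (state
utilities without adverse-event or time-to-death decrements); (5) relative
dose intensity removed. Scenarios 4 and 5 reproduce the published ICERs to
better than 1 %.

## NNT and value attribution

NNT at a time point is the signed reciprocal of the survival difference,
with the difference's standard error from Greenwood variances
(`SE(Δ) = √(SE₁² + SE₂²)`) when both inputs are Kaplan–Meier estimates and
confidence bounds as reciprocals of the Δ interval; when that interval
spans zero the bounds follow the NNTB-to-∞-to-NNTH convention, flagged on
the result. Both Kaplan–Meier and parametric backends are provided, since
the source does not state which feeds its printed values; the parametric
backend reproduces the printed 12-month mortality NNT within the stated
±1 tolerance.

Value attribution splits the combination's incremental QALYs (vs the
common comparator) between the backbone doublet and the chemotherapy
add-on. With remainder `R = ΔQ_combo − ΔQ_backbone`: balanced market power
gives the backbone its standalone increment and the add-on all of `R`;
imbalanced market power additionally grants the backbone a share of `R`
(default half — the split that reproduces the published 70.3 %/29.7 %
allocation exactly, exposed as a parameter since the general framework does
not pin it down). Monetary values are unrounded QALY allocations times the
$150,000/QALY threshold. The allocation is deliberately independent of
every cost input.

## Numerical conventions and edge cases

- Survival evaluations are clipped to [0, 1]; negative times raise.
- All-censored data cannot be fit (error); an all-censored reconstruction
  is valid and yields a flat curve.
- Degenerate knot placement (duplicated quantiles) raises before fitting.
- A curve that implies increasing survival or an increasing risk table is
  rejected at construction.
- `ModelConfig` rejects unknown keys, asymmetric or indefinite covariance
  blocks, negative costs, and out-of-range discount rates at load time;
  every run can emit a manifest (config hash, seed, warnings) for audit.

## Known limitations

- The comparator drug basket, the end-of-life inflation step and the
  time-to-death disutility mapping are under-determined by the source;
  each is exposed as an explicit configuration knob with the calibration
  documented above rather than hidden in code.
- Refit scenarios 1–3 run against synthetic reconstructions, not the
  original trial curves, so their ICERs characterize the pipeline rather
  than reproduce printed values.
- The engine is a cohort model: no individual-level microsimulation, vial
  sharing/wastage, treatment waning or stopping rules beyond the scenarios
  described; no competing risks or interval censoring in reconstruction.
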