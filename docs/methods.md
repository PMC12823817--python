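# Methods

## Statistical model

Disproportionality analysis treats the spontaneous-report database as a
case/non-case universe and asks whether reports mentioning a drug carry
the target event more often than the background. All four estimators are
functions of the per-drug 2×2 table (a, b, c, d) with N = a+b+c+d:

| statistic | point estimate | interval |
|---|---|---|
| ROR | ad/(bc) | exp(ln ROR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d) |
| PRR | a(c+d)/(c(a+b)) | Pearson χ² (no continuity correction) |
| IC | log₂[aN/((a+c)(a+b))] | IC025 = IC − 2·√V(IC) |
| EBGM | aN/((a+c)(a+b)) | EBGM05 = exp(ln EBGM − z·SE), z = 1.645 |

None of these is a causal effect: they estimate *reporting*
disproportion, subject to underreporting, stimulated reporting and
confounding by indication. The package computes them, their standard
signal criteria (ROR CI low > 1 with a ≥ 3; PRR ≥ 2 with χ² ≥ 4 and
a ≥ 3; IC025 > 0; EBGM05 > 2), a combined `any`/`all_four` flag pair,
and the IC025 risk bands (low (0, 1.5], moderate (1.5, 3], high > 3).

Deliberate modeling choices, made where published practice is ambiguous
and checked against the published per-drug values of the worked example:

* **EBGM here is the unshrunk relative reporting ratio.** The full MGPS
  applies an empirical-Bayes gamma-mixture posterior to shrink small-count
  cells. The published formula and values this package reproduces are the
  raw ratio aN/((a+c)(a+b)); no shrinkage is applied, so EBGM = 2^IC is
  an exact identity here (and is enforced by a property test). At small a
  our EBGM is therefore biased upward relative to true MGPS output.
* **EBGM05 uses z = 1.645**, the one-sided 5th percentile. Published
  EBGM05 values in this literature are numerically consistent with 1.645
  even when the accompanying formula prints 1.96; both are available
  (`ebgm05_z`), 1.645 is the default, and the choice is recorded in the
  CLI flag rather than hidden.
* **V(IC)**: the credible interval has the form E(IC) ± 2√V(IC), but
  V(IC) is rarely printed. The default is the delta-method variance of
  log₂(a) under Poisson noise in the a cell, √V(IC) = 1/(ln2·√a), which
  reproduces the published IC−IC025 gaps of the worked example across
  a ∈ {18, …, 625} to within 0.02 bits. The full Bate-style posterior
  expansion (uniform priors, γ tuned so E(IC) = 0 under independence) is
  available via `ic_variant="bate"`; the two agree to a few hundredths of
  a bit at large a and diverge at small a, where the posterior mean is
  shrunk.
* **Counting universe.** Published footnotes describe the cells as
  "reports", but the printed statistics of the worked example are
  internally consistent only with a *reaction-record* universe
  (N = 53,463,446 REAC records, not 21,838,627 deduplicated reports):
  reconstructing bupivacaine's table from a = 31, a+c = 5,787 under the
  record universe reproduces the printed χ² = 2204.18, EBGM = 73.08 and
  IC = 6.19 to rounding, whereas the report universe gives χ² ≈ 2179.
  Both universes are implemented (`universe="records"|"reports"`); the
  record universe is the default. Under it, a report with k matching PTs
  and the drug contributes k records to a; under the report universe it
  contributes 1.
* **Zero cells** make ROR/EBGM undefined; the statistics return NaN
  (never raise), NaN fails every criterion, and an optional Haldane
  correction (+0.5 to every cell, applied only when a zero cell is
  present) is available but off by default — drugs analyzed at a ≥ 3 in a
  large database never trigger it.
* **Outcome collapsing.** FAERS reports may carry several outcome codes;
  summaries need one per report. The default severity precedence is
  DE > LT > DS > CA > RI > HO > OT (configurable); no published collapse
  rule exists, so this is an explicit package choice.
* **Drug roles.** Exposure defaults to suspect roles {PS, SS};
  concomitant/interacting {C, I} can be included with `roles="all"`.
  Whether published analyses count concomitants is typically unstated;
  the default is the conservative choice.
* **Dedup tie-breaking.** "Higher PRIMARYID" is compared numerically when
  both ids parse as integers, lexicographically otherwise; unparseable
  FDA dates sort as the minimal date so any dated version of a case wins.
* **Display rounding** (2 decimals, half away from zero) happens only in
  the report layer (`rank_report`); every comparison in the test suite
  uses unrounded values.

## Inversion oracle

Published per-drug tables print a and the point statistics but not b and
d. Because a+c and N are fixed study-wide, the point ROR determines the
missing cells: b solves b = a·(N−a−c−b)/(ROR·c), an affine fixed-point
problem. The update is damped (averaged) because the plain iteration has
slope −b/d and oscillates at the independence point; in the b ≪ d regime
of any real database it converges in ≤ 5 iterations, and a property test
checks that b is recovered to ±1 from any synthetic table's own ROR.
Reconstruction tolerances used when verifying published rows: 0.1%
relative on ROR CI bounds, 1% on PRR/χ²/EBGM/EBGM05 (absorbing the
2-decimal rounding of the printed ROR that seeds the inversion), and
0.02 bits absolute on IC/IC025.

## Synthetic-data generator

`synthetic_data.generate` draws, per report: demographics from facet
margins (defaulting to the worked example's case-set distribution);
a drug set via independent Bernoulli exposures from the catalog (a
weighted fallback drug keeps every report non-empty — with the default
catalog ~3% of reports take it); the target event with probability
min(1, q₀·∏λ) over planted drugs present, where q₀ ≈ 0.01 is the
baseline implied by the PT catalog; one weighted target PT when the
event fires, plus independent background PTs (weighted fallback so every
report has ≥ 1 reaction); and, with probability `duplicate_rate`
(default 0.05), a content-identical re-report with a later FDA_DT and
higher PRIMARYID. Randomness is split into stage-keyed substreams
spawned from the config seed, so output is reproducible byte-for-byte
and one stage's draw count cannot perturb another's.

The planted multiplier acts on the event probability *conditional on
exposure* — the estimand of the reporting-ratio statistics — and the
ground truth records the nominal λ, the realized (cap-adjusted)
multiplier, the analytic report-level odds ratio implied by the
generative model, the realized report-level table, and the exact
duplicate pairs.

The standard parameter-recovery scenario (`calibration_config`) uses
50,000 reports, twelve null background drugs, and two planted drugs at
2% exposure with λ = 2 and λ = 10. At those sizes the λ = 10 drug yields
a ≈ 100 target-event co-occurrences, enough that all four criteria fire
essentially always, while λ = 2 sits near the detection boundary. The
acceptance suite runs 100 seeds of this scenario (~2 minutes) and
checks: the BCPNN false-positive rate on null drugs stays within twice
the simulation SE of its nominal one-sided level Φ(−2) ≈ 2.3%; the
λ = 10 drug is flagged by all four algorithms in ≥ 95 seeds; and the
report-level ROR CI covers the generating odds ratio at roughly its
nominal 95% level (asserted ≥ 88%, i.e. the check guards
under-coverage; mild conservatism passes).

What the generator does *not* emulate — and hence what passing tests do
not establish about real FAERS data: correlated drug co-prescription and
polypharmacy structure, event-dependent reporting propensity
(stimulated reporting, the Weber effect), content-divergent duplicates
(only key-level duplicates are generated, matching exactly what the
dedup rule can see), concomitant-role exposure (synthetic drugs are all
suspects; role filtering is exercised by hand fixtures), reporting
trends over time, and multiple target PTs on one report (the generator
emits at most one, which also makes the a cell identical under both
counting universes).

## Scale and determinism of the checks

All published-value checks are desk-scale and deterministic (inversion
oracle; < 1 s). The stochastic suite uses 100 seeds × 50,000 reports,
chosen to keep the whole test run around two minutes while leaving the
binomial simulation error on the checked rates well below the asserted
margins. The headline counts of the worked example (5,787 cases among
21.8M reports, 1,141 drugs, 30/19 positive-signal tallies) depend on the
full FAERS extract and the licensed MedDRA term list, and are out of
scope; the shipped PT list is illustrative and not MedDRA-derived.

## Known limitations

* Only the post-2012 FAERS ASCII layout is parsed (no legacy ISR files,
  no THER/INDI/RPSR tables, no XML distributions).
* Drug-class labels are pass-through configuration, not computed (no ATC
  lookup).
* The `bate` IC variant implements the closed-form posterior expansion,
  not MCMC; at very small a it and the calibrated default legitimately
  disagree.
* Country normalization is a small configurable name map, not a full
  ISO gazetteer.
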