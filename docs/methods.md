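# Methods

## Model overview

`cannacea` is an individual-patient (microsimulation) state-transition
model of chronic peripheral neuropathic pain treatment over 6-week
cycles, comparing four strategies that differ only in when smoked
cannabis is added to sequenced standard therapy: never, or together with
the 1st, 2nd, or 3rd standard agent.  Outcomes are discounted 2017-USD
costs (health-care sector perspective: third-party payer plus patient
out-of-pocket) and QALYs.

A patient's trajectory is driven by five per-cycle assessments — adverse
events, SAE mortality, adherence, pain relief, switching — described in
`engine.py`.  The model deliberately contains **no background mortality**
and **no latent long-term cannabis harms**: death is reachable only
through the serious-adverse-event pathway, because the adverse-event
evidence base for medicinal cannabis regimens spans at most one year.
Results beyond the 1-year horizon are therefore exploratory.

## Inputs

All inputs live in `src/cannacea/data/default_parameters.yaml`, one typed
distribution per parameter (family, mean, dispersion or CI).  Point
estimates drive the base case; the distributions drive probabilistic
sensitivity analysis (PSA) and the method-of-moments fits used for
patient-level draws.  Key values, with units:

| parameter | value | units / role |
|---|---|---|
| baseline age | Normal(59.72, 9.79), truncated ≥ 18 | years |
| baseline pain | Normal(6.20, 1.52), truncated to [4, 10] | 0–10 Likert; everyone starts moderate-to-severe |
| pain-score reductions | Normal per drug; cannabis 1.11 (2.38) | Likert points; drawn once per patient-drug |
| adverse-event probabilities | Beta per drug/class | per cycle |
| cannabis AE odds ratios | 1.74 (nonserious), 1.08 (serious); non-user variants 2.07 / 1.77 | applied on the odds scale to the standard agent's rates during co-use |
| adherence | Beta per drug (cannabis 0.84, SD from its CI/4) | fraction of doses taken; flag = draw ≥ τ |
| adherence threshold τ | 0.8 (Triangular(0.5, 0.8, 1.0) in PSA only) | minimum adherence to count as adherent |
| utilities | mild 0.7, moderate-severe 0.39; decrements 0.05/0.11/0.12 | QALY weights per cycle |
| drug costs | wholesale + OOP per 1-month supply, prorated ×42/30.4375 | USD per cycle |
| cannabis cost | 0.067 g THC/day ÷ 0.125 potency × $11.06/g × 42 d ≈ $248.98 | USD per cycle; wastage divides the purchased grams by (1 − 0.389) in its scenario |
| discounting | 3 %/yr, factor (1.03)^(−t) at cycle start | t in years |

The conversion between 100-point VAS and the 11-point Likert scale is a
fixed ÷10 (`convert_vas100_to_likert11`).

## Cycle mechanics and structural choices

Where the model description leaves structure open, the package makes an
explicit choice, exposed as an `EngineOptions` switch with the default
listed here:

* **Horizon discretization.**  One year = 52/6 ≈ 8.67 six-week cycles:
  8 full cycles plus a final cycle accrued at weight 2/3 (5- and 10-year
  horizons analogously).  This preserves the calendar-time QALY ceiling
  (≤ 0.7 × years).
* **Fixed per-episode draws.**  A patient's pain-score reduction and
  adherence flag for a drug are drawn once and reused every cycle on that
  drug; a non-responder therefore fails the two-cycle poor-relief rule
  deterministically.  Per-cycle redraw is available
  (`redraw_responses=True`).
* **Adverse-event severity.**  Tolerable/intolerable/serious are
  independent Bernoulli draws each cycle with precedence serious >
  intolerable > tolerable (the published class probabilities are not
  mutually exclusive complements).  During co-use, intolerable risks of
  the agent and cannabis combine as independent risks; nonserious and
  serious rates are odds-ratio-modified.  A patient adherent to nothing
  experiences neither relief nor adverse events.
* **Costs accrue while prescribed, not while adherent.**  Patients below
  the adherence threshold still fill prescriptions and purchase cannabis
  (flags `drug_cost_when_nonadherent` / `cannabis_cost_when_nonadherent`).
  This is both behaviorally natural (τ = 0.8 means "took ≥ 80 % of
  doses", not "stopped buying") and required to reproduce the published
  cost levels and the sharp ICER deterioration when cannabis adherence
  falls: nonadherent starters pay for cannabis they derive no benefit
  from.  Cannabis-nonadherent starters carry (and pay for) the drug for
  two cycles — the same clock as the poor-relief rule — and then count as
  having failed it.
* **Sequence exhaustion.**  After the fourth agent fails, the patient
  stays on it, still paying (`exhausted_policy="stay_on_last"`); the
  published 5/10-year average costs are consistent with continued
  drug-cost accrual, not with a drug-free terminal state (the `no_drug`
  alternative is available).
* **Death timing.**  SAE death occurs within the SAE cycle; the decedent
  accrues that cycle's costs (including hospitalization) and half the
  cycle's QALYs, then leaves the simulation.
* **Visit schedule.**  One regular office visit per cycle; an SAE visit
  replaces it in SAE cycles (`visit_every_cycle=False` restricts visits
  to initiation/switch/SAE cycles).
* **Poor-relief clock.**  The two-cycle inadequate-control counter
  follows the standard agent; losing cannabis alone does not reset it.
  If agent and cannabis fail in the same cycle both discontinue, and
  cannabis can never restart.
* **Triangular mode.**  The adherence-threshold range (0.5–1.0) has no
  published mode; the base-case value 0.8 is used as the mode.

## Uncertainty analysis

**One-way (tornado).**  Each parameter is varied over its class range —
95 % CI for the cannabis odds ratios and cannabis adherence; ±1 SD for
mild-pain utility, price per gram, daily THC dose, and standard-agent
adherence; 0.5–1.0 for the threshold; ±25 % for nonserious AE
probabilities; ±50 % otherwise — and the second-line vs usual-care
pairwise ICER is recomputed at each endpoint.  Every run reuses the same
seed, and the engine draws a fixed number of random numbers per cycle
regardless of parameter values, so endpoint runs differ *only* through
the varied parameter (common random numbers; verified by the property
that re-fixing a parameter at its base value reproduces the base ICER
bit for bit).

**Probabilistic.**  Each iteration redraws the model inputs from their
distributions, runs all four arms on one shared cohort, and records the
cohort mean (cost, QALY) per arm; acceptability curves report, per
willingness-to-pay value, the fraction of iterations in which each arm
maximizes net monetary benefit (ties to the cheaper arm, logged).  The
package distinguishes **first-order** from **second-order** uncertainty:
inputs whose printed dispersion is between-patient spread (baseline age
and pain, the five pain-score reductions, the four standard-agent
adherence means) are realized patient-by-patient inside every cohort and
are *not* resampled across PSA iterations; resampling their means from
the full patient-level SDs would double-count heterogeneity as parameter
uncertainty and, empirically, makes usual care the most probable
strategy at every plausible threshold — contradicting the published
acceptability curves.  All SE- or CI-parameterized inputs (event
probabilities, odds ratios, the cannabis adherence mean, utilities,
costs, death risks, THC dose, price per gram) are resampled each
iteration; the adherence threshold is drawn from its triangular
distribution in PSA only.  Odds ratios are sampled log-normally with
σ = (ln hi − ln lo)/(2·1.96).  A beta fit that becomes infeasible after a
mean is drawn near its boundary falls back to a documented clamping rule
(SD shrunk to 0.9·√(m(1−m))).

**Scenarios.**  `horizon_5y` / `horizon_10y` extend the horizon;
`nonuser_ors` substitutes the odds ratios estimated after excluding
active cannabis users (2.07 / 1.77); `wastage` inflates the cannabis
quantity purchased by 1/(1 − 0.389).  Each rebuilds the full four-arm
frontier.

## What the cohort generator does and does not emulate

The generator reproduces the *statistical* structure the analysis
assumes — truncated-normal baselines, per-patient response and adherence
heterogeneity with the published moments, uniformly random later-line
ordering — and is deterministic under a seed.  It does not emulate
features of real cohorts such as correlation between age, baseline pain
and drug response, informative dropout, time-varying adherence, placebo
response, or tolerance to cannabis; passing tests therefore certify the
model's internal logic and its agreement with the published aggregate
results, not predictive validity for any real population.

## Numerical and reporting conventions

Problem sizes are chosen so each analysis is a desk-scale run on one
CPU: base-case and scenario cohorts of 1–2 × 10⁵ patients (Monte-Carlo SE
on mean cost ≈ $6–8), PSA of 1,500 iterations × 10,000 patients in the
acceptance script.  The simulation is vectorized across patients, so a
four-arm base case at 10⁵ patients takes about a second.  Frontier
construction removes strictly dominated strategies, then iteratively
removes entries whose incremental ICER is not strictly below the next
entry's (extended dominance); exact cost/QALY ties break by declared
strategy order and are logged.  CSV outputs round costs to cents and
QALYs to 4 decimals; the run manifest records the seed, a config hash
and package versions.

## Known limitations

* Cannabis treatment episodes are short under per-cycle adverse-event
  draws (combined intolerable risk ≈ 20 %/cycle during co-use plus
  10.7 %/cycle discontinuation), so the incremental value of adjunctive
  cannabis saturates with the horizon; second- and third-line strategies
  become nearly indistinguishable at 5–10 years, and long-horizon
  frontier labels can flip on seed.  The published long-horizon results
  imply longer cannabis retention for responders than the published
  model description lets us reconstruct.
* Per-cycle serious-AE draws accumulate substantial hospitalization
  costs over multi-year horizons; 10-year mean costs are likely
  overstated relative to a per-episode adverse-event structure.
* Efficacy inputs derive from short trials in a specific neuropathic-pain
  population; the 1-year (let alone 10-year) extrapolation, fixed THC
  potency, and market-price assumptions inherit those sources'
  uncertainty.
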