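# cannacea

Individual-patient cost-effectiveness microsimulation of **adjunctive
smoked cannabis for chronic neuropathic pain**, from a U.S. health-care
sector perspective (third-party payer + patient out-of-pocket, 2017 USD).

The model is intended for health-economics researchers and students who
want a fully scripted, reproducible re-implementation of a published
decision model: every input is a typed distribution in a YAML file, every
analysis is a library call or CLI subcommand, and every table the model
produces is a plain CSV.

## The model

Treatment-naive patients with moderate-to-severe neuropathic pain
(11-point Likert score ≥ 4) enter a state-transition microsimulation with
6-week cycles.  Everyone starts standard therapy on duloxetine and, on
drug failure, switches to a uniformly random ordering of desipramine,
gabapentin and pregabalin.  Four strategies differ only in when adjunctive
smoked cannabis is added: never ("usual care"), with the 1st, 2nd, or 3rd
standard agent.

Each cycle a patient is assessed stepwise for

* **adverse events** — tolerable, intolerable, or serious (SAE), drawn as
  independent Bernoulli trials with severity precedence.  Cannabis co-use
  modifies nonserious and serious rates on the odds scale
  (`p' = OR·p / (1 − p + OR·p)`, OR 1.74 and 1.08) and combines
  intolerable risks independently; SAEs carry an age-band death risk and
  hospitalization cost;
* **adherence** — a per-patient Beta draw per drug compared against the
  adherence threshold τ = 0.8; nonadherence disqualifies relief and
  adverse events (but not spending);
* **pain relief** — achieved score = baseline − Σ reductions of adherent
  components (per-patient Normal draws, e.g. cannabis 1.11 ± 2.38);
  relief is *good* when the achieved score is < 4;
* **switching** — two consecutive poor-relief cycles, an intolerable/
  serious event, or a background discontinuation draw trigger a switch;
  failed cannabis can never be restarted.

Cycle QALYs are utility × time (mild 0.7, moderate-severe 0.39, minus AE
decrements), and costs accrue for drugs (1-month prices prorated to 42
days), cannabis (0.067 g THC/day ÷ 12.5% potency × $11.06/g ≈ $249 per
cycle), office visits and SAE hospitalizations — all discounted at 3%/yr.
Strategies are compared by incremental cost-effectiveness ratios (ICERs)
along the efficient frontier with strict and extended dominance, plus
net-monetary-benefit acceptability curves over a PSA.

## Worked example

```python
import cannacea as cc

params = cc.load_parameter_specs().point()        # the shipped input table
results = cc.run_strategies(params, 100_000, seed=1)
for name in ("usual_care", "first_line_cannabis",
             "second_line_cannabis", "third_line_cannabis"):
    r = results[name]
    print(f"{name:22s} ${r.mean_cost:7,.0f}  {r.mean_qaly:.3f} QALY")
frontier = cc.build_frontier([results[s] for s in results])
for e in frontier:
    icer = f"${e.icer:,.0f}/QALY" if e.icer is not None else e.status
    print(f"{e.strategy:22s} {icer}")
```

prints (seed 1, 100,000 patients, 1-year horizon):

```
usual_care             $  6,621  0.479 QALY
first_line_cannabis    $  7,259  0.489 QALY
second_line_cannabis   $  7,213  0.493 QALY
third_line_cannabis    $  7,098  0.490 QALY
usual_care             reference
first_line_cannabis    dominated
second_line_cannabis   $42,119/QALY
third_line_cannabis    extendedly_dominated
```

Usual care is cheapest; adding cannabis to the *first* agent costs more
and yields fewer QALYs than adding it to the second (dominated); the
*third*-line strategy is excluded by extended dominance; *second*-line
adjunctive cannabis buys its extra 0.014 QALY at ≈ $42,000 per QALY —
cost-effective at a $100,000/QALY willingness-to-pay threshold.

The same analyses are available from the shell:

```bash
cannacea base --seed 1 --n-patients 100000 --out results/
cannacea scenario --seed 1 --scenario wastage --out results/
cannacea tornado --seed 1 --n-patients 50000 --out results/
cannacea psa --seed 1 --n-iterations 2000 --n-patients 5000 --out results/
```

each writing plain-CSV tables (frontier, tornado, CEAC) and a JSON run
manifest.

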