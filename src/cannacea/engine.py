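"""Per-cycle treatment dynamics for the four strategy arms.

Each 6-week cycle a living patient is assessed stepwise: adverse events
(tolerable / intolerable / serious, with serious events carrying an
age-dependent death risk), background discontinuation, and quality of pain
relief (pain score < 4 after subtracting the reductions of all adherent
active components).  Two consecutive cycles of poor relief, an intolerable
or serious adverse event, or a discontinuation draw trigger a switch to the
next agent in the patient's sequence.  Adjunctive cannabis starts when the
patient reaches the strategy's start line and, once failed — through
nonadherence, two poor-relief cycles, an intolerable/serious event or
discontinuation — can never be restarted.

The simulation is vectorized across patients: state lives in NumPy arrays
and the cycle loop draws a fixed number of uniforms per cycle, so runs with
the same seed are aligned draw-for-draw regardless of parameter values
(common random numbers for sensitivity analyses).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import StrategyResult
from .cohort import Cohort, Patient, draw_cohort, draw_patient
from .economics import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    COMPONENTS,
    AE_CLASSES,
    CostBreakdown,
    cannabis_cycle_cost,
    discount_factor,
)
from .parameters import AGENTS, ParameterSet

__all__ = [
    "STRATEGIES",
    "CycleOutcome",
    "EngineOptions",
    "PatientLedger",
    "Regimen",
    "Strategy",
    "advance_cycle",
    "apply_odds_ratio",
    "classify_pain_state",
    "cycle_weights",
    "draw_adverse_events",
    "run_cohort",
    "run_strategies",
    "simulate_patient",
]

#: cycles per simulated year: 6-week cycles of a 52-week year
CYCLES_PER_YEAR = 52.0 / 6.0


@dataclass(frozen=True)
class Strategy:
    """A treatment arm: when (if ever) adjunctive cannabis is initiated."""

    name: str
    cannabis_start_line: int | None  # None = never; 1-based line number

    def __post_init__(self) -> None:
        if self.cannabis_start_line is not None and self.cannabis_start_line not in (1, 2, 3):
            raise ValueError("cannabis start line must be 1, 2, 3 or None")


STRATEGIES: dict[str, Strategy] = {
    "usual_care": Strategy("usual_care", None),
    "first_line_cannabis": Strategy("first_line_cannabis", 1),
    "second_line_cannabis": Strategy("second_line_cannabis", 2),
    "third_line_cannabis": Strategy("third_line_cannabis", 3),
}


def resolve_strategy(strategy: str | Strategy) -> Strategy:
    if isinstance(strategy, Strategy):
        return strategy
    try:
        return STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {sorted(STRATEGIES)}"
        ) from None


@dataclass(frozen=True)
class EngineOptions:
    """Structural switches for model behaviors the published description
    leaves open.  Defaults are the package's base-case structure.

    drug_cost_when_nonadherent / cannabis_cost_when_nonadherent
        Patients below the adherence threshold still fill prescriptions /
        purchase cannabis (they are disqualified from relief and adverse
        events, not from spending).
    exhausted_policy
        ``stay_on_last``: after the fourth agent fails the patient remains
        on it (retrying, still paying).  ``no_drug``: the patient stops
        standard therapy, keeping office visits and any active cannabis.
    redraw_responses
        Redraw each component's pain-score reduction every cycle instead of
        fixing one draw per patient-agent episode.
    nonadherent_cannabis_fail_cycles
        Cycles a cannabis-nonadherent starter carries (and pays for) the
        drug before counting as having failed it.
    visit_every_cycle
        One regular office visit per cycle (an SAE visit replaces it in SAE
        cycles); if False, visits accrue only on initiation/switch cycles.
    """

    drug_cost_when_nonadherent: bool = True
    cannabis_cost_when_nonadherent: bool = True
    exhausted_policy: str = "stay_on_last"
    redraw_responses: bool = False
    nonadherent_cannabis_fail_cycles: int = 2
    visit_every_cycle: bool = True

    def __post_init__(self) -> None:
        if self.exhausted_policy not in ("stay_on_last", "no_drug"):
            raise ValueError("exhausted_policy must be 'stay_on_last' or 'no_drug'")


@dataclass(frozen=True)
class CycleOutcome:
    """What happened to one patient in one cycle."""

    died: bool
    ae_class: str
    good_relief: bool
    switched: bool
    cannabis_failed_this_cycle: bool
    end_pain_state: str


@dataclass(frozen=True)
class Regimen:
    """The components a patient is on this cycle, with adherence flags."""

    agent: str | None
    agent_adherent: bool = False
    cannabis_active: bool = False
    cannabis_adherent: bool = False


@dataclass
class PatientLedger:
    """Per-patient accumulated discounted costs (by component) and QALYs."""

    cost_components: CostBreakdown
    discounted_qalys: float
    cycles_survived: int

    @property
    def discounted_cost_total(self) -> float:
        return self.cost_components.total


def apply_odds_ratio(p, or_):
    """Transform probability ``p`` by odds ratio ``or_`` (vectorized)."""
    p = np.asarray(p, dtype=float)
    out = or_ * p / (1.0 - p + or_ * p)
    return float(out) if out.ndim == 0 else out


def classify_pain_state(baseline: float, active_reductions: Sequence[float]) -> str:
    """Pain state after subtracting adherent components' reductions.

    The achieved score is floored at 0; relief is *good* (mild state) only
    if the achieved score is strictly below 4.
    """
    if not 0.0 <= baseline <= 10.0:
        raise ValueError(f"baseline pain must lie in [0, 10]: got {baseline}")
    achieved = max(0.0, baseline - sum(active_reductions))
    return "mild" if achieved < 4.0 else "moderate_severe"


def cycle_weights(horizon_years: float, cycle_days: float = 42.0) -> np.ndarray:
    """Accrual weight per cycle over the horizon.

    A year holds 52/6 six-week cycles; the fractional tail cycle accrues at
    reduced weight so the calendar-time QALY ceiling is preserved.
    """
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    total = horizon_years * CYCLES_PER_YEAR  # cycles over the horizon
    n_full = int(np.floor(total + 1e-9))
    frac = total - n_full
    weights = np.ones(n_full)
    if frac > 1e-9:
        weights = np.append(weights, frac)
    return weights


# ---------------------------------------------------------------------------
# adverse events


def _agent_arrays(params: ParameterSet) -> dict[str, np.ndarray]:
    ag = params.agents
    return {
        "p_ns": np.array([a.p_nonserious_ae for a in ag]),
        "p_int": np.array([a.p_intolerable_ae for a in ag]),
        "p_sae": np.array([a.p_serious_ae for a in ag]),
        "dc": np.array([a.discontinuation_rate for a in ag]),
        "wholesale": np.array([a.wholesale_cost_per_month for a in ag]),
        "oop": np.array([a.oop_cost_per_month for a in ag]),
        "red_mean": np.array([a.pain_reduction_mean for a in ag]),
        "red_sd": np.array([a.pain_reduction_sd for a in ag]),
    }


def _ae_probability_arrays(params: ParameterSet, arrays: Mapping[str, np.ndarray],
                           a_idx: np.ndarray, agent_contrib: np.ndarray,
                           cann_contrib: np.ndarray):
    """Per-patient AE probabilities given which components contribute.

    Agent alone uses the agent's published rates; agent + cannabis modifies
    nonserious and serious rates by the respective odds ratio and combines
    intolerable rates as independent risks; cannabis alone ("monotherapy")
    uses the cannabis-related event rates.  Patients with no contributing
    component have zero probabilities (nonadherence disqualifies adverse
    events).
    """
    c = params.cannabis
    ans = arrays["p_ns"][a_idx]
    aint = arrays["p_int"][a_idx]
    asae = arrays["p_sae"][a_idx]
    both = agent_contrib & cann_contrib
    agent_only = agent_contrib & ~cann_contrib
    cann_only = cann_contrib & ~agent_contrib

    p_ns = np.where(agent_only, ans, 0.0)
    p_int = np.where(agent_only, aint, 0.0)
    p_sae = np.where(agent_only, asae, 0.0)
    p_ns = np.where(both, apply_odds_ratio(ans, c.or_nonserious), p_ns)
    p_int = np.where(both, 1.0 - (1.0 - aint) * (1.0 - c.p_intolerable_mono), p_int)
    p_sae = np.where(both, apply_odds_ratio(asae, c.or_serious), p_sae)
    p_ns = np.where(cann_only, c.p_nonserious_mono, p_ns)
    p_int = np.where(cann_only, c.p_intolerable_mono, p_int)
    p_sae = np.where(cann_only, c.p_serious_mono, p_sae)
    return p_ns, p_int, p_sae


def draw_adverse_events(regimen: Regimen, params: ParameterSet,
                        rng: np.random.Generator) -> str:
    """Draw one cycle's adverse-event class for a single patient.

    Severity classes are independent Bernoulli trials with precedence
    serious > intolerable > tolerable; a patient adherent to nothing
    experiences no adverse events.
    """
    arrays = _agent_arrays(params)
    on_agent = regimen.agent is not None
    a_idx = np.array([AGENTS.index(regimen.agent) if on_agent else 0])
    agent_contrib = np.array([on_agent and regimen.agent_adherent])
    cann_contrib = np.array([regimen.cannabis_active and regimen.cannabis_adherent])
    p_ns, p_int, p_sae = _ae_probability_arrays(params, arrays, a_idx,
                                                agent_contrib, cann_contrib)
    u = rng.random(3)
    if u[2] < p_sae[0]:
        return "serious"
    if u[1] < p_int[0]:
        return "intolerable"
    if u[0] < p_ns[0]:
        return "tolerable"
    return "none"


# ---------------------------------------------------------------------------
# vectorized simulation


@dataclass
class _SimState:
    line: np.ndarray        # 0-based sequence slot; 4 = exhausted (no_drug policy)
    cann: np.ndarray        # 0 not_started, 1 active, 2 failed
    counter: np.ndarray     # consecutive poor-relief cycles on current regimen
    cann_cycles: np.ndarray
    alive: np.ndarray
    just_switched: np.ndarray

    @classmethod
    def fresh(cls, n: int) -> "_SimState":
        return cls(
            line=np.zeros(n, dtype=np.int64),
            cann=np.zeros(n, dtype=np.int8),
            counter=np.zeros(n, dtype=np.int64),
            cann_cycles=np.zeros(n, dtype=np.int64),
            alive=np.ones(n, dtype=bool),
            just_switched=np.zeros(n, dtype=bool),
        )


def _new_accumulator(n: int) -> dict[str, np.ndarray]:
    acc = {c: np.zeros(n) for c in COMPONENTS}
    acc["qalys"] = np.zeros(n)
    acc["cycles_survived"] = np.zeros(n, dtype=np.int64)
    return acc


def _step(cohort: Cohort, state: _SimState, strategy: Strategy, params: ParameterSet,
          options: EngineOptions, arrays: Mapping[str, np.ndarray], k: int,
          weight: float, rng: np.random.Generator,
          acc: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    n = cohort.n
    c = params.cannabis
    alive = state.alive.copy()

    # 1. cannabis initiation at cycle start (once; never restarted)
    if strategy.cannabis_start_line is not None:
        due = alive & (state.cann == 0) & (state.line >= strategy.cannabis_start_line - 1)
        state.cann[due] = 1
    on_cann = alive & (state.cann == 1)
    state.cann_cycles[on_cann] += 1

    on_agent = alive & (state.line <= 3)
    cur = np.minimum(state.line, 3)
    rows = np.arange(n)
    a_idx = cohort.agent_idx[rows, cur]
    a_adh = on_agent & cohort.agent_adherent[rows, cur]
    c_adh = on_cann & cohort.cannabis_adherent

    # 2. fixed-shape random draws (keeps seeded runs aligned across arms)
    u_ns = rng.random(n)
    u_int = rng.random(n)
    u_sae = rng.random(n)
    u_death = rng.random(n)
    u_dc_agent = rng.random(n)
    u_dc_cann = rng.random(n)
    if options.redraw_responses:
        agent_red = (arrays["red_mean"][a_idx]
                     + arrays["red_sd"][a_idx] * rng.standard_normal(n))
        cann_red = rng.normal(c.pain_reduction_mean, c.pain_reduction_sd, size=n)
    else:
        agent_red = cohort.agent_reduction[rows, cur]
        cann_red = cohort.cannabis_reduction

    # 3. adverse events (severity precedence serious > intolerable > tolerable)
    p_ns, p_int, p_sae = _ae_probability_arrays(params, arrays, a_idx, a_adh, c_adh)
    ev_sae = u_sae < p_sae
    ev_int = u_int < p_int
    ev_ns = u_ns < p_ns
    ae = np.zeros(n, dtype=np.int8)
    ae[ev_ns] = 1
    ae[ev_int] = 2
    ae[ev_sae] = 3

    # 4. death, only through the serious-AE pathway
    died = ev_sae & (u_death < np.asarray(params.sae_death_risk)[cohort.age_band])

    # 5. pain relief from adherent components only
    reduction = np.where(a_adh, agent_red, 0.0) + np.where(c_adh, cann_red, 0.0)
    achieved = np.maximum(cohort.baseline_pain - reduction, 0.0)
    mild = alive & (achieved < 4.0)

    # 6. accrual (discounted; decedents get the cycle's costs, half its QALYs)
    df = discount_factor(k, params.discount_rate, params.cycle_days)
    dt = params.cycle_days / DAYS_PER_YEAR
    decr = np.array([0.0, params.d_tolerable, params.d_intolerable, params.d_serious])
    utility = np.maximum(np.where(mild, params.u_mild, params.u_modsev) - decr[ae], 0.0)
    qaly = weight * dt * utility * df
    qaly = np.where(died, 0.5 * qaly, qaly)
    acc["qalys"] += np.where(alive, qaly, 0.0)

    prorate = params.cycle_days / DAYS_PER_MONTH
    pay_agent = on_agent & (a_adh | options.drug_cost_when_nonadherent)
    acc["drug_wholesale"] += np.where(pay_agent, arrays["wholesale"][a_idx], 0.0) * prorate * weight * df
    acc["drug_oop"] += np.where(pay_agent, arrays["oop"][a_idx], 0.0) * prorate * weight * df
    pay_cann = on_cann & (cohort.cannabis_adherent | options.cannabis_cost_when_nonadherent)
    ccost = cannabis_cycle_cost(c.price_per_gram, c.daily_thc_g, c.thc_fraction,
                                c.wastage_fraction, params.cycle_days)
    acc["cannabis"] += np.where(pay_cann, ccost, 0.0) * weight * df
    visit = np.where(ev_sae, params.visit_sae + params.visit_sae_oop,
                     params.visit_regular + params.visit_regular_oop)
    if options.visit_every_cycle:
        visit_due = alive
    else:  # visits only at initiation and on the cycle after a switch
        visit_due = alive & ((k == 0) | state.just_switched | ev_sae)
    acc["visits"] += np.where(visit_due, visit, 0.0) * weight * df
    hosp = np.asarray(params.sae_hospital_cost)[cohort.age_band] + params.sae_hospital_oop
    acc["sae_hospital"] += np.where(alive & ev_sae, hosp, 0.0) * df
    acc["cycles_survived"] += alive

    # 7. transitions
    survivors = alive & ~died
    dc_agent = survivors & on_agent & (u_dc_agent < arrays["dc"][a_idx])
    dc_cann = survivors & on_cann & (u_dc_cann < c.discontinuation_rate)
    poor = survivors & ~mild
    state.counter = np.where(survivors, np.where(poor, state.counter + 1, 0), state.counter)
    two_poor = survivors & (state.counter >= 2)
    ae_switch = survivors & (ae >= 2)
    switch_agent = on_agent & survivors & (two_poor | ae_switch | dc_agent)
    nonadh_fail = (on_cann & ~cohort.cannabis_adherent
                   & (state.cann_cycles >= options.nonadherent_cannabis_fail_cycles))
    fail_cann = on_cann & survivors & (two_poor | ae_switch | dc_cann | nonadh_fail)

    max_line = 3 if options.exhausted_policy == "stay_on_last" else 4
    state.line = np.where(switch_agent, np.minimum(state.line + 1, max_line), state.line)
    state.cann[fail_cann] = 2
    # the poor-relief clock follows the standard agent; losing cannabis alone
    # does not grant the agent a fresh two-cycle window
    state.counter[switch_agent] = 0
    state.just_switched = switch_agent
    state.alive = survivors

    return {"died": died, "ae": ae, "mild": mild, "switched": switch_agent,
            "cannabis_failed": fail_cann}


def _run_arrays(strategy: Strategy, params: ParameterSet, cohort: Cohort,
                weights: np.ndarray, rng: np.random.Generator,
                options: EngineOptions) -> dict[str, np.ndarray]:
    arrays = _agent_arrays(params)
    state = _SimState.fresh(cohort.n)
    acc = _new_accumulator(cohort.n)
    for k, w in enumerate(weights):
        _step(cohort, state, strategy, params, options, arrays, k, float(w), rng, acc)
    acc["total_cost"] = sum(acc[c] for c in COMPONENTS)
    return acc


def run_cohort(strategy: str | Strategy, params: ParameterSet, n_patients: int,
               seed: int | None = None, *, horizon_years: float = 1.0,
               options: EngineOptions | None = None, cohort: Cohort | None = None,
               return_ledgers: bool = False):
    """Simulate one strategy arm over a cohort and summarize it.

    Runs seeded identically share every random draw (the cohort stream and
    the per-cycle event stream are derived from ``seed`` independently of
    the strategy or parameter values), which makes paired arm comparisons
    common-random-number comparisons.  Pass a pre-drawn ``cohort`` to reuse
    patients across arms.

    Returns a :class:`~cannacea.cea.StrategyResult`; with
    ``return_ledgers=True``, a ``(result, DataFrame)`` pair with one row of
    discounted cost components, QALYs and cycles survived per patient.
    """
    strategy = resolve_strategy(strategy)
    options = options or EngineOptions()
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for every stochastic run")
    if cohort is None:
        cohort = draw_cohort(params, n_patients, np.random.default_rng([int(seed), 101]))
    elif cohort.n != n_patients:
        raise ValueError("cohort size does not match n_patients")
    rng = np.random.default_rng([int(seed), 202])
    weights = cycle_weights(horizon_years, params.cycle_days)
    acc = _run_arrays(strategy, params, cohort, weights, rng, options)

    n = cohort.n
    result = StrategyResult(
        strategy=strategy.name,
        mean_cost=float(acc["total_cost"].mean()),
        mean_qaly=float(acc["qalys"].mean()),
        se_cost=float(acc["total_cost"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(acc["qalys"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
        components={c: float(acc[c].mean()) for c in COMPONENTS},
    )
    if not return_ledgers:
        return result
    ledgers = pd.DataFrame({**{c: acc[c] for c in COMPONENTS},
                            "total_cost": acc["total_cost"],
                            "qalys": acc["qalys"],
                            "cycles_survived": acc["cycles_survived"]})
    return result, ledgers


def run_strategies(params: ParameterSet, n_patients: int, seed: int, *,
                   horizon_years: float = 1.0, options: EngineOptions | None = None,
                   strategies: Sequence[str | Strategy] | None = None,
                   ) -> dict[str, StrategyResult]:
    """Run all (or selected) strategy arms on one shared cohort.

    Arms share the patient draws and the per-cycle random streams (common
    random numbers), so between-arm differences reflect only the strategy.
    """
    chosen = [resolve_strategy(s) for s in (strategies or STRATEGIES.values())]
    cohort = draw_cohort(params, n_patients, np.random.default_rng([int(seed), 101]))
    return {s.name: run_cohort(s, params, n_patients, seed, horizon_years=horizon_years,
                               options=options, cohort=cohort)
            for s in chosen}


# ---------------------------------------------------------------------------
# single-patient views


def simulate_patient(strategy: str | Strategy, params: ParameterSet,
                     horizon_cycles: int | None = None, rng: np.random.Generator | None = None,
                     *, horizon_years: float | None = None,
                     options: EngineOptions | None = None,
                     cohort: Cohort | None = None) -> PatientLedger:
    """Simulate a single patient and return their discounted ledger.

    Provide either ``horizon_cycles`` (full cycles, >= 1) or
    ``horizon_years`` (which may end on a fractional cycle).
    """
    strategy = resolve_strategy(strategy)
    options = options or EngineOptions()
    if rng is None:
        raise ValueError("a seeded random generator is required")
    if horizon_cycles is not None:
        if horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        weights = np.ones(int(horizon_cycles))
    elif horizon_years is not None:
        weights = cycle_weights(horizon_years, params.cycle_days)
    else:
        raise ValueError("provide horizon_cycles or horizon_years")
    if cohort is None:
        cohort = draw_cohort(params, 1, rng)
    acc = _run_arrays(strategy, params, cohort, weights, rng, options)
    components = CostBreakdown(*(float(acc[c][0]) for c in COMPONENTS))
    return PatientLedger(cost_components=components,
                         discounted_qalys=float(acc["qalys"][0]),
                         cycles_survived=int(acc["cycles_survived"][0]))


_CANN_CODE = {"not_started": 0, "active": 1, "failed": 2}
_CANN_NAME = {v: k for k, v in _CANN_CODE.items()}


def advance_cycle(patient: Patient, strategy: str | Strategy, params: ParameterSet,
                  cycle_index: int, rng: np.random.Generator,
                  options: EngineOptions | None = None) -> CycleOutcome:
    """Advance a single :class:`~cannacea.cohort.Patient` by one cycle in place.

    Runs the same vectorized step as :func:`run_cohort` on a one-patient
    state.  Raises if the patient is already dead.
    """
    strategy = resolve_strategy(strategy)
    options = options or EngineOptions()
    if not patient.alive:
        raise ValueError("cannot advance a dead patient")

    seq_idx = np.array([[AGENTS.index(a) for a in patient.agent_sequence]])
    cohort = Cohort(
        age=np.array([patient.age]),
        age_band=np.array([patient._band_index]),
        baseline_pain=np.array([patient.baseline_pain]),
        agent_idx=seq_idx,
        agent_reduction=np.array([[patient.response_draws[a] for a in patient.agent_sequence]]),
        agent_adherence=np.array([[1.0 if patient.adherent[a] else 0.0
                                   for a in patient.agent_sequence]]),
        agent_adherent=np.array([[patient.adherent[a] for a in patient.agent_sequence]]),
        cannabis_reduction=np.array([patient.cannabis_response]),
        cannabis_adherence=np.array([1.0 if patient.cannabis_adherent else 0.0]),
        cannabis_adherent=np.array([patient.cannabis_adherent]),
    )
    state = _SimState(
        line=np.array([patient.current_line - 1]),
        cann=np.array([_CANN_CODE[patient.cannabis_state]], dtype=np.int8),
        counter=np.array([patient.poor_relief_cycles_on_current]),
        cann_cycles=np.array([patient.cycles_on_cannabis]),
        alive=np.array([True]),
        just_switched=np.array([False]),
    )
    acc = _new_accumulator(1)
    out = _step(cohort, state, strategy, params, options, _agent_arrays(params),
                cycle_index, 1.0, rng, acc)

    patient.alive = bool(state.alive[0])
    patient.current_line = int(state.line[0]) + 1
    patient.cannabis_state = _CANN_NAME[int(state.cann[0])]
    patient.poor_relief_cycles_on_current = int(state.counter[0])
    patient.cycles_on_cannabis = int(state.cann_cycles[0])
    mild = bool(out["mild"][0])
    patient.pain_state = "mild" if mild else "moderate_severe"
    return CycleOutcome(
        died=bool(out["died"][0]),
        ae_class=AE_CLASSES[int(out["ae"][0])],
        good_relief=mild,
        switched=bool(out["switched"][0]),
        cannabis_failed_this_cycle=bool(out["cannabis_failed"][0]),
        end_pain_state=patient.pain_state,
    )
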