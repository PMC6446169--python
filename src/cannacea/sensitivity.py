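"""One-way (tornado) sensitivity analysis, PSA, and scenario analyses.

One-way analysis varies a single parameter over its published range —
odds ratios and cannabis adherence over their 95% CIs; mild-pain utility,
cannabis price per gram, daily THC dose and standard-agent adherence over
+/- 1 SD; the adherence threshold from 0.5 to 1.0; nonserious AE
probabilities over +/- 25%; everything else over +/- 50% — and reruns the
second-line-cannabis and usual-care arms with common random numbers,
reporting the pairwise ICER at each endpoint.

Probabilistic sensitivity analysis redraws every parameter from its
distribution each iteration, runs all four arms on a shared cohort, and
summarizes the iteration-level cost/QALY pairs as cost-effectiveness
acceptability curves.

Scenario analyses rerun the full frontier under structural substitutions:
5- and 10-year horizons, adverse-event odds ratios estimated after
excluding active cannabis users, and cannabis wastage inflating the
purchased quantity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .cea import FrontierEntry, StrategyResult, build_frontier, ceac, pairwise_icer
from .engine import EngineOptions, run_cohort, run_strategies
from .parameters import AGENTS, ParameterSet, ParameterSpecs

__all__ = [
    "PSAResult",
    "SCENARIOS",
    "ScenarioResult",
    "ScenarioSpec",
    "TornadoEntry",
    "apply_override",
    "one_way_ranges",
    "one_way_tornado",
    "run_psa",
    "run_scenario",
]

logger = logging.getLogger(__name__)

_STRATEGY_ORDER = ("usual_care", "first_line_cannabis",
                   "second_line_cannabis", "third_line_cannabis")


# ---------------------------------------------------------------------------
# parameter overrides


def _set_agent(params: ParameterSet, agent: str, **changes) -> ParameterSet:
    agents = tuple(dataclasses.replace(a, **changes) if a.name == agent else a
                   for a in params.agents)
    return params.replace(agents=agents)


def _set_cannabis(params: ParameterSet, **changes) -> ParameterSet:
    return params.replace(cannabis=dataclasses.replace(params.cannabis, **changes))


def apply_override(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with the named parameter set to ``value``.

    Names use the parameter-file paths (``cannabis.adherence``,
    ``agents.duloxetine.p_nonserious_ae``, ``utilities.mild``, ...).
    Probability- and utility-valued overrides outside [0, 1] are clipped
    with a warning.
    """
    parts = name.split(".")
    prob_like = parts[-1].startswith("p_") or parts[-1] in (
        "adherence", "discontinuation_rate", "mild", "moderate_severe",
        "tolerable", "intolerable", "serious", "wastage")
    if prob_like and not 0.0 <= value <= 1.0:
        clipped = float(np.clip(value, 1e-6, 1.0 - 1e-6))
        logger.warning("override %s=%g outside natural support; clipped to %g",
                       name, value, clipped)
        value = clipped

    if parts[0] == "agents" and len(parts) == 3:
        agent, fld = parts[1], parts[2]
        if agent not in AGENTS:
            raise KeyError(f"unknown agent in override '{name}'")
        fld = {"pain_reduction": "pain_reduction_mean", "adherence": "adherence_mean"}.get(fld, fld)
        if not hasattr(params.agents[0], fld):
            raise KeyError(f"no override rule for parameter '{name}'")
        return _set_agent(params, agent, **{fld: value})
    if parts[0] == "cannabis" and len(parts) == 2:
        fld = {"pain_reduction": "pain_reduction_mean", "adherence": "adherence_mean",
               "wastage": "wastage_fraction"}.get(parts[1], parts[1])
        if not hasattr(params.cannabis, fld):
            raise KeyError(f"no override rule for parameter '{name}'")
        return _set_cannabis(params, **{fld: value})
    if name == "adherence_threshold":
        return params.replace(adherence_threshold=value)
    if name == "utilities.mild":
        return params.replace(u_mild=value)
    if name == "utilities.moderate_severe":
        return params.replace(u_modsev=value)
    if name == "decrements.tolerable":
        return params.replace(d_tolerable=value)
    if name == "decrements.intolerable":
        return params.replace(d_intolerable=value)
    if name == "decrements.serious":
        return params.replace(d_serious=value)
    if name == "sae_hospital_oop":
        return params.replace(sae_hospital_oop=value)
    if parts[0] == "visit_costs" and len(parts) == 2:
        fld = {"regular": "visit_regular", "sae": "visit_sae",
               "regular_oop": "visit_regular_oop", "sae_oop": "visit_sae_oop"}[parts[1]]
        return params.replace(**{fld: value})
    raise KeyError(f"no override rule for parameter '{name}'")


def one_way_ranges(specs: ParameterSpecs) -> dict[str, tuple[float, float]]:
    """Low/high endpoint per parameter, following the per-class range rules."""
    ranges: dict[str, tuple[float, float]] = {}

    def ci(name: str) -> tuple[float, float]:
        s = specs[name]
        return (s.ci_low, s.ci_high)

    def pm_sd(name: str) -> tuple[float, float]:
        s = specs[name]
        return (s.mean - s.sd, s.mean + s.sd)

    def pm_frac(name: str, frac: float) -> tuple[float, float]:
        m = specs[name].mean
        return (m * (1.0 - frac), m * (1.0 + frac))

    # 95% CI ranges: AE odds ratios and cannabis adherence
    for nm in ("cannabis.or_nonserious", "cannabis.or_serious"):
        ranges[nm] = ci(nm)
    ranges["cannabis.adherence"] = ci("cannabis.adherence")
    # +/- 1 SD
    ranges["utilities.mild"] = pm_sd("utilities.mild")
    ranges["cannabis.price_per_gram"] = pm_sd("cannabis.price_per_gram")
    ranges["cannabis.daily_thc_g"] = pm_sd("cannabis.daily_thc_g")
    for ag in AGENTS:
        ranges[f"agents.{ag}.adherence"] = pm_sd(f"agents.{ag}.adherence")
    # full assumed range
    ranges["adherence_threshold"] = (specs["adherence_threshold"].lo,
                                     specs["adherence_threshold"].hi)
    # +/- 25%: nonserious AE probabilities
    for ag in AGENTS:
        ranges[f"agents.{ag}.p_nonserious_ae"] = pm_frac(f"agents.{ag}.p_nonserious_ae", 0.25)
    ranges["cannabis.p_nonserious_mono"] = pm_frac("cannabis.p_nonserious_mono", 0.25)
    # +/- 50%: everything else we vary
    for nm in ("utilities.moderate_severe", "cannabis.pain_reduction",
               "cannabis.discontinuation_rate", "cannabis.p_intolerable_mono",
               "decrements.tolerable", "decrements.intolerable"):
        ranges[nm] = pm_frac(nm, 0.50)
    return ranges


# ---------------------------------------------------------------------------
# tornado


@dataclass(frozen=True)
class TornadoEntry:
    """One-way result for one parameter: pairwise ICER at each endpoint.

    An endpoint at which second-line cannabis is dominated by usual care
    (negative QALY gain) carries ``status='dominated'`` and a negative or
    infinite ICER value.
    """

    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    status_at_low: str = "icer"
    status_at_high: str = "icer"

    @property
    def span(self) -> float:
        vals = [v for v, s in ((self.icer_at_low, self.status_at_low),
                               (self.icer_at_high, self.status_at_high))
                if s == "icer" and np.isfinite(v)]
        if not vals:
            return np.inf
        if len(vals) == 1:  # one dominated endpoint: unbounded bar
            return np.inf
        return abs(vals[1] - vals[0])


def _pairwise_run(params: ParameterSet, n_patients: int, seed: int,
                  horizon_years: float, options: EngineOptions | None,
                  ) -> tuple[float, str]:
    """ICER of second-line cannabis vs usual care under common random numbers."""
    results = run_strategies(params, n_patients, seed, horizon_years=horizon_years,
                             options=options,
                             strategies=["usual_care", "second_line_cannabis"])
    usual, second = results["usual_care"], results["second_line_cannabis"]
    dq = second.mean_qaly - usual.mean_qaly
    dc = second.mean_cost - usual.mean_cost
    if dq <= 0.0 and dc >= 0.0:
        return pairwise_icer(usual, second), "dominated"
    return pairwise_icer(usual, second), "icer"


def one_way_tornado(params: ParameterSet, specs: ParameterSpecs, n_patients: int,
                    seed: int, *, horizon_years: float = 1.0,
                    options: EngineOptions | None = None,
                    parameters: Sequence[str] | None = None) -> list[TornadoEntry]:
    """One-way sensitivity of the second-line vs usual-care ICER.

    Every run (both endpoints of every parameter, and implicitly the base
    case) uses the same seed, so endpoint runs differ only through the
    varied parameter.  Entries are sorted by ICER span, widest first.
    """
    ranges = one_way_ranges(specs)
    names = list(parameters) if parameters is not None else list(ranges)
    entries = []
    for name in names:
        lo, hi = ranges[name]
        icers, statuses = [], []
        for endpoint in (lo, hi):
            p = apply_override(params, name, endpoint)
            icer, status = _pairwise_run(p, n_patients, seed, horizon_years, options)
            icers.append(icer)
            statuses.append(status)
        entries.append(TornadoEntry(name, lo, hi, icers[0], icers[1],
                                    statuses[0], statuses[1]))
    entries.sort(key=lambda e: -e.span if np.isfinite(e.span) else -np.inf)
    # unbounded (dominated-endpoint) bars first, then by finite span
    entries.sort(key=lambda e: (0 if not np.isfinite(e.span) else 1,
                                -e.span if np.isfinite(e.span) else 0))
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAResult:
    """Iteration-level PSA output and derived acceptability curves."""

    strategies: tuple[str, ...]
    costs: np.ndarray   # (iterations, strategies) cohort mean costs
    qalys: np.ndarray   # (iterations, strategies) cohort mean QALYs
    wtp_grid: np.ndarray
    ceac: "object"      # DataFrame: rows WTP, columns strategies, row sums 1
    seed: int

    def probability_best(self, strategy: str, wtp: float) -> float:
        """CEAC value for one strategy at one willingness-to-pay threshold."""
        return float(self.ceac.loc[wtp, strategy])


def run_psa(specs: ParameterSpecs, n_iterations: int = 10_000,
            n_patients_per_iteration: int = 10_000,
            wtp_grid: Sequence[float] | None = None, seed: int = 0, *,
            horizon_years: float = 1.0,
            options: EngineOptions | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis over all parameters at once.

    Each iteration redraws a full parameter set from the model
    distributions (the adherence threshold from its triangular
    distribution), simulates all four arms on a shared cohort with common
    random numbers, and records the cohort mean cost and QALYs per arm.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_001.0, 5_000.0)
    wtp = np.asarray(list(wtp_grid), dtype=float)
    strategies = _STRATEGY_ORDER
    costs = np.empty((n_iterations, len(strategies)))
    qalys = np.empty((n_iterations, len(strategies)))
    root = np.random.SeedSequence([int(seed), 303])
    for i, child in enumerate(root.spawn(n_iterations)):
        param_rng, run_seed_seq = child.spawn(2)
        params_i = specs.sample(np.random.default_rng(param_rng))
        run_seed = int(run_seed_seq.generate_state(1, np.uint32)[0])
        results = run_strategies(params_i, n_patients_per_iteration, run_seed,
                                 horizon_years=horizon_years, options=options,
                                 strategies=list(strategies))
        for j, s in enumerate(strategies):
            costs[i, j] = results[s].mean_cost
            qalys[i, j] = results[s].mean_qaly
    curves = ceac(costs, qalys, wtp, strategies)
    return PSAResult(strategies=tuple(strategies), costs=costs, qalys=qalys,
                     wtp_grid=wtp, ceac=curves, seed=int(seed))


# ---------------------------------------------------------------------------
# scenario analyses


@dataclass(frozen=True)
class ScenarioSpec:
    """A named structural scenario: a horizon and/or parameter overrides."""

    name: str
    horizon_years: float = 1.0
    transform: Callable[[ParameterSet], ParameterSet] | None = field(
        default=None, compare=False)

    def parameters(self, params: ParameterSet) -> ParameterSet:
        return self.transform(params) if self.transform is not None else params


def _nonuser_ors(params: ParameterSet) -> ParameterSet:
    c = params.cannabis
    return _set_cannabis(params, or_nonserious=c.or_nonserious_nonuser,
                         or_serious=c.or_serious_nonuser)


def _apply_wastage(params: ParameterSet) -> ParameterSet:
    return _set_cannabis(params,
                         wastage_fraction=params.cannabis.wastage_scenario_fraction)


SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec("base"),
    "horizon_5y": ScenarioSpec("horizon_5y", horizon_years=5.0),
    "horizon_10y": ScenarioSpec("horizon_10y", horizon_years=10.0),
    "nonuser_ors": ScenarioSpec("nonuser_ors", transform=_nonuser_ors),
    "wastage": ScenarioSpec("wastage", transform=_apply_wastage),
}


@dataclass
class ScenarioResult:
    """Four-arm scenario outcome: per-arm means and the resulting frontier."""

    scenario: str
    horizon_years: float
    results: dict[str, StrategyResult]
    frontier: list[FrontierEntry]

    def entry(self, strategy: str) -> FrontierEntry:
        for e in self.frontier:
            if e.strategy == strategy:
                return e
        raise KeyError(strategy)


def run_scenario(scenario: str | ScenarioSpec, params: ParameterSet,
                 n_patients: int, seed: int, *,
                 options: EngineOptions | None = None) -> ScenarioResult:
    """Run all four arms under a named scenario and build the frontier."""
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}"
            ) from None
    scenario_params = scenario.parameters(params)
    results = run_strategies(scenario_params, n_patients, seed,
                             horizon_years=scenario.horizon_years, options=options)
    ordered = [results[name] for name in _STRATEGY_ORDER]
    return ScenarioResult(scenario=scenario.name,
                          horizon_years=scenario.horizon_years,
                          results=results,
                          frontier=build_frontier(ordered))
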