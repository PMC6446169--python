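"""Model parameters as typed distributions.

Every model input is a :class:`DistributionSpec` — a point estimate plus a
sampling family and dispersion — loaded from a YAML file that transcribes
the published input table.  A :class:`ParameterSet` is one fully realized
input vector: either the point estimates (base-case analysis) or one
independent draw per parameter (probabilistic sensitivity analysis).

Families
--------
normal            value ~ N(mean, sd); draws may be negative (a pain-score
                  "reduction" drawn negative means the drug worsened pain).
beta              shape parameters fitted from (mean, sd) by the method of
                  moments; used for probabilities, utilities and adherence.
gamma             shape/scale fitted from (mean, sd); used for costs, the
                  cannabis price per gram and the daily THC dose.
log_odds_normal   odds ratios: ln(OR) ~ N(ln mean, sigma) with sigma taken
                  from the printed 95% CI as (ln hi - ln lo)/(2*1.96).
triangular        the adherence threshold, Triangular(lo, mode, hi); static
                  at its base-case value outside of PSA.
point             a constant (the THC potency of the modeled product).
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "AGENTS",
    "AGE_BAND_LABELS",
    "AgentParams",
    "CannabisParams",
    "DistributionSpec",
    "ParameterError",
    "ParameterSet",
    "ParameterSpecs",
    "convert_vas100_to_likert11",
    "default_parameter_file",
    "fit_beta_from_moments",
    "fit_gamma_from_moments",
    "load_parameter_specs",
    "sample_parameter_set",
]

#: Standard-therapy agents in canonical order; every patient starts on
#: duloxetine and the remaining three are tried in random order.
AGENTS = ("duloxetine", "desipramine", "gabapentin", "pregabalin")

#: Age bands for SAE death risk and hospitalization cost.
AGE_BAND_LABELS = ("18-44", "45-64", "65-84", "85+")
_BAND_KEYS = ("age_18_44", "age_45_64", "age_65_84", "age_85_plus")

_FAMILIES = frozenset(
    {"normal", "beta", "gamma", "triangular", "log_odds_normal", "point"}
)


class ParameterError(ValueError):
    """Invalid, infeasible or missing model parameter."""


#: Parameters whose printed dispersion is *between-patient* spread, realized
#: per patient by the cohort generator (first-order uncertainty).  PSA
#: resamples only second-order (parameter) uncertainty, so these keep their
#: point estimates across iterations; redrawing their means from the full
#: patient-level SD would double-count heterogeneity as parameter
#: uncertainty.  The cannabis adherence mean is CI-parameterized (a
#: meta-analytic mean), so it *is* resampled.
PATIENT_LEVEL_PARAMS = frozenset(
    {"baseline.age", "baseline.pain_score", "cannabis.pain_reduction"}
    | {f"agents.{ag}.pain_reduction" for ag in AGENTS}
    | {f"agents.{ag}.adherence" for ag in AGENTS}
)


def fit_beta_from_moments(mean: float, sd: float, name: str = "") -> tuple[float, float]:
    """Method-of-moments beta fit: return ``(alpha, beta)`` matching (mean, sd).

    Requires ``0 < mean < 1`` and ``sd**2 < mean*(1-mean)``; otherwise raises
    :class:`ParameterError` naming the offending parameter.
    """
    label = f" for '{name}'" if name else ""
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must lie in (0,1){label}: got {mean}")
    if sd <= 0.0:
        raise ParameterError(f"beta sd must be positive{label}: got {sd}")
    var = sd * sd
    limit = mean * (1.0 - mean)
    if var >= limit:
        raise ParameterError(
            f"infeasible beta moments{label}: sd^2={var:.6g} >= mean*(1-mean)={limit:.6g}"
        )
    nu = limit / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def beta_params_clamped(mean: float, sd: float, name: str = "") -> tuple[float, float]:
    """Beta fit with the documented fallback for infeasible moments.

    When ``sd**2 >= mean*(1-mean)`` (which can occur after a PSA draw moves a
    mean toward 0 or 1 while its dispersion stays fixed), the dispersion is
    shrunk to ``0.9*sqrt(mean*(1-mean))`` before fitting.
    """
    mean = float(np.clip(mean, 1e-9, 1.0 - 1e-9))
    limit = math.sqrt(mean * (1.0 - mean))
    if sd <= 0.0:
        sd = 1e-9 * limit
    sd = min(sd, 0.9 * limit)
    return fit_beta_from_moments(mean, sd, name)


def fit_gamma_from_moments(mean: float, sd: float, name: str = "") -> tuple[float, float]:
    """Method-of-moments gamma fit: return ``(shape, scale)``."""
    label = f" for '{name}'" if name else ""
    if mean <= 0.0 or sd <= 0.0:
        raise ParameterError(f"gamma moments must be positive{label}: mean={mean}, sd={sd}")
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


def convert_vas100_to_likert11(score: float) -> float:
    """Convert a 0–100 visual-analog pain score to the 0–10 Likert scale."""
    if not 0.0 <= score <= 100.0:
        raise ParameterError(f"VAS score must lie in [0, 100]: got {score}")
    return score / 10.0


@dataclass(frozen=True)
class DistributionSpec:
    """One named model input: point estimate, dispersion and sampling family."""

    name: str
    family: str
    mean: float
    dispersion: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    lo: float | None = None
    hi: float | None = None
    mode: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown distribution family '{self.family}' for '{self.name}'")
        if self.ci_low is not None or self.ci_high is not None:
            if self.ci_low is None or self.ci_high is None:
                raise ParameterError(f"'{self.name}': both CI bounds are required")
            if not self.ci_low < self.mean < self.ci_high:
                raise ParameterError(
                    f"'{self.name}': CI ({self.ci_low}, {self.ci_high}) must bracket mean {self.mean}"
                )
        if self.family == "triangular":
            if self.lo is None or self.hi is None:
                raise ParameterError(f"'{self.name}': triangular needs lo/hi")
            if not self.lo < self.hi:
                raise ParameterError(f"'{self.name}': triangular lo must be < hi")

    @property
    def sd(self) -> float:
        """Dispersion on the natural scale (from the CI if not given directly)."""
        if self.dispersion is not None:
            return self.dispersion
        if self.ci_low is not None and self.ci_high is not None:
            return (self.ci_high - self.ci_low) / 4.0
        return 0.0

    def point(self) -> float:
        return self.mean

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the spec's family (degenerate dispersion => the mean)."""
        if self.family == "point":
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "triangular":
            mode = self.mode if self.mode is not None else self.mean
            return rng.triangular(self.lo, mode, self.hi, size=size)
        if self.family == "log_odds_normal":
            if self.ci_low is None or self.ci_high is None:
                raise ParameterError(f"'{self.name}': log_odds_normal needs a 95% CI")
            sigma = (math.log(self.ci_high) - math.log(self.ci_low)) / (2.0 * 1.959963984540054)
            return np.exp(rng.normal(math.log(self.mean), sigma, size=size))
        sd = self.sd
        if sd <= 0.0:
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "normal":
            return rng.normal(self.mean, sd, size=size)
        if self.family == "beta":
            a, b = fit_beta_from_moments(self.mean, sd, self.name)
            return rng.beta(a, b, size=size)
        # gamma
        shape, scale = fit_gamma_from_moments(self.mean, sd, self.name)
        return rng.gamma(shape, scale, size=size)


@dataclass(frozen=True)
class AgentParams:
    """Realized inputs for one standard-therapy agent."""

    name: str
    pain_reduction_mean: float
    pain_reduction_sd: float
    p_nonserious_ae: float
    p_intolerable_ae: float
    p_serious_ae: float
    adherence_mean: float
    adherence_sd: float
    discontinuation_rate: float
    wholesale_cost_per_month: float
    oop_cost_per_month: float


@dataclass(frozen=True)
class CannabisParams:
    """Realized inputs for adjunctive smoked cannabis."""

    pain_reduction_mean: float
    pain_reduction_sd: float
    p_nonserious_mono: float
    p_intolerable_mono: float
    p_serious_mono: float
    or_nonserious: float
    or_serious: float
    or_nonserious_nonuser: float
    or_serious_nonuser: float
    adherence_mean: float
    adherence_sd: float
    discontinuation_rate: float
    price_per_gram: float
    daily_thc_g: float
    thc_fraction: float
    #: wastage applied to the purchased quantity; 0 in the base case
    wastage_fraction: float
    #: the published wastage estimate, applied by the wastage scenario
    wastage_scenario_fraction: float


@dataclass(frozen=True)
class ParameterSet:
    """One complete realized model input vector (a draw or the point estimates)."""

    baseline_age_mean: float
    baseline_age_sd: float
    baseline_pain_mean: float
    baseline_pain_sd: float
    agents: tuple[AgentParams, ...]  # canonical AGENTS order
    cannabis: CannabisParams
    adherence_threshold: float
    sae_death_risk: tuple[float, float, float, float]  # by age band
    sae_hospital_cost: tuple[float, float, float, float]
    sae_hospital_oop: float
    u_mild: float
    u_modsev: float
    d_tolerable: float
    d_intolerable: float
    d_serious: float
    visit_regular: float
    visit_sae: float
    visit_regular_oop: float
    visit_sae_oop: float
    discount_rate: float = 0.03
    cycle_days: float = 42.0

    def __post_init__(self) -> None:
        probs = []
        for a in self.agents:
            probs += [a.p_nonserious_ae, a.p_intolerable_ae, a.p_serious_ae,
                      a.discontinuation_rate]
        c = self.cannabis
        probs += [c.p_nonserious_mono, c.p_intolerable_mono, c.p_serious_mono,
                  c.discontinuation_rate, *self.sae_death_risk]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("all event probabilities must lie in [0, 1]")
        if not self.u_mild > self.u_modsev:
            raise ParameterError("mild-pain utility must exceed moderate-to-severe utility")
        if not 0.0 <= self.adherence_threshold <= 1.0:
            raise ParameterError("adherence threshold must lie in [0, 1]")
        if not 0.0 < c.thc_fraction < 1.0:
            raise ParameterError("THC fraction must lie in (0, 1)")
        if not 0.0 <= c.wastage_fraction < 1.0:
            raise ParameterError("wastage fraction must lie in [0, 1)")
        costs = [a.wholesale_cost_per_month for a in self.agents]
        costs += [a.oop_cost_per_month for a in self.agents]
        costs += [*self.sae_hospital_cost, self.sae_hospital_oop, self.visit_regular,
                  self.visit_sae, self.visit_regular_oop, self.visit_sae_oop,
                  c.price_per_gram]
        if any(v < 0 for v in costs):
            raise ParameterError("costs must be nonnegative")

    def agent(self, name: str) -> AgentParams:
        for a in self.agents:
            if a.name == name:
                return a
        raise KeyError(name)

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


def default_parameter_file() -> Path:
    """Path to the packaged base-case parameter file."""
    return Path(resources.files("cannacea").joinpath("data/default_parameters.yaml"))


class ParameterSpecs:
    """The full collection of distribution specs read from a parameter file."""

    def __init__(self, specs: Mapping[str, DistributionSpec],
                 settings: Mapping[str, float] | None = None):
        self._specs = dict(specs)
        self.settings = dict(settings or {})

    def __getitem__(self, name: str) -> DistributionSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise ParameterError(f"no distribution spec for '{name}'") from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def names(self) -> tuple[str, ...]:
        return tuple(self._specs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSpecs":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, source=str(path))

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], source: str = "<dict>") -> "ParameterSpecs":
        specs: dict[str, DistributionSpec] = {}

        def leaf(path: str, node: Any) -> None:
            if not isinstance(node, Mapping) or "family" not in node:
                raise ParameterError(f"{source}: '{path}' is not a distribution spec")
            kwargs: dict[str, Any] = {
                "name": path,
                "family": node["family"],
                "mean": float(node["mean"]),
            }
            if "sd" in node:
                kwargs["dispersion"] = float(node["sd"])
            if "ci" in node:
                lo, hi = node["ci"]
                kwargs["ci_low"], kwargs["ci_high"] = float(lo), float(hi)
            for key in ("lo", "hi", "mode"):
                if key in node:
                    kwargs[key] = float(node[key])
            extra = set(node) - {"family", "mean", "sd", "ci", "lo", "hi", "mode"}
            if extra:
                raise ParameterError(f"{source}: '{path}' has unknown keys {sorted(extra)}")
            specs[path] = DistributionSpec(**kwargs)

        def walk(prefix: str, node: Any) -> None:
            if isinstance(node, Mapping) and "family" not in node:
                for key, sub in node.items():
                    walk(f"{prefix}.{key}" if prefix else str(key), sub)
            else:
                leaf(prefix, node)

        data = dict(raw)
        settings = {k: float(v) for k, v in (data.pop("settings", {}) or {}).items()}
        unknown = set(settings) - {"discount_rate", "cycle_days"}
        if unknown:
            raise ParameterError(f"{source}: unknown settings {sorted(unknown)}")
        walk("", data)
        return cls(specs, settings)

    # -- realization ----------------------------------------------------

    def build(self, mode: str = "point", rng: np.random.Generator | None = None) -> ParameterSet:
        """Realize a :class:`ParameterSet`.

        ``mode='point'`` returns the printed means exactly.  ``mode='psa'``
        draws each second-order (parameter-uncertainty) input independently
        from its family (probabilities and utilities clipped to [0, 1]); the
        adherence threshold is drawn from its triangular distribution in PSA
        only.  Parameters listed in :data:`PATIENT_LEVEL_PARAMS` describe
        between-patient spread and keep their point estimates — the cohort
        generator realizes their dispersion patient by patient.
        """
        if mode not in ("point", "psa"):
            raise ParameterError(f"mode must be 'point' or 'psa': got {mode!r}")
        if mode == "psa" and rng is None:
            raise ParameterError("psa mode requires a seeded random generator")

        def value(name: str) -> float:
            spec = self[name]
            if mode == "point" or name in PATIENT_LEVEL_PARAMS:
                return spec.point()
            return float(spec.sample(rng))

        def prob(name: str) -> float:
            return float(np.clip(value(name), 0.0, 1.0))

        agents = []
        for ag in AGENTS:
            p = f"agents.{ag}"
            agents.append(AgentParams(
                name=ag,
                pain_reduction_mean=value(f"{p}.pain_reduction"),
                pain_reduction_sd=self[f"{p}.pain_reduction"].sd,
                p_nonserious_ae=prob(f"{p}.p_nonserious_ae"),
                p_intolerable_ae=prob(f"{p}.p_intolerable_ae"),
                p_serious_ae=prob(f"{p}.p_serious_ae"),
                adherence_mean=prob(f"{p}.adherence"),
                adherence_sd=self[f"{p}.adherence"].sd,
                discontinuation_rate=prob(f"{p}.discontinuation_rate"),
                wholesale_cost_per_month=value(f"{p}.wholesale_cost_per_month"),
                oop_cost_per_month=value(f"{p}.oop_cost_per_month"),
            ))

        cannabis = CannabisParams(
            pain_reduction_mean=value("cannabis.pain_reduction"),
            pain_reduction_sd=self["cannabis.pain_reduction"].sd,
            p_nonserious_mono=prob("cannabis.p_nonserious_mono"),
            p_intolerable_mono=prob("cannabis.p_intolerable_mono"),
            p_serious_mono=prob("cannabis.p_serious_mono"),
            or_nonserious=value("cannabis.or_nonserious"),
            or_serious=value("cannabis.or_serious"),
            or_nonserious_nonuser=value("cannabis.or_nonserious_nonuser"),
            or_serious_nonuser=value("cannabis.or_serious_nonuser"),
            adherence_mean=prob("cannabis.adherence"),
            adherence_sd=self["cannabis.adherence"].sd,
            discontinuation_rate=prob("cannabis.discontinuation_rate"),
            price_per_gram=value("cannabis.price_per_gram"),
            daily_thc_g=value("cannabis.daily_thc_g"),
            thc_fraction=value("cannabis.thc_fraction"),
            wastage_fraction=0.0,
            wastage_scenario_fraction=self["cannabis.wastage"].point(),
        )

        threshold_spec = self["adherence_threshold"]
        threshold = threshold_spec.point() if mode == "point" else float(threshold_spec.sample(rng))

        u_mild = prob("utilities.mild")
        u_modsev = prob("utilities.moderate_severe")
        if u_modsev >= u_mild:  # rare PSA draw ordering flip; keep states ordered
            u_mild, u_modsev = max(u_mild, u_modsev), min(u_mild, u_modsev)
            if u_mild == u_modsev:
                u_modsev = max(0.0, u_mild - 1e-9)

        return ParameterSet(
            baseline_age_mean=value("baseline.age"),
            baseline_age_sd=self["baseline.age"].sd,
            baseline_pain_mean=value("baseline.pain_score"),
            baseline_pain_sd=self["baseline.pain_score"].sd,
            agents=tuple(agents),
            cannabis=cannabis,
            adherence_threshold=threshold,
            sae_death_risk=tuple(prob(f"sae_death_risk.{k}") for k in _BAND_KEYS),
            sae_hospital_cost=tuple(value(f"sae_hospital_cost.{k}") for k in _BAND_KEYS),
            sae_hospital_oop=value("sae_hospital_oop"),
            u_mild=u_mild,
            u_modsev=u_modsev,
            d_tolerable=prob("decrements.tolerable"),
            d_intolerable=prob("decrements.intolerable"),
            d_serious=prob("decrements.serious"),
            visit_regular=value("visit_costs.regular"),
            visit_sae=value("visit_costs.sae"),
            visit_regular_oop=value("visit_costs.regular_oop"),
            visit_sae_oop=value("visit_costs.sae_oop"),
            discount_rate=self.settings.get("discount_rate", 0.03),
            cycle_days=self.settings.get("cycle_days", 42.0),
        )

    def point(self) -> ParameterSet:
        return self.build("point")

    def sample(self, rng: np.random.Generator) -> ParameterSet:
        return self.build("psa", rng)


def load_parameter_specs(path: str | Path | None = None) -> ParameterSpecs:
    """Load distribution specs from ``path`` (default: the packaged file)."""
    return ParameterSpecs.from_yaml(path if path is not None else default_parameter_file())


def sample_parameter_set(specs: ParameterSpecs, mode: str = "point",
                         rng: np.random.Generator | None = None) -> ParameterSet:
    """Realize a :class:`ParameterSet` from ``specs`` (see :meth:`ParameterSpecs.build`)."""
    return specs.build(mode, rng)
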