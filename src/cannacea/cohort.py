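"""Synthetic treatment-naive patient cohorts.

Patients enter the model newly diagnosed with chronic neuropathic pain, in
the moderate-to-severe pain state (11-point Likert score >= 4).  Baseline
age and pain score are drawn from the published normal distributions (age
truncated below at 18, pain truncated to [4, 10] so every patient starts
moderate-to-severe).  Every patient starts standard therapy on duloxetine
and holds a uniformly random ordering of the remaining three agents for
later lines.

Individual heterogeneity is drawn once per patient at cohort creation:

* a per-agent pain-score reduction ~ Normal(agent mean, agent SD), fixed
  for the whole episode on that agent (a negative draw means the drug
  worsens that patient's pain);
* a per-agent adherence level ~ Beta fitted to the agent's adherence
  moments, compared against the adherence threshold tau to give a fixed
  adherent/nonadherent flag;
* the same two draws for adjunctive cannabis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .parameters import AGENTS, AGE_BAND_LABELS, ParameterSet, beta_params_clamped

__all__ = ["Cohort", "Patient", "draw_cohort", "draw_patient"]

_BAND_EDGES = np.array([45.0, 65.0, 85.0])


def age_band_of(age) -> np.ndarray:
    """Map age in years to band index 0..3 (18-44, 45-64, 65-84, 85+)."""
    return np.searchsorted(_BAND_EDGES, np.asarray(age, dtype=float), side="right")


@dataclass
class Cohort:
    """Vectorized container of per-patient baseline draws.

    Agent-indexed arrays are laid out by *sequence slot* (column j holds the
    patient's j-th line of standard therapy); ``agent_idx`` maps slots to
    canonical agent indices, with column 0 always duloxetine.
    """

    age: np.ndarray              # (n,) years
    age_band: np.ndarray         # (n,) int 0..3
    baseline_pain: np.ndarray    # (n,) Likert 0-10, all >= 4 at entry
    agent_idx: np.ndarray        # (n, 4) int, column 0 == 0
    agent_reduction: np.ndarray  # (n, 4) Likert reduction per slot
    agent_adherence: np.ndarray  # (n, 4) adherence level in [0, 1]
    agent_adherent: np.ndarray   # (n, 4) bool, level >= tau
    cannabis_reduction: np.ndarray  # (n,)
    cannabis_adherence: np.ndarray  # (n,)
    cannabis_adherent: np.ndarray   # (n,) bool

    @property
    def n(self) -> int:
        return self.age.shape[0]


def _truncated_normal(mean: float, sd: float, low: float, high: float,
                      size: int, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return np.full(size, np.clip(mean, low, high))
    a = (low - mean) / sd
    b = (high - mean) / sd if np.isfinite(high) else np.inf
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_cohort(params: ParameterSet, n: int, rng: np.random.Generator) -> Cohort:
    """Draw ``n`` patients with the baseline structure described above.

    The number and order of random draws is fixed for given ``n``, so two
    runs seeded identically remain aligned even when parameter values differ
    (common-random-number discipline for sensitivity analyses).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    age = _truncated_normal(params.baseline_age_mean, params.baseline_age_sd,
                            18.0, np.inf, n, rng)
    pain = _truncated_normal(params.baseline_pain_mean, params.baseline_pain_sd,
                             4.0, 10.0, n, rng)

    # duloxetine first; the other three agents in uniformly random order
    agent_idx = np.zeros((n, 4), dtype=np.int64)
    agent_idx[:, 1:] = 1 + np.argsort(rng.random((n, 3)), axis=1)

    red_mean = np.array([a.pain_reduction_mean for a in params.agents])
    red_sd = np.array([a.pain_reduction_sd for a in params.agents])
    agent_reduction = red_mean[agent_idx] + red_sd[agent_idx] * rng.standard_normal((n, 4))

    ab = [beta_params_clamped(a.adherence_mean, a.adherence_sd, f"agents.{a.name}.adherence")
          for a in params.agents]
    alpha = np.array([p[0] for p in ab])
    beta = np.array([p[1] for p in ab])
    agent_adherence = rng.beta(alpha[agent_idx], beta[agent_idx])

    c = params.cannabis
    cannabis_reduction = rng.normal(c.pain_reduction_mean, c.pain_reduction_sd, size=n)
    ca, cb = beta_params_clamped(c.adherence_mean, c.adherence_sd, "cannabis.adherence")
    cannabis_adherence = rng.beta(ca, cb, size=n)

    tau = params.adherence_threshold
    return Cohort(
        age=age,
        age_band=age_band_of(age),
        baseline_pain=pain,
        agent_idx=agent_idx,
        agent_reduction=agent_reduction,
        agent_adherence=agent_adherence,
        agent_adherent=agent_adherence >= tau,
        cannabis_reduction=cannabis_reduction,
        cannabis_adherence=cannabis_adherence,
        cannabis_adherent=cannabis_adherence >= tau,
    )


@dataclass
class Patient:
    """One simulated individual (scalar view of a cohort row plus run state)."""

    age: float
    age_band: str
    baseline_pain: float
    agent_sequence: tuple[str, ...]
    response_draws: dict[str, float]
    adherent: dict[str, bool]
    cannabis_response: float
    cannabis_adherent: bool
    alive: bool = True
    current_line: int = 1
    cannabis_state: str = "not_started"          # not_started | active | failed
    poor_relief_cycles_on_current: int = 0
    pain_state: str = "moderate_severe"          # mild | moderate_severe
    cycles_on_cannabis: int = 0
    _band_index: int = field(default=0, repr=False)


def patient_from_cohort(cohort: Cohort, i: int) -> Patient:
    seq = tuple(AGENTS[j] for j in cohort.agent_idx[i])
    return Patient(
        age=float(cohort.age[i]),
        age_band=AGE_BAND_LABELS[int(cohort.age_band[i])],
        baseline_pain=float(cohort.baseline_pain[i]),
        agent_sequence=seq,
        response_draws={name: float(cohort.agent_reduction[i, j]) for j, name in enumerate(seq)},
        adherent={name: bool(cohort.agent_adherent[i, j]) for j, name in enumerate(seq)},
        cannabis_response=float(cohort.cannabis_reduction[i]),
        cannabis_adherent=bool(cohort.cannabis_adherent[i]),
        _band_index=int(cohort.age_band[i]),
    )


def draw_patient(params: ParameterSet, rng: np.random.Generator) -> Patient:
    """Draw a single patient (see :func:`draw_cohort` for the structure)."""
    return patient_from_cohort(draw_cohort(params, 1, rng), 0)
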