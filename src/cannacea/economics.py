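"""Per-cycle cost and QALY accrual.

Costs take a U.S. health-care-sector perspective: third-party payer costs
plus patient out-of-pocket costs.  Components are standard-agent drug costs
(wholesale + out-of-pocket, priced per 1-month supply and prorated to the
6-week cycle), cannabis purchases (priced from THC dose, product potency,
price per gram and wastage), office visits, and SAE hospitalizations.
Costs and QALYs are discounted at 3% annually, applied at cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "CostBreakdown",
    "accrue_cycle",
    "cannabis_cycle_cost",
    "discount_factor",
    "prorate_monthly_cost",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # 30.4375

#: cost component names, in ledger order
COMPONENTS = ("drug_wholesale", "drug_oop", "cannabis", "visits", "sae_hospital")

#: adverse-event classes in engine encoding order
AE_CLASSES = ("none", "tolerable", "intolerable", "serious")


@dataclass
class CostBreakdown:
    """Discounted cost components for one cycle or one whole patient ledger."""

    drug_wholesale: float = 0.0
    drug_oop: float = 0.0
    cannabis: float = 0.0
    visits: float = 0.0
    sae_hospital: float = 0.0

    @property
    def total(self) -> float:
        return (self.drug_wholesale + self.drug_oop + self.cannabis
                + self.visits + self.sae_hospital)

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(*(getattr(self, c) + getattr(other, c) for c in COMPONENTS))


def discount_factor(cycle_index, rate: float = 0.03, cycle_days: float = 42.0):
    """Discount factor ``(1+rate)**(-t)`` at the start of a 6-week cycle.

    ``t = cycle_index * cycle_days / 365.25`` years.  Vectorizes over
    ``cycle_index``.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be nonnegative: got {rate}")
    t = np.asarray(cycle_index, dtype=float) * cycle_days / DAYS_PER_YEAR
    out = (1.0 + rate) ** (-t)
    return float(out) if np.isscalar(cycle_index) else out


def cannabis_cycle_cost(price_per_gram: float, daily_thc_g: float, thc_fraction: float,
                        wastage: float = 0.0, cycle_days: float = 42.0) -> float:
    """Cost of the cannabis purchased for one cycle.

    The daily THC dose is delivered by whole-plant product of the given THC
    fraction; wastage inflates the quantity that must be bought:
    ``grams/day = daily_thc_g / thc_fraction / (1 - wastage)``.
    """
    if thc_fraction <= 0.0:
        raise ValueError("THC fraction must be positive")
    if not 0.0 <= wastage < 1.0:
        raise ValueError(f"wastage must lie in [0, 1): got {wastage}")
    grams_per_day = daily_thc_g / thc_fraction / (1.0 - wastage)
    return grams_per_day * price_per_gram * cycle_days


def prorate_monthly_cost(cost_per_month: float, cycle_days: float = 42.0) -> float:
    """Prorate a 1-month-supply drug cost to one cycle (calendar-month basis)."""
    return cost_per_month * cycle_days / DAYS_PER_MONTH


def cycle_utility(mild, ae_class, params: ParameterSet):
    """State utility net of adverse-event decrement, floored at 0.

    ``ae_class`` follows the engine encoding 0=none, 1=tolerable,
    2=intolerable, 3=serious.  Vectorized.
    """
    decrements = np.array([0.0, params.d_tolerable, params.d_intolerable, params.d_serious])
    u = np.where(mild, params.u_mild, params.u_modsev) - decrements[np.asarray(ae_class)]
    return np.maximum(u, 0.0)


def accrue_cycle(*, params: ParameterSet, cycle_index: int, mild: bool,
                 ae_class: str, died: bool, age_band: int,
                 on_agent: bool = True, agent_index: int = 0,
                 cannabis_active: bool = False, weight: float = 1.0,
                 alive_at_entry: bool = True) -> tuple[CostBreakdown, float]:
    """Accrue one cycle's discounted costs and QALYs for a single patient.

    ``weight`` scales the final fractional cycle of the horizon.  A patient
    dead at cycle entry accrues nothing; a patient who dies during the cycle
    accrues the cycle's costs (including SAE hospitalization) and half the
    cycle's QALYs.
    """
    if not alive_at_entry:
        return CostBreakdown(), 0.0
    if ae_class not in AE_CLASSES:
        raise ValueError(f"unknown adverse-event class {ae_class!r}")
    df = discount_factor(cycle_index, params.discount_rate, params.cycle_days)
    dt = params.cycle_days / DAYS_PER_YEAR
    ae_idx = AE_CLASSES.index(ae_class)
    serious = ae_class == "serious"

    utility = float(cycle_utility(mild, ae_idx, params))
    qaly = weight * dt * utility * df
    if died:
        qaly *= 0.5

    costs = CostBreakdown()
    if on_agent:
        agent = params.agents[agent_index]
        costs.drug_wholesale = prorate_monthly_cost(
            agent.wholesale_cost_per_month, params.cycle_days) * weight * df
        costs.drug_oop = prorate_monthly_cost(
            agent.oop_cost_per_month, params.cycle_days) * weight * df
    if cannabis_active:
        c = params.cannabis
        costs.cannabis = cannabis_cycle_cost(
            c.price_per_gram, c.daily_thc_g, c.thc_fraction,
            c.wastage_fraction, params.cycle_days) * weight * df
    if serious:
        costs.visits = (params.visit_sae + params.visit_sae_oop) * weight * df
        costs.sae_hospital = (params.sae_hospital_cost[age_band]
                              + params.sae_hospital_oop) * df
    else:
        costs.visits = (params.visit_regular + params.visit_regular_oop) * weight * df
    return costs, qaly
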