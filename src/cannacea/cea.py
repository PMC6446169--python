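"""Cost-effectiveness aggregation: frontier, dominance, NMB and CEAC.

A strategy is *strictly dominated* when some alternative is at least as
effective and no more costly (strict in at least one).  It is *extendedly
dominated* when it is excluded from the efficient frontier because a more
effective alternative has a lower incremental cost-effectiveness ratio
(ICER); ICERs along a valid frontier are strictly increasing with
effectiveness, each computed referent to the next least costly
nondominated option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrontierEntry",
    "StrategyResult",
    "build_frontier",
    "ceac",
    "net_monetary_benefit",
    "pairwise_icer",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrategyResult:
    """Cohort means for one strategy arm, with Monte-Carlo standard errors."""

    strategy: str
    mean_cost: float
    mean_qaly: float
    se_cost: float = 0.0
    se_qaly: float = 0.0
    n: int = 0
    components: dict | None = None

    def __post_init__(self) -> None:
        if self.mean_qaly < 0:
            raise ValueError(f"{self.strategy}: mean QALYs must be nonnegative")


@dataclass(frozen=True)
class FrontierEntry:
    """One strategy's position on (or off) the cost-effectiveness frontier."""

    strategy: str
    status: str  # reference | on_frontier | dominated | extendedly_dominated
    mean_cost: float
    mean_qaly: float
    incr_cost: float | None = None
    incr_qaly: float | None = None
    icer: float | None = None


def pairwise_icer(reference: StrategyResult, alternative: StrategyResult) -> float:
    """ICER of ``alternative`` vs ``reference`` ($/QALY); +/-inf on zero QALY gain."""
    dq = alternative.mean_qaly - reference.mean_qaly
    dc = alternative.mean_cost - reference.mean_cost
    if dq == 0.0:
        return float("inf") if dc >= 0 else float("-inf")
    return dc / dq


def net_monetary_benefit(cost, qaly, wtp: float):
    """Net monetary benefit ``wtp * qaly - cost`` (vectorized)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * np.asarray(qaly) - np.asarray(cost)


def build_frontier(results: Sequence[StrategyResult]) -> list[FrontierEntry]:
    """Classify strategies and compute frontier ICERs.

    Returns one entry per input strategy, in input order.  The least costly
    nondominated strategy is the ``reference``; every other surviving
    strategy is ``on_frontier`` with its ICER computed against the previous
    survivor in the cost-ordered chain.  Exact (cost, QALY) ties are broken
    deterministically by input order and logged.
    """
    if not results:
        raise ValueError("at least one strategy is required")
    order = {r.strategy: i for i, r in enumerate(results)}
    ranked = sorted(results, key=lambda r: (r.mean_cost, -r.mean_qaly, order[r.strategy]))

    for a in ranked:
        for b in ranked:
            if a is not b and a.mean_cost == b.mean_cost and a.mean_qaly == b.mean_qaly:
                logger.info("tie between %s and %s broken by declared order",
                            a.strategy, b.strategy)

    status: dict[str, str] = {}
    # strict dominance: someone is no more costly and at least as effective,
    # strictly better on one margin (ties resolved by declared order)
    for r in results:
        for other in results:
            if other is r:
                continue
            better = (other.mean_cost <= r.mean_cost and other.mean_qaly >= r.mean_qaly
                      and (other.mean_cost < r.mean_cost or other.mean_qaly > r.mean_qaly))
            equal = (other.mean_cost == r.mean_cost and other.mean_qaly == r.mean_qaly
                     and order[other.strategy] < order[r.strategy])
            if better or equal:
                status[r.strategy] = "dominated"
                break

    chain = [r for r in ranked if status.get(r.strategy) != "dominated"]
    # extended dominance: drop entries whose ICER vs the previous survivor is
    # not strictly below the next entry's ICER
    changed = True
    while changed and len(chain) > 2:
        changed = False
        for i in range(1, len(chain) - 1):
            icer_here = pairwise_icer(chain[i - 1], chain[i])
            icer_next = pairwise_icer(chain[i], chain[i + 1])
            if icer_here >= icer_next:
                status[chain[i].strategy] = "extendedly_dominated"
                del chain[i]
                changed = True
                break

    entries: dict[str, FrontierEntry] = {}
    for i, r in enumerate(chain):
        if i == 0:
            entries[r.strategy] = FrontierEntry(r.strategy, "reference",
                                                r.mean_cost, r.mean_qaly)
        else:
            prev = chain[i - 1]
            dc = r.mean_cost - prev.mean_cost
            dq = r.mean_qaly - prev.mean_qaly
            entries[r.strategy] = FrontierEntry(r.strategy, "on_frontier",
                                                r.mean_cost, r.mean_qaly,
                                                incr_cost=dc, incr_qaly=dq,
                                                icer=pairwise_icer(prev, r))
    for r in results:
        if r.strategy not in entries:
            entries[r.strategy] = FrontierEntry(r.strategy, status[r.strategy],
                                                r.mean_cost, r.mean_qaly)
    return [entries[r.strategy] for r in results]


def ceac(costs: np.ndarray, qalys: np.ndarray, wtp_grid: Sequence[float],
         strategies: Sequence[str]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA iterations.

    ``costs`` and ``qalys`` are (iterations, strategies) arrays of cohort
    means.  At each willingness-to-pay threshold the fraction of iterations
    in which each strategy attains the maximal net monetary benefit is
    returned (rows index the WTP grid, columns the strategies; each row sums
    to 1).  NMB ties within an iteration go to the cheaper strategy (then to
    declared order) and are logged.
    """
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    if costs.ndim != 2 or costs.shape != qalys.shape:
        raise ValueError("costs and qalys must be matching (iterations, strategies) arrays")
    n_iter, n_strat = costs.shape
    if n_iter < 1 or len(strategies) != n_strat:
        raise ValueError("need >= 1 iteration and one name per strategy column")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size < 1:
        raise ValueError("need >= 1 willingness-to-pay threshold")

    probs = np.empty((wtp.size, n_strat))
    tie_count = 0
    for k, w in enumerate(wtp):
        nmb = net_monetary_benefit(costs, qalys, float(w))
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb == best
        ties = is_best.sum(axis=1) > 1
        tie_count += int(ties.sum())
        # among maximizers, pick the cheapest (declared order breaks residual ties)
        masked_cost = np.where(is_best, costs, np.inf)
        winner = masked_cost.argmin(axis=1)
        probs[k] = np.bincount(winner, minlength=n_strat) / n_iter
    if tie_count:
        logger.info("%d NMB ties broken toward the cheaper strategy", tie_count)
    return pd.DataFrame(probs, index=pd.Index(wtp, name="wtp"), columns=list(strategies))
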