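"""Economic outputs: net monetary benefit, ICER efficiency frontier, MCSE.

The incremental cost-effectiveness ratio (ICER) between two strategies is
dC/dE, the incremental cost per quality-adjusted life-year gained. A
strategy is strictly dominated when another delivers at least as many
QALYs for less cost, and extended-dominated when a mixture of two other
strategies would; the remaining strategies form the efficiency frontier,
along which ICERs are strictly increasing. Net monetary benefit at a
willingness-to-pay threshold lambda is NMB = lambda * E - C; the
NMB-maximal strategy at any lambda always lies on the frontier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "net_monetary_benefit",
    "FrontierEntry",
    "EconResult",
    "efficiency_frontier",
    "icer_mcse",
]

REFERENCE = "reference"
ON_FRONTIER = "frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


def net_monetary_benefit(mean_qaly, mean_cost, wtp: float):
    """NMB = lambda x effectiveness - cost (vectorises over inputs)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * np.asarray(mean_qaly) - np.asarray(mean_cost)


@dataclass
class FrontierEntry:
    label: str
    cost: float
    qaly: float
    status: str                 # reference | frontier | dominated | extended_dominated
    icer: float | None = None   # vs previous frontier member
    icer_mcse: float | None = None
    nmb: float | None = None
    nmb_rank: int | None = None


@dataclass
class EconResult:
    entries: list[FrontierEntry]
    wtp: float

    @property
    def frontier(self) -> list[FrontierEntry]:
        """Undominated strategies, ordered by ascending cost."""
        kept = [e for e in self.entries if e.status in (REFERENCE, ON_FRONTIER)]
        return sorted(kept, key=lambda e: (e.cost, e.qaly))

    def entry(self, label: str) -> FrontierEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def optimal(self) -> FrontierEntry:
        """The NMB-maximal strategy at this result's willingness-to-pay."""
        return max(self.entries, key=lambda e: e.nmb)


def efficiency_frontier(
    points: Mapping[str, tuple[float, float]] | Sequence[tuple[float, float]],
    wtp: float = 100_000.0,
) -> EconResult:
    """Classify strategies and compute frontier ICERs.

    Parameters
    ----------
    points
        Mapping label -> (mean cost, mean QALY), or a sequence of
        (cost, qaly) pairs (labelled by index). Ties in cost/QALY are
        broken by input order.
    wtp
        Willingness-to-pay used for the reported NMB and NMB ranks.
    """
    if isinstance(points, Mapping):
        labels = list(points.keys())
        pairs = [points[k] for k in labels]
    else:
        pairs = list(points)
        labels = [str(i) for i in range(len(pairs))]
    if not pairs:
        raise ValueError("efficiency_frontier requires at least one strategy")

    entries = [
        FrontierEntry(label=lab, cost=float(c), qaly=float(q), status=ON_FRONTIER)
        for lab, (c, q) in zip(labels, pairs)
    ]

    # Sort by ascending cost (ties: descending QALY, then input order).
    order = sorted(range(len(entries)), key=lambda i: (entries[i].cost, -entries[i].qaly, i))

    # Strict dominance: more costly and no more effective than a cheaper option.
    best_qaly = -math.inf
    candidates: list[int] = []
    for i in order:
        e = entries[i]
        if e.qaly <= best_qaly:
            e.status = DOMINATED
        else:
            best_qaly = e.qaly
            candidates.append(i)

    # Extended dominance: drop candidates until ICERs strictly increase.
    while True:
        removed = False
        for k in range(1, len(candidates) - 1):
            a, b, c = (entries[candidates[k - 1]], entries[candidates[k]], entries[candidates[k + 1]])
            icer_ab = (b.cost - a.cost) / (b.qaly - a.qaly)
            icer_bc = (c.cost - b.cost) / (c.qaly - b.qaly)
            if icer_bc <= icer_ab:
                b.status = EXTENDED_DOMINATED
                del candidates[k]
                removed = True
                break
        if not removed:
            break

    for pos, i in enumerate(candidates):
        e = entries[i]
        if pos == 0:
            e.status = REFERENCE
            e.icer = None
        else:
            prev = entries[candidates[pos - 1]]
            e.status = ON_FRONTIER
            e.icer = (e.cost - prev.cost) / (e.qaly - prev.qaly)

    nmb = net_monetary_benefit([e.qaly for e in entries], [e.cost for e in entries], wtp)
    for e, v in zip(entries, nmb):
        e.nmb = float(v)
    for rank, e in enumerate(sorted(entries, key=lambda e: -e.nmb), start=1):
        e.nmb_rank = rank
    return EconResult(entries=entries, wtp=wtp)


def icer_mcse(
    costs_a: np.ndarray,
    qalys_a: np.ndarray,
    costs_b: np.ndarray,
    qalys_b: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Monte Carlo standard error of the ICER of strategy B vs A.

    Nonparametric paired bootstrap: patients are resampled with
    replacement, the same indices applied to both strategies (preserving
    common-random-number pairing), and the ICER of the resampled means
    recomputed; the reported MCSE is the standard deviation of the
    bootstrap ICERs.

    Returns ``(mcse, unstable)`` where ``unstable`` flags bootstrap
    replicates in which the incremental QALY changed sign — the ICER is
    then ill-behaved and the MCSE should be interpreted with care (a
    RuntimeWarning is also emitted).
    """
    costs_a = np.asarray(costs_a, dtype=float)
    qalys_a = np.asarray(qalys_a, dtype=float)
    costs_b = np.asarray(costs_b, dtype=float)
    qalys_b = np.asarray(qalys_b, dtype=float)
    n = costs_a.size
    if not (qalys_a.size == costs_b.size == qalys_b.size == n):
        raise ValueError("paired patient-level arrays must have equal length")

    d_cost = costs_b - costs_a
    d_qaly = qalys_b - qalys_a
    if np.all(d_cost == d_cost[0]) and np.all(d_qaly == d_qaly[0]):
        return 0.0, False  # zero-variance input

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    dc = d_cost[idx].mean(axis=1)
    de = d_qaly[idx].mean(axis=1)
    base_sign = np.sign(d_qaly.mean())
    unstable = bool(np.any(np.sign(de) != base_sign) or np.any(de == 0.0))
    if unstable:
        warnings.warn(
            "incremental QALY changes sign across bootstrap replicates; "
            "ICER MCSE is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = dc / de
    icers = icers[np.isfinite(icers)]
    if icers.size < 2:
        return float("nan"), unstable
    return float(np.std(icers, ddof=1)), unstable
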