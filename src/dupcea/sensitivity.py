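"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs all regimens with a single parameter pushed to
its low and high bound (common random numbers, so ranking changes are
attributable to the parameter). Probabilistic sensitivity analysis (PSA)
samples every uncertain parameter jointly and independently from its
fitted distribution — beta for probabilities and utilities, truncated
normal for costs and days off work, uniform for the starting age — and
evaluates every regimen per draw; cost-effectiveness acceptability curves
(CEAC) report, per willingness-to-pay value, the fraction of draws in
which each regimen attains maximal net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .economics import net_monetary_benefit
from .lifetable import MortalityModel
from .microsim import Regimen, enumerate_regimens, run_all_regimens
from .params import ParameterError, ParameterSet, Scenario, fit_distribution

__all__ = [
    "OWSARecord",
    "one_way_sweep",
    "owsa_all",
    "PSAResult",
    "run_psa",
    "CEACResult",
    "ceac",
    "default_wtp_grid",
]


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid $0..300k in $10k steps."""
    return np.arange(0.0, 300_001.0, 10_000.0)


# ---------------------------------------------------------------------------
# one-way (deterministic) sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class OWSARecord:
    param_id: str
    low: float
    high: float
    optimal_at_low: str
    optimal_at_base: str
    optimal_at_high: str
    nmb_at_low: dict[str, float] = field(repr=False)
    nmb_at_base: dict[str, float] = field(repr=False)
    nmb_at_high: dict[str, float] = field(repr=False)
    focal_pair: tuple[str, str] = ("PNA-PNA-PNA", "LF-LF-LF")

    def focal_spread(self, setting: str) -> float:
        """NMB(first focal regimen) - NMB(second) at low/base/high."""
        table = {"low": self.nmb_at_low, "base": self.nmb_at_base, "high": self.nmb_at_high}[setting]
        a, b = self.focal_pair
        return table[a] - table[b]

    @property
    def tornado_width(self) -> float:
        """Absolute swing of the focal-pair NMB gap across the bounds."""
        return abs(self.focal_spread("high") - self.focal_spread("low"))


def _nmb_table(results, wtp: float) -> dict[str, float]:
    return {
        label: float(net_monetary_benefit(r.mean_qaly, r.mean_cost, wtp))
        for label, r in results.items()
    }


def one_way_sweep(
    param_id: str,
    params: ParameterSet,
    scenario: Scenario,
    wtp: float | None = None,
    n: int | None = None,
    seed: int = 0,
    *,
    mortality: MortalityModel | None = None,
    regimens: Sequence[Regimen] | None = None,
    focal_pair: tuple[str, str] = ("PNA-PNA-PNA", "LF-LF-LF"),
) -> OWSARecord:
    """Re-run every regimen with one parameter at its low and high bound.

    The same seed (hence the same uniform streams) is used at the base,
    low and high settings, so the recorded NMB changes and any change of
    the optimal regimen are caused by the swept parameter alone.
    """
    value = params.get(param_id)  # raises ParameterError if unknown
    if wtp is None:
        wtp = params.econ.willingness_to_pay

    tables: dict[str, dict[str, float]] = {}
    optima: dict[str, str] = {}
    for setting, x in (("low", value.low), ("base", value.base), ("high", value.high)):
        pset = params if x == value.base else params.with_value(param_id, x)
        results = run_all_regimens(
            scenario, pset, mortality, n, seed, regimens=regimens
        )
        table = _nmb_table(results, wtp)
        tables[setting] = table
        optima[setting] = max(table, key=table.get)

    return OWSARecord(
        param_id=param_id,
        low=value.low,
        high=value.high,
        optimal_at_low=optima["low"],
        optimal_at_base=optima["base"],
        optimal_at_high=optima["high"],
        nmb_at_low=tables["low"],
        nmb_at_base=tables["base"],
        nmb_at_high=tables["high"],
        focal_pair=focal_pair,
    )


def owsa_all(
    params: ParameterSet,
    scenario: Scenario,
    wtp: float | None = None,
    n: int | None = None,
    seed: int = 0,
    *,
    mortality: MortalityModel | None = None,
    param_ids: Sequence[str] | None = None,
    focal_pair: tuple[str, str] = ("PNA-PNA-PNA", "LF-LF-LF"),
) -> list[OWSARecord]:
    """One-way sweep of every (or a chosen subset of) model parameter."""
    ids = list(param_ids) if param_ids is not None else params.parameter_ids()
    return [
        one_way_sweep(
            pid, params, scenario, wtp, n, seed,
            mortality=mortality, focal_pair=focal_pair,
        )
        for pid in ids
    ]


def owsa_tornado_frame(records: Sequence[OWSARecord]) -> pd.DataFrame:
    """Tornado table: one row per parameter, sorted by NMB-gap swing."""
    rows = [
        {
            "parameter": r.param_id,
            "low": r.low,
            "high": r.high,
            "gap_at_low": r.focal_spread("low"),
            "gap_at_base": r.focal_spread("base"),
            "gap_at_high": r.focal_spread("high"),
            "swing": r.tornado_width,
            "optimal_at_low": r.optimal_at_low,
            "optimal_at_high": r.optimal_at_high,
        }
        for r in records
    ]
    return pd.DataFrame(rows).sort_values("swing", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    scenario: Scenario
    labels: list[str]
    costs: np.ndarray   # (n_draws, n_regimens) per-draw mean cost
    qalys: np.ndarray   # (n_draws, n_regimens)
    n_draws: int
    patients_per_draw: int
    sampled: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def run_psa(
    params: ParameterSet,
    scenario: Scenario,
    n_draws: int = 10_000,
    patients_per_draw: int = 1,
    seed: int | None = None,
    *,
    mortality: MortalityModel | None = None,
    regimens: Sequence[Regimen] | None = None,
    vary: Sequence[str] | None = None,
) -> PSAResult:
    """Joint parameter-uncertainty simulation over all regimens.

    Per draw, every non-fixed parameter (including the starting age,
    sampled uniformly over its bounds) is drawn independently from its
    fitted distribution; all regimens are then evaluated on the same
    simulated patients (common random numbers within a draw). With
    ``patients_per_draw = 1`` each draw is a single simulated patient —
    parameter uncertainty and patient-level stochasticity mix, which is
    the literal single-level design; larger values average each draw over
    a small cohort, separating the two uncertainty levels.

    ``vary`` restricts sampling to the named parameter ids; an empty
    sequence collapses every distribution to its base value.
    """
    if n_draws < 1 or patients_per_draw < 1:
        raise ParameterError("n_draws and patients_per_draw must be >= 1")
    rng = np.random.default_rng(seed)
    flat = {fp.id: fp for fp in params.flatten()}
    if vary is None:
        vary_ids = list(flat)
    else:
        for pid in vary:
            if pid not in flat:
                raise ParameterError(f"unknown parameter id {pid!r}")
        vary_ids = list(vary)

    sampled: dict[str, np.ndarray] = {}
    for pid in vary_ids:
        fp = flat[pid]
        dist = fit_distribution(fp.value, unit_interval=fp.unit_interval)
        if dist.kind == "point":
            continue
        sampled[pid] = np.asarray(dist.sample(rng, n_draws), dtype=float)

    m = patients_per_draw
    n_total = n_draws * m
    sampled_rep = (
        sampled if m == 1 else {k: np.repeat(v, m) for k, v in sampled.items()}
    )

    results = run_all_regimens(
        scenario,
        params,
        mortality,
        n_total,
        seed=int(rng.integers(0, 2**31 - 1)),
        regimens=regimens,
        sampled=sampled_rep,
    )
    labels = list(results.keys())
    costs = np.column_stack([results[k].costs for k in labels])
    qalys = np.column_stack([results[k].qalys for k in labels])
    if m > 1:
        costs = costs.reshape(n_draws, m, -1).mean(axis=1)
        qalys = qalys.reshape(n_draws, m, -1).mean(axis=1)
    return PSAResult(
        scenario=scenario,
        labels=labels,
        costs=costs,
        qalys=qalys,
        n_draws=n_draws,
        patients_per_draw=m,
        sampled=sampled,
    )


@dataclass
class CEACResult:
    scenario: Scenario
    labels: list[str]
    wtp_grid: np.ndarray
    probabilities: np.ndarray  # (n_wtp, n_regimens), rows sum to 1

    def probability(self, label: str, wtp: float) -> float:
        j = self.labels.index(label)
        i = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        if abs(self.wtp_grid[i] - wtp) > 1e-6:
            raise KeyError(f"willingness-to-pay {wtp} not on the grid")
        return float(self.probabilities[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (scenario, regimen, wtp, probability)."""
        rows = []
        for i, wtp in enumerate(self.wtp_grid):
            for j, label in enumerate(self.labels):
                rows.append(
                    {
                        "scenario": self.scenario.label,
                        "regimen": label,
                        "wtp": float(wtp),
                        "probability": float(self.probabilities[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def ceac(psa: PSAResult, wtp_grid: Sequence[float] | None = None) -> CEACResult:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each willingness-to-pay value, the regimen with maximal net
    monetary benefit wins the draw (ties broken by regimen enumeration
    order); probabilities are win fractions and sum to one.
    """
    grid = np.asarray(wtp_grid if wtp_grid is not None else default_wtp_grid(), dtype=float)
    if grid.size == 0:
        raise ParameterError("willingness-to-pay grid must be non-empty")
    n_reg = len(psa.labels)
    probs = np.empty((grid.size, n_reg))
    for i, wtp in enumerate(grid):
        nmb = wtp * psa.qalys - psa.costs
        winners = np.argmax(nmb, axis=1)
        probs[i] = np.bincount(winners, minlength=n_reg) / psa.n_draws
    return CEACResult(
        scenario=psa.scenario, labels=list(psa.labels), wtp_grid=grid, probabilities=probs
    )
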