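"""Patient-level annual-cycle simulation of recurrent contracture treatment.

Each simulated patient starts symptomatic at the cohort entry age and works
through a fixed regimen of three treatment attempts. Within a one-year
cycle: a symptomatic patient with attempts remaining receives the next
treatment in the sequence (accruing its direct cost, any sampled
complication costs and, under the societal perspective, wage loss below
retirement age) and moves to the symptom-free state on a success draw; a
patient who entered the cycle symptom-free faces an annual recurrence draw
governed by the treatment that produced the remission; the year's utility
(full symptom-free utility, or the scenario's symptomatic utility for a
year with failure, recurrence or untreated disease) and costs are
discounted at the annual rate; finally the patient faces an age-dependent
mortality draw, so the entry year is always accrued. After the third
treatment, recurrent disease persists until death.

A deterministic expected-value recursion over the expanded state space
(health state x treatments used x age) provides an exact analytic oracle
for the cohort means.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .lifetable import MortalityModel, build_mortality
from .params import (
    ParameterError,
    ParameterSet,
    Scenario,
    TREATMENTS,
    Treatment,
)

__all__ = [
    "Regimen",
    "enumerate_regimens",
    "UniformStreams",
    "PatientResult",
    "CohortResult",
    "simulate_patient",
    "simulate_cohort",
    "run_all_regimens",
    "expected_value_recursion",
]

_MAX_TREATMENTS = 3
_N_COMPLICATION_SLOTS = 6  # widest complication list over the treatments


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of exactly three treatment attempts."""

    treatments: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.treatments) != _MAX_TREATMENTS:
            raise ParameterError("a regimen holds exactly 3 treatments")
        for t in self.treatments:
            if t not in (tr.value for tr in TREATMENTS):
                raise ParameterError(f"unknown treatment {t!r} in regimen")

    @classmethod
    def from_label(cls, label: str) -> "Regimen":
        parts = tuple(label.replace("_", "-").upper().split("-"))
        return cls(parts)  # type: ignore[arg-type]

    @property
    def label(self) -> str:
        return "-".join(self.treatments)

    def __str__(self) -> str:
        return self.label


def enumerate_regimens() -> list[Regimen]:
    """All 27 ordered three-treatment sequences, in a stable order."""
    return [
        Regimen(combo)
        for combo in itertools.product([t.value for t in TREATMENTS], repeat=3)
    ]


@dataclass
class UniformStreams:
    """Pre-drawn uniform random streams shared across regimens.

    Keeping the mortality, success, recurrence and complication draws in
    per-patient, per-cycle arrays makes runs reproducible and lets the
    same patients be pushed through every regimen (common random numbers),
    which sharply reduces the variance of incremental comparisons.
    """

    mortality: np.ndarray     # (n, cycles)
    success: np.ndarray       # (n, cycles)
    recurrence: np.ndarray    # (n, cycles)
    complication: np.ndarray  # (n, cycles, slots)

    @property
    def n(self) -> int:
        return self.mortality.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.mortality.shape[1]

    @classmethod
    def draw(
        cls,
        rng: np.random.Generator,
        n: int,
        n_cycles: int,
        n_complication_slots: int = _N_COMPLICATION_SLOTS,
    ) -> "UniformStreams":
        return cls(
            mortality=rng.random((n, n_cycles)),
            success=rng.random((n, n_cycles)),
            recurrence=rng.random((n, n_cycles)),
            complication=rng.random((n, n_cycles, n_complication_slots)),
        )


@dataclass(frozen=True)
class Event:
    cycle: int
    kind: str  # treatment | success | failure | recurrence | complication | death
    detail: str = ""


@dataclass
class PatientResult:
    discounted_cost: float
    discounted_qaly: float
    discounted_life_years: float
    events: list[Event]
    time_to_first_recurrence: float | None
    death_age: float | None
    n_treatments: int


@dataclass
class CohortResult:
    """Aggregate of ``n`` independent simulated patients for one regimen."""

    regimen: Regimen
    scenario: Scenario
    n: int
    mean_cost: float
    sd_cost: float
    mean_qaly: float
    sd_qaly: float
    mean_time_to_first_recurrence: float
    costs: np.ndarray = field(repr=False)
    qalys: np.ndarray = field(repr=False)
    life_years: np.ndarray = field(repr=False)
    time_to_first_recurrence: np.ndarray = field(repr=False)
    death_age: np.ndarray = field(repr=False)
    n_treatments: np.ndarray = field(repr=False)
    patient_results: list[PatientResult] | None = None

    @property
    def se_cost(self) -> float:
        return self.sd_cost / math.sqrt(self.n)

    @property
    def se_qaly(self) -> float:
        return self.sd_qaly / math.sqrt(self.n)


# ---------------------------------------------------------------------------
# compiled per-run inputs
# ---------------------------------------------------------------------------

def _value(pid: str, base: float, sampled: Mapping[str, np.ndarray] | None):
    if sampled is not None and pid in sampled:
        return np.asarray(sampled[pid], dtype=float)
    return base


def _take(x, mask):
    return x[mask] if isinstance(x, np.ndarray) and x.ndim > 0 else x


@dataclass
class _Compiled:
    n: int
    n_cycles: int
    start_age: np.ndarray              # (n,)
    p_succ: list                       # per slot, scalar or (n,)
    p_rec: list
    direct: list
    days_off: list
    comps: list                        # per slot: list of (rate, cost)
    u_sympt: object                    # scalar or (n,)
    u_free: float
    daily_wage: float
    retirement_age: float
    discount_rate: float
    societal: bool
    success_year_free: bool
    mortality: MortalityModel


def _compile(
    regimen: Regimen,
    scenario: Scenario,
    params: ParameterSet,
    mortality: MortalityModel,
    n: int,
    *,
    start_age=None,
    sampled: Mapping[str, np.ndarray] | None = None,
) -> _Compiled:
    j, s = scenario.joint, scenario.severity
    if start_age is None:
        start_age = _value("age", params.age.base, sampled)
    start_age = np.broadcast_to(np.asarray(start_age, dtype=float), (n,)).copy()

    p_succ, p_rec, direct, days_off, comps = [], [], [], [], []
    for t in regimen.treatments:
        p_succ.append(
            _value(f"success.{t}.{j}.{s}", params.success[(t, j, s)].base, sampled)
        )
        p_rec.append(
            _value(f"recurrence.{t}.{j}.{s}", params.recurrence[(t, j, s)].base, sampled)
        )
        total = 0.0
        for cname, pv in params.direct_components(t).items():
            total = total + _value(f"direct_cost.{t}.{cname}", pv.base, sampled)
        direct.append(total)
        days_off.append(_value(f"days_off.{t}", params.days_off_work[t].base, sampled))
        clist = []
        for label, rate, cost in params.complications(t):
            clist.append(
                (
                    _value(f"complication_rate.{t}.{label}", rate.base, sampled),
                    _value(f"complication_cost.{label}", cost.base, sampled),
                )
            )
        comps.append(clist)

    max_age = getattr(mortality, "max_age", 100.0)
    n_cycles = int(math.ceil(max_age - float(np.min(start_age)))) + 1
    return _Compiled(
        n=n,
        n_cycles=n_cycles,
        start_age=start_age,
        p_succ=p_succ,
        p_rec=p_rec,
        direct=direct,
        days_off=days_off,
        comps=comps,
        u_sympt=_value(f"utility.{j}.{s}", params.utilities[(j, s)].base, sampled),
        u_free=params.symptom_free_utility,
        daily_wage=params.indirect.daily_wage,
        retirement_age=params.indirect.retirement_age,
        discount_rate=params.econ.discount_rate,
        societal=params.econ.perspective == "societal",
        success_year_free=params.sim.success_year_utility == "symptom_free",
        mortality=mortality,
    )


# ---------------------------------------------------------------------------
# core engine
# ---------------------------------------------------------------------------

def _run(c: _Compiled, streams: UniformStreams, regimen: Regimen, keep_events: bool = False):
    n = c.n
    if streams.n < n or streams.n_cycles < c.n_cycles:
        raise ParameterError(
            f"uniform streams too small: need ({n}, {c.n_cycles}), "
            f"got ({streams.n}, {streams.n_cycles})"
        )
    alive = np.ones(n, dtype=bool)
    free = np.zeros(n, dtype=bool)
    slots = np.zeros(n, dtype=np.int64)
    cur_rec = np.zeros(n, dtype=float)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    life = np.zeros(n)
    t_first_rec = np.full(n, np.nan)
    death_age = np.full(n, np.nan)
    n_treat = np.zeros(n, dtype=np.int64)
    events: list[list[Event]] | None = [[] for _ in range(n)] if keep_events else None
    idx_all = np.arange(n)

    for t in range(c.n_cycles):
        if not alive.any():
            break
        age = c.start_age + t
        disc = (1.0 + c.discount_rate) ** (-t)
        entered_free = free.copy()
        sympt = alive & ~entered_free
        succ_now = np.zeros(n, dtype=bool)
        slots_at_entry = slots.copy()  # one treatment per cycle at most

        for s in range(_MAX_TREATMENTS):
            m = sympt & (slots_at_entry == s)
            if not m.any():
                continue
            idx = idx_all[m]
            treatment = regimen.treatments[s]
            add = np.broadcast_to(
                np.asarray(_take(c.direct[s], m), dtype=float), idx.shape
            ).copy()
            if c.societal:
                working = age[m] < c.retirement_age
                add += np.where(working, _take(c.days_off[s], m) * c.daily_wage, 0.0)
            for jslot, (rate, ccost) in enumerate(c.comps[s]):
                hit = streams.complication[idx, t, jslot] < _take(rate, m)
                add += np.where(hit, _take(ccost, m), 0.0)
                if keep_events and hit.any():
                    for i in idx[hit]:
                        events[i].append(Event(t, "complication", treatment))
            cost[idx] += add * disc
            ok = streams.success[idx, t] < _take(c.p_succ[s], m)
            free[idx[ok]] = True
            succ_now[idx[ok]] = True
            rec_p = np.broadcast_to(
                np.asarray(_take(c.p_rec[s], m), dtype=float), idx.shape
            )
            cur_rec[idx[ok]] = rec_p[ok]
            slots[idx] += 1
            n_treat[idx] += 1
            if keep_events:
                for i in idx:
                    events[i].append(Event(t, "treatment", treatment))
                for i in idx[ok]:
                    events[i].append(Event(t, "success", treatment))
                for i in idx[~ok]:
                    events[i].append(Event(t, "failure", treatment))

        rec = alive & entered_free & (streams.recurrence[:, t] < cur_rec)
        free[rec] = False
        newly = rec & np.isnan(t_first_rec)
        t_first_rec[newly] = t
        if keep_events and rec.any():
            for i in idx_all[rec]:
                events[i].append(Event(t, "recurrence"))

        u_year = np.where(free, c.u_free, c.u_sympt)
        if not c.success_year_free:
            u_year = np.where(succ_now, np.broadcast_to(np.asarray(c.u_sympt, float), (n,)), u_year)
        qaly += np.where(alive, u_year * disc, 0.0)
        life += np.where(alive, disc, 0.0)

        h = c.mortality.annual_probability(age)
        die = alive & (streams.mortality[:, t] < h)
        death_age[die] = age[die] + 1.0
        alive &= ~die
        if keep_events and die.any():
            for i in idx_all[die]:
                events[i].append(Event(t, "death"))

    return {
        "cost": cost,
        "qaly": qaly,
        "life": life,
        "t_first_rec": t_first_rec,
        "death_age": death_age,
        "n_treat": n_treat,
        "events": events,
    }


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

def _resolve_mortality(params: ParameterSet, mortality: MortalityModel | None) -> MortalityModel:
    return mortality if mortality is not None else build_mortality(params.mortality)


def simulate_patient(
    regimen: Regimen,
    scenario: Scenario,
    params: ParameterSet,
    mortality: MortalityModel | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    streams: UniformStreams | None = None,
    start_age: float | None = None,
) -> PatientResult:
    """Simulate a single patient and return the full event log."""
    mortality = _resolve_mortality(params, mortality)
    compiled = _compile(regimen, scenario, params, mortality, 1, start_age=start_age)
    if streams is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        streams = UniformStreams.draw(rng, 1, compiled.n_cycles)
    out = _run(compiled, streams, regimen, keep_events=True)
    ttr = out["t_first_rec"][0]
    da = out["death_age"][0]
    return PatientResult(
        discounted_cost=float(out["cost"][0]),
        discounted_qaly=float(out["qaly"][0]),
        discounted_life_years=float(out["life"][0]),
        events=out["events"][0],
        time_to_first_recurrence=None if np.isnan(ttr) else float(ttr),
        death_age=None if np.isnan(da) else float(da),
        n_treatments=int(out["n_treat"][0]),
    )


def simulate_cohort(
    regimen: Regimen,
    scenario: Scenario,
    params: ParameterSet,
    mortality: MortalityModel | None = None,
    n: int | None = None,
    seed: int | np.random.Generator | None = None,
    *,
    streams: UniformStreams | None = None,
    sampled: Mapping[str, np.ndarray] | None = None,
    start_age=None,
    keep_patients: bool = False,
) -> CohortResult:
    """Simulate ``n`` independent patients under one regimen.

    Passing the same ``streams`` object for several regimens runs them on
    identical random draws (common random numbers).
    """
    mortality = _resolve_mortality(params, mortality)
    if n is None:
        n = streams.n if streams is not None else params.sim.n_patients
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    compiled = _compile(
        regimen, scenario, params, mortality, n, start_age=start_age, sampled=sampled
    )
    if streams is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        streams = UniformStreams.draw(rng, n, compiled.n_cycles)
    out = _run(compiled, streams, regimen, keep_events=keep_patients)

    patient_results = None
    if keep_patients:
        patient_results = []
        for i in range(n):
            ttr = out["t_first_rec"][i]
            da = out["death_age"][i]
            patient_results.append(
                PatientResult(
                    discounted_cost=float(out["cost"][i]),
                    discounted_qaly=float(out["qaly"][i]),
                    discounted_life_years=float(out["life"][i]),
                    events=out["events"][i],
                    time_to_first_recurrence=None if np.isnan(ttr) else float(ttr),
                    death_age=None if np.isnan(da) else float(da),
                    n_treatments=int(out["n_treat"][i]),
                )
            )

    costs, qalys = out["cost"], out["qaly"]
    ddof = 1 if n > 1 else 0
    with np.errstate(invalid="ignore"):
        mean_ttr = float(np.nanmean(out["t_first_rec"])) if np.any(
            ~np.isnan(out["t_first_rec"])
        ) else float("nan")
    return CohortResult(
        regimen=regimen,
        scenario=scenario,
        n=n,
        mean_cost=float(costs.mean()),
        sd_cost=float(costs.std(ddof=ddof)),
        mean_qaly=float(qalys.mean()),
        sd_qaly=float(qalys.std(ddof=ddof)),
        mean_time_to_first_recurrence=mean_ttr,
        costs=costs,
        qalys=qalys,
        life_years=out["life"],
        time_to_first_recurrence=out["t_first_rec"],
        death_age=out["death_age"],
        n_treatments=out["n_treat"],
        patient_results=patient_results,
    )


def run_all_regimens(
    scenario: Scenario,
    params: ParameterSet,
    mortality: MortalityModel | None = None,
    n: int | None = None,
    seed: int | None = None,
    *,
    regimens: Sequence[Regimen] | None = None,
    common_random_numbers: bool = True,
    sampled: Mapping[str, np.ndarray] | None = None,
    start_age=None,
) -> dict[str, CohortResult]:
    """Simulate every regimen for one scenario, sharing random streams.

    With common random numbers (default) every regimen sees the same
    per-patient uniform draws, so incremental cost and QALY differences
    reflect the regimens rather than sampling noise.
    """
    mortality = _resolve_mortality(params, mortality)
    if regimens is None:
        regimens = enumerate_regimens()
    if n is None:
        n = params.sim.n_patients
    if start_age is None:
        start_age = _value("age", params.age.base, sampled)
    start_arr = np.broadcast_to(np.asarray(start_age, dtype=float), (n,))
    max_age = getattr(mortality, "max_age", 100.0)
    n_cycles = int(math.ceil(max_age - float(start_arr.min()))) + 1

    rng = np.random.default_rng(seed)
    shared = UniformStreams.draw(rng, n, n_cycles) if common_random_numbers else None
    results: dict[str, CohortResult] = {}
    for reg in regimens:
        streams = shared if shared is not None else UniformStreams.draw(rng, n, n_cycles)
        results[reg.label] = simulate_cohort(
            reg,
            scenario,
            params,
            mortality,
            n,
            streams=streams,
            sampled=sampled,
            start_age=start_age,
        )
    return results


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------

def expected_value_recursion(
    regimen: Regimen,
    scenario: Scenario,
    params: ParameterSet,
    mortality: MortalityModel | None = None,
    *,
    start_age: float | None = None,
) -> tuple[float, float]:
    """Exact expected discounted (cost, QALY) for one regimen.

    Forward recursion propagating occupancy probabilities over the states
    (symptomatic with s treatments used, s = 0..3; symptom-free after the
    s-th treatment, s = 1..3), with complication costs entering in
    expectation. Shares every accounting convention with the stochastic
    engine, of which it is the analytic expectation.
    """
    from .params import direct_cost as _dc, expected_complication_cost as _ecc

    mortality = _resolve_mortality(params, mortality)
    if start_age is None:
        start_age = params.age.base
    j, s_ = scenario.joint, scenario.severity
    r = params.econ.discount_rate
    u_free = params.symptom_free_utility
    u_sympt = params.utilities[(j, s_)].base
    societal = params.econ.perspective == "societal"
    daily_wage = params.indirect.daily_wage
    retire = params.indirect.retirement_age
    success_year_free = params.sim.success_year_utility == "symptom_free"

    p_succ = [params.success[(t, j, s_)].base for t in regimen.treatments]
    p_rec = [params.recurrence[(t, j, s_)].base for t in regimen.treatments]
    base_cost = [_dc(t, params) + _ecc(t, params) for t in regimen.treatments]
    days = [params.days_off_work[t].base for t in regimen.treatments]

    max_age = getattr(mortality, "max_age", 100.0)
    horizon = int(math.ceil(max_age - start_age)) + 1

    occ_sympt = np.zeros(4)  # treatments used 0..3
    occ_free = np.zeros(4)   # symptom-free after treatment s (1..3)
    occ_sympt[0] = 1.0
    total_cost = 0.0
    total_qaly = 0.0

    for t in range(horizon):
        age = start_age + t
        disc = (1.0 + r) ** (-t)
        new_sympt = np.zeros(4)
        new_free = np.zeros(4)

        for s in range(_MAX_TREATMENTS):
            occ = occ_sympt[s]
            if occ <= 0.0:
                continue
            c = base_cost[s]
            if societal and age < retire:
                c += days[s] * daily_wage
            total_cost += occ * c * disc
            p = p_succ[s]
            new_free[s + 1] += occ * p
            new_sympt[s + 1] += occ * (1.0 - p)
            u_success_year = u_free if success_year_free else u_sympt
            total_qaly += occ * (p * u_success_year + (1.0 - p) * u_sympt) * disc

        total_qaly += occ_sympt[3] * u_sympt * disc
        new_sympt[3] += occ_sympt[3]

        for s in range(1, 4):
            occ = occ_free[s]
            if occ <= 0.0:
                continue
            q = p_rec[s - 1]
            new_sympt[s] += occ * q
            new_free[s] += occ * (1.0 - q)
            total_qaly += occ * (q * u_sympt + (1.0 - q) * u_free) * disc

        h = float(mortality.annual_probability(age))
        occ_sympt = new_sympt * (1.0 - h)
        occ_free = new_free * (1.0 - h)
        if occ_sympt.sum() + occ_free.sum() < 1e-15:
            break

    return float(total_cost), float(total_qaly)
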