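"""Scenario-grid runner: batch simulation, tables and manifest.

Runs the full analysis for any set of contracture scenarios — cohort
results for every regimen, the ICER efficiency frontier with bootstrap
MCSEs, and optionally one-way and probabilistic sensitivity analyses —
and writes deterministic CSV/JSON artifacts plus a manifest (seed, config
hash, code version) from which a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .economics import efficiency_frontier, icer_mcse
from .lifetable import build_mortality
from .microsim import CohortResult, Regimen, enumerate_regimens, run_all_regimens
from .params import ParameterError, ParameterSet, Scenario, SCENARIOS, load_parameters
from .sensitivity import ceac, default_wtp_grid, owsa_all, owsa_tornado_frame, run_psa

__all__ = ["RunConfig", "run_scenario_grid", "cohort_table", "frontier_table"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a scenario-grid run; defaults are the base case."""

    scenarios: Sequence[str] = ("MCP/low", "MCP/high", "PIP/low", "PIP/high")
    regimens: Sequence[str] | None = None  # None = all 27
    n_patients: int | None = None          # None = parameter-set default (10 000)
    seed: int = 0
    wtp: float | None = None               # None = parameter-set default ($100k/QALY)
    perspective: str | None = None
    discount_rate: float | None = None
    config_path: str | None = None
    run_owsa: bool = False
    owsa_params: Sequence[str] | None = None
    run_psa: bool = False
    psa_draws: int = 10_000
    patients_per_draw: int = 1
    n_boot: int = 1000
    out_dir: str = "results"

    def parameter_overrides(self) -> dict:
        overrides: dict = {}
        if self.perspective is not None:
            overrides.setdefault("economics", {})["perspective"] = self.perspective
        if self.discount_rate is not None:
            overrides.setdefault("economics", {})["discount_rate"] = self.discount_rate
        if self.wtp is not None:
            overrides.setdefault("economics", {})["willingness_to_pay"] = self.wtp
        if self.n_patients is not None:
            overrides.setdefault("simulation", {})["n_patients"] = self.n_patients
        return overrides


def _scenario(label: str) -> Scenario:
    try:
        joint, severity = label.replace("_", "/").split("/")
    except ValueError as exc:
        raise ParameterError(f"bad scenario label {label!r}; expected e.g. 'MCP/low'") from exc
    return Scenario(joint, severity)


def cohort_table(results: Mapping[str, CohortResult]) -> pd.DataFrame:
    """Per-regimen summary mirroring the cost/QALY results layout."""
    rows = [
        {
            "regimen": label,
            "n": r.n,
            "mean_cost": r.mean_cost,
            "sd_cost": r.sd_cost,
            "mean_qaly": r.mean_qaly,
            "sd_qaly": r.sd_qaly,
            "mean_time_to_first_recurrence": r.mean_time_to_first_recurrence,
        }
        for label, r in results.items()
    ]
    return pd.DataFrame(rows)


def frontier_table(
    results: Mapping[str, CohortResult],
    wtp: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Frontier classification with ICERs and bootstrap MCSEs."""
    econ = efficiency_frontier(
        {label: (r.mean_cost, r.mean_qaly) for label, r in results.items()}, wtp=wtp
    )
    prev_label: str | None = None
    rows = []
    for e in sorted(econ.entries, key=lambda e: e.cost):
        mcse = np.nan
        if e.status == "frontier" and prev_label is not None and n_boot > 0:
            ref = results[prev_label]
            cur = results[e.label]
            mcse, _ = icer_mcse(
                ref.costs, ref.qalys, cur.costs, cur.qalys, n_boot=n_boot, seed=seed
            )
        if e.status in ("reference", "frontier"):
            prev_label = e.label
        rows.append(
            {
                "regimen": e.label,
                "mean_cost": e.cost,
                "mean_qaly": e.qaly,
                "status": e.status,
                "icer": e.icer if e.icer is not None else np.nan,
                "icer_mcse": mcse,
                "nmb": e.nmb,
                "nmb_rank": e.nmb_rank,
            }
        )
    return pd.DataFrame(rows)


def _config_hash(params: ParameterSet) -> str:
    canonical = yaml.safe_dump(params.raw, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_scenario_grid(config: RunConfig, params: ParameterSet | None = None) -> dict:
    """Run the configured scenario grid and write all artifacts.

    Returns a bundle ``{scenario label: {"cohorts": ..., "frontier": ...,
    "ceac": ..., "owsa": ...}}`` plus the manifest dict under ``"manifest"``.
    Identical config and seed produce byte-identical output files.
    """
    if params is None:
        params = load_parameters(config.config_path, overrides=config.parameter_overrides())
    mortality = build_mortality(params.mortality)
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ParameterError(f"output directory {config.out_dir!r} is not writable: {exc}") from exc

    n = params.sim.n_patients
    if n < 1:
        raise ParameterError("simulation.n_patients must be >= 1")
    wtp = params.econ.willingness_to_pay
    regimens = None
    if config.regimens is not None:
        regimens = [Regimen.from_label(lbl) for lbl in config.regimens]

    bundle: dict = {}
    for label in config.scenarios:
        scen = _scenario(label)
        tag = f"{scen.joint}_{scen.severity}"
        log.info("scenario %s: simulating %d regimens x %d patients (seed=%d)",
                 scen.label, len(regimens or enumerate_regimens()), n, config.seed)
        results = run_all_regimens(scen, params, mortality, n, config.seed, regimens=regimens)
        cohorts = cohort_table(results)
        frontier = frontier_table(results, wtp, n_boot=config.n_boot, seed=config.seed)
        cohorts.to_csv(out / f"cohort_{tag}.csv", index=False)
        frontier.to_csv(out / f"frontier_{tag}.csv", index=False)
        entry = {"cohorts": cohorts, "frontier": frontier}

        if config.run_owsa:
            records = owsa_all(
                params, scen, wtp, n, config.seed,
                mortality=mortality, param_ids=config.owsa_params,
            )
            tornado = owsa_tornado_frame(records)
            tornado.to_csv(out / f"owsa_{tag}.csv", index=False)
            entry["owsa"] = tornado
        if config.run_psa:
            log.info("scenario %s: PSA with %d draws x %d patients",
                     scen.label, config.psa_draws, config.patients_per_draw)
            psa = run_psa(
                params, scen, config.psa_draws, config.patients_per_draw,
                config.seed, mortality=mortality, regimens=regimens,
            )
            curves = ceac(psa, default_wtp_grid())
            curves.to_frame().to_csv(out / f"ceac_{tag}.csv", index=False)
            entry["ceac"] = curves
        bundle[scen.label] = entry

    manifest = {
        "package": "dupcea",
        "version": __version__,
        "seed": config.seed,
        "n_patients": n,
        "willingness_to_pay": wtp,
        "perspective": params.econ.perspective,
        "discount_rate": params.econ.discount_rate,
        "scenarios": list(config.scenarios),
        "regimens": list(config.regimens) if config.regimens is not None else "all",
        "psa": {"enabled": config.run_psa, "draws": config.psa_draws,
                "patients_per_draw": config.patients_per_draw},
        "owsa": {"enabled": config.run_owsa},
        "config_hash": _config_hash(params),
        "config_path": config.config_path,
        "run_config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def run_from_manifest(manifest_path: str) -> dict:
    """Re-run a grid exactly as recorded in a manifest file."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    rc = manifest["run_config"]
    cfg = RunConfig(**{k: (tuple(v) if isinstance(v, list) and k in ("scenarios", "regimens")
                           else v) for k, v in rc.items()})
    return run_scenario_grid(cfg)
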