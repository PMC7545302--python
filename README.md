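# dupcea — cost-effectiveness of recurrent Dupuytren contracture treatment

`dupcea` is a patient-level state-transition (Markov) microsimulation and
full cost-effectiveness analysis of treatment sequences for **recurrent
Dupuytren contracture**, written for health-economics researchers and hand
surgeons comparing the three standard interventions:

- **CCH** — collagenase clostridium histolyticum injection,
- **PNA** — percutaneous needle aponeurotomy,
- **LF** — limited fasciectomy.

Patients may attempt up to three treatments for a single contracture, so
there are 27 ordered regimens (CCH/PNA/LF in every sequence). Treatment
success and annual recurrence depend on the affected joint
(metacarpophalangeal, MCP, vs proximal interphalangeal, PIP) and on
contracture severity (below vs above 45° of flexion). The package
reimplements the published US analysis of this question — all model inputs
are bundled as a validated default configuration — and reproduces its
base-case results.

## Model in brief

Three health states: *symptomatic*, *symptom-free*, *dead*. Annual cycles
over a lifetime horizon from entry age 60 (death certain by 100). Each
cycle a symptomatic patient with attempts remaining receives the next
treatment in the regimen and becomes symptom-free with probability
`p_success(treatment, joint, severity)`; symptom-free patients recur with
annual probability `p_recurrence(treatment, joint, severity)`; after the
third treatment, recurrent disease persists until death. Mortality follows
a Gompertz hazard anchored to US all-cause rates (0.87%/yr at 60, 0.18%/yr
at 45).

Costs (2018–19 USD, societal perspective) accrue per treatment event:
direct components, complication costs sampled per event, and lost wages.
Utilities are 1.0 when symptom-free and 0.938–0.970 in the symptomatic
state depending on phenotype. Costs and QALYs are discounted at 3%/yr.
Outputs follow standard health-economic practice:

- **ICER** efficiency frontier with strict and extended dominance,
  `ICER = ΔC/ΔE` against the previous frontier member,
- **NMB** `= λ·E − C` at willingness-to-pay λ ($100 000/QALY by default),
- bootstrap **MCSE** for frontier ICERs,
- one-way sensitivity analysis (tornado) over every Table-of-inputs
  parameter,
- probabilistic sensitivity analysis with **CEAC** curves (every
  parameter drawn jointly from beta / truncated-normal / uniform
  distributions).

See `docs/methods.md` for conventions, distribution fitting, validation
and limitations.

## Worked example

```python
import dupcea as d

params = d.load_parameters()                  # packaged base-case inputs
mort = d.build_mortality(params.mortality)
scen = d.Scenario("MCP", "high")              # severe knuckle contracture

results = d.run_all_regimens(scen, params, mort, n=10_000, seed=1)
econ = d.efficiency_frontier(
    {k: (r.mean_cost, r.mean_qaly) for k, r in results.items()}, wtp=100_000
)
for e in econ.frontier:
    print(e.label, round(e.cost), round(e.qaly, 2), e.icer and round(e.icer))
```

```
PNA-PNA-PNA 3505 14.61 None
PNA-PNA-LF 11107 14.7 86336
PNA-LF-LF 18876 14.78 96070
LF-LF-LF 26678 14.86 98289
```

Reading: for severe MCP contractures, escalating from repeat needle
aponeurotomy to sequences ending in fasciectomy buys extra QALYs at
$86k–98k per QALY — below the conventional $100 000/QALY threshold, so
LF-containing sequences are cost-effective here. Running the same code for
`Scenario("MCP", "low")` or either PIP scenario puts every step above
$200k/QALY, leaving PNA-PNA-PNA (mean cost ≈ $3.3k, ≈15.1 QALYs for
low-severity MCP) the only cost-effective regimen.

The same analysis is packaged as narrative drivers:

```bash
python analysis/01_base_case.py          # cohort + frontier tables, 4 scenarios
python analysis/02_owsa_tornado.py       # one-way sensitivity tornado
python analysis/03_psa_ceac.py           # PSA + acceptability curves
python analysis/04_external_validity.py  # time-to-first-recurrence check
```

or as a CLI: `dupcea report --scenario MCP/high --out results/` (also
`simulate | frontier | owsa | psa | ceac`; any model input can be
overridden from a YAML file via `--config`, mirroring
`src/dupcea/data/table1_defaults.yaml`).

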