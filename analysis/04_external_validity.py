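#!/usr/bin/env python
"""External-validity check: simulated time to first recurrence.

Clinical series report first recurrences roughly 19-33 months after
needle aponeurotomy and around 24 months after collagenase injection,
and earlier recurrence at PIP than MCP joints. This driver reports the
model's mean time from entry to the first recurrence event (patients who
never recur are excluded) for single-treatment-type regimens.
"""

import argparse

import numpy as np

from dupcea import Regimen, Scenario, build_mortality, load_parameters, simulate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-patients", type=int, default=10_000)
    args = ap.parse_args()

    params = load_parameters()
    mortality = build_mortality(params.mortality)

    print("mean (sd) years from model entry to first recurrence, by joint:")
    for treatment in ("PNA", "CCH", "LF"):
        reg = Regimen((treatment,) * 3)
        row = [f"  {treatment}:"]
        for joint in ("MCP", "PIP"):
            scen = Scenario(joint, "high")
            res = simulate_cohort(reg, scen, params, mortality,
                                  args.n_patients, seed=args.seed)
            t = res.time_to_first_recurrence
            t = t[~np.isnan(t)]
            row.append(f"{joint} {t.mean():4.1f} ({t.std(ddof=1):4.1f}) y  "
                       f"[{len(t)/args.n_patients:4.0%} recur]")
        print("  ".join(row))
    print("\nNote: entry-to-first-recurrence includes years spent with failed")
    print("treatments before the first remission, so it exceeds the")
    print("remission-to-recurrence times reported in clinical series.")


if __name__ == "__main__":
    main()
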