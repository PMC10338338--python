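#!/usr/bin/env python
"""Contrast the feedback and feed-forward network architectures.

Mitogen-removal trajectories (does CDK2 activity reach zero, and when?),
rescue perturbations (p107/p130 knockout, constitutive cyclin A2),
dose–response curves for pre-R vs post-R branches, and hysteresis widths
at ~mitosis time and at steady state.  The feedback loop is bistable and
stays ON after mitogen removal; the feed-forward chain is transiently
indistinguishable from it at ~11 h but relaxes to a unique OFF state.
"""

import json
from pathlib import Path

import numpy as np

from clockrace.network_models import (Architecture, MitogenSchedule,
                                      build_network, dose_response,
                                      hysteresis_width, simulate_network)

RESULTS = Path(__file__).resolve().parent.parent / "results"
EVAL_TIME = 11.0  # hours; when an MCF-10A cell would normally reach mitosis


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    summary = {}
    removal = MitogenSchedule.constant(0.0)
    for arch in (Architecture.FEEDBACK, Architecture.FEEDFORWARD):
        model = build_network(arch)
        traj = simulate_network(model, removal, horizon=200.0, init="HIGH")
        traj.to_csv(RESULTS / f"trajectory_{arch.value.lower()}.csv",
                    index=False)
        k0 = traj["cdk2"].iloc[0]
        at11 = traj.loc[(traj["time_h"] - EVAL_TIME).abs().idxmin(), "cdk2"]
        final = traj["cdk2"].iloc[-1]
        print(f"{arch.value}: CDK2 after mitogen removal — "
              f"{at11 / k0:.2f} of initial at {EVAL_TIME:g} h, "
              f"{final / k0:.3f} at 200 h")
        summary[arch.value.lower()] = {
            "cdk2_fraction_at_11h": float(at11 / k0),
            "cdk2_fraction_final": float(final / k0),
        }

    ff = build_network(Architecture.FEEDFORWARD)
    for flag in ("knockout_repressor", "constitutive_ccna2"):
        sched = MitogenSchedule.constant(0.0, **{flag: True})
        traj = simulate_network(ff, sched, horizon=200.0, init="HIGH")
        frac = traj["cdk2"].iloc[-1] / traj["cdk2"].iloc[0]
        print(f"feed-forward + {flag}: CDK2 {frac:.2f} of initial at 200 h "
              "(exit abolished)")
        summary[flag] = {"cdk2_fraction_final": float(frac)}

    doses = np.linspace(0.0, 1.0, 51)
    for arch in (Architecture.FEEDBACK, Architecture.FEEDFORWARD):
        model = build_network(arch)
        for label, eval_time in (("11h", EVAL_TIME), ("steady", None)):
            for branch in ("HIGH", "LOW"):
                curve = dose_response(model, doses, eval_time, branch)
                curve.to_csv(
                    RESULTS / f"dose_{arch.value.lower()}_{label}_"
                              f"{branch.lower()}.csv", index=False)
        w = hysteresis_width(model, None)
        w11 = hysteresis_width(model, EVAL_TIME)
        print(f"{arch.value}: hysteresis width {w:.3f} at steady state, "
              f"{w11:.3f} at {EVAL_TIME:g} h")
        summary[arch.value.lower()]["hysteresis_width_steady"] = w
        summary[arch.value.lower()]["hysteresis_width_11h"] = w11

    (RESULTS / "network_summary.json").write_text(
        json.dumps(summary, indent=2))
    print("\nfeed-forward: apparent irreversibility at mitosis time, "
          "no hysteresis at steady state; feedback: true hysteresis.")


if __name__ == "__main__":
    main()
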