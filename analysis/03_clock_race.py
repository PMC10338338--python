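#!/usr/bin/env python
"""Fit the pre-competition clocks and run the Monte Carlo race.

The exit clock is fitted to the mitosis-blocked cohort's exit times and
the mitosis clock to the full-growth cohort's division times (both from
treatment).  The Monte Carlo competition between the two fitted
log-normal clocks should reproduce the exit fraction observed in the
competition cohort, match the closed-form win probability, and its
winner-side exit-time distribution should agree with the observed
post-competition exit times (two-sample KS).
"""

import json
from pathlib import Path

import pandas as pd

from clockrace.race import (ClockFamily, analytic_exit_probability,
                            compare_post_competition, fit_clock_distribution,
                            simulate_competition)

RESULTS = Path(__file__).resolve().parent.parent / "results"
TREATMENT_TIME = 12.0
N_RACE = 100_000
SEED = 20230710


def clock_from_features(path: Path, column: str):
    times = pd.read_csv(path)[column].dropna() - TREATMENT_TIME
    return fit_clock_distribution(times, ClockFamily.LOGNORMAL)


def main() -> None:
    exit_clock = clock_from_features(
        RESULTS / "features_mitosis_blocked.csv", "exit_time")
    mit_clock = clock_from_features(
        RESULTS / "features_full_growth.csv", "mitosis_time")
    print(f"exit clock:    median {exit_clock.median:.2f} h, "
          f"log-sd {exit_clock.log_sd:.3f}")
    print(f"mitosis clock: median {mit_clock.median:.2f} h, "
          f"log-sd {mit_clock.log_sd:.3f}")

    sim = simulate_competition(exit_clock, mit_clock, N_RACE, SEED)
    analytic = analytic_exit_probability(exit_clock, mit_clock)
    print(f"simulated exit fraction {sim.exit_fraction:.4f} "
          f"(analytic {analytic:.4f}, n = {N_RACE})")

    comp = pd.read_csv(RESULTS / "features_competition.csv")
    observed = (comp["exit_time"].dropna() - TREATMENT_TIME).to_numpy()
    obs_fraction = comp["fate"].eq("EXIT").sum() / \
        comp["fate"].isin(["EXIT", "MITOSIS"]).sum()
    stat, p = compare_post_competition(sim, observed, "EXIT")
    print(f"observed exit fraction {obs_fraction:.4f}; "
          f"post-competition exit times KS = {stat:.3f} (p = {p:.3f})")

    summary = {
        "exit_clock": {"median_h": exit_clock.median,
                       "log_sd": exit_clock.log_sd},
        "mitosis_clock": {"median_h": mit_clock.median,
                          "log_sd": mit_clock.log_sd},
        "simulated_exit_fraction": sim.exit_fraction,
        "analytic_exit_probability": analytic,
        "observed_exit_fraction": float(obs_fraction),
        "ks_exit": {"stat": stat, "p": p},
    }
    (RESULTS / "race_summary.json").write_text(json.dumps(summary, indent=2))
    pd.DataFrame({"t": sim.winner_times_exit}).to_csv(
        RESULTS / "winner_times_exit.csv", index=False)
    pd.DataFrame({"t": sim.winner_times_mitosis}).to_csv(
        RESULTS / "winner_times_mitosis.csv", index=False)


if __name__ == "__main__":
    main()
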