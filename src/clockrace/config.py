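"""Run configuration, seeding and the end-to-end pipeline.

A single master seed deterministically derives one sub-seed per stage by
hashing ``"{master_seed}:{stage_name}"`` with SHA-256 and taking the first
four bytes modulo 2^31, so the stages' RNG streams are decoupled but the
whole run is reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as trace_io
from . import race as race_mod
from .kinetics import (KineticParams, estimate_half_life, fit_exit_vs_halflife,
                       predict_exit_time, predict_mrna)
from .network_models import (Architecture, MitogenSchedule, build_network,
                             hysteresis_width, simulate_network)
from .synthetic_data import (TreatmentProgram, generate_decay_assay,
                             generate_population, make_preset)
from .trace_analysis import (AnalysisConfig, classify_fates,
                             exit_fraction_by_offset, fit_exit_logistic)

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

log = logging.getLogger("clockrace")

HALF_LIFE_PRESETS = ("MCF10A", "RPE1", "RPE1_CCNA2dd", "RPE1_CCNA2dd_DIA")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full pipeline run."""

    seed: int
    out_dir: str
    preset: str = "MCF10A"
    treatment: str = "CDK46I"
    n_cells: int = 1000
    delay_hours: float = 0.0
    race_n: int = 100_000
    decay_n: int = 300
    decay_noise_cv: float = 0.04
    cdk2_threshold: float = 0.6
    ode_eval_time: float = 11.0
    ode_dose_step: float = 0.01
    ode_params_file: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.race_n < 1 or self.decay_n < 1:
            raise ValueError("n_cells, race_n and decay_n must all be >= 1")
        if self.decay_noise_cv < 0:
            raise ValueError("decay_noise_cv must be >= 0")
        if not 0 < self.cdk2_threshold < 1.5:
            raise ValueError("cdk2_threshold must lie in (0, 1.5)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw or "out_dir" not in raw:
            raise ValueError("config requires 'seed' and 'out_dir'")
        return cls(**raw)


def _median_event_times(features, attr: str, treatment_time: float):
    vals = [getattr(f, attr) - treatment_time for f in features
            if getattr(f, attr) is not None]
    return (float(np.median(vals)) if vals else None), len(vals)


def run_pipeline(config: RunConfig) -> dict:
    """generate -> analyze -> race -> kinetics -> ode, writing all artifacts.

    Returns (and writes as ``summary.json``) a machine-readable summary with
    the headline quantities of every stage.  Identical config gives an
    identical summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    summary: dict = {"config": dataclasses.asdict(config)}
    preset = make_preset(config.preset)
    cfg = AnalysisConfig(cdk2_exit_threshold=config.cdk2_threshold)

    current_stage = "setup"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s", name)
        return stage_seed(config.seed, name)

    try:
        # --- generate: competition, mitosis-blocked, and full-growth runs
        seed = _stage("generate")
        cohorts = {
            "competition": TreatmentProgram(config.treatment,
                                            delay_hours=config.delay_hours),
            "mitosis_blocked": TreatmentProgram("CDK46I_CDK1I"),
            "full_growth": TreatmentProgram("DMSO"),
        }
        traces = {}
        for i, (name, prog) in enumerate(cohorts.items()):
            traces[name] = generate_population(
                preset, prog, config.n_cells, seed + i)
            trace_io.write_traces(traces[name], out / f"traces_{name}.csv")

        # --- analyze
        _stage("analyze")
        feats = {name: classify_fates(trs, cfg)
                 for name, trs in traces.items()}
        for name, fs in feats.items():
            rows = [dataclasses.asdict(f) for f in fs]
            pd.DataFrame(rows).to_csv(out / f"features_{name}.csv", index=False)
        comp = feats["competition"]
        decided = [f for f in comp if f.fate in ("EXIT", "MITOSIS")]
        observed_exit_fraction = (
            sum(f.fate == "EXIT" for f in decided) / len(decided)
            if decided else float("nan"))
        bins = exit_fraction_by_offset(comp, bin_width=1.0)
        bins.to_csv(out / "exit_fraction_by_offset.csv", index=False)
        logit = fit_exit_logistic(comp)
        t_treat = cohorts["competition"].treatment_time
        exit_median, n_exit = _median_event_times(
            feats["mitosis_blocked"], "exit_time", t_treat)
        mitosis_median, n_mit = _median_event_times(
            feats["full_growth"], "mitosis_time", t_treat)
        summary["analysis"] = {
            "observed_exit_fraction": observed_exit_fraction,
            "exit_clock_median_h": exit_median,
            "mitosis_clock_median_h": mitosis_median,
            "logistic_slope": logit.slope,
            "logistic_p": logit.p_value,
            "logistic_degenerate": logit.degenerate,
        }

        # --- race
        seed = _stage("race")
        exit_clock = race_mod.fit_clock_distribution(
            [f.exit_time - t_treat for f in feats["mitosis_blocked"]
             if f.exit_time is not None], race_mod.ClockFamily.LOGNORMAL)
        mit_clock = race_mod.fit_clock_distribution(
            [f.mitosis_time - t_treat for f in feats["full_growth"]
             if f.mitosis_time is not None], race_mod.ClockFamily.LOGNORMAL)
        sim = race_mod.simulate_competition(
            exit_clock, mit_clock, config.race_n, seed)
        analytic = race_mod.analytic_exit_probability(exit_clock, mit_clock)
        observed_exits = [f.exit_time - t_treat for f in comp
                          if f.exit_time is not None]
        ks = (race_mod.compare_post_competition(sim, observed_exits, "EXIT")
              if observed_exits else (float("nan"), float("nan")))
        summary["race"] = {
            "fitted_exit_clock": {"median": exit_clock.median,
                                  "log_sd": exit_clock.log_sd, "n": n_exit},
            "fitted_mitosis_clock": {"median": mit_clock.median,
                                     "log_sd": mit_clock.log_sd, "n": n_mit},
            "simulated_exit_fraction": sim.exit_fraction,
            "analytic_exit_probability": analytic,
            "ks_exit_stat": ks[0], "ks_exit_p": ks[1],
        }

        # --- kinetics
        seed = _stage("kinetics")
        half_lives, points = {}, []
        for i, name in enumerate(HALF_LIFE_PRESETS):
            p = make_preset(name)
            assay = generate_decay_assay(p, config.decay_n,
                                         config.decay_noise_cv, seed + i)
            ests = [estimate_half_life(tr.times, tr.ccna2).half_life
                    for tr in assay]
            half_lives[name] = float(np.median(ests))
            points.append((p.protein_half_life,
                           predict_exit_time(p.kinetic_params)))
        slope, intercept, r2 = fit_exit_vs_halflife(points)
        summary["kinetics"] = {
            "half_life_estimates_h": half_lives,
            "mrna_remaining_2h_fraction": predict_mrna(KineticParams(h_p=12), 2.0),
            "predicted_exit_times_h": {n: t for (_, t), n
                                       in zip(points, HALF_LIFE_PRESETS)},
            "exit_vs_halflife": {"slope": slope, "intercept": intercept,
                                 "r_squared": r2},
        }

        # --- ode
        _stage("ode")
        summary["ode"] = {}
        for arch in (Architecture.FEEDBACK, Architecture.FEEDFORWARD):
            model = build_network(arch, params_file=config.ode_params_file)
            traj = simulate_network(model, MitogenSchedule.constant(0.0),
                                    horizon=200.0, init="HIGH")
            traj.to_csv(out / f"trajectory_{arch.value.lower()}.csv",
                        index=False)
            k0 = traj["cdk2"].iloc[0]
            summary["ode"][arch.value.lower()] = {
                "cdk2_final_fraction": float(traj["cdk2"].iloc[-1] / k0),
                "cdk2_at_11h_fraction": float(
                    traj.loc[(traj["time_h"] - 11.0).abs().idxmin(), "cdk2"]
                    / k0),
                "hysteresis_width_steady_state": hysteresis_width(
                    model, None, dose_step=config.ode_dose_step),
            }
        summary["ode"]["feedforward"]["hysteresis_width_at_eval_time"] = \
            hysteresis_width(build_network(Architecture.FEEDFORWARD,
                                           params_file=config.ode_params_file),
                             config.ode_eval_time,
                             dose_step=config.ode_dose_step)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage '{current_stage}': {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
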