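"""Synthetic single-cell reporter traces for the competing-clocks analysis.

Emulates live-cell imaging of cells carrying a CDK2 activity sensor
(dimensionless; activity below 0.6 marks cell-cycle exit), an APC/C
activity sensor (high in G0/G1, switched off at S entry, reactivated at
division or premature exit), and optionally a cyclin A2 abundance channel.
Each generated cell is in S/G2 when a treatment lands and then races its
two fate clocks:

* the mitosis clock — remaining time to division, drawn from the cell's
  S-to-mitosis duration minus how far into S/G2 the treatment landed;
* the cell-cycle exit clock — time for cyclin A2 (and hence CDK2 activity)
  to decay below threshold after mitogen/CDK4/6 signalling is lost,
  computed from the kinetic shutoff-cascade model scaled by a median-1
  log-normal cell-to-cell factor.

Treatments that leave mitogen signalling intact (DMSO, CDK1i alone) never
start the exit clock; CDK1i-containing treatments disable the mitosis
clock; S-phase stall pulses extend it by ``delay_hours``; constitutive
cyclin A2 expression (unregulated promoter) disables the exit clock.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import KineticParams, predict_exit_time, predict_protein
from .race import ClockDistribution

__all__ = [
    "TREATMENT_LABELS",
    "PopulationPreset",
    "TreatmentProgram",
    "CellTrace",
    "make_preset",
    "available_presets",
    "generate_population",
    "generate_decay_assay",
]

TREATMENT_LABELS = (
    "DMSO",
    "MITOGEN_REMOVAL",
    "MEKI",
    "CDK46I",
    "CDK1I",
    "CDK46I_CDK1I",
    "MEKI_DOSE",
)

#: treatments that cut mitogen signalling and start the exit clock
_EXIT_TRIGGERS = {"MITOGEN_REMOVAL", "MEKI", "CDK46I", "CDK46I_CDK1I"}
#: treatments that disable the mitosis clock
_MITOSIS_BLOCKERS = {"CDK1I", "CDK46I_CDK1I"}

# --- channel construction constants (sensor conventions) ---
CDK2_AT_S_ENTRY = 0.8       # activity when APC/C switches off
CDK2_AT_TREATMENT = 1.2     # activity of a post-R cell at treatment
CDK2_PRE_MITOSIS = 1.3      # peak just before division
CDK2_START = 0.5            # activity at the start of recording (G1)
CDK2_POST_DIVISION = 0.15   # collapse after anaphase
APC_ON = 1.0
APC_OFF = 0.05
EXIT_THRESHOLD = 0.6        # commitment threshold of the CDK2 sensor
MIN_REMAINING_MITOSIS_H = 0.5
G1_FRACTION_OF_CYCLE = 0.35  # daughter G1 length as fraction of full cycle


@dataclass(frozen=True)
class PopulationPreset:
    """Cell-line preset: kinetic constants plus clock-dispersion settings.

    protein_half_life / mrna_half_life are the cyclin A2 turnover constants
    in hours; threshold_ratio is the pre-treatment cyclin A2 level relative
    to the exit-threshold level.  mitosis_clock is the nominal
    treatment-to-mitosis distribution; exit_clock_dispersion the log-scale
    s.d. of cell-to-cell exit-time scatter.  s_to_m_duration_median and
    treatment_offset_window shape where in S/G2 the treatment lands.
    """

    name: str
    protein_half_life: float
    mrna_half_life: float = 2.0
    threshold_ratio: float = 2.0
    mitosis_clock: ClockDistribution = field(
        default_factory=lambda: ClockDistribution.lognormal(11.0, 0.18)
    )
    exit_clock_dispersion: float = 0.22
    s_to_m_duration_median: float = 14.0
    s_to_m_log_sd: float = 0.18
    treatment_offset_window: float = 6.0

    def __post_init__(self) -> None:
        if not self.protein_half_life > 0 or not self.mrna_half_life > 0:
            raise ValueError("half-lives must be > 0")
        if not self.threshold_ratio > 1:
            raise ValueError("threshold_ratio must be > 1")
        if self.exit_clock_dispersion < 0:
            raise ValueError("exit_clock_dispersion must be >= 0")
        if not self.s_to_m_duration_median > 0:
            raise ValueError("s_to_m_duration_median must be > 0")
        if self.treatment_offset_window < 0:
            raise ValueError("treatment_offset_window must be >= 0")

    @property
    def kinetic_params(self) -> KineticParams:
        return KineticParams(
            h_p=self.protein_half_life,
            h_m=self.mrna_half_life,
            rho=self.threshold_ratio,
        )

    def exit_clock(self) -> ClockDistribution:
        """Pre-competition exit clock implied by the kinetic model."""
        return ClockDistribution.lognormal(
            median=predict_exit_time(self.kinetic_params),
            log_sd=self.exit_clock_dispersion,
        )


_PRESETS: dict[str, PopulationPreset] = {
    # cyclin A2 protein half-lives: 12 h (MCF-10A), 10 h (RPE-1),
    # 5 h (degron-tagged RPE-1), 2 h (+DIA cocktail), ~13 h (U2OS,
    # not printed; excluded from half-life targets)
    "MCF10A": PopulationPreset(name="MCF10A", protein_half_life=12.0),
    "RPE1": PopulationPreset(name="RPE1", protein_half_life=10.0),
    "RPE1_CCNA2dd": PopulationPreset(name="RPE1_CCNA2dd", protein_half_life=5.0),
    "RPE1_CCNA2dd_DIA": PopulationPreset(
        name="RPE1_CCNA2dd_DIA", protein_half_life=2.0
    ),
    "U2OS": PopulationPreset(name="U2OS", protein_half_life=13.0),
}


def available_presets() -> tuple[str, ...]:
    return tuple(_PRESETS)


def make_preset(name: str, **overrides) -> PopulationPreset:
    """Return a built-in cell-line preset, optionally with field overrides."""
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        )
    preset = _PRESETS[name]
    return replace(preset, **overrides) if overrides else preset


@dataclass(frozen=True)
class TreatmentProgram:
    """A treatment applied at ``treatment_time`` hours on the recording clock.

    delay_hours models an S-phase stall pulse that extends the mitosis
    clock; constitutive_ccna2 models cyclin A2 expressed from an
    unregulated promoter (rescues exit); dose applies to MEKI_DOSE only
    (relative MEKi dose in [0, 1]).
    """

    label: str
    delay_hours: float = 0.0
    constitutive_ccna2: bool = False
    treatment_time: float = 12.0
    dose: float | None = None

    def __post_init__(self) -> None:
        if self.label not in TREATMENT_LABELS:
            raise ValueError(
                f"unknown treatment {self.label!r}; one of {TREATMENT_LABELS}"
            )
        if self.delay_hours < 0:
            raise ValueError("delay_hours must be >= 0")
        if self.treatment_time < 0:
            raise ValueError("treatment_time must be >= 0")
        if self.label == "MEKI_DOSE":
            if self.dose is None or not 0.0 <= self.dose <= 1.0:
                raise ValueError("MEKI_DOSE requires dose in [0, 1]")
        elif self.dose is not None:
            raise ValueError("dose is only valid for MEKI_DOSE")

    @property
    def blocks_mitosis(self) -> bool:
        return self.label in _MITOSIS_BLOCKERS

    @property
    def triggers_exit(self) -> bool:
        """Does the treatment cut mitogen signalling and start the exit clock?

        Full-dose MEKi, mitogen removal and CDK4/6i are equivalent exit-clock
        triggers; partial MEKI_DOSE below 1 only drives the ODE module.
        Constitutive cyclin A2 expression rescues exit entirely.
        """
        if self.constitutive_ccna2:
            return False
        if self.label in _EXIT_TRIGGERS:
            return True
        return self.label == "MEKI_DOSE" and self.dose >= 1.0

    @property
    def mitogen_level(self) -> float:
        """Mitogen input S in [0, 1] for the network models."""
        if self.label == "DMSO" or self.label == "CDK1I":
            return 1.0
        if self.label == "MEKI_DOSE":
            return 1.0 - self.dose
        return 0.0

    def encode(self) -> str:
        """Compact string for the trace-table treatment column."""
        s = self.label
        if self.dose is not None:
            s += f"@{self.dose:g}"
        if self.delay_hours:
            s += f"+delay{self.delay_hours:g}"
        if self.constitutive_ccna2:
            s += "+const"
        return s

    @classmethod
    def decode(cls, text: str, treatment_time: float) -> "TreatmentProgram":
        parts = text.split("+")
        head, delay, const = parts[0], 0.0, False
        for p in parts[1:]:
            if p.startswith("delay"):
                delay = float(p[5:])
            elif p == "const":
                const = True
            else:
                raise ValueError(f"unparseable treatment field {text!r}")
        m = re.fullmatch(r"([A-Z0-9_]+)(?:@([0-9.eE+-]+))?", head)
        if m is None:
            raise ValueError(f"unparseable treatment field {text!r}")
        dose = float(m.group(2)) if m.group(2) is not None else None
        return cls(
            label=m.group(1),
            delay_hours=delay,
            constitutive_ccna2=const,
            treatment_time=treatment_time,
            dose=dose,
        )


@dataclass
class CellTrace:
    """One cell's multi-channel reporter time series.

    times is a uniform grid in hours; cdk2/apc/ccna2 are per-frame channel
    values (a channel may be absent).  division_times are anaphase events
    within the recording.  truth, when present, records the generating
    landmarks for use as a test oracle only.
    """

    cell_id: str
    times: np.ndarray
    cdk2: np.ndarray | None
    apc: np.ndarray | None
    ccna2: np.ndarray | None
    division_times: list[float]
    treatment: TreatmentProgram
    preset_name: str
    truth: dict | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("trace needs at least 2 time points")
        steps = np.diff(t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("times must be strictly increasing with a "
                             "constant step")
        for name in ("cdk2", "apc", "ccna2"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape != t.shape:
                    raise ValueError(f"channel {name} length mismatch")
                if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                    raise ValueError(f"channel {name} must be finite and >= 0")
                setattr(self, name, ch)
        self.times = t
        eps = 1e-9 * max(1.0, abs(t[-1]))
        for d in self.division_times:
            if not t[0] - eps <= d <= t[-1] + eps:
                raise ValueError("division_times must lie inside the recording")

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def value_at(self, channel: str, t: float) -> float:
        """Channel value at the frame nearest to ``t``."""
        ch = getattr(self, channel)
        if ch is None:
            raise ValueError(f"trace {self.cell_id} has no {channel} channel")
        idx = int(np.argmin(np.abs(self.times - t)))
        return float(ch[idx])


def _ramp(t: np.ndarray, t0: float, t1: float, v0: float, v1: float) -> np.ndarray:
    """Piecewise-linear ramp: v0 before t0, v1 after t1."""
    return np.interp(t, [t0, max(t1, t0 + 1e-9)], [v0, v1])


def generate_population(
    preset: PopulationPreset,
    treatment: TreatmentProgram,
    n_cells: int,
    seed: int,
    grid_step: float = 0.2,
    horizon: float = 48.0,
    noise: bool = True,
    cdk2_noise_sd: float = 0.03,
    apc_noise_sd: float = 0.03,
    ccna2_noise_cv: float = 0.04,
    return_truth: bool = False,
) -> list[CellTrace]:
    """Generate ``n_cells`` post-R reporter traces under one treatment.

    Every cell enters S phase (APC/C off) before the treatment lands, at an
    offset drawn uniformly from the preset's treatment_offset_window, and
    then races its two clocks (see module docstring).  Output is
    reproducible for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if treatment.treatment_time < preset.treatment_offset_window:
        raise ValueError("treatment_time must be >= treatment_offset_window "
                         "so that S entry falls inside the recording")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, horizon + grid_step / 2, grid_step)
    t_treat = treatment.treatment_time
    kin = preset.kinetic_params
    t_exit_kinetic = predict_exit_time(kin)

    traces: list[CellTrace] = []
    for i in range(n_cells):
        u = rng.uniform(0.0, preset.treatment_offset_window)
        s_entry = t_treat - u
        d_sm = float(np.exp(rng.normal(
            math.log(preset.s_to_m_duration_median), preset.s_to_m_log_sd)))
        cell_factor = float(np.exp(rng.normal(0.0, preset.exit_clock_dispersion)))
        # next-cycle durations are drawn unconditionally to keep the RNG
        # stream identical across treatments for a given seed
        cycle_lens = np.exp(rng.normal(math.log(20.0), 0.12, 2))

        r_mit = max(d_sm - u, MIN_REMAINING_MITOSIS_H) + treatment.delay_hours
        if treatment.blocks_mitosis:
            r_mit = math.inf
        t_exit = cell_factor * t_exit_kinetic if treatment.triggers_exit \
            else math.inf

        exits = t_exit < r_mit  # tie goes to mitosis
        divides = math.isfinite(r_mit) and not exits

        # ---- baseline channels ----
        cdk2 = np.empty_like(t)
        pre = t < s_entry
        cdk2[pre] = _ramp(t[pre], 0.0, s_entry, CDK2_START, CDK2_AT_S_ENTRY)
        mid = (t >= s_entry) & (t < t_treat)
        cdk2[mid] = _ramp(t[mid], s_entry, t_treat,
                          CDK2_AT_S_ENTRY, CDK2_AT_TREATMENT)
        post = t >= t_treat
        apc_low_windows: list[tuple[float, float]] = []
        division_times: list[float] = []
        ccna2 = np.ones_like(t)

        if exits:
            exit_abs = t_treat + t_exit
            decay = predict_protein(kin, (t[post] - t_treat) / cell_factor)
            cdk2[post] = EXIT_THRESHOLD * preset.threshold_ratio * decay
            ccna2[post] = decay
            apc_low_windows.append((s_entry, exit_abs))
        elif divides:
            # snap the event to the frame grid so trace tables round-trip
            div1 = round((t_treat + r_mit) / grid_step) * grid_step
            if treatment.triggers_exit:
                decay = predict_protein(kin, (t[post] - t_treat) / cell_factor)
                ccna2[post] = decay
            if div1 > horizon:
                # still climbing toward mitosis at the end of the recording
                cdk2[post] = _ramp(t[post], t_treat, div1,
                                   CDK2_AT_TREATMENT, CDK2_PRE_MITOSIS)
                apc_low_windows.append((s_entry, horizon + 1.0))
            else:
                division_times.append(div1)
                seg = post & (t < div1)
                cdk2[seg] = _ramp(t[seg], t_treat, div1,
                                  CDK2_AT_TREATMENT, CDK2_PRE_MITOSIS)
                apc_low_windows.append((s_entry, div1))
                after = t >= div1
                if treatment.label == "DMSO":
                    # daughters re-enter the cycle and divide again
                    prev_div = div1
                    for cl in cycle_lens:
                        nxt = round((prev_div + float(cl)) / grid_step) \
                            * grid_step
                        seg2 = (t >= prev_div) & (t < min(nxt, horizon + 1.0))
                        cdk2[seg2] = _ramp(t[seg2], prev_div, nxt,
                                           CDK2_POST_DIVISION, CDK2_PRE_MITOSIS)
                        s2 = prev_div + G1_FRACTION_OF_CYCLE * float(cl)
                        apc_low_windows.append((s2, min(nxt, horizon + 1.0)))
                        if nxt > horizon:
                            break
                        division_times.append(nxt)
                        prev_div = nxt
                else:
                    # daughters arrest in G0: CDK2 low, APC/C on
                    cdk2[after] = CDK2_POST_DIVISION - 0.03
                    ccna2[after] = APC_OFF
        else:
            # committed: neither clock fires within the model
            # (e.g. CDK1i alone) — CDK2 plateaus high
            cdk2[post] = _ramp(t[post], t_treat, t_treat + 4.0,
                               CDK2_AT_TREATMENT, 1.25)
            apc_low_windows.append((s_entry, horizon + 1.0))

        apc = np.full_like(t, APC_ON)
        for lo, hi in apc_low_windows:
            apc[(t >= lo) & (t < hi)] = APC_OFF

        if noise:
            cdk2 = np.clip(cdk2 + rng.normal(0.0, cdk2_noise_sd, t.shape), 0, None)
            apc = np.clip(apc + rng.normal(0.0, apc_noise_sd, t.shape), 0, 1.5)
            ccna2 = ccna2 * np.exp(rng.normal(0.0, ccna2_noise_cv, t.shape))
        else:
            # RNG draws kept so that noise on/off does not shift later cells
            rng.normal(0.0, 1.0, 3 * t.size)

        truth = None
        if return_truth:
            truth = {
                "s_entry": s_entry,
                "treatment_offset": u,
                "s_to_m_duration": d_sm,
                "remaining_mitosis": r_mit,
                "t_exit": t_exit,
                "cell_factor": cell_factor,
                "fate": "EXIT" if exits else ("MITOSIS" if divides and
                        division_times else "COMMITTED"),
                "exit_abs": t_treat + t_exit if exits else None,
                "mitosis_abs": division_times[0] if division_times else None,
            }
        traces.append(CellTrace(
            cell_id=f"cell{i:05d}",
            times=t.copy(),
            cdk2=cdk2,
            apc=apc,
            ccna2=ccna2,
            division_times=division_times,
            treatment=treatment,
            preset_name=preset.name,
            truth=truth,
        ))
    return traces


def generate_decay_assay(
    preset: PopulationPreset,
    n_cells: int,
    noise_cv: float,
    seed: int,
    duration: float = 24.0,
    grid_step: float = 0.5,
) -> list[CellTrace]:
    """Pure cyclin A2 decay traces for half-life estimation.

    The ccna2 channel follows exponential decay with the preset's protein
    half-life from t = 0, with per-frame multiplicative log-normal noise of
    coefficient ``noise_cv``; the kinase and APC/C channels are omitted.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + grid_step / 2, grid_step)
    base = np.exp2(-t / preset.protein_half_life)
    treatment = TreatmentProgram(label="CDK46I_CDK1I", treatment_time=0.0)
    traces = []
    for i in range(n_cells):
        level = base.copy()
        if noise_cv > 0:
            level = level * np.exp(rng.normal(0.0, noise_cv, t.shape))
        traces.append(CellTrace(
            cell_id=f"decay{i:05d}",
            times=t.copy(),
            cdk2=None,
            apc=None,
            ccna2=level,
            division_times=[],
            treatment=treatment,
            preset_name=preset.name,
        ))
    return traces
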