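"""ODE models of the mitogen -> CDK2 pathway in two architectures.

FEEDBACK — the textbook bistable restriction-point switch (a reduced
Rb–E2F module in the spirit of Yao et al.'s serum-response switch): CDK2
phosphorylates Rb, phosphorylated Rb releases E2F, and E2F drives cyclin
(and hence CDK2) synthesis, closing a self-sustaining positive loop.  The
Rb phosphorylation balance uses zero-order-ultrasensitive
(Goldbeter–Koshland) kinetics, which gives bistability: once ignited by
mitogen-driven CDK4/6, CDK2 activity persists even at zero mitogen, so
the switch is hysteretic and effectively irreversible.

FEEDFORWARD — the revised architecture: mitogen -> CDK4/6 (fast) -|
active p107/p130 repressor (dephosphorylated on a 1–2 h time scale) -|
CCNA2 transcription -> cyclin A2 mRNA (2 h half-life) -> cyclin A2
protein (half-life per cell line) -> CDK2 activity, with Rb
phosphorylation carried as a passive readout and *no* return edge from
CDK2 or Rb to transcription.  The chain is monotone, so it has a unique
steady state for every mitogen level: no hysteresis, but the long protein
half-life makes CDK2 persist transiently — apparent irreversibility at
the time a cell would normally reach mitosis.

All rate parameters live in ``data/network_params.json`` (hours; state
variables dimensionless, scaled to ~1 in the proliferating state).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Architecture",
    "NetworkModel",
    "MitogenSchedule",
    "build_network",
    "simulate_network",
    "steady_state",
    "dose_response",
    "hysteresis_width",
]

LN2 = math.log(2.0)

STATE_NAMES = {
    "FEEDBACK": ("cdk46", "e2f", "cdk2", "rb_phos"),
    "FEEDFORWARD": ("cdk46", "repressor", "mrna", "protein", "cdk2", "rb_phos"),
}


class Architecture(enum.Enum):
    FEEDBACK = "FEEDBACK"
    FEEDFORWARD = "FEEDFORWARD"


def _hill(x: float, K: float, n: float) -> float:
    xn = max(x, 0.0) ** n
    return xn / (K**n + xn)


def _load_default_params() -> dict:
    with resources.files("clockrace.data").joinpath(
        "network_params.json"
    ).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class MitogenSchedule:
    """Piecewise-constant mitogen input plus genetic perturbation flags.

    segments: list of (start_hour, S) with contiguous coverage from t = 0.
    knockout_repressor: p107/p130 removed (transcription never repressed).
    constitutive_ccna2: CCNA2 transcribed from an unregulated promoter.
    """

    segments: tuple[tuple[float, float], ...]
    knockout_repressor: bool = False
    constitutive_ccna2: bool = False

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b)) for a, b in self.segments)
        if not segs or segs[0][0] != 0.0:
            raise ValueError("segments must start at t = 0")
        starts = [s[0] for s in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment starts must be strictly increasing")
        if any(not 0.0 <= s[1] <= 1.0 for s in segs):
            raise ValueError("mitogen levels must lie in [0, 1]")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, S: float, **flags) -> "MitogenSchedule":
        return cls(segments=((0.0, S),), **flags)

    @classmethod
    def step_down(cls, S_before: float = 1.0, S_after: float = 0.0,
                  at: float = 0.0, **flags) -> "MitogenSchedule":
        if at <= 0:
            return cls.constant(S_after, **flags)
        return cls(segments=((0.0, S_before), (at, S_after)), **flags)


class NetworkModel:
    """One architecture with a concrete parameter set.

    Exposes the right-hand side, branch initial conditions and the CDK2
    readout index.  Construct via :func:`build_network`.
    """

    def __init__(self, architecture: Architecture, params: dict):
        self.architecture = architecture
        self.params = dict(params)
        self.state_names = STATE_NAMES[architecture.value]

    @property
    def cdk2_index(self) -> int:
        return self.state_names.index("cdk2")

    # ---- dynamics ----
    def rhs(self, t: float, y: np.ndarray, S: float,
            knockout_repressor: bool = False,
            constitutive_ccna2: bool = False) -> np.ndarray:
        p = self.params
        if self.architecture is Architecture.FEEDBACK:
            c4, e2f, k2, rp = y
            rp = min(max(rp, 0.0), 1.0)
            phos = p["k_phos"] * (max(c4, 0.0) + max(k2, 0.0))
            d_c4 = (S - c4) / p["tau_cdk46"]
            d_rp = (phos * (1.0 - rp) / (p["J_phos"] + 1.0 - rp)
                    - p["k_dephos"] * rp / (p["J_dephos"] + rp))
            d_e2f = p["k_e2f"] * _hill(rp, p["K_rp"], p["n_rp"]) \
                - p["d_e2f"] * e2f
            d_k2 = p["k_cdk2"] * max(e2f, 0.0) - p["d_cdk2"] * k2
            return np.array([d_c4, d_e2f, d_k2, d_rp])
        # FEEDFORWARD
        c4, rep, m, a, k2, rp = y
        lam_m = LN2 / p["mrna_half_life"]
        lam_p = LN2 / p["protein_half_life"]
        d_c4 = (S - c4) / p["tau_cdk46"]
        rep_target = 0.0 if knockout_repressor else \
            1.0 - _hill(c4, p["K_cdk46"], p["n_cdk46"])
        d_rep = (rep_target - rep) / p["tau_repressor"]
        synthesis = 1.0 if constitutive_ccna2 else \
            (1.0 if knockout_repressor else 1.0 - min(max(rep, 0.0), 1.0))
        d_m = lam_m * synthesis - lam_m * m
        d_a = lam_p * m - lam_p * a
        k2_target = (1.0 + p["K_cdk2"]) * max(a, 0.0) / (p["K_cdk2"] + max(a, 0.0))
        d_k2 = (k2_target - k2) / p["tau_cdk2"]
        total_cdk = 0.5 * (max(c4, 0.0) + max(k2, 0.0))
        d_rp = (_hill(total_cdk, p["K_rb"], p["n_rb"]) - rp) / p["tau_rb"]
        return np.array([d_c4, d_rep, d_m, d_a, d_k2, d_rp])

    def initial_state(self, branch: str, S: float = 1.0) -> np.ndarray:
        """HIGH: proliferating (post-R-like) state; LOW: quiescent state.

        Branch seeds are relaxed to the corresponding steady state at the
        given mitogen level elsewhere; these are the raw seeds.
        """
        branch = branch.upper()
        if branch not in ("HIGH", "LOW"):
            raise ValueError("branch must be 'HIGH' or 'LOW'")
        if self.architecture is Architecture.FEEDBACK:
            return np.array([S, 2.0, 2.4, 1.0]) if branch == "HIGH" \
                else np.array([S, 0.0, 0.0, 0.0])
        if branch == "HIGH":
            return np.array([S, 0.0, 1.0, 1.0, 1.0, 1.0])
        return np.array([S, 1.0, 0.0, 0.0, 0.0, 0.0])


def build_network(
    architecture: Architecture | str,
    overrides: dict | None = None,
    params_file: str | None = None,
) -> NetworkModel:
    """Construct a network model from the shipped (or a user) parameter file.

    Unknown override keys raise, listing the valid parameter names.
    """
    if isinstance(architecture, str):
        architecture = Architecture(architecture.upper())
    if params_file is None:
        defaults = _load_default_params()
    else:
        with open(params_file) as fh:
            defaults = json.load(fh)
    params = dict(defaults[architecture.value.lower()])
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {sorted(unknown)}; valid names: "
                f"{sorted(params)}"
            )
        params.update(overrides)
    return NetworkModel(architecture, params)


def _integrate(model: NetworkModel, y0: np.ndarray, t_span: tuple[float, float],
               S: float, schedule_flags: dict, t_eval=None,
               rtol: float = 1e-8, atol: float = 1e-10):
    sol = solve_ivp(
        lambda t, y: model.rhs(t, y, S, **schedule_flags),
        t_span, y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
        max_step=5.0,
    )
    if not sol.success:
        raise RuntimeError(
            f"{model.architecture.value} integration failed on "
            f"t={t_span} at S={S}: {sol.message}"
        )
    return sol


def simulate_network(
    model: NetworkModel,
    schedule: MitogenSchedule,
    horizon: float,
    init: str = "HIGH",
    init_S: float | None = None,
    grid_step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate a model under a piecewise-constant mitogen schedule.

    The initial condition is the requested branch relaxed to steady state
    at ``init_S`` — the mitogen level the cells saw *before* t = 0
    (default 1.0, a proliferating history).  A constant-zero schedule with
    the default history is therefore "mitogen removal at t = 0 from the
    proliferating state".  Output is a tidy table on a uniform grid with
    one column per state variable.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if init_S is None:
        init_S = 1.0 if init.upper() == "HIGH" else schedule.segments[0][1]
    flags = {
        "knockout_repressor": schedule.knockout_repressor,
        "constitutive_ccna2": schedule.constitutive_ccna2,
    }
    y0 = steady_state(model, init_S, init,
                      knockout_repressor=schedule.knockout_repressor,
                      constitutive_ccna2=schedule.constitutive_ccna2)
    bounds = [s[0] for s in schedule.segments] + [horizon]
    levels = [s[1] for s in schedule.segments]
    grid = np.arange(0.0, horizon + grid_step / 2, grid_step)
    rows, y = [], y0
    for (t0, t1), S in zip(zip(bounds[:-1], bounds[1:]), levels):
        if t1 <= t0:
            continue
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        sol = _integrate(model, y, (t0, t1), S, flags,
                         t_eval=t_eval if len(t_eval) else None,
                         rtol=rtol, atol=atol)
        seg = np.clip(sol.y, 0.0, None)
        for k, tk in enumerate(sol.t):
            if rows and math.isclose(tk, rows[-1][0]):
                continue
            rows.append((tk, *seg[:, k]))
        y = sol.y[:, -1]
    return pd.DataFrame(rows, columns=("time_h", *model.state_names))


def steady_state(
    model: NetworkModel,
    S: float,
    init: str = "HIGH",
    max_hours: float = 500.0,
    tol: float = 1e-8,
    knockout_repressor: bool = False,
    constitutive_ccna2: bool = False,
) -> np.ndarray:
    """Relax one branch to steady state at mitogen level ``S``.

    Integrates from the branch seed until the derivative norm falls below
    ``tol`` (declared steady) with a hard cap at ``max_hours``;
    non-convergence raises.
    """
    if not 0.0 <= S <= 1.0:
        raise ValueError("S must lie in [0, 1]")
    flags = {"knockout_repressor": knockout_repressor,
             "constitutive_ccna2": constitutive_ccna2}
    y = model.initial_state(init, S)
    elapsed, chunk = 0.0, 100.0
    while elapsed < max_hours:
        sol = _integrate(model, y, (0.0, chunk), S, flags)
        y = sol.y[:, -1]
        elapsed += chunk
        if np.max(np.abs(model.rhs(0.0, y, S, **flags))) < tol:
            return np.clip(y, 0.0, None)
    residual = np.max(np.abs(model.rhs(0.0, y, S, **flags)))
    raise RuntimeError(
        f"steady state not reached within {max_hours} h "
        f"(|dx/dt| = {residual:.2e} > {tol:g})"
    )


def dose_response(
    model: NetworkModel,
    doses,
    eval_time: float | None,
    init: str = "HIGH",
) -> pd.DataFrame:
    """CDK2 activity vs MEKi dose for one branch.

    A dose d maps linearly to mitogen level S = 1 - d.  The branch seed is
    first relaxed at its home level (HIGH: S = 1, post-R proliferating;
    LOW: S = 0, pre-R quiescent), then the dose is applied and CDK2 read
    at ``eval_time`` hours — or at steady state when ``eval_time`` is None.
    """
    doses = np.asarray(list(doses), dtype=float)
    if np.any((doses < 0) | (doses > 1)):
        raise ValueError("doses must lie in [0, 1]")
    home_S = 1.0 if init.upper() == "HIGH" else 0.0
    y_home = steady_state(model, home_S, init)
    rows = []
    for d in doses:
        S = 1.0 - d
        if eval_time is None or math.isinf(eval_time):
            sol_y = _relax_from(model, y_home, S)
        else:
            sol = _integrate(model, y_home, (0.0, eval_time), S, {})
            sol_y = sol.y[:, -1]
        rows.append((float(d), S, max(float(sol_y[model.cdk2_index]), 0.0)))
    return pd.DataFrame(rows, columns=["dose", "S", "cdk2"])


def _relax_from(model: NetworkModel, y0: np.ndarray, S: float,
                max_hours: float = 500.0, tol: float = 1e-8) -> np.ndarray:
    y, elapsed, chunk = y0, 0.0, 100.0
    while elapsed < max_hours:
        sol = _integrate(model, y, (0.0, chunk), S, {})
        y = sol.y[:, -1]
        elapsed += chunk
        if np.max(np.abs(model.rhs(0.0, y, S))) < tol:
            return y
    raise RuntimeError(f"relaxation at S={S} did not converge")


def hysteresis_width(
    model: NetworkModel,
    eval_time: float | None = None,
    dose_step: float = 0.005,
) -> float:
    """Dose gap between the HIGH-branch off-switch and the LOW-branch
    on-switch at half-maximal CDK2.

    Both branch dose–response curves must be monotone non-increasing in
    dose (up to a small numerical tolerance); a violation raises a
    diagnostic error.  A branch that never crosses half-maximum within
    the dose range contributes the range endpoint (an irreversibly-ON
    high branch extends the width to the full remaining dose axis).
    Width 0 (within the dose grid) means no hysteresis.
    """
    doses = np.arange(0.0, 1.0 + dose_step / 2, dose_step)
    high = dose_response(model, doses, eval_time, init="HIGH")["cdk2"].to_numpy()
    low = dose_response(model, doses, eval_time, init="LOW")["cdk2"].to_numpy()
    half = 0.5 * max(high.max(), low.max())
    width_tol = 0.02 * max(high.max(), low.max())
    for name, curve in (("HIGH", high), ("LOW", low)):
        if np.any(np.diff(curve) > width_tol):
            raise RuntimeError(
                f"{name}-branch dose-response is not monotone non-increasing; "
                "cannot localise a half-maximal crossing"
            )

    def cross(curve: np.ndarray) -> float:
        idx = np.flatnonzero(curve < half)
        if idx.size == 0:
            return float(doses[-1])  # never switches off within the range
        i = idx[0]
        if i == 0:
            return float(doses[0])
        c0, c1 = curve[i - 1], curve[i]
        return float(doses[i - 1] + (c0 - half) / (c0 - c1) * dose_step)

    return max(cross(high) - cross(low), 0.0)
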