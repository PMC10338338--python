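"""Feature extraction and fate calling on reporter traces.

Landmarks per cell: S entry (sustained APC/C inactivation), mitosis (the
division event channel, or a one-frame collapse of CDK2 activity), and
cell-cycle exit (CDK2 activity sustained below the 0.6 commitment
threshold with no intervening division).  Post-R status is evaluated at
the treatment frame (APC/C off = post-R).  Downstream: exit probability
binned by cell-cycle position at treatment, and a per-cell logistic
regression of exit vs mitosis on the treatment offset with a two-sided
Wald test on the slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.ndimage import median_filter

from .synthetic_data import CellTrace

__all__ = [
    "AnalysisConfig",
    "TraceFeatures",
    "LogisticExitFit",
    "detect_s_entry",
    "detect_mitosis",
    "detect_exit",
    "classify_fates",
    "exit_fraction_by_offset",
    "fit_exit_logistic",
    "order_for_heatmap",
]

FATES = ("MITOSIS", "EXIT", "COMMITTED", "PRE_R")
ENDPOINTS = ("G0_2N", "G0LIKE_4N", "CYCLING", "COMMITTED_HIGH")


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and debounce windows for landmark detection.

    cdk2_exit_threshold: activity below which a cell is scored as losing
        CDK2 activity (0.6, the commitment threshold).
    apc_off_threshold: APC/C activity below which the APC/C is inactive.
    exit_sustain_hours / apc_sustain_hours: how long a crossing must
    persist to reject sensor noise (debounce).
    mitosis_drop_fraction: one-frame fractional CDK2 collapse that scores
        as division when no event channel is available.
    post_r_grace_hours: cells treated within this long after APC/C
        inactivation still count as post-R (boundary rule).
    exit_smooth_hours: width of the centered moving-median filter applied
        to the CDK2 channel before exit-crossing detection.  The median
        filter is exact on monotone segments, so it removes sensor noise
        without shifting a clean ramp's crossing.
    """

    cdk2_exit_threshold: float = 0.6
    apc_off_threshold: float = 0.5
    exit_sustain_hours: float = 2.0
    apc_sustain_hours: float = 1.0
    mitosis_drop_fraction: float = 0.5
    post_r_grace_hours: float = 1.0
    exit_smooth_hours: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cdk2_exit_threshold < 1.5:
            raise ValueError("cdk2_exit_threshold must lie in (0, 1.5)")
        if self.exit_sustain_hours < 0 or self.apc_sustain_hours < 0:
            raise ValueError("sustain windows must be >= 0")
        if not 0.0 < self.mitosis_drop_fraction <= 1.0:
            raise ValueError("mitosis_drop_fraction must lie in (0, 1]")


@dataclass
class TraceFeatures:
    """Extracted landmarks and the fate label for one cell."""

    cell_id: str
    s_entry_time: float | None
    mitosis_time: float | None
    exit_time: float | None
    post_r_at_treatment: bool
    treatment_offset: float | None
    fate: str
    endpoint: str

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.fate == "MITOSIS" and (self.mitosis_time is None
                                       or self.exit_time is not None):
            raise ValueError("MITOSIS fate requires mitosis_time and no "
                             "exit_time")
        if self.fate == "EXIT" and (self.exit_time is None
                                    or self.mitosis_time is not None):
            raise ValueError("EXIT fate requires exit_time and no "
                             "mitosis_time")


@dataclass(frozen=True)
class LogisticExitFit:
    """Logistic regression of exit (1) vs mitosis (0) on treatment offset."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n: int
    degenerate: bool = False


def _first_sustained_below(
    times: np.ndarray, values: np.ndarray, threshold: float, sustain: float
) -> int | None:
    """Index of the first frame below threshold that stays below for at
    least ``sustain`` hours (the window must be fully recorded)."""
    below = values < threshold
    n = len(times)
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if times[j] - times[i] >= sustain:
                return i
            if j == n - 1:
                return None  # recording ends before the window can complete
            i = j + 1
        else:
            i += 1
    return None


def detect_s_entry(trace: CellTrace, cfg: AnalysisConfig) -> float | None:
    """Time of S entry: first sustained APC/C inactivation, or None."""
    if trace.apc is None:
        raise ValueError(f"trace {trace.cell_id} has no apc channel")
    idx = _first_sustained_below(
        trace.times, trace.apc, cfg.apc_off_threshold, cfg.apc_sustain_hours
    )
    return None if idx is None else float(trace.times[idx])


def detect_mitosis(trace: CellTrace, cfg: AnalysisConfig) -> float | None:
    """Time of the first mitosis after treatment, or None.

    Uses the division event channel when present; otherwise falls back to
    a one-frame CDK2 collapse of at least ``mitosis_drop_fraction`` of the
    running maximum while that maximum exceeds 1.0.
    """
    t_treat = trace.treatment.treatment_time
    if trace.division_times:
        after = [d for d in trace.division_times if d > t_treat]
        return float(min(after)) if after else None
    if trace.cdk2 is None:
        return None
    run_max = np.maximum.accumulate(trace.cdk2)
    drops = trace.cdk2[:-1] - trace.cdk2[1:]
    hits = np.flatnonzero(
        (drops >= cfg.mitosis_drop_fraction * run_max[:-1]) & (run_max[:-1] > 1.0)
    )
    for h in hits:
        t_hit = trace.times[h + 1]
        if t_hit > t_treat:
            return float(t_hit)
    return None


def detect_exit(trace: CellTrace, cfg: AnalysisConfig) -> float | None:
    """Time of cell-cycle exit: first sustained loss of CDK2 activity.

    The first post-treatment crossing of the exit threshold that stays
    below it for the debounce window, with no division between treatment
    and the crossing.  The reported time is the threshold crossing itself,
    linearly interpolated between frames.
    """
    if trace.cdk2 is None:
        raise ValueError(f"trace {trace.cell_id} has no cdk2 channel")
    t_treat = trace.treatment.treatment_time
    theta = cfg.cdk2_exit_threshold
    mask = trace.times > t_treat
    if not mask.any():
        return None
    win = int(round(cfg.exit_smooth_hours / trace.step))
    win += 1 - win % 2  # centered window must be odd
    cdk2 = median_filter(trace.cdk2, size=max(win, 1), mode="nearest") \
        if win > 1 else trace.cdk2
    start = int(np.argmax(mask))
    idx = _first_sustained_below(
        trace.times[start:], cdk2[start:], theta, cfg.exit_sustain_hours
    )
    if idx is None:
        return None
    i = start + idx
    # a division anywhere up to the first below-threshold frame means the
    # cell reached mitosis first (the post-anaphase CDK2 collapse itself
    # must not be scored as exit)
    for d in trace.division_times:
        if t_treat < d <= trace.times[i] + 1e-9:
            return None
    t_cross = trace.times[i]
    if i > 0 and cdk2[i - 1] >= theta and trace.times[i - 1] > t_treat:
        # interpolate the crossing within the preceding frame interval
        c0, c1 = cdk2[i - 1], cdk2[i]
        t_cross = trace.times[i - 1] + (c0 - theta) / (c0 - c1) * trace.step
    return float(t_cross)


def _endpoint(trace: CellTrace, cfg: AnalysisConfig, fate: str,
              s_entry: float | None) -> str:
    if fate == "COMMITTED":
        return "COMMITTED_HIGH"
    if fate == "EXIT":
        return "G0LIKE_4N"  # exited from S/G2 without dividing: 4N, APC/C on
    if fate == "PRE_R":
        return "CYCLING" if trace.treatment.label == "DMSO" else "G0_2N"
    # MITOSIS: did the daughters arrest (G0, 2N) or keep cycling?
    t_treat = trace.treatment.treatment_time
    n_div = sum(1 for d in trace.division_times if d > t_treat)
    if n_div >= 2:
        return "CYCLING"
    tail = trace.times >= trace.times[-1] - 2.0
    cdk2_low = trace.cdk2 is not None and \
        float(np.mean(trace.cdk2[tail])) < cfg.cdk2_exit_threshold
    apc_high = trace.apc is not None and \
        float(np.mean(trace.apc[tail])) > cfg.apc_off_threshold
    return "G0_2N" if (cdk2_low and apc_high) else "CYCLING"


def classify_fates(
    traces, cfg: AnalysisConfig | None = None
) -> list[TraceFeatures]:
    """Extract landmarks and assign a fate to every trace.

    Fates for post-R cells partition into MITOSIS (divided first), EXIT
    (lost CDK2 activity first) and COMMITTED (still above threshold,
    neither event — right-censored).  Cells whose APC/C was still active
    at treatment are PRE_R.
    """
    cfg = cfg or AnalysisConfig()
    out: list[TraceFeatures] = []
    for trace in traces:
        t_treat = trace.treatment.treatment_time
        s_entry = detect_s_entry(trace, cfg)
        apc_at_treat = trace.value_at("apc", t_treat)
        post_r = apc_at_treat < cfg.apc_off_threshold
        if not post_r and s_entry is not None:
            post_r = 0.0 <= t_treat - s_entry <= cfg.post_r_grace_hours
        if not post_r:
            out.append(TraceFeatures(
                cell_id=trace.cell_id, s_entry_time=s_entry,
                mitosis_time=None, exit_time=None,
                post_r_at_treatment=False, treatment_offset=None,
                fate="PRE_R",
                endpoint=_endpoint(trace, cfg, "PRE_R", s_entry),
            ))
            continue
        offset = t_treat - s_entry if (s_entry is not None
                                       and s_entry <= t_treat) else None
        t_mit = detect_mitosis(trace, cfg)
        t_exit = detect_exit(trace, cfg)
        if t_mit is not None and (t_exit is None or t_mit <= t_exit):
            fate, t_exit = "MITOSIS", None
        elif t_exit is not None:
            fate, t_mit = "EXIT", None
        else:
            fate = "COMMITTED"
        out.append(TraceFeatures(
            cell_id=trace.cell_id, s_entry_time=s_entry,
            mitosis_time=t_mit, exit_time=t_exit,
            post_r_at_treatment=True, treatment_offset=offset,
            fate=fate, endpoint=_endpoint(trace, cfg, fate, s_entry),
        ))
    return out


def exit_fraction_by_offset(features, bin_width: float) -> pd.DataFrame:
    """Exit probability binned by cell-cycle position at treatment.

    Restricted to decided post-R cells (EXIT or MITOSIS) with a measured
    offset; k = exits, n = exits + mitoses per bin.  Empty interior bins
    are reported with n = 0 and NaN fraction.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    rows = [(f.treatment_offset, f.fate) for f in features
            if f.fate in ("EXIT", "MITOSIS") and f.treatment_offset is not None]
    if not rows:
        return pd.DataFrame(columns=["bin_center", "n", "k", "fraction"])
    df = pd.DataFrame(rows, columns=["offset", "fate"])
    n_bins = int(math.ceil((df["offset"].max() + 1e-9) / bin_width))
    n_bins = max(n_bins, 1)
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.clip(np.digitize(df["offset"], edges) - 1, 0, n_bins - 1)
    k = np.bincount(idx[df["fate"] == "EXIT"], minlength=n_bins)
    n = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    return pd.DataFrame({
        "bin_center": edges[:-1] + bin_width / 2,
        "n": n.astype(int),
        "k": k.astype(int),
        "fraction": frac,
    })


def fit_exit_logistic(features) -> LogisticExitFit:
    """Maximum-likelihood logistic fit of exit vs mitosis on offset.

    Fits on per-cell binary outcomes (exit = 1).  The p-value is a
    two-sided Wald test of the slope against the standard normal.
    Perfect separation or a one-class outcome yields a flagged degenerate
    result (infinite-magnitude slope, NaN p) rather than a silent number.
    """
    rows = [(f.treatment_offset, 1.0 if f.fate == "EXIT" else 0.0)
            for f in features
            if f.fate in ("EXIT", "MITOSIS") and f.treatment_offset is not None]
    if len(rows) < 2:
        raise ValueError("need at least 2 decided cells with offsets")
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct offsets")

    def _degenerate(sign: float) -> LogisticExitFit:
        return LogisticExitFit(
            slope=sign * math.inf, intercept=math.nan, slope_se=math.nan,
            p_value=math.nan, n=len(y), degenerate=True,
        )

    if y.min() == y.max():
        return _degenerate(0.0 if y[0] == 0 else math.copysign(1.0, -1.0))
    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            # separation manifests as overflow/convergence warnings; it is
            # detected and flagged explicitly below
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=False, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        sign = 1.0 if np.mean(x[y == 1]) > np.mean(x[y == 0]) else -1.0
        return _degenerate(sign)
    slope, se = float(res.params[1]), float(res.bse[1])
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged or not np.isfinite(se) or se > 1e3 or abs(slope) > 50:
        # quasi-separation: the MLE diverges and the Wald test is meaningless
        sign = math.copysign(1.0, slope)
        return _degenerate(sign)
    z = slope / se
    p = 2.0 * stats.norm.sf(abs(z))
    return LogisticExitFit(
        slope=slope, intercept=float(res.params[0]), slope_se=se,
        p_value=float(p), n=len(y),
    )


def order_for_heatmap(features) -> list[str]:
    """Cell ordering for fate heat maps: dividers first by ascending
    mitosis time, then non-dividers by ascending exit time; stable for
    ties and for cells with neither landmark (kept last in input order)."""
    feats = list(features)
    dividers = [f for f in feats if f.mitosis_time is not None]
    others = [f for f in feats if f.mitosis_time is None]
    dividers.sort(key=lambda f: f.mitosis_time)  # Timsort is stable
    others.sort(key=lambda f: (f.exit_time is None,
                               f.exit_time if f.exit_time is not None else 0.0))
    return [f.cell_id for f in dividers + others]
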