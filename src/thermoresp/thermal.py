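"""PSII thermal-tolerance traits from fluorescence-temperature ramps.

Tcrit is the temperature at the breakpoint between the slow- and fast-rise
phases of basal fluorescence F0: the trace is modelled as a continuous
two-segment piecewise-linear function f0 = b0 + b1*T + b2*(T - psi)+ and the
breakpoint psi is found by exhaustive least-squares over a dense grid
(default 0.1 degC) on the central 80% of the temperature range — a
deterministic alternative to iterative segmented regression, with no
starting-value sensitivity.  Tmax is the temperature at the global maximum of
the rolling-median-smoothed F0.  Cooling ramps are analysed on the negated
temperature axis so the rise-phase logic is shared between directions.

Acclimation deltas follow the hot-arm-minus-control / cold-arm-minus-control
convention: for heat traits a positive delta means gained heat tolerance; for
cold traits a positive delta (critical temperature moving toward 0 degC)
means worsened cold performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, NoBreakpointError, ValidationError

log = logging.getLogger(__name__)

DIRECTIONS = ("heating", "cooling")


@dataclass
class FluorescenceTrace:
    sample_id: str
    species_id: str
    treatment: str
    direction: str  # heating | cooling
    temperature: np.ndarray  # degC, ramp (chronological) order after QC
    f0: np.ndarray


@dataclass
class TcritFit:
    tcrit: float
    slope_slow: float
    slope_fast: float
    rss: float
    fast_not_steeper: bool  # warning flag: fast phase slope <= slow phase


def qc_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Clean a trace: drop non-finite points, average duplicate temperatures,
    sort into ramp order.  Fewer than 20 points after QC is an error."""
    t = np.asarray(trace.temperature, dtype=float)
    f = np.asarray(trace.f0, dtype=float)
    ok = np.isfinite(t) & np.isfinite(f) & (f >= 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("trace %s: dropped %d non-finite/negative points", trace.sample_id, n_dropped)
    t, f = t[ok], f[ok]
    df = pd.DataFrame({"t": t, "f": f}).groupby("t", sort=True).mean().reset_index()
    if trace.direction == "cooling":
        df = df.iloc[::-1].reset_index(drop=True)
    elif trace.direction != "heating":
        raise ValidationError(f"trace {trace.sample_id}: unknown direction '{trace.direction}'")
    if len(df) < 20:
        raise ValidationError(
            f"trace {trace.sample_id}: only {len(df)} usable points (need >= 20)"
        )
    return FluorescenceTrace(
        trace.sample_id, trace.species_id, trace.treatment, trace.direction,
        df["t"].to_numpy(), df["f"].to_numpy(),
    )


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    """Read long-format trace CSV (sample_id, species_id, treatment,
    direction, temperature_C, f0) into QC'd traces."""
    df = pd.read_csv(path)
    required = {"sample_id", "species_id", "treatment", "direction", "temperature_C", "f0"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"traces {path}: missing columns {sorted(missing)}")
    traces = []
    for sid, grp in df.groupby("sample_id", sort=True):
        traces.append(
            qc_trace(
                FluorescenceTrace(
                    sample_id=str(sid),
                    species_id=str(grp["species_id"].iloc[0]),
                    treatment=str(grp["treatment"].iloc[0]).lower(),
                    direction=str(grp["direction"].iloc[0]).lower(),
                    temperature=grp["temperature_C"].to_numpy(float),
                    f0=grp["f0"].to_numpy(float),
                )
            )
        )
    return traces


def _smooth(f0: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(f0).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def _two_segment_rss(x: np.ndarray, y: np.ndarray, psi: float):
    X = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0, None)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def fit_tcrit(
    trace: FluorescenceTrace,
    grid_step: float = 0.1,
    central_span: float = 0.8,
    truncate_at_peak: bool = True,
    smoothing_window: int = 5,
) -> TcritFit:
    """Grid-search breakpoint of the two-segment F0 model.

    The trace is truncated at the (smoothed) F0 peak by default so the
    post-peak decay does not distort the rise-phase fit.  A monotone RSS
    profile (argmin at a grid boundary) or an essentially linear trace raises
    :class:`NoBreakpointError`; a fast-phase slope not exceeding the
    slow-phase slope is flagged, not fatal.
    """
    x = trace.temperature.astype(float)
    y = trace.f0.astype(float)
    if trace.direction == "cooling":
        x = -x
    if truncate_at_peak:
        peak = int(np.argmax(_smooth(y, smoothing_window)))
        if peak >= 10:  # keep enough points for a two-segment fit
            x, y = x[: peak + 1], y[: peak + 1]
    span = x[-1] - x[0]
    lo = x[0] + (1 - central_span) / 2 * span
    hi = x[-1] - (1 - central_span) / 2 * span
    grid = np.arange(lo, hi + 1e-9, grid_step)
    if grid.size < 3:
        raise ValidationError(f"trace {trace.sample_id}: breakpoint grid too small")

    rss = np.empty(grid.size)
    betas = []
    for i, psi in enumerate(grid):
        rss[i], beta = _two_segment_rss(x, y, psi)
        betas.append(beta)
    best = int(np.argmin(rss))
    # linear-fit baseline: does a breakpoint explain anything at all?
    Xlin = np.column_stack([np.ones_like(x), x])
    blin, *_ = np.linalg.lstsq(Xlin, y, rcond=None)
    res_lin = y - Xlin @ blin
    rss_lin = float(res_lin @ res_lin)
    improvement = rss_lin - rss[best]
    if best in (0, grid.size - 1) or improvement <= 1e-9 * max(rss_lin, 1e-12):
        raise NoBreakpointError(
            f"trace {trace.sample_id}: no breakpoint detected"
        )
    beta = betas[best]
    slope_slow, slope_fast = float(beta[1]), float(beta[1] + beta[2])
    psi = float(grid[best])
    tcrit = -psi if trace.direction == "cooling" else psi
    fast_not_steeper = beta[2] <= 0
    if fast_not_steeper:
        log.warning("trace %s: fast-phase slope not exceeding slow phase", trace.sample_id)
    return TcritFit(
        tcrit=tcrit,
        slope_slow=slope_slow,
        slope_fast=slope_fast,
        rss=float(rss[best]),
        fast_not_steeper=bool(fast_not_steeper),
    )


def extract_tmax(
    trace: FluorescenceTrace, smoothing_window: int = 5
) -> tuple[float, bool]:
    """Temperature of the global maximum of smoothed F0.

    Ties resolve to the earliest point in ramp order (the side where Tcrit
    lies).  A maximum at a trace endpoint is flagged as a possibly truncated
    ramp.  Returns (tmax, endpoint_flag).
    """
    smoothed = _smooth(trace.f0, smoothing_window)
    idx = int(np.argmax(smoothed))
    endpoint = idx in (0, len(smoothed) - 1)
    if endpoint:
        log.warning("trace %s: F0 maximum at ramp endpoint", trace.sample_id)
    return float(trace.temperature[idx]), endpoint


def trace_traits(
    traces: list[FluorescenceTrace],
    grid_step: float = 0.1,
    smoothing_window: int = 5,
) -> pd.DataFrame:
    """Per-sample Tcrit and Tmax table with fit flags.

    Traces whose breakpoint cannot be detected are recorded with missing
    Tcrit rather than aborting the whole batch.
    """
    rows = []
    for trace in traces:
        tmax, endpoint = extract_tmax(trace, smoothing_window)
        try:
            fit = fit_tcrit(trace, grid_step, smoothing_window=smoothing_window)
            tcrit, warn = fit.tcrit, fit.fast_not_steeper
        except NoBreakpointError:
            log.warning("trace %s: no breakpoint; Tcrit missing", trace.sample_id)
            tcrit, warn = np.nan, False
        rows.append(
            {
                "sample_id": trace.sample_id,
                "species_id": trace.species_id,
                "treatment": trace.treatment,
                "direction": trace.direction,
                "tcrit": tcrit,
                "tmax": tmax,
                "fast_not_steeper": warn,
                "tmax_at_endpoint": endpoint,
            }
        )
    return pd.DataFrame(rows)


#: trait column -> (direction, treatment arm used for the delta)
TRAIT_ARMS = {
    "Tcrit_hot": ("heating", "hot", "tcrit"),
    "Tmax_hot": ("heating", "hot", "tmax"),
    "Tcrit_cold": ("cooling", "cold", "tcrit"),
    "Tmax_cold": ("cooling", "cold", "tmax"),
}


def acclimation_deltas(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-species acclimation deltas (treatment arm mean minus control mean).

    Heat traits pair with the hot arm, cold traits with the cold arm.
    Species missing either arm for a trait are reported missing for that
    trait (with a logged warning), not dropped from the table.
    """
    species = sorted(traits["species_id"].unique())
    out = pd.DataFrame(index=pd.Index(species, name="species_id"))
    for trait, (direction, arm, col) in TRAIT_ARMS.items():
        sub = traits[traits["direction"] == direction]
        deltas = []
        for sp in species:
            sp_rows = sub[sub["species_id"] == sp]
            arm_vals = sp_rows.loc[sp_rows["treatment"] == arm, col].dropna()
            ctl_vals = sp_rows.loc[sp_rows["treatment"] == "control", col].dropna()
            if arm_vals.empty or ctl_vals.empty:
                log.warning("species %s: missing arm for %s", sp, trait)
                deltas.append(np.nan)
            else:
                deltas.append(float(arm_vals.mean() - ctl_vals.mean()))
        out[trait] = deltas
    return out.reset_index()


def species_treatment_means(traits: pd.DataFrame) -> pd.DataFrame:
    """Trait means per species x treatment x direction (reporting table)."""
    return (
        traits.groupby(["species_id", "treatment", "direction"], sort=True)[
            ["tcrit", "tmax"]
        ]
        .mean()
        .reset_index()
    )
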