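"""High-resolution respirometry: coupling-control flux analysis and the
Bioenergetic Health Index (BHI).

An oxygraph trace is a time series of O2 concentration (nmol/mL) in a closed
chamber with a known cell suspension.  The coupling-control protocol titrates
oligomycin (ATP-synthase inhibition -> LEAK), stepwise FCCP (uncoupling ->
maximal electron-transfer capacity, ETS) and rotenone + antimycin A
(complex I/III inhibition -> residual oxygen consumption, ROX).  Oxygen flux
is the negative slope of the concentration scaled to pmol O2 per second per
10^6 cells; each respiratory state is the robust plateau flux between
titration events.

The bioenergetic profile splits those states into ATP-linked respiration
(ROUTINE - LEAK), proton leak (LEAK - ROX), reserve capacity (ETS - ROUTINE)
and non-mitochondrial respiration (ROX), and summarizes them as

    BHI = log10[(reserve x ATP-linked) / (non-mitochondrial x proton leak)],

a scale-invariant index that is positive when the beneficial components
dominate.  The cohort comparison adjusts BHI for the donor's percentage of
memory CD4+ T cells (memory cells respire differently from naive cells, and
an unbalanced memory fraction confounds the age contrast) by ordinary least
squares, with robust flagging of memory-fraction outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import TestResult, welch_ttest

__all__ = [
    "OxygraphTrace",
    "StateFluxes",
    "BioenergeticProfile",
    "compute_flux_trace",
    "extract_state_fluxes",
    "derive_profile",
    "flag_memory_outliers",
    "adjust_bhi_for_memory",
    "compare_respiration",
]

AGENTS = ("oligomycin", "fccp_step", "rotenone", "antimycin_a")


@dataclass
class OxygraphTrace:
    """Event-annotated O2 concentration record for one chamber run."""

    time_s: np.ndarray  # strictly increasing, seconds
    o2_nmol_per_ml: np.ndarray
    events: list[tuple[float, str]]  # (time_s, agent), ordered
    chamber_volume_ml: float = 2.0
    cell_count: float = 5e6

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_nmol_per_ml = np.asarray(self.o2_nmol_per_ml, dtype=float)
        if self.time_s.shape != self.o2_nmol_per_ml.shape:
            raise ValueError("time and concentration must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        order = [t for t, _ in self.events]
        if order != sorted(order):
            raise ValueError("events must be ordered in time")
        agents = [a for _, a in self.events]
        for a in agents:
            if a not in AGENTS:
                raise ValueError(f"unknown agent {a!r}")
        # protocol order: oligomycin < first fccp_step < rotenone < antimycin_a
        def first(agent: str) -> float:
            times = [t for t, a in self.events if a == agent]
            if not times:
                raise ValueError(f"protocol event {agent!r} missing")
            return times[0]

        if not first("oligomycin") < first("fccp_step") < first("rotenone") < first("antimycin_a"):
            raise ValueError("events violate the coupling-control order oligomycin -> FCCP -> rotenone -> antimycin A")

    def event_time(self, agent: str) -> float:
        return next(t for t, a in self.events if a == agent)

    def fccp_times(self) -> list[float]:
        return [t for t, a in self.events if a == "fccp_step"]


def compute_flux_trace(trace: OxygraphTrace, window_s: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window oxygen flux, pmol O2 / s / 10^6 cells.

    At each sample point, fit a least-squares slope to the concentration over
    a centered window of ``window_s`` seconds; flux is the negative slope
    scaled by chamber volume (mL -> total nmol/s), by 1000 (nmol -> pmol) and
    per 10^6 cells.  Returns (time, flux) restricted to points whose window
    lies fully inside the record.
    """
    t, y = trace.time_s, trace.o2_nmol_per_ml
    if t[-1] - t[0] < 2 * window_s:
        raise ValueError("record shorter than twice the slope window")
    half = window_s / 2.0
    # windows via searchsorted; slopes from first/second moments (exact LS)
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    n = (hi - lo).astype(float)
    st = ct[hi] - ct[lo]
    sy = cy[hi] - cy[lo]
    stt = ctt[hi] - ctt[lo]
    sty = cty[hi] - cty[lo]
    denom = n * stt - st * st
    valid = (t - half >= t[0]) & (t + half <= t[-1]) & (n >= 2) & (denom > 0)
    slope = np.full_like(t, np.nan)
    slope[valid] = (n[valid] * sty[valid] - st[valid] * sy[valid]) / denom[valid]
    flux = -slope * trace.chamber_volume_ml * 1000.0 / (trace.cell_count / 1e6)
    return t[valid], flux[valid]


@dataclass
class StateFluxes:
    """Plateau fluxes of the four coupling-control states (pmol/s/10^6 cells)."""

    routine: float
    leak: float
    ets: float
    rox: float
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _plateau(t: np.ndarray, flux: np.ndarray, start: float, stop: float, window_s: float, state: str) -> tuple[float, dict[str, float]]:
    mask = (t >= start) & (t < stop)
    if stop - start < window_s or mask.sum() < 2:
        raise ValueError(f"state window for {state!r} shorter than {window_s} s")
    vals = flux[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError(f"state window for {state!r} has too few valid flux points")
    return float(np.median(vals)), {"span_s": float(stop - start), "residual_sd": float(np.std(vals, ddof=1)), "n": float(vals.size)}


def extract_state_fluxes(
    trace: OxygraphTrace,
    settle_s: float = 60.0,
    window_s: float = 120.0,
    slope_window_s: float = 30.0,
) -> StateFluxes:
    """Median plateau flux per state, trimming ``settle_s`` after each event.

    ROUTINE: start -> oligomycin; LEAK: oligomycin -> first FCCP step;
    ETS: maximum over the per-FCCP-step plateaus (titration to the optimum
    uncoupler dose); ROX: antimycin A -> end of record.  Injection artifacts
    fall inside the settle trim; the median of windowed slopes resists the
    remainder.  Expected ordering ETS >= ROUTINE >= LEAK >= ROX is checked
    and violations recorded as flags, not errors.
    """
    t, flux = compute_flux_trace(trace, window_s=slope_window_s)
    t0 = trace.time_s[0]
    t_oli = trace.event_time("oligomycin")
    fccp = trace.fccp_times()
    t_rot = trace.event_time("rotenone")
    t_ama = trace.event_time("antimycin_a")
    t_end = trace.time_s[-1]

    diags: dict[str, dict[str, float]] = {}
    routine, diags["routine"] = _plateau(t, flux, t0 + settle_s, t_oli, window_s, "routine")
    leak, diags["leak"] = _plateau(t, flux, t_oli + settle_s, fccp[0], window_s, "leak")
    steps = []
    bounds = fccp + [t_rot]
    for i, ts in enumerate(fccp):
        val, d = _plateau(t, flux, ts + settle_s, bounds[i + 1], window_s, f"ets_step_{i}")
        diags[f"ets_step_{i}"] = d
        steps.append(val)
    ets = float(max(steps))
    diags["ets"] = diags[f"ets_step_{int(np.argmax(steps))}"]
    rox, diags["rox"] = _plateau(t, flux, t_ama + settle_s, t_end, window_s, "rox")

    flags = []
    if not ets >= routine:
        flags.append("ETS below ROUTINE")
    if not routine >= leak:
        flags.append("ROUTINE below LEAK")
    if not leak >= rox:
        flags.append("LEAK below ROX")
    return StateFluxes(routine=routine, leak=leak, ets=ets, rox=rox, diagnostics=diags, flags=flags)


@dataclass
class BioenergeticProfile:
    atp_linked: float
    proton_leak: float
    reserve_capacity: float
    non_mitochondrial: float
    bhi: float  # NaN when undefined
    flags: list[str] = field(default_factory=list)

    @property
    def bhi_defined(self) -> bool:
        return bool(np.isfinite(self.bhi))


def derive_profile(states: StateFluxes, log_base: float = 10.0) -> BioenergeticProfile:
    """Bioenergetic components and BHI from the four state fluxes.

    atp_linked = ROUTINE - LEAK; proton_leak = LEAK - ROX;
    reserve = ETS - ROUTINE; non_mitochondrial = ROX;
    BHI = log10[(reserve x atp_linked) / (non_mitochondrial x proton_leak)].
    Any component <= 0 leaves BHI undefined (NaN) with a flag naming it.
    """
    atp = states.routine - states.leak
    leak_c = states.leak - states.rox
    reserve = states.ets - states.routine
    nm = states.rox
    flags = list(states.flags)
    for name, v in [("atp_linked", atp), ("proton_leak", leak_c), ("reserve_capacity", reserve), ("non_mitochondrial", nm)]:
        if not (np.isfinite(v) and v > 0):
            flags.append(f"component {name} <= 0; BHI undefined")
    if any(f.endswith("BHI undefined") for f in flags):
        bhi = float("nan")
    else:
        bhi = float(np.log(reserve * atp / (nm * leak_c)) / np.log(log_base))
    return BioenergeticProfile(
        atp_linked=float(atp),
        proton_leak=float(leak_c),
        reserve_capacity=float(reserve),
        non_mitochondrial=float(nm),
        bhi=bhi,
        flags=flags,
    )


def flag_memory_outliers(cohort: pd.DataFrame, multiplier: float = 1.5, scope: str = "cohort") -> pd.Series:
    """Flag donors whose memory-cell percentage is atypical.

    A donor is flagged when its ``memory_pct`` lies farther than
    ``multiplier`` x IQR from the median, computed over the whole cohort by
    default (``scope="cohort"``) or within the donor's age group
    (``scope="group"``).  Cohort scope is the default because a single
    aberrant donor is most visible against all remaining samples.
    """
    x = cohort["memory_pct"].astype(float)
    if ((x < 0) | (x > 100)).any():
        raise ValueError("memory_pct must lie in [0, 100]")

    def _flag(sub: pd.Series) -> pd.Series:
        q1, q3 = np.percentile(sub, [25, 75])
        iqr = q3 - q1
        med = float(np.median(sub))
        if iqr == 0:
            return pd.Series(False, index=sub.index)
        return (sub - med).abs() > multiplier * iqr

    if scope == "cohort":
        return _flag(x)
    if scope == "group":
        return x.groupby(cohort["age_group"]).transform(lambda s: _flag(s))
    raise ValueError("scope must be 'cohort' or 'group'")


def _adjusted_fit(cohort: pd.DataFrame) -> dict:
    """OLS bhi ~ group + memory_pct; adjusted group means at grand-mean memory."""
    grp = (cohort["age_group"] == "old").astype(float).to_numpy()  # old = 1
    mem = cohort["memory_pct"].astype(float).to_numpy()
    y = cohort["bhi"].astype(float).to_numpy()
    if np.ptp(mem) == 0:
        res = welch_ttest(y[grp == 0], y[grp == 1])
        return {
            "adjusted": False,
            "warning": "memory_pct constant; fell back to unadjusted Welch comparison",
            "mean_young": res.mean_a,
            "mean_old": res.mean_b,
            "group_p": res.p_value,
            "coef": None,
        }
    X = sm.add_constant(np.column_stack([grp, mem]))
    fit = sm.OLS(y, X).fit()
    b0, b1, b2 = fit.params
    mbar = mem.mean()
    return {
        "adjusted": True,
        "warning": None,
        "mean_young": float(b0 + b2 * mbar),
        "mean_old": float(b0 + b1 + b2 * mbar),
        "group_p": float(fit.pvalues[1]),
        "coef": {"intercept": float(b0), "group_old": float(b1), "memory_pct": float(b2)},
        "coef_se": {"intercept": float(fit.bse[0]), "group_old": float(fit.bse[1]), "memory_pct": float(fit.bse[2])},
    }


def adjust_bhi_for_memory(cohort: pd.DataFrame, outlier_multiplier: float = 1.5, outlier_scope: str = "cohort") -> dict:
    """Memory-fraction-adjusted young/old BHI comparison, with and without outliers.

    ``cohort`` needs columns donor, age_group, bhi, memory_pct.  Fits
    bhi = b0 + b1*[old] + b2*memory_pct by OLS; adjusted means are evaluated
    at the grand-mean memory percentage and the group p comes from the t of
    b1.  Donors flagged by :func:`flag_memory_outliers` are reported and the
    analysis repeated without them (never silently excluded).
    """
    cohort = cohort.reset_index(drop=True)
    for g in ("young", "old"):
        if (cohort["age_group"] == g).sum() < 3:
            raise ValueError(f"need >= 3 {g} samples with memory_pct")
    flags = flag_memory_outliers(cohort, multiplier=outlier_multiplier, scope=outlier_scope)
    out = {
        "outliers": list(cohort.loc[flags, "donor"]),
        "all_samples": _adjusted_fit(cohort),
    }
    if flags.any() and (~flags).sum() >= 6:
        out["without_outliers"] = _adjusted_fit(cohort[~flags])
    else:
        out["without_outliers"] = None
    return out


def compare_respiration(cohort: pd.DataFrame, metrics: tuple[str, ...] = ("bhi", "non_mitochondrial", "reserve_capacity")) -> dict[str, TestResult]:
    """Per-metric Welch comparison young (group a) vs old (group b)."""
    young = cohort[cohort["age_group"] == "young"]
    old = cohort[cohort["age_group"] == "old"]
    if len(young) < 2 or len(old) < 2:
        raise ValueError("need >= 2 donors per age group")
    results = {}
    for m in metrics:
        results[m] = welch_ttest(young[m].to_numpy(dtype=float), old[m].to_numpy(dtype=float))
    return results
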