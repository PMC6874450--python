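"""Flow-cytometry mitophagy-flux gating.

A pH-sensitive, mitochondria-targeted dye brightens as its compartment
acidifies, so per-event fluorescence separates cytosolic mitochondria (low),
mitochondria inside immature autophagic compartments (intermediate) and
mitochondria in acidified autolysosomes (high).  Two shared gates split each
sample's events into lo / int / hi bins; bin percentages are compared young
vs old per pharmacologic condition (dye only, CCCP uncoupling, bafilomycin
A1 acidification block), plus within-donor paired condition contrasts.

Gate placement is derived from controls — the upper tail of the unstained
distribution (autofluorescence) for the lo/int boundary and an upper
quantile of the pooled young dye-only distribution for the int/hi boundary —
because the study design calls for one fixed gate set applied to every
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats as sps

from .stats import TestResult, student_ttest

__all__ = [
    "IntensityGates",
    "BinFractions",
    "derive_gates",
    "bin_fractions",
    "sample_bin_table",
    "condition_contrast",
]

CONDITIONS = ("unstained", "dye_only", "cccp", "bafilomycin")
BINS = ("lo", "int", "hi")


def _safe_student(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Student t that treats identical constant groups as no evidence (p = 1).

    The three bin percentages are linearly dependent (they sum to 100), so a
    perfectly constant bin can arise in legitimate fixtures; failing the
    whole contrast table for it would be unhelpful.
    """
    from .stats import DegenerateDataError

    try:
        return student_ttest(a, b)
    except DegenerateDataError:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, float(a.size + b.size - 2), float(a.mean()), float(b.mean()), a.size, b.size)
        raise


@dataclass(frozen=True)
class IntensityGates:
    lo_int_boundary: float
    int_hi_boundary: float

    def __post_init__(self) -> None:
        if not self.lo_int_boundary < self.int_hi_boundary:
            raise ValueError("gates out of order: lo/int boundary must lie below int/hi boundary")


@dataclass(frozen=True)
class BinFractions:
    pct_lo: float
    pct_int: float
    pct_hi: float


def derive_gates(
    events: pd.DataFrame,
    unstained_quantile: float = 0.99,
    dye_only_quantile: float = 0.90,
    explicit: tuple[float, float] | None = None,
) -> IntensityGates:
    """One experiment-wide gate pair from control distributions.

    lo/int boundary: ``unstained_quantile`` of all unstained events (above
    nearly all autofluorescence); int/hi boundary: ``dye_only_quantile`` of
    the pooled *young* dye-only events.  ``explicit=(lo, hi)`` bypasses
    derivation.  ``events`` needs columns condition, age_group, intensity.
    """
    if explicit is not None:
        return IntensityGates(*map(float, explicit))
    unst = events.loc[events["condition"] == "unstained", "intensity"]
    dye_y = events.loc[(events["condition"] == "dye_only") & (events["age_group"] == "young"), "intensity"]
    if unst.empty:
        raise ValueError("no unstained reference events")
    if dye_y.empty:
        raise ValueError("no young dye-only reference events")
    lo = float(np.quantile(unst.to_numpy(dtype=float), unstained_quantile))
    hi = float(np.quantile(dye_y.to_numpy(dtype=float), dye_only_quantile))
    return IntensityGates(lo, hi)


def bin_fractions(intensities, gates: IntensityGates) -> BinFractions:
    """Percent of events below, between and above the gates.

    Half-open convention: lo is intensity < lo/int boundary; int is
    [lo/int, int/hi); hi is >= int/hi.  The three percentages sum to 100
    exactly.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty event vector")
    n = x.size
    lo = np.count_nonzero(x < gates.lo_int_boundary)
    hi = np.count_nonzero(x >= gates.int_hi_boundary)
    return BinFractions(
        pct_lo=100.0 * lo / n,
        pct_int=100.0 * (n - lo - hi) / n,
        pct_hi=100.0 * hi / n,
    )


def sample_bin_table(events: pd.DataFrame, gates: IntensityGates) -> pd.DataFrame:
    """Per (donor, condition) bin percentages for all stained samples."""
    stained = events[events["condition"] != "unstained"]
    x = stained["intensity"].to_numpy(dtype=float)
    bin_idx = np.digitize(x, [gates.lo_int_boundary, gates.int_hi_boundary])  # 0=lo 1=int 2=hi
    donor_codes, donors = pd.factorize(stained["donor"], sort=True)
    cond_codes, conds = pd.factorize(stained["condition"], sort=True)
    n_d, n_c = len(donors), len(conds)
    flat = (donor_codes * n_c + cond_codes) * 3 + bin_idx
    counts = np.bincount(flat, minlength=n_d * n_c * 3).reshape(n_d, n_c, 3)
    age_by_donor = (
        stained.drop_duplicates("donor").set_index("donor")["age_group"].astype(str).to_dict()
    )
    rows = []
    for i, donor in enumerate(donors):
        for j, cond in enumerate(conds):
            c = counts[i, j]
            total = c.sum()
            if total == 0:
                continue
            rows.append(
                {
                    "donor": str(donor),
                    "condition": str(cond),
                    "age_group": age_by_donor[donor],
                    "pct_lo": 100.0 * c[0] / total,
                    "pct_int": 100.0 * c[1] / total,
                    "pct_hi": 100.0 * c[2] / total,
                }
            )
    return pd.DataFrame(rows)


def condition_contrast(bin_table: pd.DataFrame) -> pd.DataFrame:
    """Age contrasts per condition/bin plus paired drug-vs-dye-only contrasts.

    Unpaired rows: young vs old two-tailed Student t for every bin of every
    condition.  Paired rows: within each age group, CCCP vs dye-only and
    bafilomycin vs dye-only compared by a paired t across donors (each donor
    provides all conditions).
    """
    rows = []
    for cond in sorted(bin_table["condition"].unique()):
        sub = bin_table[bin_table["condition"] == cond]
        y = sub[sub["age_group"] == "young"]
        o = sub[sub["age_group"] == "old"]
        if len(y) < 2 or len(o) < 2:
            raise ValueError(f"condition {cond}: need >= 2 donors per age group")
        for b in BINS:
            res = _safe_student(y[f"pct_{b}"].to_numpy(float), o[f"pct_{b}"].to_numpy(float))
            rows.append(
                {
                    "contrast": f"young_vs_old:{cond}",
                    "bin": b,
                    "mean_a": res.mean_a,
                    "mean_b": res.mean_b,
                    "t": res.statistic,
                    "p_value": res.p_value,
                    "paired": False,
                }
            )
    wide = bin_table.pivot(index="donor", columns="condition")
    ages = bin_table.groupby("donor")["age_group"].first()
    for age in ("young", "old"):
        donors = ages.index[ages == age]
        for drug in ("cccp", "bafilomycin"):
            for b in BINS:
                try:
                    a = wide.loc[donors, (f"pct_{b}", drug)].to_numpy(dtype=float)
                    ref = wide.loc[donors, (f"pct_{b}", "dye_only")].to_numpy(dtype=float)
                except KeyError:
                    continue
                ok = np.isfinite(a) & np.isfinite(ref)
                if ok.sum() < 2:
                    continue
                t, p = sps.ttest_rel(a[ok], ref[ok])
                rows.append(
                    {
                        "contrast": f"{drug}_vs_dye_only:{age}",
                        "bin": b,
                        "mean_a": float(np.mean(a[ok])),
                        "mean_b": float(np.mean(ref[ok])),
                        "t": float(t),
                        "p_value": float(p),
                        "paired": True,
                    }
                )
    return pd.DataFrame(rows)
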