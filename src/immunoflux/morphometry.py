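"""TEM morphometry of autophagic vacuoles in naive and memory CD4+ T cells.

Annotated vesicles are classified by a deterministic rule table into
autophagosomes (AP: double membrane, ribosome-free cytosolic face, cytosol-
like lumen, identifiable engulfed organelles) or autolysosomes (AL: single
or <40%-double membrane with a lucent or amorphous-content lumen).
Autophagic vacuoles (AV) are AP + AL; maturation is the percentage of AV
that have progressed to the AL state.  Per-cell summaries (counts, areas in
arbitrary units, AP area as % of cytosol) feed stratified two-sample
comparisons across age group and naive/memory subset, with cells as the
replication unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .stats import TestResult, student_ttest

__all__ = [
    "VesicleFeatures",
    "CellAnnotation",
    "CellSummary",
    "classify_vesicle",
    "summarize_cell",
    "summaries_frame",
    "compare_morphometry",
]

LUMINAL_DENSITIES = ("lower_than_cytosol", "similar_to_cytosol", "dense_amorphous")
AP, AL, UNCLASSIFIED = "AP", "AL", "unclassified"


@dataclass(frozen=True)
class VesicleFeatures:
    vesicle_id: str
    diameter_um: float
    double_membrane_fraction: float
    ribosomes_attached: bool
    luminal_density: str
    contains_identifiable_organelle: bool
    multiple_inner_single_membrane_vesicles: bool
    area_au: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.double_membrane_fraction <= 1.0:
            raise ValueError("double_membrane_fraction must lie in [0, 1]")
        if self.luminal_density not in LUMINAL_DENSITIES:
            raise ValueError(f"unknown luminal_density {self.luminal_density!r}")
        if self.diameter_um <= 0 or self.area_au <= 0:
            raise ValueError("diameter and area must be positive")


@dataclass
class CellAnnotation:
    cell_id: str
    donor: str
    age_group: str  # young | old
    subset: str  # naive | memory
    cytosol_area_au: float
    mitochondria_areas_au: list[float]
    vesicles: list[VesicleFeatures]

    def __post_init__(self) -> None:
        if self.cytosol_area_au <= 0:
            raise ValueError("cytosol area must be positive")
        if any(a <= 0 for a in self.mitochondria_areas_au):
            raise ValueError("mitochondrion areas must be positive")
        if self.subset not in ("naive", "memory"):
            raise ValueError(f"unknown subset {self.subset!r}")


def classify_vesicle(v: VesicleFeatures, size_min_um: float = 0.5) -> str:
    """Deterministic AP/AL/unclassified call from morphological criteria.

    AP requires at least two of: a double membrane (complete or partial,
    i.e. fraction > 0), no ribosomes on the cytosolic face, luminal density
    similar to cytosol, identifiable organelle content.  A non-AP vesicle is
    AL when its membrane is single or <40% double AND its lumen is either
    lucent (lower than cytosol) or consists of multiple single-membrane inner
    vesicles with light or dense amorphous content.  Everything else —
    including vesicles below the minimum diameter — is unclassified.
    """
    if v.diameter_um < size_min_um:
        return UNCLASSIFIED
    ap_criteria = (
        v.double_membrane_fraction > 0.0,
        not v.ribosomes_attached,
        v.luminal_density == "similar_to_cytosol",
        v.contains_identifiable_organelle,
    )
    if sum(ap_criteria) >= 2:
        return AP
    al_membrane = v.double_membrane_fraction < 0.4
    al_lumen = v.luminal_density == "lower_than_cytosol" or (
        v.multiple_inner_single_membrane_vesicles
        and v.luminal_density in ("lower_than_cytosol", "dense_amorphous")
    )
    if al_membrane and al_lumen:
        return AL
    return UNCLASSIFIED


def enumerate_feature_space(
    membrane_fractions: tuple[float, ...] = (0.0, 0.2, 0.6),
    diameter_um: float = 1.0,
) -> list[VesicleFeatures]:
    """Discretized grid over the categorical feature space (for exhaustive checks)."""
    out = []
    combos = product(membrane_fractions, (False, True), LUMINAL_DENSITIES, (False, True), (False, True))
    for i, (dm, rib, lum, org, multi) in enumerate(combos):
        out.append(
            VesicleFeatures(
                vesicle_id=f"v{i}",
                diameter_um=diameter_um,
                double_membrane_fraction=dm,
                ribosomes_attached=rib,
                luminal_density=lum,
                contains_identifiable_organelle=org,
                multiple_inner_single_membrane_vesicles=multi,
                area_au=1.0,
            )
        )
    return out


@dataclass
class CellSummary:
    cell_id: str
    donor: str
    age_group: str
    subset: str
    ap_count: int
    al_count: int
    unclassified_count: int
    mito_count: int
    mean_mito_area_au: float
    ap_area_au: float
    ap_area_pct_cytosol: float

    @property
    def av_count(self) -> int:
        return self.ap_count + self.al_count

    @property
    def maturation_pct(self) -> float:
        """Percent of AV in the AL state; NaN when the cell has no AV."""
        if self.av_count == 0:
            return float("nan")
        return 100.0 * self.al_count / self.av_count


def summarize_cell(cell: CellAnnotation, size_min_um: float = 0.5) -> CellSummary:
    """Counts, maturation and AP area fractions for one annotated cell."""
    labels = [classify_vesicle(v, size_min_um=size_min_um) for v in cell.vesicles]
    ap_area = sum(v.area_au for v, lab in zip(cell.vesicles, labels) if lab == AP)
    mito = cell.mitochondria_areas_au
    return CellSummary(
        cell_id=cell.cell_id,
        donor=cell.donor,
        age_group=cell.age_group,
        subset=cell.subset,
        ap_count=labels.count(AP),
        al_count=labels.count(AL),
        unclassified_count=labels.count(UNCLASSIFIED),
        mito_count=len(mito),
        mean_mito_area_au=float(np.mean(mito)) if mito else float("nan"),
        ap_area_au=float(ap_area),
        ap_area_pct_cytosol=100.0 * ap_area / cell.cytosol_area_au,
    )


def summaries_frame(summaries: list[CellSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "cell_id": s.cell_id,
                "donor": s.donor,
                "age_group": s.age_group,
                "subset": s.subset,
                "ap_count": s.ap_count,
                "al_count": s.al_count,
                "av_count": s.av_count,
                "unclassified_count": s.unclassified_count,
                "maturation_pct": s.maturation_pct,
                "mito_count": s.mito_count,
                "mean_mito_area_au": s.mean_mito_area_au,
                "ap_area_au": s.ap_area_au,
                "ap_area_pct_cytosol": s.ap_area_pct_cytosol,
            }
        )
    return pd.DataFrame(rows)


METRICS = (
    "mito_count",
    "mean_mito_area_au",
    "ap_count",
    "al_count",
    "av_count",
    "maturation_pct",
    "ap_area_au",
    "ap_area_pct_cytosol",
)


def compare_morphometry(summaries: pd.DataFrame, metrics: tuple[str, ...] = METRICS) -> pd.DataFrame:
    """Stratified Student comparisons mirroring the figure-level analysis.

    Two families of contrasts: naive vs memory within each age group, and
    young vs old within each subset; every metric is tested per contrast by
    a two-tailed pooled-variance t with cells as replicates.  NaN metric
    values (e.g. maturation of AV-free cells) are dropped per test.  Means
    and SEM per stratum are reported alongside for plotting parity.
    """
    contrasts = []
    for age in sorted(summaries["age_group"].unique()):
        contrasts.append((f"naive_vs_memory_in_{age}", summaries["age_group"] == age, "subset", "naive", "memory"))
    for subset in sorted(summaries["subset"].unique()):
        contrasts.append((f"young_vs_old_in_{subset}", summaries["subset"] == subset, "age_group", "young", "old"))

    rows = []
    for name, mask, col, lev_a, lev_b in contrasts:
        sub = summaries[mask]
        a_all = sub[sub[col] == lev_a]
        b_all = sub[sub[col] == lev_b]
        for metric in metrics:
            a = a_all[metric].dropna().to_numpy(dtype=float)
            b = b_all[metric].dropna().to_numpy(dtype=float)
            if a.size < 2 or b.size < 2:
                raise ValueError(f"contrast {name}: stratum with < 2 cells for {metric}")
            res: TestResult = student_ttest(a, b)
            rows.append(
                {
                    "contrast": name,
                    "metric": metric,
                    "mean_a": res.mean_a,
                    "sem_a": float(np.std(a, ddof=1) / np.sqrt(a.size)),
                    "mean_b": res.mean_b,
                    "sem_b": float(np.std(b, ddof=1) / np.sqrt(b.size)),
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "t": res.statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
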