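"""Isobaric-tag (iTRAQ 8plex) protein quantification: reference-channel
normalization across plexes, old/young ratio statistics, and the three-stage
significance/evidence filter cascade.

The experimental design this module serves: several 8plex runs, each carrying
one aliquot of a single common reference sample.  Dividing every channel by
the same-protein reference intensity within its own plex places all plexes on
one scale, after which group averages, old/young ratios and pooled-variance
t-tests are computed per protein, and proteins are screened by
(1) fold-change, (2) p-value, (3) identification evidence
(unique peptides, sequence confidence, ion score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


__all__ = [
    "ChannelSample",
    "ProteinQuantTable",
    "NormalizedAbundances",
    "CascadeConfig",
    "FilterCascadeReport",
    "normalize_to_reference",
    "group_ratio_test",
    "filter_cascade",
]

YOUNG, OLD = "young", "old"
ROLES = ("biological", "reference", "technical_duplicate")


@dataclass(frozen=True)
class ChannelSample:
    donor: str
    age_group: str  # "young" | "old"
    role: str  # "biological" | "reference" | "technical_duplicate"


@dataclass
class ProteinQuantTable:
    """One 8plex run: protein x channel reporter-ion intensities."""

    plex_id: str
    intensities: pd.DataFrame  # index: protein accessions, columns: channel tags
    sample_map: dict[str, ChannelSample]  # channel tag -> sample

    def __post_init__(self) -> None:
        missing = set(self.intensities.columns) - set(self.sample_map)
        if missing:
            raise ValueError(f"plex {self.plex_id}: channels without sample_map entry: {sorted(missing)}")
        refs = [c for c, s in self.sample_map.items() if s.role == "reference"]
        if len(refs) != 1:
            raise ValueError(f"plex {self.plex_id}: expected exactly one reference channel, got {len(refs)}")
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"plex {self.plex_id}: intensities must be finite and >= 0")

    @property
    def reference_channel(self) -> str:
        return next(c for c, s in self.sample_map.items() if s.role == "reference")


@dataclass
class NormalizedAbundances:
    """Reference-normalized protein abundances pooled across plexes.

    ``values`` columns are ``"<plex>:<channel>"``; ``samples`` (indexed the
    same way) carries plex, channel, donor, age_group and role per column.
    ``dropped`` maps protein -> reason for proteins excluded during
    normalization (zero reference intensity, absent from some plex).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    dropped: dict[str, str] = field(default_factory=dict)


def normalize_to_reference(tables: list[ProteinQuantTable]) -> NormalizedAbundances:
    """Divide each channel by the same-protein reference intensity of its plex.

    The reference column of every plex becomes exactly 1 for every retained
    protein.  Proteins are intersected across plexes; a protein missing from
    any plex, or with reference intensity 0 in any plex, is dropped with a
    logged reason.  Technical-duplicate channels are retained as separate,
    tagged columns.
    """
    if not tables:
        raise ValueError("no plex tables supplied")
    ids = [t.plex_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate plex_id")

    common = set(tables[0].intensities.index)
    universe: set[str] = set()
    for t in tables:
        universe |= set(t.intensities.index)
        common &= set(t.intensities.index)
    dropped = {p: "absent from at least one plex" for p in universe - common}

    # drop proteins whose reference intensity is zero in any plex
    zero_ref: set[str] = set()
    for t in tables:
        ref = t.intensities.loc[sorted(common), t.reference_channel]
        zero_ref |= set(ref.index[ref == 0.0])
    for p in zero_ref:
        dropped[p] = "zero reference intensity"
    keep = sorted(common - zero_ref)
    if not keep:
        raise ValueError("no protein is quantified with nonzero reference in every plex")

    blocks, meta = [], []
    for t in tables:
        block = t.intensities.loc[keep]
        ref = block[t.reference_channel]
        norm = block.div(ref, axis=0)
        norm.columns = [f"{t.plex_id}:{c}" for c in block.columns]
        blocks.append(norm)
        for c in block.columns:
            s = t.sample_map[c]
            meta.append(
                {
                    "column": f"{t.plex_id}:{c}",
                    "plex": t.plex_id,
                    "channel": c,
                    "donor": s.donor,
                    "age_group": s.age_group,
                    "role": s.role,
                }
            )
    values = pd.concat(blocks, axis=1)
    samples = pd.DataFrame(meta).set_index("column")
    return NormalizedAbundances(values=values, samples=samples, dropped=dropped)


def collapse_technical_duplicates(norm: NormalizedAbundances) -> tuple[pd.DataFrame, pd.Series]:
    """Average all non-reference columns of the same donor into one value.

    Returns the protein x donor matrix and a donor -> age_group series.
    Reference aliquots are excluded (they are the normalization unit, not a
    biological observation).
    """
    bio = norm.samples[norm.samples["role"] != "reference"]
    if bio.empty:
        raise ValueError("no biological channels present")
    groups = bio.groupby("donor")["age_group"].agg(set)
    bad = [d for d, g in groups.items() if len(g) != 1]
    if bad:
        raise ValueError(f"donor(s) mapped to multiple age groups: {bad}")
    donor_age = groups.map(lambda s: next(iter(s)))
    cols_by_donor = {d: list(sub.index) for d, sub in bio.groupby("donor")}
    collapsed = pd.DataFrame(
        {d: norm.values[cols].mean(axis=1) for d, cols in cols_by_donor.items()},
        index=norm.values.index,
    )
    return collapsed, donor_age


def group_ratio_test(norm: NormalizedAbundances) -> pd.DataFrame:
    """Per-protein old/young averages, ratio and two-tailed Student p.

    Technical duplicates are first collapsed to their donor mean, so donors
    are the replication unit.  Columns mirror a standard differential table:
    ``avg_young``, ``avg_old``, ``ratio`` (= avg_old / avg_young, the o/y
    fold change), ``p_value``, ``n_young``, ``n_old``.  Proteins for which
    the test is degenerate (no variance in either group) get p = NaN and are
    flagged in ``note``.
    """
    donors, donor_age = collapse_technical_duplicates(norm)
    young = [d for d in donors.columns if donor_age[d] == YOUNG]
    old = [d for d in donors.columns if donor_age[d] == OLD]
    if len(young) < 2 or len(old) < 2:
        raise ValueError(f"need >= 2 donors per group, got {len(young)} young / {len(old)} old")

    import scipy.stats as sps

    y = donors[young].to_numpy(dtype=float)
    o = donors[old].to_numpy(dtype=float)
    avg_y = y.mean(axis=1)
    avg_o = o.mean(axis=1)
    p = np.asarray(sps.ttest_ind(o, y, axis=1, equal_var=True).pvalue, dtype=float)
    degenerate = (y.var(axis=1, ddof=1) == 0) & (o.var(axis=1, ddof=1) == 0)
    p[degenerate] = np.nan
    out = pd.DataFrame(
        {
            "avg_young": avg_y,
            "avg_old": avg_o,
            "ratio": np.where(avg_y > 0, avg_o / np.where(avg_y > 0, avg_y, np.nan), np.nan),
            "p_value": p,
            "n_young": len(young),
            "n_old": len(old),
            "note": np.where(degenerate, "degenerate: no variance in either group", ""),
        },
        index=donors.index,
    ).rename_axis("protein")
    return out


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the three-stage screen (defaults are the study screen)."""

    up: float = 1.3
    down: float = 0.7
    alpha: float = 0.05
    min_unique_peptides: int = 2
    min_confidence: str = "high"
    min_ion_score: float = 30.0


@dataclass
class FilterCascadeReport:
    n_input: int
    n_pass_ratio: int
    n_pass_pvalue: int
    n_pass_evidence: int
    selected: list[str]
    selected_up: list[str]
    selected_down: list[str]
    rejections: dict[str, str]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_input, self.n_pass_ratio, self.n_pass_pvalue, self.n_pass_evidence)


def filter_cascade(
    records: pd.DataFrame,
    evidence: pd.DataFrame,
    config: CascadeConfig = CascadeConfig(),
) -> FilterCascadeReport:
    """Apply the fold-change / p-value / evidence screen in order.

    Stage 1 keeps ratio > ``up`` or ratio < ``down``; stage 2 keeps
    p < ``alpha``; stage 3 keeps unique_peptides >= min, confidence == high
    and max ion score > min.  Missing or NaN fields fail their stage.
    ``evidence`` must be indexed (or indexable) by protein with columns
    ``unique_peptides``, ``confidence``, ``max_ion_score``.
    """
    if "protein" in records.columns:
        records = records.set_index("protein")
    if "protein_id" in evidence.columns:
        evidence = evidence.set_index("protein_id")

    rejections: dict[str, str] = {}
    pass_ratio: list[str] = []
    for protein, row in records.iterrows():
        r = row["ratio"]
        if np.isfinite(r) and (r > config.up or r < config.down):
            pass_ratio.append(protein)
        else:
            rejections[protein] = f"ratio {r:.4g} within [{config.down}, {config.up}]"

    pass_p: list[str] = []
    for protein in pass_ratio:
        p = records.at[protein, "p_value"]
        if np.isfinite(p) and p < config.alpha:
            pass_p.append(protein)
        else:
            rejections[protein] = f"p-value {p:.4g} >= {config.alpha}"

    pass_ev: list[str] = []
    for protein in pass_p:
        if protein not in evidence.index:
            rejections[protein] = "no evidence record"
            continue
        ev = evidence.loc[protein]
        ok = (
            int(ev["unique_peptides"]) >= config.min_unique_peptides
            and str(ev["confidence"]) == config.min_confidence
            and float(ev["max_ion_score"]) > config.min_ion_score
        )
        if ok:
            pass_ev.append(protein)
        else:
            rejections[protein] = (
                f"evidence failed (peptides={ev['unique_peptides']}, "
                f"confidence={ev['confidence']}, ion={ev['max_ion_score']})"
            )

    up = [p for p in pass_ev if records.at[p, "ratio"] > config.up]
    down = [p for p in pass_ev if records.at[p, "ratio"] < config.down]
    return FilterCascadeReport(
        n_input=len(records),
        n_pass_ratio=len(pass_ratio),
        n_pass_pvalue=len(pass_p),
        n_pass_evidence=len(pass_ev),
        selected=pass_ev,
        selected_up=up,
        selected_down=down,
        rejections=rejections,
    )
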