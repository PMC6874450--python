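"""Shared fixture builders and independent oracles used by several test modules."""

import pandas as pd

from immunoflux.morphometry import AL, AP, UNCLASSIFIED, VesicleFeatures
from immunoflux.proteomics import NormalizedAbundances


def norm_from_donor_values(values: dict[str, tuple[list[float], list[float]]]) -> NormalizedAbundances:
    """NormalizedAbundances built from per-protein (young, old) donor values."""
    n_y = len(next(iter(values.values()))[0])
    n_o = len(next(iter(values.values()))[1])
    cols = [f"P:y{i}" for i in range(n_y)] + [f"P:o{i}" for i in range(n_o)]
    rows = {p: list(y) + list(o) for p, (y, o) in values.items()}
    vals = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    samples = pd.DataFrame(
        {
            "plex": "P",
            "channel": [c.split(":")[1] for c in cols],
            "donor": [c.split(":")[1] for c in cols],
            "age_group": ["young"] * n_y + ["old"] * n_o,
            "role": "biological",
        },
        index=pd.Index(cols, name="column"),
    )
    return NormalizedAbundances(values=vals, samples=samples)


def toy_cascade_records():
    """Six records: 2 fail ratio, 1 more fails p, 1 more fails evidence."""
    records = pd.DataFrame(
        {
            "ratio": [1.20, 0.90, 1.50, 1.60, 0.50, 2.00],
            "p_value": [0.001, 0.001, 0.20, 0.01, 0.02, 0.003],
            "avg_young": 1.0,
            "avg_old": 1.0,
        },
        index=pd.Index([f"R{i}" for i in range(6)], name="protein"),
    )
    evidence = pd.DataFrame(
        {
            "protein_id": [f"R{i}" for i in range(6)],
            "unique_peptides": [5, 5, 5, 5, 1, 4],  # R4 fails peptides
            "confidence": ["high"] * 6,
            "max_ion_score": [80.0] * 6,
        }
    )
    return records, evidence


def truth_table_label(v: VesicleFeatures) -> str:
    """Independent re-statement of the vesicle classification rules.

    Written as an explicit decision list rather than criterion counting, so a
    bookkeeping bug in the implementation cannot hide in both places.
    """
    hits = 0
    if v.double_membrane_fraction > 0:
        hits += 1
    if not v.ribosomes_attached:
        hits += 1
    if v.luminal_density == "similar_to_cytosol":
        hits += 1
    if v.contains_identifiable_organelle:
        hits += 1
    if hits >= 2:
        return AP
    if v.double_membrane_fraction >= 0.4:
        return UNCLASSIFIED
    if v.luminal_density == "lower_than_cytosol":
        return AL
    if v.multiple_inner_single_membrane_vesicles and v.luminal_density == "dense_amorphous":
        return AL
    return UNCLASSIFIED
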