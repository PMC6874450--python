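"""Published reference values: proteins elevated in CD4+ T cells from older
donors, as reported by an iTRAQ LC-MS/MS screen (group-average normalized
abundance for young and old, the old/young ratio, and the test p-value).

These printed group averages and ratios serve as fixed inputs for
verification: for rows whose printed averages and ratio are arithmetically
consistent at 4 decimals, recomputing ``avg_old / avg_young`` must reproduce
the printed ratio.  Rounding in the published table makes a subset of rows
inconsistent at the 4th decimal; :func:`consistent_rows` selects the rest.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["UPREGULATED_PROTEINS", "upregulated_protein_table", "consistent_rows"]

# gene symbol -> (p_value, avg_young, avg_old, printed o/y ratio)
UPREGULATED_PROTEINS: dict[str, tuple[float, float, float, float]] = {
    "GPDM": (0.0004, 0.9734, 1.5531, 1.5956),
    "HNRPL": (0.0006, 1.1832, 1.7053, 1.4412),
    "NB5R3": (0.0011, 1.1119, 1.5432, 1.3879),
    "COX41": (0.0012, 1.0433, 1.6018, 1.5353),
    "DHSB": (0.0018, 0.9829, 1.4623, 1.4878),
    "ATPB": (0.0019, 1.0133, 1.3217, 1.3043),
    "ATPA": (0.0023, 0.9533, 1.2703, 1.3325),
    "NDUA4": (0.0025, 1.0289, 1.5362, 1.4931),
    "SUN2": (0.0031, 1.1153, 1.5392, 1.3801),
    "COX5A": (0.0053, 1.0940, 1.7087, 1.5619),
    "MPCP": (0.0057, 1.1626, 2.0633, 1.7747),
    "CYB5B": (0.0082, 1.1481, 1.4972, 1.3040),
    "COX7B": (0.0084, 1.0530, 2.0184, 1.9168),
    "PGRC2": (0.0104, 1.0354, 1.7378, 1.6784),
    "DHSA": (0.0123, 0.9902, 1.5637, 1.5792),
    "BCL2": (0.0125, 1.0076, 1.4705, 1.4594),
    "ATPD": (0.0148, 0.9403, 1.4305, 1.5213),
    "ATP6": (0.0153, 0.9667, 1.6244, 1.6804),
    "COX7C": (0.0165, 0.9625, 2.0954, 2.1770),
    "CX7A2": (0.0177, 1.0284, 1.6805, 1.6341),
    "STML2": (0.0260, 1.0155, 1.4892, 1.4665),
    "ITAM": (0.0303, 0.9807, 1.3973, 1.4248),
    "COX2": (0.0304, 1.0580, 1.4211, 1.3432),
    "ATP5H": (0.0345, 1.0268, 1.3764, 1.3405),
    "LMNB1": (0.0391, 1.3814, 1.9963, 1.4451),
    "ATP5J": (0.0431, 1.0240, 1.9787, 1.9323),
    "ATPO": (0.0453, 1.0983, 1.6420, 1.4950),
    "ADT1": (0.0543, 1.2815, 1.7950, 1.4007),
    "DPM1": (0.0222, 1.1323, 1.6071, 1.4193),
}


def upregulated_protein_table() -> pd.DataFrame:
    """The published table as a DataFrame indexed by gene symbol."""
    return pd.DataFrame.from_dict(
        UPREGULATED_PROTEINS,
        orient="index",
        columns=["p_value", "avg_young", "avg_old", "ratio"],
    ).rename_axis("protein")


def consistent_rows(decimals: int = 4) -> pd.DataFrame:
    """Rows whose printed averages reproduce the printed ratio at ``decimals``."""
    t = upregulated_protein_table()
    recomputed = (t["avg_old"] / t["avg_young"]).round(decimals)
    return t[recomputed == t["ratio"].round(decimals)]
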