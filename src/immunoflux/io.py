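"""Readers and writers for the plain-text interchange formats of every arm.

Proteomics: per-plex TSV (protein_id + one column per channel), a design TSV
(plex, tag, donor, age_group, role) and an evidence TSV.  Expression: gene x
sample TSV pairs (log-signal + detection p) and a sample sheet; gene sets in
GMT.  Respirometry: per-trace CSV (time_s, o2_nmol_per_ml) with an events
CSV (time_s, agent) and a cohort CSV.  Morphometry: vesicle, mitochondrion
and cell sheets.  Flow: a long per-event CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .enrichment import ExpressionStudy
from .morphometry import CellAnnotation, VesicleFeatures
from .proteomics import ChannelSample, ProteinQuantTable
from .respirometry import OxygraphTrace

__all__ = [
    "read_gmt",
    "write_gmt",
    "write_plex_tables",
    "read_plex_tables",
    "write_expression_study",
    "read_expression_study",
    "write_trace",
    "read_trace",
    "write_cells",
    "read_cells",
    "load_yaml_config",
]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (name, description, members per line)."""
    return _gseapy_read_gmt(str(path))


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------- proteomics


def write_plex_tables(tables: list[ProteinQuantTable], evidence: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design_rows = []
    for t in tables:
        df = t.intensities.copy()
        df.columns = [f"{t.plex_id}:{c}" for c in df.columns]
        df.rename_axis("protein_id").to_csv(out / f"{t.plex_id}.tsv", sep="\t")
        for tag, s in t.sample_map.items():
            design_rows.append(
                {"plex": t.plex_id, "tag": tag, "donor": s.donor, "age_group": s.age_group, "role": s.role}
            )
    pd.DataFrame(design_rows).to_csv(out / "design.tsv", sep="\t", index=False)
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)


def read_plex_tables(plex_paths: list[str | Path], design_path: str | Path) -> list[ProteinQuantTable]:
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    tables = []
    for path in plex_paths:
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        plex_ids = {c.split(":", 1)[0] for c in df.columns}
        if len(plex_ids) != 1:
            raise ValueError(f"{path}: columns must all belong to one plex, found {sorted(plex_ids)}")
        plex_id = plex_ids.pop()
        df.columns = [c.split(":", 1)[1] for c in df.columns]
        sub = design[design["plex"] == plex_id]
        sample_map = {
            r["tag"]: ChannelSample(donor=r["donor"], age_group=r["age_group"], role=r["role"])
            for _, r in sub.iterrows()
        }
        tables.append(ProteinQuantTable(plex_id=plex_id, intensities=df, sample_map=sample_map))
    return tables


def read_evidence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- expression


def write_expression_study(study: ExpressionStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.log_signal.rename_axis("gene").to_csv(out / "expression.tsv", sep="\t")
    study.detection_p.rename_axis("gene").to_csv(out / "detection_p.tsv", sep="\t")
    study.samples.rename_axis("sample").to_csv(out / "samples.tsv", sep="\t")


def read_expression_study(expr: str | Path, detection: str | Path, samples: str | Path) -> ExpressionStudy:
    return ExpressionStudy(
        log_signal=pd.read_csv(expr, sep="\t", index_col="gene"),
        detection_p=pd.read_csv(detection, sep="\t", index_col="gene"),
        samples=pd.read_csv(samples, sep="\t", index_col="sample"),
    )


# --------------------------------------------------------------- respirometry


def write_trace(trace: OxygraphTrace, trace_path: str | Path, events_path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "o2_nmol_per_ml": trace.o2_nmol_per_ml}).to_csv(trace_path, index=False)
    pd.DataFrame(trace.events, columns=["time_s", "agent"]).to_csv(events_path, index=False)


def read_trace(
    trace_path: str | Path,
    events_path: str | Path,
    chamber_volume_ml: float = 2.0,
    cell_count: float = 5e6,
) -> OxygraphTrace:
    df = pd.read_csv(trace_path)
    ev = pd.read_csv(events_path)
    return OxygraphTrace(
        time_s=df["time_s"].to_numpy(),
        o2_nmol_per_ml=df["o2_nmol_per_ml"].to_numpy(),
        events=[(float(r["time_s"]), str(r["agent"])) for _, r in ev.iterrows()],
        chamber_volume_ml=chamber_volume_ml,
        cell_count=cell_count,
    )


# ---------------------------------------------------------------- morphometry


def write_cells(cells: list[CellAnnotation], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cell_rows, ves_rows, mito_rows = [], [], []
    for c in cells:
        cell_rows.append(
            {
                "cell_id": c.cell_id,
                "donor": c.donor,
                "age_group": c.age_group,
                "subset": c.subset,
                "cytosol_area_au": c.cytosol_area_au,
            }
        )
        for i, a in enumerate(c.mitochondria_areas_au):
            mito_rows.append({"cell_id": c.cell_id, "mito_id": f"{c.cell_id}_m{i}", "area_au": a})
        for v in c.vesicles:
            ves_rows.append(
                {
                    "cell_id": c.cell_id,
                    "vesicle_id": v.vesicle_id,
                    "diameter_um": v.diameter_um,
                    "double_membrane_fraction": v.double_membrane_fraction,
                    "ribosomes_attached": v.ribosomes_attached,
                    "luminal_density": v.luminal_density,
                    "contains_organelle": v.contains_identifiable_organelle,
                    "multiple_inner_vesicles": v.multiple_inner_single_membrane_vesicles,
                    "area_au": v.area_au,
                }
            )
    pd.DataFrame(cell_rows).to_csv(out / "cells.tsv", sep="\t", index=False)
    pd.DataFrame(mito_rows).to_csv(out / "mitochondria.tsv", sep="\t", index=False)
    pd.DataFrame(ves_rows).to_csv(out / "vesicles.tsv", sep="\t", index=False)


def read_cells(vesicles: str | Path, mitochondria: str | Path, cells: str | Path) -> list[CellAnnotation]:
    cell_df = pd.read_csv(cells, sep="\t")
    mito_df = pd.read_csv(mitochondria, sep="\t")
    ves_df = pd.read_csv(vesicles, sep="\t")
    out = []
    for _, row in cell_df.iterrows():
        cid = row["cell_id"]
        vs = [
            VesicleFeatures(
                vesicle_id=str(v["vesicle_id"]),
                diameter_um=float(v["diameter_um"]),
                double_membrane_fraction=float(v["double_membrane_fraction"]),
                ribosomes_attached=bool(v["ribosomes_attached"]),
                luminal_density=str(v["luminal_density"]),
                contains_identifiable_organelle=bool(v["contains_organelle"]),
                multiple_inner_single_membrane_vesicles=bool(v["multiple_inner_vesicles"]),
                area_au=float(v["area_au"]),
            )
            for _, v in ves_df[ves_df["cell_id"] == cid].iterrows()
        ]
        out.append(
            CellAnnotation(
                cell_id=str(cid),
                donor=str(row["donor"]),
                age_group=str(row["age_group"]),
                subset=str(row["subset"]),
                cytosol_area_au=float(row["cytosol_area_au"]),
                mitochondria_areas_au=[float(a) for a in mito_df.loc[mito_df["cell_id"] == cid, "area_au"]],
                vesicles=vs,
            )
        )
    return out


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
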