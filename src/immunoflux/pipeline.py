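"""End-to-end orchestration: simulate (or load) every assay arm, run its
analysis, and tie the five arms together in a cross-assay summary.

The headline cross-assay observation this report surfaces is the
protein-up / transcript-down discordance: mitochondrial proteins surviving
the proteomics screen while OXPHOS gene sets are negatively enriched in old
donors — alongside lower BHI and reserve capacity in old, inflated
autophagosome counts in old, and the intermediate-bin mitophagy-dye shift.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import (
    detection_filter,
    pathway_contrast,
    per_donor_pathway_scores,
    z_ratio,
    z_transform,
)
from .mitophagy import condition_contrast, derive_gates, sample_bin_table
from .morphometry import compare_morphometry, summaries_frame, summarize_cell
from .proteomics import filter_cascade, group_ratio_test, normalize_to_reference
from .respirometry import (
    adjust_bhi_for_memory,
    compare_respiration,
    derive_profile,
    extract_state_fluxes,
)
from .simulate import (
    StudyConfig,
    simulate_expression,
    simulate_flow,
    simulate_morphometry,
    simulate_oxygraph,
    simulate_proteomics,
)

__all__ = [
    "RunManifest",
    "run_proteomics_arm",
    "run_expression_arm",
    "run_respirometry_arm",
    "run_morphometry_arm",
    "run_mitophagy_arm",
    "run_pipeline",
    "headline_summary",
]


def _jsonable(obj):
    """Recursively convert configs/frames/numpy scalars to JSON-safe values."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


@dataclass
class RunManifest:
    version: str
    seed: int
    resolved_config: dict
    stages: dict[str, str] = field(default_factory=dict)  # stage -> "ok" | error text
    outputs: dict[str, str] = field(default_factory=dict)  # stage -> path

    def digest(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def run_proteomics_arm(tables, evidence) -> dict:
    norm = normalize_to_reference(tables)
    records = group_ratio_test(norm)
    report = filter_cascade(records, evidence)
    return {"normalized": norm, "records": records, "cascade": report}


def run_expression_arm(study, gene_sets) -> dict:
    filtered = detection_filter(study)
    z = z_transform(filtered.log_signal)
    genes = z_ratio(z, filtered.samples)
    pathway_z = per_donor_pathway_scores(z, gene_sets)
    contrast = pathway_contrast(pathway_z, filtered.samples)
    return {"zmatrix": z, "gene_table": genes, "pathway_z": pathway_z, "contrast": contrast}


def run_respirometry_arm(traces, cohort) -> dict:
    rows = []
    for donor, trace in traces.items():
        states = extract_state_fluxes(trace)
        profile = derive_profile(states)
        rows.append(
            {
                "donor": donor,
                "routine": states.routine,
                "leak": states.leak,
                "ets": states.ets,
                "rox": states.rox,
                "atp_linked": profile.atp_linked,
                "proton_leak": profile.proton_leak,
                "reserve_capacity": profile.reserve_capacity,
                "non_mitochondrial": profile.non_mitochondrial,
                "bhi": profile.bhi,
                "flags": ";".join(profile.flags),
            }
        )
    profiles = pd.DataFrame(rows).merge(cohort, on="donor")
    adjusted = adjust_bhi_for_memory(profiles)
    comparisons = compare_respiration(profiles)
    return {"profiles": profiles, "adjusted": adjusted, "comparisons": comparisons}


def run_morphometry_arm(cells) -> dict:
    summaries = summaries_frame([summarize_cell(c) for c in cells])
    comparisons = compare_morphometry(summaries)
    return {"summaries": summaries, "comparisons": comparisons}


def run_mitophagy_arm(events) -> dict:
    gates = derive_gates(events)
    bins = sample_bin_table(events, gates)
    contrasts = condition_contrast(bins)
    return {"gates": gates, "bins": bins, "contrasts": contrasts}


def headline_summary(results: dict) -> dict:
    """Cross-assay qualitative summary of the study's headline directions."""
    cascade = results["proteomics"]["cascade"]
    mito_survivors = [p for p in cascade.selected_up if p.startswith("MITO")]
    contrast = results["expression"]["contrast"]
    oxphos = contrast[contrast.index.str.startswith("OXPHOS")]
    profiles = results["respirometry"]["profiles"]
    bhi_young = profiles.loc[profiles["age_group"] == "young", "bhi"].mean()
    bhi_old = profiles.loc[profiles["age_group"] == "old", "bhi"].mean()
    bins = results["mitophagy"]["bins"]
    wide = bins.pivot(index="donor", columns="condition", values="pct_hi")
    ages = bins.groupby("donor")["age_group"].first()
    cccp_up = {
        g: bool((wide.loc[ages == g, "cccp"] > wide.loc[ages == g, "dye_only"]).all())
        for g in ("young", "old")
    }
    summ = results["morphometry"]["summaries"]
    ap_naive = summ[summ["subset"] == "naive"].groupby("age_group")["ap_count"].mean()
    return {
        "mitochondrial_proteins_pass_cascade": len(mito_survivors),
        "cascade_counts": list(cascade.counts),
        "oxphos_sets_down_in_old": int((oxphos["mean_z_old"] < oxphos["mean_z_young"]).sum()),
        "oxphos_sets_total": int(len(oxphos)),
        "protein_up_transcript_down_discordance": bool(
            len(mito_survivors) > 0 and (oxphos["mean_z_old"] < oxphos["mean_z_young"]).all()
        ),
        "mean_bhi_young": float(bhi_young),
        "mean_bhi_old": float(bhi_old),
        "bhi_young_gt_old": bool(bhi_young > bhi_old),
        "cccp_raises_hi_bin_in_every_donor": cccp_up,
        "ap_count_naive_young": float(ap_naive.get("young", np.nan)),
        "ap_count_naive_old": float(ap_naive.get("old", np.nan)),
    }


def run_pipeline(config: StudyConfig = StudyConfig(), out_dir: str | Path | None = None) -> tuple[RunManifest, dict]:
    """Simulate every arm from ``config`` and analyze it; optionally write outputs.

    Stages run in dependency order; a stage failure is recorded in the
    manifest and re-raised after the manifest is written (nonzero exit at the
    CLI).  Returns (manifest, results).
    """
    manifest = RunManifest(version=__version__, seed=config.seed, resolved_config=_jsonable(config.resolved()))
    results: dict = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _write(name: str, payload) -> None:
        if out is None:
            return
        if isinstance(payload, pd.DataFrame):
            path = out / f"{name}.tsv"
            payload.to_csv(path, sep="\t")
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(_jsonable(payload), indent=2))
        manifest.outputs[name] = str(path)

    stages = [
        (
            "proteomics",
            lambda: run_proteomics_arm(*simulate_proteomics(config.proteomics, seed=config.seed)[:2]),
        ),
        (
            "expression",
            lambda: run_expression_arm(*simulate_expression(config.expression, seed=config.seed)[:2]),
        ),
        (
            "respirometry",
            lambda: run_respirometry_arm(*simulate_oxygraph(config.respirometry, seed=config.seed)[:2]),
        ),
        ("morphometry", lambda: run_morphometry_arm(simulate_morphometry(config.morphometry, seed=config.seed)[0])),
        ("mitophagy", lambda: run_mitophagy_arm(simulate_flow(config.flow, seed=config.seed)[0])),
    ]
    current = "setup"
    try:
        for current, fn in stages:
            results[current] = fn()
            manifest.stages[current] = "ok"
        current = "report"
        results["report"] = headline_summary(results)
        manifest.stages["report"] = "ok"
    except Exception as exc:  # noqa: BLE001 - recorded then re-raised
        manifest.stages[current] = f"error: {exc}"
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(_jsonable(asdict(manifest)), indent=2))
        raise

    _write("proteomics_differential", results["proteomics"]["records"])
    _write(
        "proteomics_cascade",
        {
            "counts": list(results["proteomics"]["cascade"].counts),
            "selected_up": results["proteomics"]["cascade"].selected_up,
            "selected_down": results["proteomics"]["cascade"].selected_down,
        },
    )
    _write("expression_genes", results["expression"]["gene_table"])
    _write("expression_pathway_contrast", results["expression"]["contrast"])
    _write("respirometry_profiles", results["respirometry"]["profiles"])
    _write("respirometry_adjusted", results["respirometry"]["adjusted"])
    _write("morphometry_summaries", results["morphometry"]["summaries"])
    _write("morphometry_comparisons", results["morphometry"]["comparisons"])
    _write("mitophagy_bins", results["mitophagy"]["bins"])
    _write("mitophagy_contrasts", results["mitophagy"]["contrasts"])
    _write("report", results["report"])
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(_jsonable(asdict(manifest)), indent=2))
    return manifest, results
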