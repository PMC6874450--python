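"""Seeded synthetic-study generators for all five assay arms.

Each generator is a pure function of (config, seed): it emulates the
statistical structure of the corresponding assay — group sizes, noise
families and planted effect directions — and returns both the input objects
the analysis modules consume and a ground-truth sidecar sufficient to score
recovery.  Default group sizes mirror the study design (4 young / 18 old
proteomics extracts over four 8plex runs with a shared reference channel and
technical duplicates; 8 young / 25 old expression donors; 7 / 7 respirometry
donors; 5 / 4 TEM donors with 15 / 12 images per stratum; 12 / 12 flow
donors), and default effects mirror its reported directions: mitochondrial
proteins up in old, OXPHOS transcription down in old, lower reserve capacity
and higher non-mitochondrial respiration in old, inflated autophagosome
counts in old, and an intermediate-intensity mitophagy-dye shift in old.

Noise families are the simplest consistent with each assay's support:
log-normal for reporter intensities and areas, Gaussian for oxygen traces
and log-signals, Poisson for vesicle and mitochondrion counts, log-normal
mixtures for flow fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .morphometry import CellAnnotation, VesicleFeatures
from .proteomics import ChannelSample, ProteinQuantTable
from .enrichment import ExpressionStudy
from .respirometry import OxygraphTrace

__all__ = [
    "ProteomicsConfig",
    "ExpressionConfig",
    "RespirometryConfig",
    "MorphometryConfig",
    "FlowConfig",
    "StudyConfig",
    "simulate_proteomics",
    "simulate_expression",
    "simulate_oxygraph",
    "simulate_morphometry",
    "simulate_flow",
]

ITRAQ_TAGS = ("113", "114", "115", "116", "117", "118", "119", "121")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------- proteomics


@dataclass(frozen=True)
class ProteomicsConfig:
    n_proteins: int = 600
    n_mito_up: int = 60
    up_fold: float = 1.5
    intensity_cv: float = 0.10
    n_plexes: int = 4
    n_young: int = 4
    n_old: int = 18
    evidence_fail_up: float = 0.05  # fraction of planted-up proteins with failing evidence
    evidence_fail_null: float = 0.30


def _plex_layout(cfg: ProteomicsConfig) -> list[dict[str, ChannelSample]]:
    """Channel assignment: 1 reference per plex, all donors once, duplicates fill.

    One within-plex technical duplicate (first young donor twice in plex 1)
    and cross-plex duplicates for the remaining spare channels, mirroring a
    design with technical controls within and between runs.
    """
    donors = [(f"y{i+1}", "young") for i in range(cfg.n_young)] + [
        (f"o{i+1}", "old") for i in range(cfg.n_old)
    ]
    per_plex = len(ITRAQ_TAGS) - 1
    bio_slots = cfg.n_plexes * per_plex
    slots: list[tuple[str, str, str]] = [(d, g, "biological") for d, g in donors]
    if bio_slots < len(slots) + 1:
        raise ValueError("not enough channels for the requested donors")
    # within-plex technical control: first donor repeated inside plex 1
    slots.insert(min(per_plex - 1, len(slots)), (*donors[0], "technical_duplicate"))
    # remaining spare channels: between-plex technical controls
    i = 1
    while len(slots) < bio_slots:
        d, g = donors[i % len(donors)]
        slots.append((d, g, "technical_duplicate"))
        i += 1
    layouts = []
    k = 0
    for _ in range(cfg.n_plexes):
        layout = {ITRAQ_TAGS[0]: ChannelSample(donor="ref", age_group="young", role="reference")}
        for tag in ITRAQ_TAGS[1:]:
            d, g, role = slots[k]
            layout[tag] = ChannelSample(donor=d, age_group=g, role=role)
            k += 1
        layouts.append(layout)
    return layouts


def simulate_proteomics(cfg: ProteomicsConfig = ProteomicsConfig(), seed: int = 0):
    """Multi-plex reporter-intensity tables with a planted mitochondrial up-shift.

    Per protein: a base abundance (log-normal across proteins) shared by the
    common reference sample in every plex; per plex a multiplicative batch
    factor; per channel log-normal measurement noise at ``intensity_cv``.
    The first ``n_mito_up`` proteins (accessions prefixed ``MITO``) are
    multiplied by ``up_fold`` in every old channel.  Evidence records are
    drawn so a configurable fraction of proteins fails the evidence stage.

    Returns (tables, evidence, ground_truth).
    """
    rng = _rng(seed, 1)
    n = cfg.n_proteins
    proteins = [f"MITO{i:04d}" for i in range(cfg.n_mito_up)] + [
        f"PROT{i:04d}" for i in range(n - cfg.n_mito_up)
    ]
    planted = set(proteins[: cfg.n_mito_up])
    base = rng.lognormal(mean=np.log(1e6), sigma=0.6, size=n)
    sigma = np.sqrt(np.log1p(cfg.intensity_cv**2))  # log-normal sd for the given CV

    layouts = _plex_layout(cfg)
    tables = []
    for p, layout in enumerate(layouts):
        batch = rng.lognormal(mean=0.0, sigma=0.15)
        cols = {}
        for tag, samp in layout.items():
            fold = np.where(
                [prot in planted for prot in proteins],
                cfg.up_fold if samp.age_group == "old" and samp.role != "reference" else 1.0,
                1.0,
            )
            noise = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n)
            cols[tag] = base * batch * fold * noise
        tables.append(
            ProteinQuantTable(
                plex_id=f"plex{p+1}",
                intensities=pd.DataFrame(cols, index=proteins),
                sample_map=layout,
            )
        )

    ev_rows = []
    for prot in proteins:
        fail_p = cfg.evidence_fail_up if prot in planted else cfg.evidence_fail_null
        fails = rng.random() < fail_p
        if fails:
            mode = rng.integers(3)
            unique = 1 if mode == 0 else int(2 + rng.poisson(3))
            conf = "medium" if mode == 1 else "high"
            ion = float(rng.uniform(5, 30)) if mode == 2 else float(rng.uniform(31, 120))
            if mode == 0:
                conf, ion = "high", float(rng.uniform(31, 120))
        else:
            unique = int(2 + rng.poisson(4))
            conf = "high"
            ion = float(rng.uniform(31, 120))
        ev_rows.append(
            {"protein_id": prot, "unique_peptides": unique, "confidence": conf, "max_ion_score": ion}
        )
    evidence = pd.DataFrame(ev_rows)
    truth = {
        "planted_up": sorted(planted),
        "up_fold": cfg.up_fold,
        "n_proteins": n,
        "evidence_pass": {
            r["protein_id"]: bool(
                r["unique_peptides"] >= 2 and r["confidence"] == "high" and r["max_ion_score"] > 30
            )
            for r in ev_rows
        },
    }
    return tables, evidence, truth


# ---------------------------------------------------------------- expression


@dataclass(frozen=True)
class ExpressionConfig:
    n_genes: int = 2000
    n_young_m: int = 5
    n_young_f: int = 3
    n_old_m: int = 19
    n_old_f: int = 6
    gene_mean: float = 8.0
    gene_sd: float = 1.5  # spread of gene base levels across the array
    sample_noise_sd: float = 0.3
    n_random_sets: int = 40
    random_set_size: tuple[int, int] = (20, 50)
    n_shifted_sets: int = 3
    shifted_set_size: int = 30
    shift_z: float = -0.5  # planted OXPHOS shift in old, in array-Z units
    dropout_fraction: float = 0.10


def simulate_expression(cfg: ExpressionConfig = ExpressionConfig(), seed: int = 0):
    """Expression matrix + GMT collection with OXPHOS sets shifted in old.

    Shifted-set genes are displaced in old samples by ``shift_z`` array-Z
    units (converted to the log-signal scale through the array spread).
    A ``dropout_fraction`` of non-set genes carries high detection p-values
    everywhere and is meant to be removed by the detection filter.

    Returns (study, gene_sets, ground_truth).
    """
    rng = _rng(seed, 2)
    if cfg.n_shifted_sets * cfg.shifted_set_size > cfg.n_genes:
        raise ValueError("planted sets do not fit inside the gene universe")
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sample_rows = []
    for i in range(cfg.n_young_m):
        sample_rows.append({"sample": f"Y_M{i+1}", "age_group": "young", "sex": "M"})
    for i in range(cfg.n_young_f):
        sample_rows.append({"sample": f"Y_F{i+1}", "age_group": "young", "sex": "F"})
    for i in range(cfg.n_old_m):
        sample_rows.append({"sample": f"O_M{i+1}", "age_group": "old", "sex": "M"})
    for i in range(cfg.n_old_f):
        sample_rows.append({"sample": f"O_F{i+1}", "age_group": "old", "sex": "F"})
    samples = pd.DataFrame(sample_rows).set_index("sample")

    base = rng.normal(cfg.gene_mean, cfg.gene_sd, size=cfg.n_genes)
    X = base[:, None] + rng.normal(0.0, cfg.sample_noise_sd, size=(cfg.n_genes, len(samples)))

    # planted sets occupy the head of the gene list, disjoint
    gene_sets: dict[str, list[str]] = {}
    cursor = 0
    shifted_names = []
    for s in range(cfg.n_shifted_sets):
        name = f"OXPHOS_SET_{s+1}"
        members = genes[cursor : cursor + cfg.shifted_set_size]
        cursor += cfg.shifted_set_size
        gene_sets[name] = members
        shifted_names.append(name)
    array_spread = float(np.sqrt(cfg.gene_sd**2 + cfg.sample_noise_sd**2))
    shift_raw = cfg.shift_z * array_spread
    old_cols = np.asarray(samples["age_group"] == "old")
    X[:cursor, old_cols] += shift_raw

    lo, hi = cfg.random_set_size
    for s in range(cfg.n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(genes, size=size, replace=False))
        gene_sets[f"RANDOM_SET_{s+1:02d}"] = members

    detection = rng.uniform(0.0, 0.01, size=X.shape)
    eligible = np.arange(cursor, cfg.n_genes)  # never drop planted-set genes
    n_drop = int(round(cfg.dropout_fraction * cfg.n_genes))
    dropped = rng.choice(eligible, size=min(n_drop, eligible.size), replace=False)
    detection[dropped, :] = rng.uniform(0.05, 1.0, size=(dropped.size, X.shape[1]))

    study = ExpressionStudy(
        log_signal=pd.DataFrame(X, index=genes, columns=samples.index),
        detection_p=pd.DataFrame(detection, index=genes, columns=samples.index),
        samples=samples,
    )
    truth = {
        "shifted_sets": shifted_names,
        "shift_z": cfg.shift_z,
        "dropped_genes": sorted(genes[i] for i in dropped),
    }
    return study, gene_sets, truth


# --------------------------------------------------------------- respirometry


@dataclass(frozen=True)
class RespirometryConfig:
    n_young: int = 7
    n_old: int = 7
    # group mean state fluxes, pmol O2/s/1e6 cells; old: lower reserve, higher ROX
    young_fluxes: dict = field(
        default_factory=lambda: {"routine": 50.0, "leak": 12.0, "ets": 130.0, "rox": 6.0}
    )
    old_fluxes: dict = field(
        default_factory=lambda: {"routine": 45.0, "leak": 14.0, "ets": 90.0, "rox": 10.0}
    )
    between_donor_cv: float = 0.10
    noise_frac: float = 0.01  # trace noise sd = noise_frac * routine flux, nmol/mL
    sample_interval_s: float = 1.0
    t_oligomycin: float = 600.0
    t_fccp: tuple[float, ...] = (1200.0, 1500.0, 1800.0)
    fccp_plateau_fractions: tuple[float, ...] = (0.75, 1.0, 0.9)  # titration to the optimum
    t_rotenone: float = 2100.0
    t_antimycin: float = 2160.0
    t_end: float = 2700.0
    o2_start: float = 1000.0
    chamber_volume_ml: float = 2.0
    cell_count: float = 5e6
    # memory-fraction covariate of the cohort comparison
    memory_pct_young: tuple[float, float] = (30.0, 6.0)  # mean, sd
    memory_pct_old: tuple[float, float] = (40.0, 6.0)


def _piecewise_trace(cfg: RespirometryConfig, fluxes: dict, rng: np.random.Generator) -> OxygraphTrace:
    t = np.arange(0.0, cfg.t_end + cfg.sample_interval_s / 2, cfg.sample_interval_s)
    # flux value at every time point
    f = np.empty_like(t)
    f[t < cfg.t_oligomycin] = fluxes["routine"]
    f[(t >= cfg.t_oligomycin) & (t < cfg.t_fccp[0])] = fluxes["leak"]
    bounds = list(cfg.t_fccp) + [cfg.t_rotenone]
    for i, frac in enumerate(cfg.fccp_plateau_fractions):
        f[(t >= bounds[i]) & (t < bounds[i + 1])] = frac * fluxes["ets"]
    f[(t >= cfg.t_rotenone) & (t < cfg.t_antimycin)] = 1.3 * fluxes["rox"]  # rotenone-only residual
    f[t >= cfg.t_antimycin] = fluxes["rox"]

    slope = f * (cfg.cell_count / 1e6) / (1000.0 * cfg.chamber_volume_ml)  # nmol/mL/s
    conc = cfg.o2_start - np.concatenate([[0.0], np.cumsum((slope[1:] + slope[:-1]) / 2 * np.diff(t))])
    noise_sd = cfg.noise_frac * fluxes["routine"]
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=conc.shape)
    # brief injection transient after each titration
    events = [(cfg.t_oligomycin, "oligomycin")]
    events += [(ts, "fccp_step") for ts in cfg.t_fccp]
    events += [(cfg.t_rotenone, "rotenone"), (cfg.t_antimycin, "antimycin_a")]
    for ts, _ in events:
        idx = (t >= ts) & (t < ts + 10.0)
        conc[idx] += 3.0 * noise_sd * np.exp(-(t[idx] - ts) / 4.0)
    return OxygraphTrace(
        time_s=t,
        o2_nmol_per_ml=conc,
        events=events,
        chamber_volume_ml=cfg.chamber_volume_ml,
        cell_count=cfg.cell_count,
    )


def simulate_oxygraph(cfg: RespirometryConfig = RespirometryConfig(), seed: int = 0):
    """Per-donor piecewise oxygraph traces encoding true state fluxes.

    Segment slopes encode the donor's true fluxes; Gaussian concentration
    noise and small post-injection transients are superimposed.  FCCP is
    titrated in steps whose plateau fractions peak at the optimum dose.

    Returns (traces: donor -> OxygraphTrace, cohort: DataFrame with
    memory_pct, ground_truth: donor -> true fluxes and BHI).
    """
    from .respirometry import StateFluxes, derive_profile

    rng = _rng(seed, 3)
    traces: dict[str, OxygraphTrace] = {}
    truth: dict[str, dict] = {}
    cohort_rows = []
    for group, n, means, mem in (
        ("young", cfg.n_young, cfg.young_fluxes, cfg.memory_pct_young),
        ("old", cfg.n_old, cfg.old_fluxes, cfg.memory_pct_old),
    ):
        for i in range(n):
            donor = f"{group[0]}{i+1}"
            fl = {k: float(v * rng.lognormal(0.0, cfg.between_donor_cv)) for k, v in means.items()}
            fl["ets"] = max(fl["ets"], 1.05 * fl["routine"])  # keep reserve positive
            fl["leak"] = min(max(fl["leak"], 1.05 * fl["rox"]), 0.95 * fl["routine"])
            traces[donor] = _piecewise_trace(cfg, fl, rng)
            profile = derive_profile(StateFluxes(**fl))
            truth[donor] = {"fluxes": fl, "bhi": profile.bhi, "age_group": group}
            cohort_rows.append(
                {
                    "donor": donor,
                    "age_group": group,
                    "memory_pct": float(np.clip(rng.normal(*mem), 5.0, 95.0)),
                }
            )
    cohort = pd.DataFrame(cohort_rows)
    return traces, cohort, truth


# ---------------------------------------------------------------- morphometry


@dataclass(frozen=True)
class MorphometryConfig:
    n_young_donors: int = 5
    n_old_donors: int = 4
    cells_per_stratum: dict = field(
        default_factory=lambda: {
            ("young", "naive"): 15,
            ("old", "naive"): 12,
            ("young", "memory"): 15,
            ("old", "memory"): 12,
        }
    )
    ap_means: dict = field(
        default_factory=lambda: {
            ("young", "naive"): 2.0,
            ("old", "naive"): 6.0,
            ("young", "memory"): 3.0,
            ("old", "memory"): 6.0,
        }
    )
    al_mean: float = 2.0  # no age effect on autolysosome counts
    mito_means: dict = field(
        default_factory=lambda: {
            ("young", "naive"): 8.0,
            ("old", "naive"): 7.0,
            ("young", "memory"): 14.0,
            ("old", "memory"): 14.0,
        }
    )
    mito_area_mean: dict = field(default_factory=lambda: {"naive": 1.0, "memory": 1.4})
    area_sigma_ln: float = 0.3
    cytosol_area_mean: float = 100.0
    feature_noise: float = 0.02  # probability a vesicle's features are scrambled


def _draw_vesicle(intended: str, idx: int, rng: np.random.Generator, cfg: MorphometryConfig) -> VesicleFeatures:
    from .morphometry import LUMINAL_DENSITIES

    diameter = float(rng.uniform(0.5, 1.5))
    area = float(rng.lognormal(np.log(0.3), cfg.area_sigma_ln))
    if rng.random() < cfg.feature_noise:
        return VesicleFeatures(
            vesicle_id=f"ves{idx}",
            diameter_um=diameter,
            double_membrane_fraction=float(rng.choice([0.0, 0.2, 0.6])),
            ribosomes_attached=bool(rng.integers(2)),
            luminal_density=str(rng.choice(LUMINAL_DENSITIES)),
            contains_identifiable_organelle=bool(rng.integers(2)),
            multiple_inner_single_membrane_vesicles=bool(rng.integers(2)),
            area_au=area,
        )
    if intended == "AP":
        return VesicleFeatures(
            vesicle_id=f"ves{idx}",
            diameter_um=diameter,
            double_membrane_fraction=float(rng.uniform(0.5, 1.0)),
            ribosomes_attached=False,
            luminal_density="similar_to_cytosol",
            contains_identifiable_organelle=bool(rng.random() < 0.5),
            multiple_inner_single_membrane_vesicles=False,
            area_au=area,
        )
    # AL: single/scant double membrane, lucent or amorphous multi-vesicular
    # lumen.  A partial double membrane together with a ribosome-free face
    # would already satisfy two AP criteria, so AL draws take one or the other.
    if rng.random() < 0.8:
        lum, multi = "lower_than_cytosol", bool(rng.integers(2))
    else:
        lum, multi = "dense_amorphous", True
    ribosomes = bool(rng.random() < 0.5)
    return VesicleFeatures(
        vesicle_id=f"ves{idx}",
        diameter_um=diameter,
        double_membrane_fraction=float(rng.uniform(0.05, 0.35)) if ribosomes else 0.0,
        ribosomes_attached=ribosomes,
        luminal_density=lum,
        contains_identifiable_organelle=False,
        multiple_inner_single_membrane_vesicles=multi,
        area_au=area,
    )


def simulate_morphometry(cfg: MorphometryConfig = MorphometryConfig(), seed: int = 0):
    """Annotated TEM cells with planted per-stratum count means.

    AP/AL/mitochondrion counts are Poisson with the configured stratum means
    (autophagosomes inflated in old cells); vesicle features are drawn
    consistent with the intended class apart from a small scrambled fraction;
    areas are log-normal.  Cells are assigned round-robin to donors.

    Returns (cells, ground_truth with intended labels per vesicle).
    """
    rng = _rng(seed, 4)
    cells: list[CellAnnotation] = []
    intended_labels: dict[str, str] = {}
    vix = 0
    for (age, subset), n_cells in cfg.cells_per_stratum.items():
        n_donors = cfg.n_young_donors if age == "young" else cfg.n_old_donors
        for c in range(n_cells):
            donor = f"{age[0]}d{(c % n_donors) + 1}"
            n_ap = int(rng.poisson(cfg.ap_means[(age, subset)]))
            n_al = int(rng.poisson(cfg.al_mean))
            n_mito = max(1, int(rng.poisson(cfg.mito_means[(age, subset)])))
            vesicles = []
            for intended in ["AP"] * n_ap + ["AL"] * n_al:
                v = _draw_vesicle(intended, vix, rng, cfg)
                intended_labels[v.vesicle_id] = intended
                vesicles.append(v)
                vix += 1
            mito_areas = list(
                rng.lognormal(np.log(cfg.mito_area_mean[subset]), cfg.area_sigma_ln, size=n_mito)
            )
            cells.append(
                CellAnnotation(
                    cell_id=f"{age}_{subset}_{c+1}",
                    donor=donor,
                    age_group=age,
                    subset=subset,
                    cytosol_area_au=float(rng.lognormal(np.log(cfg.cytosol_area_mean), 0.15)),
                    mitochondria_areas_au=[float(a) for a in mito_areas],
                    vesicles=vesicles,
                )
            )
    truth = {
        "intended_labels": intended_labels,
        "ap_means": {f"{a}_{s}": m for (a, s), m in cfg.ap_means.items()},
        "al_mean": cfg.al_mean,
    }
    return cells, truth


# -------------------------------------------------------------------- flow


@dataclass(frozen=True)
class FlowConfig:
    n_young: int = 12
    n_old: int = 12
    n_events: int = 20000
    component_medians: tuple[float, float, float] = (30.0, 300.0, 3000.0)
    sigma_ln: float = 0.5
    # dye-only bin weights: (mean int weight, sd) per group; hi weight fixed
    int_weight_young: tuple[float, float] = (0.20, 0.06)
    int_weight_old: tuple[float, float] = (0.35, 0.06)
    hi_weight: float = 0.10
    cccp_transfer: float = 0.6  # fraction of lo+int mass moved to hi by CCCP
    baf_transfer: float = 0.5  # fraction of lo and hi mass moved to int by bafilomycin


def _mixture_events(weights: np.ndarray, cfg: FlowConfig, rng: np.random.Generator) -> np.ndarray:
    comp = np.searchsorted(np.cumsum(weights), rng.random(cfg.n_events), side="right")
    comp = np.clip(comp, 0, 2)
    mu = np.log(np.asarray(cfg.component_medians))[comp]
    return np.exp(mu + cfg.sigma_ln * rng.standard_normal(cfg.n_events))


def simulate_flow(cfg: FlowConfig = FlowConfig(), seed: int = 0):
    """Per-event mitophagy-dye intensity tables for all four conditions.

    Each stained sample is a three-component log-normal mixture (lo/int/hi
    compartments).  Dye-only weights give old donors a larger intermediate
    component than young; CCCP moves lo+int mass into hi (forced mitophagy)
    and bafilomycin moves lo and hi mass into int (blocked acidification) —
    both applied to the donor's own dye-only weights, so the drug direction
    holds within every donor.  Unstained samples are pure low-component
    autofluorescence.

    Returns (events DataFrame, ground_truth: donor -> condition -> weights).
    """
    rng = _rng(seed, 5)
    truth: dict[str, dict[str, list[float]]] = {}
    blocks: list[np.ndarray] = []
    labels: list[tuple[str, str, str, str]] = []  # (sample, donor, age_group, condition)
    for group, n, (w_int_mu, w_int_sd) in (
        ("young", cfg.n_young, cfg.int_weight_young),
        ("old", cfg.n_old, cfg.int_weight_old),
    ):
        for i in range(n):
            donor = f"{group[0]}f{i+1}"
            w_int = float(np.clip(rng.normal(w_int_mu, w_int_sd), 0.02, 0.85))
            w_hi = cfg.hi_weight
            w_lo = 1.0 - w_int - w_hi
            dye = np.array([w_lo, w_int, w_hi])
            tr = cfg.cccp_transfer
            cccp = np.array([w_lo * (1 - tr), w_int * (1 - tr), w_hi + tr * (w_lo + w_int)])
            bt = cfg.baf_transfer
            baf = np.array([w_lo * (1 - bt), w_int + bt * (w_lo + w_hi), w_hi * (1 - bt)])
            cond_weights = {"dye_only": dye, "cccp": cccp, "bafilomycin": baf}
            truth[donor] = {c: [float(x) for x in w] for c, w in cond_weights.items()}
            blocks.append(
                np.exp(
                    np.log(cfg.component_medians[0]) + cfg.sigma_ln * rng.standard_normal(cfg.n_events)
                )
            )
            labels.append((f"{donor}_unstained", donor, group, "unstained"))
            for cond, w in cond_weights.items():
                blocks.append(_mixture_events(w, cfg, rng))
                labels.append((f"{donor}_{cond}", donor, group, cond))
    reps = np.array([b.size for b in blocks])

    def _cat(col: int) -> pd.Categorical:
        vals = [l[col] for l in labels]
        cats = sorted(set(vals))
        idx = {c: i for i, c in enumerate(cats)}
        codes = np.repeat(np.array([idx[v] for v in vals], dtype=np.int32), reps)
        return pd.Categorical.from_codes(codes, categories=cats)

    events = pd.DataFrame(
        {
            "sample": _cat(0),
            "donor": _cat(1),
            "age_group": _cat(2),
            "condition": _cat(3),
            "intensity": np.concatenate(blocks),
        }
    )
    return events, truth


# -------------------------------------------------------------------- study


@dataclass(frozen=True)
class StudyConfig:
    """Top-level configuration bundling all five assay arms and the seed."""

    seed: int = 0
    proteomics: ProteomicsConfig = ProteomicsConfig()
    expression: ExpressionConfig = ExpressionConfig()
    respirometry: RespirometryConfig = RespirometryConfig()
    morphometry: MorphometryConfig = MorphometryConfig()
    flow: FlowConfig = FlowConfig()

    def resolved(self) -> dict:
        return asdict(self)
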