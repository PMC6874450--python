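"""Transcriptome differential analysis and parametric gene-set enrichment.

Pipeline: detection-p filtering of a gene x sample log-signal matrix;
array-wise Z-transformation (each sample standardized over its genes);
per-gene Z-ratio statistics between age groups; PAGE (parametric analysis
of gene-set enrichment), which scores a set of m genes by

    Z = (S_m - mu) * sqrt(m) / delta,

where S_m is the mean gene score within the set and mu, delta are the mean
and standard deviation of all gene scores; and the young-vs-old pathway
contrast (per-donor pathway Z-scores averaged within each age group, ranked
by their difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_fdr, normal_ztest_p

__all__ = [
    "ExpressionStudy",
    "ZRatioConfig",
    "detection_filter",
    "z_transform",
    "z_ratio",
    "page",
    "per_donor_pathway_scores",
    "pathway_contrast",
]

YOUNG, OLD = "young", "old"


def _rowwise_student_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-tailed pooled-variance t p-values row by row (vectorized).

    Rows where both groups are constant (zero pooled variance) get p = 1:
    in a matrix-wide screen a flat gene carries no evidence either way, and
    aborting the whole screen for it would be unhelpful.
    """
    from scipy import stats as sps

    res = sps.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    p[degenerate] = 1.0
    return p


@dataclass
class ExpressionStudy:
    """Gene x sample log-signals with detection p-values and a sample sheet.

    ``samples`` must be indexed by sample id with at least an ``age_group``
    column ("young"/"old"); ``sex`` is optional metadata.
    """

    log_signal: pd.DataFrame
    detection_p: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.log_signal.columns.equals(self.detection_p.columns) or not self.log_signal.index.equals(
            self.detection_p.index
        ):
            raise ValueError("log_signal and detection_p must share genes and samples")
        missing = set(self.log_signal.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet missing entries for: {sorted(missing)}")
        dp = self.detection_p.to_numpy(dtype=float)
        if np.any((dp < 0) | (dp > 1)):
            raise ValueError("detection p-values must lie in [0, 1]")


def detection_filter(study: ExpressionStudy, p_cut: float = 0.02, min_fraction: float = 0.5) -> ExpressionStudy:
    """Keep genes detected (detection p <= p_cut) in >= min_fraction of samples."""
    detected = (study.detection_p <= p_cut).mean(axis=1) >= min_fraction
    if not detected.any():
        raise ValueError(
            f"no gene passes detection filtering (p_cut={p_cut}, min_fraction={min_fraction}); relax thresholds"
        )
    return ExpressionStudy(
        log_signal=study.log_signal.loc[detected],
        detection_p=study.detection_p.loc[detected],
        samples=study.samples,
    )


def z_transform(log_signal: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Array-wise Z-transformation: standardize each sample over its genes.

    Every column of the result has mean 0 and sd 1 (to the chosen ddof).
    Location and scale changes of a column leave its Z-scores unchanged.
    """
    if log_signal.shape[0] < 2:
        raise ValueError("need >= 2 genes to standardize")
    mu = log_signal.mean(axis=0)
    sd = log_signal.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero spread in sample(s) {bad}; cannot Z-transform")
    return (log_signal - mu) / sd


@dataclass(frozen=True)
class ZRatioConfig:
    z_ratio_cut: float = 1.5
    alpha: float = 0.05
    fdr_cut: float = 0.3


def z_ratio(zmatrix: pd.DataFrame, samples: pd.DataFrame, config: ZRatioConfig = ZRatioConfig()) -> pd.DataFrame:
    """Per-gene Z-ratio between old and young plus per-gene t-test p/q.

    z_ratio(g) = (mean Z_old(g) - mean Z_young(g)) / sd_over_genes(differences),
    so the z_ratio vector itself has sd 1 across genes.  Per-gene p-values
    come from a two-sample Student t on the Z values; q-values from BH-FDR;
    ``significant`` applies the |z_ratio| / p / q cutoffs together.
    """
    young = [s for s in zmatrix.columns if samples.loc[s, "age_group"] == YOUNG]
    old = [s for s in zmatrix.columns if samples.loc[s, "age_group"] == OLD]
    if len(young) < 2 or len(old) < 2:
        raise ValueError("need >= 2 samples per age group")
    diff = zmatrix[old].mean(axis=1) - zmatrix[young].mean(axis=1)
    spread = diff.std(ddof=1)
    if spread == 0:
        if (diff == 0).all():
            zr = diff  # identical group profiles: no signal anywhere
        else:
            raise ValueError("degenerate: per-gene group differences have zero spread")
    else:
        zr = diff / spread

    yv = zmatrix[young].to_numpy(dtype=float)
    ov = zmatrix[old].to_numpy(dtype=float)
    pvals = _rowwise_student_p(ov, yv)
    qvals = bh_fdr(pvals)
    out = pd.DataFrame(
        {
            "mean_z_young": zmatrix[young].mean(axis=1),
            "mean_z_old": zmatrix[old].mean(axis=1),
            "z_ratio": zr,
            "p_value": pvals,
            "q_value": qvals,
        },
        index=zmatrix.index,
    )
    out["significant"] = (
        (out["z_ratio"].abs() >= config.z_ratio_cut)
        & (out["p_value"] <= config.alpha)
        & (out["q_value"] <= config.fdr_cut)
    )
    return out.rename_axis("gene")


def page(
    scores: pd.Series,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.05,
    fdr_cut: float = 0.3,
    min_set_size: int = 10,
) -> pd.DataFrame:
    """PAGE enrichment of each gene set against the all-gene score distribution.

    Sets are first mapped onto the score universe; genes absent from the
    universe are ignored and sets left empty are dropped.  Sets smaller than
    ``min_set_size`` are scored but flagged (``small_set``), since the normal
    approximation behind the Z is weak there.
    """
    scores = scores.astype(float)
    if not np.all(np.isfinite(scores.to_numpy())):
        raise ValueError("gene scores must be finite")
    mu = float(scores.mean())
    delta = float(scores.std(ddof=1))
    if delta == 0:
        raise ValueError("zero spread of gene scores")
    universe = set(scores.index)

    rows = []
    for name, members in gene_sets.items():
        mapped = [g for g in members if g in universe]
        m = len(mapped)
        if m == 0:
            continue  # unmappable set: dropped
        s_m = float(scores.loc[mapped].mean())
        z = (s_m - mu) * np.sqrt(m) / delta
        rows.append(
            {
                "set_name": name,
                "m": m,
                "S_m": s_m,
                "mu": mu,
                "delta": delta,
                "z": z,
                "p_value": normal_ztest_p(z),
                "small_set": m < min_set_size,
            }
        )
    if not rows:
        raise ValueError("no gene set overlaps the score universe")
    out = pd.DataFrame(rows).set_index("set_name")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["selected"] = (out["p_value"] <= alpha) & (out["q_value"] <= fdr_cut)
    return out


def per_donor_pathway_scores(zmatrix: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """PAGE Z-score of every set within every donor's Z-profile (set x donor).

    Matrix form of :func:`page` applied column by column: for donor d,
    z(set, d) = (mean_set Z_d - mean_all Z_d) * sqrt(m) / sd_all(Z_d).
    Sets with no gene in the matrix are dropped.
    """
    X = zmatrix.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(zmatrix.index)}
    mu = X.mean(axis=0)
    delta = X.std(axis=0, ddof=1)
    names, rows = [], []
    for name, members in gene_sets.items():
        idx = [pos[g] for g in members if g in pos]
        if not idx:
            continue
        m = len(idx)
        s_m = X[idx].mean(axis=0)
        names.append(name)
        rows.append((s_m - mu) * np.sqrt(m) / delta)
    if not names:
        raise ValueError("no gene set overlaps the Z matrix")
    return pd.DataFrame(np.vstack(rows), index=names, columns=zmatrix.columns)


@dataclass(frozen=True)
class ContrastConfig:
    top_k: int = 50
    alpha: float = 0.05
    fdr_cut: float = 0.3


def pathway_contrast(
    pathway_z: pd.DataFrame,
    samples: pd.DataFrame,
    config: ContrastConfig = ContrastConfig(),
) -> pd.DataFrame:
    """Young-vs-old contrast of per-donor pathway Z-scores.

    Per set: group means of the per-donor PAGE scores, their difference
    (young - old), a two-sample Student p across donors with BH q, a rank by
    |difference|, and a ``selected`` flag marking the top-K up and top-K down
    sets among those passing the p/FDR gates.
    """
    young = [d for d in pathway_z.columns if samples.loc[d, "age_group"] == YOUNG]
    old = [d for d in pathway_z.columns if samples.loc[d, "age_group"] == OLD]
    if len(young) < 2 or len(old) < 2:
        raise ValueError("need >= 2 donors per age group")
    yv = pathway_z[young].to_numpy(dtype=float)
    ov = pathway_z[old].to_numpy(dtype=float)
    pvals = _rowwise_student_p(yv, ov)
    out = pd.DataFrame(
        {
            "mean_z_young": pathway_z[young].mean(axis=1),
            "mean_z_old": pathway_z[old].mean(axis=1),
            "p_value": pvals,
            "q_value": bh_fdr(pvals),
        },
        index=pathway_z.index,
    )
    out["z_difference"] = out["mean_z_young"] - out["mean_z_old"]
    out["rank"] = out["z_difference"].abs().rank(ascending=False, method="first").astype(int)
    passing = (out["p_value"] <= config.alpha) & (out["q_value"] <= config.fdr_cut)
    up = out[passing & (out["z_difference"] > 0)].nlargest(config.top_k, "z_difference").index
    down = out[passing & (out["z_difference"] < 0)].nsmallest(config.top_k, "z_difference").index
    out["selected"] = out.index.isin(up) | out.index.isin(down)
    return out.sort_values("z_difference", ascending=False)
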