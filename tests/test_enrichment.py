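"""Detection filtering, array-wise Z-transformation, Z-ratio statistics,
PAGE enrichment and the young/old pathway contrast."""

import numpy as np
import pandas as pd
import pytest

from immunoflux.enrichment import (
    ContrastConfig,
    ExpressionStudy,
    detection_filter,
    page,
    pathway_contrast,
    per_donor_pathway_scores,
    z_ratio,
    z_transform,
)
from immunoflux.simulate import ExpressionConfig, simulate_expression


def _study(log_signal: pd.DataFrame, groups: list[str]) -> ExpressionStudy:
    samples = pd.DataFrame({"age_group": groups, "sex": "M"}, index=log_signal.columns)
    return ExpressionStudy(
        log_signal=log_signal,
        detection_p=pd.DataFrame(0.0, index=log_signal.index, columns=log_signal.columns),
        samples=samples,
    )


class TestDetectionFilter:
    def _mixed(self):
        genes = [f"g{i}" for i in range(10)]
        cols = [f"s{i}" for i in range(4)]
        det = pd.DataFrame(0.0, index=genes, columns=cols)
        det.iloc[6:] = 1.0  # 4 genes undetected everywhere
        expr = pd.DataFrame(1.0 + np.arange(40).reshape(10, 4), index=genes, columns=cols)
        samples = pd.DataFrame({"age_group": ["young", "young", "old", "old"]}, index=cols)
        return ExpressionStudy(log_signal=expr, detection_p=det, samples=samples)

    def test_detected_gene_retained_undetected_removed(self):
        out = detection_filter(self._mixed())
        assert len(out.log_signal) == 6
        assert "g0" in out.log_signal.index and "g9" not in out.log_signal.index

    def test_all_filtered_raises(self):
        study = self._mixed()
        study.detection_p.iloc[:] = 1.0
        with pytest.raises(ValueError, match="relax"):
            detection_filter(study)


class TestZTransform:
    def test_hand_example(self):
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0]})
        assert np.allclose(z_transform(df)["s"], [-1.0, 0.0, 1.0])  # sample sd of (1,2,3) is 1

    def test_column_moments(self, rng):
        df = pd.DataFrame(rng.normal(5, 2, size=(50, 4)))
        z = z_transform(df)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_location_and_scale_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)))
        z = z_transform(df)
        assert np.allclose(z_transform(df + 7.0), z)
        assert np.allclose(z_transform(df * 10.0), z)

    def test_zero_spread_raises(self):
        with pytest.raises(ValueError, match="spread"):
            z_transform(pd.DataFrame({"s": [2.0, 2.0, 2.0]}))


class TestZRatio:
    def test_identical_group_profiles_give_zero(self, rng):
        base = rng.normal(size=(20, 2))
        df = pd.DataFrame(np.hstack([base, base]), columns=["y1", "y2", "o1", "o2"])
        study_groups = pd.DataFrame({"age_group": ["young", "young", "old", "old"]}, index=df.columns)
        out = z_ratio(z_transform(df), study_groups)
        assert np.allclose(out["z_ratio"], 0.0)

    def test_self_normalized_spread_is_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 6)), columns=[f"s{i}" for i in range(6)])
        groups = pd.DataFrame({"age_group": ["young"] * 3 + ["old"] * 3}, index=df.columns)
        out = z_ratio(z_transform(df), groups)
        assert out["z_ratio"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_planted_shift_ranks_top(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 8)), columns=[f"s{i}" for i in range(8)])
        groups = pd.DataFrame({"age_group": ["young"] * 4 + ["old"] * 4}, index=df.columns)
        df.iloc[:5, 4:] += 3.0  # shift first 5 genes in old samples
        out = z_ratio(z_transform(df), groups)
        top5 = out["z_ratio"].abs().nlargest(5).index
        assert set(top5) == set(df.index[:5])


class TestPage:
    def test_whole_universe_set_scores_zero(self, rng):
        scores = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        out = page(scores, {"all": list(scores.index)})
        assert out.loc["all", "z"] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_set_reduction(self, rng):
        scores = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        out = page(scores, {"one": ["g7"]})
        expected = (scores["g7"] - scores.mean()) / scores.std(ddof=1)
        assert out.loc["one", "z"] == pytest.approx(expected, rel=1e-12)
        assert bool(out.loc["one", "small_set"])

    def test_shifted_set_closed_form(self):
        """20 of 200 genes shifted by +1 null-sd: z matches the exact closed
        form on the fixture and sits near sqrt(20)."""
        n, m = 200, 20
        null = np.linspace(-1, 1, n - m)
        null = (null - null.mean()) / null.std(ddof=0)  # mean 0, population sd 1
        scores = pd.Series(
            np.concatenate([null, np.ones(m)]), index=[f"g{i}" for i in range(n)]
        )
        members = [f"g{i}" for i in range(n - m, n)]
        out = page(scores, {"shifted": members})
        mu, delta = scores.mean(), scores.std(ddof=1)
        exact = (1.0 - mu) * np.sqrt(m) / delta
        assert out.loc["shifted", "z"] == pytest.approx(exact, rel=1e-12)
        assert abs(out.loc["shifted", "z"] - np.sqrt(m)) / np.sqrt(m) < 0.15

    def test_unmappable_set_dropped(self, rng):
        scores = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        out = page(scores, {"ghost": ["nope"], "ok": ["g1", "g2"]})
        assert list(out.index) == ["ok"]

    def test_per_donor_scores_match_page_columnwise(self, rng):
        z = pd.DataFrame(rng.normal(size=(60, 3)), index=[f"g{i}" for i in range(60)], columns=list("abc"))
        sets = {"s1": [f"g{i}" for i in range(15)], "s2": [f"g{i}" for i in range(30, 55)]}
        mat = per_donor_pathway_scores(z, sets)
        for donor in "abc":
            ref = page(z[donor], sets)["z"]
            assert np.allclose(mat[donor], ref.loc[mat.index])


class TestPathwayContrast:
    def test_identical_groups_zero_difference_empty_selection(self, rng):
        block = rng.normal(size=(10, 3))
        pz = pd.DataFrame(
            np.hstack([block, block]),
            index=[f"set{i}" for i in range(10)],
            columns=["y1", "y2", "y3", "o1", "o2", "o3"],
        )
        samples = pd.DataFrame({"age_group": ["young"] * 3 + ["old"] * 3}, index=pz.columns)
        out = pathway_contrast(pz, samples)
        assert np.allclose(out["z_difference"], 0.0)
        assert not out["selected"].any()

    def test_planted_down_in_old_detected_with_sign(self):
        cfg = ExpressionConfig(n_genes=600, n_random_sets=10, n_shifted_sets=2)
        study, gene_sets, truth = simulate_expression(cfg, seed=7)
        filtered = detection_filter(study)
        z = z_transform(filtered.log_signal)
        pz = per_donor_pathway_scores(z, gene_sets)
        out = pathway_contrast(pz, filtered.samples)
        for name in truth["shifted_sets"]:
            assert out.loc[name, "mean_z_old"] < out.loc[name, "mean_z_young"]
            assert out.loc[name, "selected"]
            assert out.loc[name, "rank"] <= len(truth["shifted_sets"])

    def test_top_k_larger_than_passing_returns_all_passing(self, rng):
        pz = pd.DataFrame(
            np.vstack([np.repeat([[0.0, 0.0, 0.0, 5.0, 5.0, 5.0]], 4, axis=0) + rng.normal(0, 0.1, (4, 6))]),
            index=[f"set{i}" for i in range(4)],
            columns=["y1", "y2", "y3", "o1", "o2", "o3"],
        )
        samples = pd.DataFrame({"age_group": ["young"] * 3 + ["old"] * 3}, index=pz.columns)
        out = pathway_contrast(pz, samples, ContrastConfig(top_k=100))
        assert out["selected"].sum() == (out["p_value"] <= 0.05).sum()


def test_affine_rescaling_of_samples_leaves_z_ratio_unchanged(rng):
    """Per-sample affine changes of raw log-signals cancel in Z-transform + Z-ratio."""
    df = pd.DataFrame(rng.normal(8, 1.5, size=(40, 6)), columns=[f"s{i}" for i in range(6)])
    groups = pd.DataFrame({"age_group": ["young"] * 3 + ["old"] * 3}, index=df.columns)
    scale = rng.uniform(0.5, 2.0, 6)
    shift = rng.uniform(-3, 3, 6)
    rescaled = df * scale + shift
    a = z_ratio(z_transform(df), groups)
    b = z_ratio(z_transform(rescaled), groups)
    assert np.allclose(a["z_ratio"], b["z_ratio"])
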