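"""Reference-channel normalization, old/young ratio statistics and the
three-stage filter cascade."""

import numpy as np
import pandas as pd
import pytest

from immunoflux.proteomics import (
    CascadeConfig,
    ChannelSample,
    ProteinQuantTable,
    collapse_technical_duplicates,
    filter_cascade,
    group_ratio_test,
    normalize_to_reference,
)
from immunoflux.reference import consistent_rows, upregulated_protein_table
from immunoflux.simulate import ProteomicsConfig, simulate_proteomics
from immunoflux.stats import student_ttest
from helpers import norm_from_donor_values, toy_cascade_records


class TestNormalization:
    def test_channel_over_reference(self, two_plexes):
        norm = normalize_to_reference(two_plexes)
        assert norm.values.loc["P1", "A:c2"] == pytest.approx(2.0)  # 200 / 100

    def test_reference_column_is_one(self, two_plexes):
        norm = normalize_to_reference(two_plexes)
        for col in ("A:c1", "B:c1"):
            assert np.allclose(norm.values[col], 1.0)

    def test_plex_scaling_cancels(self, two_plexes):
        """Plex B is an exact 3x copy of A: the shared sample normalizes identically."""
        norm = normalize_to_reference(two_plexes)
        assert np.allclose(norm.values["A:c4"], norm.values["B:c4"])

    def test_all_channels_equal_reference_gives_ones(self):
        ints = pd.DataFrame({"c1": [5.0, 7.0], "c2": [5.0, 7.0]}, index=["P1", "P2"])
        table = ProteinQuantTable(
            plex_id="X",
            intensities=ints,
            sample_map={
                "c1": ChannelSample("ref", "young", "reference"),
                "c2": ChannelSample("d", "old", "biological"),
            },
        )
        norm = normalize_to_reference([table])
        assert np.allclose(norm.values.to_numpy(), 1.0)

    def test_idempotent_on_normalized_matrix(self, two_plexes):
        norm = normalize_to_reference(two_plexes)
        renorm_tables = []
        for t in two_plexes:
            cols = [f"{t.plex_id}:{c}" for c in t.intensities.columns]
            block = norm.values[cols].copy()
            block.columns = list(t.intensities.columns)
            renorm_tables.append(
                ProteinQuantTable(plex_id=t.plex_id, intensities=block, sample_map=t.sample_map)
            )
        renorm = normalize_to_reference(renorm_tables)
        pd.testing.assert_frame_equal(renorm.values, norm.values)

    def test_zero_reference_protein_dropped_with_reason(self, two_plexes):
        two_plexes[0].intensities.loc["P2", "c1"] = 0.0
        norm = normalize_to_reference(two_plexes)
        assert "P2" not in norm.values.index
        assert norm.dropped["P2"] == "zero reference intensity"

    def test_protein_missing_from_one_plex_dropped(self, two_plexes):
        two_plexes[1].intensities = two_plexes[1].intensities.drop(index="P3")
        norm = normalize_to_reference(two_plexes)
        assert "P3" not in norm.values.index
        assert "absent" in norm.dropped["P3"]

    def test_missing_reference_channel_rejected(self):
        ints = pd.DataFrame({"c1": [1.0, 2.0]}, index=["P1", "P2"])
        with pytest.raises(ValueError, match="reference"):
            ProteinQuantTable(
                plex_id="X",
                intensities=ints,
                sample_map={"c1": ChannelSample("d", "old", "biological")},
            )


class TestGroupRatio:
    @staticmethod
    def _norm_from_values(values: dict[str, tuple[list[float], list[float]]]):
        return norm_from_donor_values(values)

    def test_identical_group_values_give_unit_ratio_and_p(self):
        norm = self._norm_from_values({"P1": ([1.0, 2.0], [1.0, 2.0])})
        rec = group_ratio_test(norm)
        assert rec.loc["P1", "ratio"] == pytest.approx(1.0)
        assert rec.loc["P1", "p_value"] == pytest.approx(1.0)

    def test_p_matches_student_oracle_4v4(self, rng):
        y = list(rng.lognormal(0, 0.2, 4))
        o = list(rng.lognormal(0.3, 0.2, 4))
        rec = group_ratio_test(self._norm_from_values({"P1": (y, o)}))
        oracle = student_ttest(o, y)
        assert rec.loc["P1", "p_value"] == pytest.approx(oracle.p_value, rel=1e-10)
        assert rec.loc["P1", "ratio"] == pytest.approx(np.mean(o) / np.mean(y), rel=1e-12)

    def test_published_averages_reproduce_published_ratios(self):
        """Donor values engineered to the published group averages must yield
        the published old/young ratio at 4 decimals for every arithmetically
        consistent published row."""
        table = consistent_rows()
        assert {"COX7C", "MPCP", "COX7B", "NB5R3", "COX41"} <= set(table.index)
        values = {
            p: (
                [row["avg_young"] - 0.01, row["avg_young"] + 0.01],
                [row["avg_old"] - 0.01, row["avg_old"] + 0.01],
            )
            for p, row in table.iterrows()
        }
        rec = group_ratio_test(self._norm_from_values(values))
        assert np.allclose(rec["ratio"].round(4), table.loc[rec.index, "ratio"])

    def test_swapping_age_labels_inverts_ratio_preserves_p(self, rng):
        y = list(rng.lognormal(0, 0.2, 3))
        o = list(rng.lognormal(0.4, 0.2, 5))
        fwd = group_ratio_test(self._norm_from_values({"P1": (y, o)}))
        rev = group_ratio_test(self._norm_from_values({"P1": (o, y)}))
        assert fwd.loc["P1", "ratio"] == pytest.approx(1.0 / rev.loc["P1", "ratio"], rel=1e-12)
        assert fwd.loc["P1", "p_value"] == pytest.approx(rev.loc["P1", "p_value"], rel=1e-10)

    def test_technical_duplicates_collapse_to_donor_mean(self, two_plexes):
        norm = normalize_to_reference(two_plexes)
        collapsed, ages = collapse_technical_duplicates(norm)
        manual = (norm.values["A:c4"] + norm.values["B:c4"]) / 2
        assert np.allclose(collapsed["dX"], manual)
        assert ages["dX"] == "old"


class TestFilterCascade:
    @staticmethod
    def _toy():
        return toy_cascade_records()

    def test_toy_counts_and_selection(self):
        records, evidence = self._toy()
        report = filter_cascade(records, evidence)
        assert report.counts == (6, 4, 3, 2)
        assert sorted(report.selected) == ["R3", "R5"]
        assert report.selected_up == ["R3", "R5"]
        assert report.selected_down == []

    def test_subthreshold_ratio_rejected_at_stage_one(self):
        records, evidence = self._toy()
        report = filter_cascade(records, evidence)
        assert "ratio" in report.rejections["R0"]

    def test_published_retained_example(self):
        """A protein with ratio 1.5956, p 0.0004 and solid evidence survives."""
        row = upregulated_protein_table().loc["GPDM"]
        records = pd.DataFrame(
            {"ratio": [row["ratio"]], "p_value": [row["p_value"]]},
            index=pd.Index(["GPDM"], name="protein"),
        )
        evidence = pd.DataFrame(
            {"protein_id": ["GPDM"], "unique_peptides": [3], "confidence": ["high"], "max_ion_score": [55.0]}
        )
        assert filter_cascade(records, evidence).selected == ["GPDM"]

    def test_missing_evidence_fails_final_stage(self):
        records, evidence = self._toy()
        report = filter_cascade(records, evidence.iloc[:3])
        assert report.n_pass_evidence < report.n_pass_pvalue
        assert report.rejections["R5"] == "no evidence record"

    def test_empty_input(self):
        records = pd.DataFrame(columns=["ratio", "p_value"], index=pd.Index([], name="protein"))
        evidence = pd.DataFrame(columns=["protein_id", "unique_peptides", "confidence", "max_ion_score"])
        report = filter_cascade(records, evidence)
        assert report.counts == (0, 0, 0, 0)
        assert report.selected == []

    def test_custom_thresholds(self):
        records, evidence = self._toy()
        report = filter_cascade(records, evidence, CascadeConfig(up=1.9, down=0.3, alpha=0.01))
        assert report.n_pass_ratio == 1  # only R5 at ratio 2.0
        assert report.selected == ["R5"]


class TestSyntheticRecovery:
    def test_planted_up_proteins_survive_cascade(self):
        """Most planted 1.5-fold mitochondrial proteins survive; nulls rarely do."""
        cfg = ProteomicsConfig(n_proteins=300, n_mito_up=30)
        surv_frac, null_surv = [], []
        for seed in range(3):
            tables, evidence, truth = simulate_proteomics(cfg, seed=seed)
            norm = normalize_to_reference(tables)
            records = group_ratio_test(norm)
            report = filter_cascade(records, evidence)
            planted = set(truth["planted_up"])
            surv_frac.append(len(planted & set(report.selected)) / len(planted))
            null_surv.append(len(set(report.selected) - planted))
        assert np.mean(surv_frac) >= 0.8
        assert np.mean(null_surv) <= 2.0
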