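"""Oxygen-flux derivation, coupling-state extraction, the BHI and the
memory-adjusted cohort comparison."""

import numpy as np
import pandas as pd
import pytest

from immunoflux.respirometry import (
    BioenergeticProfile,
    OxygraphTrace,
    StateFluxes,
    adjust_bhi_for_memory,
    compare_respiration,
    compute_flux_trace,
    derive_profile,
    extract_state_fluxes,
    flag_memory_outliers,
)
from immunoflux.simulate import RespirometryConfig, simulate_oxygraph


def _events():
    return [
        (600.0, "oligomycin"),
        (1200.0, "fccp_step"),
        (1500.0, "fccp_step"),
        (1800.0, "fccp_step"),
        (2100.0, "rotenone"),
        (2160.0, "antimycin_a"),
    ]


def _linear_trace(slope: float, cell_count: float = 5e6) -> OxygraphTrace:
    t = np.arange(0.0, 2701.0)
    return OxygraphTrace(
        time_s=t,
        o2_nmol_per_ml=200.0 - slope * t,
        events=_events(),
        chamber_volume_ml=2.0,
        cell_count=cell_count,
    )


class TestFluxTrace:
    def test_unit_arithmetic(self):
        # 0.05 nmol/mL/s decline, 2 mL, 5e6 cells -> 0.05*2*1000/5 = 20
        _, flux = compute_flux_trace(_linear_trace(0.05))
        assert np.allclose(flux, 20.0, atol=1e-9)

    def test_flat_trace_gives_zero_flux(self):
        _, flux = compute_flux_trace(_linear_trace(0.0))
        assert np.allclose(flux, 0.0, atol=1e-12)

    def test_doubling_cells_halves_flux(self):
        _, f1 = compute_flux_trace(_linear_trace(0.05, cell_count=5e6))
        _, f2 = compute_flux_trace(_linear_trace(0.05, cell_count=1e7))
        assert np.allclose(f2, f1 / 2)

    def test_window_larger_than_record_raises(self):
        tr = _linear_trace(0.05)
        with pytest.raises(ValueError, match="window"):
            compute_flux_trace(tr, window_s=5000.0)


class TestStateExtraction:
    def test_noiseless_recovery_is_exact(self):
        cfg = RespirometryConfig(noise_frac=0.0, between_donor_cv=0.0, n_young=1, n_old=0)
        traces, _, truth = simulate_oxygraph(cfg, seed=0)
        donor = next(iter(traces))
        states = extract_state_fluxes(traces[donor])
        for k in ("routine", "leak", "ets", "rox"):
            assert getattr(states, k) == pytest.approx(truth[donor]["fluxes"][k], abs=1e-6)

    def test_noisy_recovery_within_five_percent(self):
        cfg = RespirometryConfig(n_young=2, n_old=2)
        traces, _, truth = simulate_oxygraph(cfg, seed=11)
        for donor, trace in traces.items():
            states = extract_state_fluxes(trace)
            for k in ("routine", "leak", "ets", "rox"):
                true = truth[donor]["fluxes"][k]
                assert abs(getattr(states, k) - true) / true < 0.05

    def test_ets_is_maximum_over_titration_steps(self):
        cfg = RespirometryConfig(
            noise_frac=0.0, between_donor_cv=0.0, n_young=1, n_old=0,
            fccp_plateau_fractions=(90 / 130, 1.0, 110 / 130),
        )
        traces, _, truth = simulate_oxygraph(cfg, seed=0)
        donor = next(iter(traces))
        states = extract_state_fluxes(traces[donor])
        assert states.ets == pytest.approx(truth[donor]["fluxes"]["ets"], abs=1e-6)

    def test_event_order_violation_rejected(self):
        t = np.arange(0.0, 2701.0)
        bad = [(600.0, "rotenone"), (1200.0, "fccp_step"), (1800.0, "oligomycin"), (2160.0, "antimycin_a")]
        with pytest.raises(ValueError, match="order"):
            OxygraphTrace(time_s=t, o2_nmol_per_ml=200 - 0.01 * t, events=sorted(bad))

    def test_state_window_too_short_names_state(self):
        t = np.arange(0.0, 2701.0)
        events = [(100.0, "oligomycin"), (1200.0, "fccp_step"), (2100.0, "rotenone"), (2160.0, "antimycin_a")]
        trace = OxygraphTrace(time_s=t, o2_nmol_per_ml=200 - 0.01 * t, events=events)
        with pytest.raises(ValueError, match="routine"):
            extract_state_fluxes(trace)  # only 40 s of usable ROUTINE window


class TestProfile:
    def test_arithmetic_example(self):
        prof = derive_profile(StateFluxes(routine=4, leak=2, ets=6, rox=1))
        assert prof.atp_linked == 2 and prof.proton_leak == 1
        assert prof.reserve_capacity == 2 and prof.non_mitochondrial == 1
        assert prof.bhi == pytest.approx(np.log10(4.0), rel=1e-12)

    def test_balanced_components_give_zero(self):
        # reserve*atp = 2*2 = 4 = non_mito*proton_leak = 2*2
        prof = derive_profile(StateFluxes(routine=6, leak=4, ets=8, rox=2))
        assert prof.bhi == pytest.approx(0.0, abs=1e-12)

    def test_zero_rox_flags_undefined(self):
        prof = derive_profile(StateFluxes(routine=4, leak=2, ets=6, rox=0))
        assert not prof.bhi_defined
        assert any("non_mitochondrial" in f for f in prof.flags)

    def test_bhi_invariant_under_component_scaling(self):
        a = derive_profile(StateFluxes(routine=4, leak=2, ets=6, rox=1))
        b = derive_profile(StateFluxes(routine=40, leak=20, ets=60, rox=10))
        assert a.bhi == pytest.approx(b.bhi, rel=1e-12)

    def test_concentration_scaling_scales_fluxes_not_bhi(self):
        cfg = RespirometryConfig(noise_frac=0.0, between_donor_cv=0.0, n_young=1, n_old=0)
        traces, _, _ = simulate_oxygraph(cfg, seed=0)
        tr = next(iter(traces.values()))
        scaled = OxygraphTrace(
            time_s=tr.time_s, o2_nmol_per_ml=tr.o2_nmol_per_ml * 3.0, events=tr.events,
            chamber_volume_ml=tr.chamber_volume_ml, cell_count=tr.cell_count,
        )
        s1, s2 = extract_state_fluxes(tr), extract_state_fluxes(scaled)
        for k in ("routine", "leak", "ets", "rox"):
            assert getattr(s2, k) == pytest.approx(3.0 * getattr(s1, k), rel=1e-6)
        assert derive_profile(s2).bhi == pytest.approx(derive_profile(s1).bhi, rel=1e-6)


def _cohort(rng, b0=1.5, b1=-0.3, b2=0.0, noise=0.02, n=8):
    mem_y = rng.uniform(25, 45, n)
    mem_o = rng.uniform(28, 48, n)
    rows = []
    for i in range(n):
        rows.append({"donor": f"y{i}", "age_group": "young", "memory_pct": mem_y[i],
                     "bhi": b0 + b2 * mem_y[i] + rng.normal(0, noise)})
        rows.append({"donor": f"o{i}", "age_group": "old", "memory_pct": mem_o[i],
                     "bhi": b0 + b1 + b2 * mem_o[i] + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestAdjustment:
    def test_null_covariate_leaves_means_unchanged(self, rng):
        cohort = _cohort(rng, b2=0.0, noise=0.0)
        out = adjust_bhi_for_memory(cohort)
        fit = out["all_samples"]
        raw_y = cohort.loc[cohort["age_group"] == "young", "bhi"].mean()
        raw_o = cohort.loc[cohort["age_group"] == "old", "bhi"].mean()
        assert fit["mean_young"] == pytest.approx(raw_y, abs=1e-8)
        assert fit["mean_old"] == pytest.approx(raw_o, abs=1e-8)

    def test_known_coefficients_recovered_within_3_se(self, rng):
        cohort = _cohort(rng, b0=1.2, b1=-0.25, b2=-0.01, noise=0.05, n=12)
        fit = adjust_bhi_for_memory(cohort)["all_samples"]
        for name, true in [("intercept", 1.2), ("group_old", -0.25), ("memory_pct", -0.01)]:
            assert abs(fit["coef"][name] - true) <= 3 * fit["coef_se"][name]

    def test_extreme_memory_fraction_flagged(self):
        """One donor at 59% memory among others spanning 26-48% is the outlier."""
        others = np.linspace(26, 48, 13)
        cohort = pd.DataFrame(
            {
                "donor": [f"d{i}" for i in range(14)],
                "age_group": ["young"] * 7 + ["old"] * 7,
                "memory_pct": list(others) + [59.0],
                "bhi": 1.5,
            }
        )
        flags = flag_memory_outliers(cohort)
        assert list(cohort.loc[flags, "donor"]) == ["d13"]

    def test_constant_memory_falls_back_to_welch(self, rng):
        cohort = _cohort(rng, noise=0.05)
        cohort["memory_pct"] = 35.0
        out = adjust_bhi_for_memory(cohort)
        assert not out["all_samples"]["adjusted"]
        assert "Welch" in out["all_samples"]["warning"]

    def test_reported_with_and_without_outliers(self, rng):
        cohort = _cohort(rng, noise=0.05, n=7)
        cohort.loc[cohort.index[-1], "memory_pct"] = 90.0
        out = adjust_bhi_for_memory(cohort)
        assert out["outliers"]
        assert out["without_outliers"] is not None


class TestCohortComparison:
    def test_identical_groups_give_unit_p(self):
        vals = [1.0, 1.2, 1.4]
        cohort = pd.DataFrame(
            {
                "donor": list("abcdef"),
                "age_group": ["young"] * 3 + ["old"] * 3,
                "bhi": vals * 2,
                "non_mitochondrial": vals * 2,
                "reserve_capacity": vals * 2,
            }
        )
        res = compare_respiration(cohort)
        for m in res:
            assert res[m].p_value == pytest.approx(1.0)

    def test_single_group_raises(self):
        cohort = pd.DataFrame({"donor": list("ab"), "age_group": ["young", "young"], "bhi": [1, 2],
                               "non_mitochondrial": [1, 2], "reserve_capacity": [1, 2]})
        with pytest.raises(ValueError):
            compare_respiration(cohort)

    def test_planted_reserve_difference_detected(self):
        cfg = RespirometryConfig()
        traces, cohort, truth = simulate_oxygraph(cfg, seed=3)
        rows = []
        for donor, tr in traces.items():
            prof = derive_profile(extract_state_fluxes(tr))
            rows.append({"donor": donor, "age_group": truth[donor]["age_group"],
                         "bhi": prof.bhi, "non_mitochondrial": prof.non_mitochondrial,
                         "reserve_capacity": prof.reserve_capacity})
        res = compare_respiration(pd.DataFrame(rows))
        assert res["reserve_capacity"].p_value < 0.05
        assert res["reserve_capacity"].mean_a > res["reserve_capacity"].mean_b  # young higher
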