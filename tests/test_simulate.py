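"""Synthetic-trial generator: randomization, PK model, censoring, scenarios."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from sadmad.design import CohortSpec, InvalidDesignError, PKModelParams, SubjectRecord
from sadmad.immunogenicity import timelines_from_frame, classify_timeline
from sadmad.simulate import (
    ADA_SCENARIOS,
    LLOQ_NG_ML,
    apply_blq_censoring,
    generate_randomization,
    predicted_concentration,
    read_trial_dataset,
    sc_peak_time,
    simulate_ada_titers,
    simulate_biomarker,
    simulate_concentration_profile,
    simulate_safety_streams,
    simulate_trial,
    write_trial_dataset,
)


def _cohort(**kw):
    base = dict(label="X", dose_mg=100.0, route="SC", n_active=6, n_placebo=2)
    base.update(kw)
    return CohortSpec(**base)


class TestRandomization:
    @pytest.mark.parametrize("n_active,n_placebo", [(6, 2), (12, 4)])
    def test_counts_match_allocation_ratio(self, n_active, n_placebo):
        spec = _cohort(n_active=n_active, n_placebo=n_placebo)
        arms = generate_randomization(spec, seed=123)
        assert len(arms) == n_active + n_placebo
        assert arms.count("active") == n_active
        assert arms.count("placebo") == n_placebo

    def test_deterministic_given_seed(self):
        spec = _cohort()
        assert generate_randomization(spec, seed=5) == generate_randomization(spec, seed=5)

    def test_blocks_respect_ratio(self):
        spec = _cohort(n_active=12, n_placebo=4)
        arms = generate_randomization(spec, seed=9, block_size=4)
        for i in range(0, 16, 4):
            block = arms[i : i + 4]
            assert block.count("active") == 3 and block.count("placebo") == 1

    def test_incompatible_block_size_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_randomization(_cohort(), seed=1, block_size=3)

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(InvalidDesignError):
            _cohort(n_active=1, n_placebo=0)


class TestConcentrationModel:
    def test_iv_bolus_initial_concentration(self):
        # D/V = 100 ng/mL at t = 0
        p = PKModelParams(CL=0.7, V=7.0).noiseless()  # k = 0.1/day
        c = predicted_concentration([0.0], [(0.0, 0.7)], "IV", p)  # 0.7 mg / 7 L = 100 ng/mL
        assert c[0] == pytest.approx(100.0)

    def test_sc_peak_matches_grid_maximization(self, noiseless_params):
        p = noiseless_params
        grid = np.arange(0.0, 40.0, 1e-3)
        c = predicted_concentration(grid, [(0.0, 100.0)], "SC", p)
        t_grid = grid[np.argmax(c)]
        assert t_grid == pytest.approx(sc_peak_time(p.ka, p.k_elim), abs=1e-3)

    def test_trough_after_one_half_life_is_half(self):
        p = PKModelParams(CL=0.7, V=7.0).noiseless()
        tau = math.log(2) / p.k_elim
        c0 = predicted_concentration([0.0], [(0.0, 1.0)], "IV", p)[0]
        trough = predicted_concentration([tau - 1e-12], [(0.0, 1.0)], "IV", p)[0]
        assert trough == pytest.approx(c0 / 2, rel=1e-9)

    def test_absorption_rate_equal_elimination_limit(self):
        p = PKModelParams(CL=0.7, V=7.0, ka=0.1).noiseless()  # ka = k exactly
        near = PKModelParams(CL=0.7, V=7.0, ka=0.1000001).noiseless()
        t = np.linspace(0.1, 50, 20)
        c_lim = predicted_concentration(t, [(0.0, 10.0)], "SC", p)
        c_near = predicted_concentration(t, [(0.0, 10.0)], "SC", near)
        assert np.allclose(c_lim, c_near, rtol=1e-4)
        assert np.isfinite(c_lim).all()

    def test_negative_time_rejected(self, noiseless_params):
        with pytest.raises(ValueError):
            predicted_concentration([-1.0], [(0.0, 10.0)], "SC", noiseless_params)

    def test_single_sc_dose_total_auc_is_fd_over_cl(self, noiseless_params):
        p = noiseless_params
        f = lambda t: predicted_concentration([t], [(0.0, 90.0)], "SC", p)[0]
        auc, _ = quad(f, 0, 600, limit=200)
        assert auc == pytest.approx(p.F_abs * 90e6 / (p.CL * 1000), rel=1e-6)

    def test_infusion_continuous_at_end_and_decays(self):
        p = PKModelParams(CL=0.2, V=7.0).noiseless()
        dur_h = 1.0
        dur = dur_h / 24.0
        t = np.array([dur - 1e-9, dur, dur + 1e-9])
        c = predicted_concentration(t, [(0.0, 300.0)], "IV", p, infusion_duration_h=dur_h)
        assert c[0] == pytest.approx(c[2], rel=1e-6)
        assert np.argmax(c) <= 1

    def test_placebo_profile_all_zero(self, design, noiseless_params):
        subj = SubjectRecord("A01", "A", "placebo", 70.0)
        prof = simulate_concentration_profile(subj, design[0], noiseless_params, seed=3)
        assert (prof["conc_ng_ml"] == 0).all()

    def test_noiseless_profile_matches_closed_form(self, design, noiseless_params):
        spec = design[5]  # multiple-dose cohort
        subj = SubjectRecord("F01", "F", "active", 70.0)
        prof = simulate_concentration_profile(subj, spec, noiseless_params, seed=3)
        t = prof["day_decimal"].to_numpy() - 1.0
        expected = predicted_concentration(
            t, [(d - 1.0, spec.dose_mg) for d in spec.dosing_days], "SC", noiseless_params
        )
        assert np.allclose(prof["conc_ng_ml"], expected, rtol=1e-9)


class TestBLQCensoring:
    def test_boundary_at_lloq(self):
        df = pd.DataFrame(
            {"subject_id": "s", "day_decimal": [1.0, 2.0, 3.0], "conc_ng_ml": [139.9, 140.0, 1000.0], "blq_flag": False}
        )
        out = apply_blq_censoring(df)
        assert out["conc_ng_ml"].tolist() == [0.0, 140.0, 1000.0]
        assert out["blq_flag"].tolist() == [True, False, False]

    def test_all_zero_series_flagged_unchanged(self):
        df = pd.DataFrame({"subject_id": "s", "day_decimal": [1.0, 2.0], "conc_ng_ml": [0.0, 0.0], "blq_flag": False})
        out = apply_blq_censoring(df)
        assert (out["conc_ng_ml"] == 0).all() and out["blq_flag"].all()

    def test_idempotent(self):
        df = pd.DataFrame(
            {"subject_id": "s", "day_decimal": [1.0, 2.0], "conc_ng_ml": [10.0, 500.0], "blq_flag": False}
        )
        once = apply_blq_censoring(df)
        twice = apply_blq_censoring(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_never_increases_and_conserves_records(self, trial_dataset):
        raw = trial_dataset.pk_conc
        out = apply_blq_censoring(raw)
        assert len(out) == len(raw)
        assert (out["conc_ng_ml"] <= raw["conc_ng_ml"] + 1e-12).all()


EXPECTED_LABEL = {
    "never": ("none", "none", False),
    "induced_transient": ("treatment_induced", "transient", True),
    "induced_persistent": ("treatment_induced", "persistent", True),
    "enhanced": ("treatment_enhanced", "persistent", True),
    "baseline_positive_stable": ("none", "none", False),
}


class TestADAScenarios:
    @pytest.mark.parametrize("scenario", ADA_SCENARIOS)
    @pytest.mark.parametrize("cohort_idx", [0, 5])  # single- and multiple-dose calendars
    def test_scenario_forces_classifier_label(self, design, scenario, cohort_idx):
        spec = design[cohort_idx]
        for seed in range(5):
            subj = SubjectRecord(f"{spec.label}01", spec.label, "active", 70.0)
            ada = simulate_ada_titers(subj, spec, scenario, seed=seed)
            subjects = pd.DataFrame([{"subject_id": subj.subject_id, "cohort": spec.label, "arm": "active"}])
            tl = timelines_from_frame(ada, subjects)[0]
            cls = classify_timeline(tl)
            mech, dur, pos = EXPECTED_LABEL[scenario]
            assert (cls.mechanism, cls.duration, cls.ada_positive) == (mech, dur, pos)

    def test_never_scenario_all_negative(self, design):
        subj = SubjectRecord("A01", "A", "active", 70.0)
        ada = simulate_ada_titers(subj, design[0], "never", seed=0)
        assert (ada["status"] == "negative").all()

    def test_enhanced_rise_meets_threshold(self, design):
        subj = SubjectRecord("A01", "A", "active", 70.0)
        ada = simulate_ada_titers(subj, design[0], "enhanced", seed=0)
        base = ada.iloc[0]["titer"]
        assert ada["titer"].iloc[1:].max() >= base + 0.60

    def test_unknown_scenario_rejected(self, design):
        subj = SubjectRecord("A01", "A", "active", 70.0)
        with pytest.raises(ValueError):
            simulate_ada_titers(subj, design[0], "sometimes", seed=0)


class TestBiomarkerSimulation:
    def test_zero_drug_stays_at_baseline_scale(self, design, noiseless_params):
        subj = SubjectRecord("A02", "A", "placebo", 70.0)
        conc = simulate_concentration_profile(subj, design[0], noiseless_params, seed=4)
        rec = simulate_biomarker(subj, conc, "IL17AA", seed=4)
        # noise-free expectation: all values equal the baseline draw
        assert rec["value_pg_ml"].max() < 3 * rec["value_pg_ml"].min() + 20

    def test_peak_nondecreasing_in_dose_noiseless(self, design, noiseless_params):
        from sadmad.simulate import BiomarkerParams

        peaks = []
        p = BiomarkerParams(emax_pg_ml=40.0, sigma_ln=0.0, frac_below_mqc=1.0)
        for dose in (30.0, 90.0, 300.0):
            spec = CohortSpec("A", dose, "SC", 6, 2)
            subj = SubjectRecord("A01", "A", "active", 70.0)
            conc = simulate_concentration_profile(subj, spec, noiseless_params, seed=11)
            rec = simulate_biomarker(subj, conc, "IL17AA", seed=11, params=p)
            peaks.append(rec["value_pg_ml"].max())
        assert peaks == sorted(peaks)


class TestSafetyStreams:
    def test_eosinophilia_edge_case_exceeds_threshold(self):
        subj = SubjectRecord("A01", "A", "active", 70.0)
        _, labs = simulate_safety_streams(subj, seed=0, edge_cases=("eosinophilia",))
        assert (labs[labs["test"] == "AEC"]["value"] > 1500).any()

    def test_neutropenia_edge_case(self):
        subj = SubjectRecord("A01", "A", "active", 70.0)
        _, labs = simulate_safety_streams(subj, seed=0, edge_cases=("neutropenia",))
        assert (labs[labs["test"] == "ANC"]["value"] < 1000).any()

    def test_zero_rate_empty_ae_stream(self):
        subj = SubjectRecord("A01", "A", "active", 70.0)
        ae, _ = simulate_safety_streams(subj, seed=0, ae_rate=0.0)
        assert ae.empty


class TestDatasetRoundTrip:
    def test_write_read_round_trip(self, trial_dataset, tmp_path):
        write_trial_dataset(trial_dataset, tmp_path)
        back = read_trial_dataset(tmp_path)
        for name in trial_dataset.TABLES:
            a, b = getattr(trial_dataset, name), getattr(back, name)
            pd.testing.assert_frame_equal(
                a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False, atol=1e-9
            )

    def test_same_seed_byte_identical(self, design, tmp_path):
        d1 = simulate_trial(design[:2], seed=42)
        d2 = simulate_trial(design[:2], seed=42)
        m1 = write_trial_dataset(d1, tmp_path / "a")
        m2 = write_trial_dataset(d2, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_adding_cohort_does_not_perturb_existing_subjects(self, design):
        small = simulate_trial(design[:1], seed=7)
        bigger = simulate_trial(design[:2], seed=7)
        a_small = small.pk_conc
        a_big = bigger.pk_conc[bigger.pk_conc["subject_id"].str.startswith("A")]
        pd.testing.assert_frame_equal(a_small.reset_index(drop=True), a_big.reset_index(drop=True))

    def test_empty_design_manifest_only(self, tmp_path):
        from sadmad.simulate import TrialDataset

        empty = TrialDataset(
            design=[], subjects=pd.DataFrame(columns=["subject_id"]), dosing=pd.DataFrame(columns=["subject_id"]),
            pk_conc=pd.DataFrame(columns=["subject_id"]), ada=pd.DataFrame(columns=["subject_id"]),
            biomarker=pd.DataFrame(columns=["subject_id"]), labs=pd.DataFrame(columns=["subject_id"]),
            ae=pd.DataFrame(columns=["subject_id"]), seed=0,
        )
        manifest = write_trial_dataset(empty, tmp_path)
        assert manifest["files"] == {}
        assert (tmp_path / "manifest.json").exists()
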