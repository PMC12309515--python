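"""Survival inference: exposure groups, follow-up matching, IPTW balance,
weighted Cox/KM and raking standardization."""

import numpy as np
import pandas as pd
import pytest

from ctsurveil.io import EHRBundle
from ctsurveil.survival import (
    build_survival_records,
    fit_propensity_and_weights,
    match_followup_controls,
    run_sensitivity_subsets,
    standardize_to_reference,
    standardized_mean_differences,
    weighted_cox,
    weighted_km,
)


def _records(n=2000, seed=0, confounded=False, log_hr=np.log(0.6)):
    """Small self-contained record generator for weighting/Cox unit tests."""
    rng = np.random.default_rng(seed)
    sex = rng.choice(["m", "f"], n)
    stage = rng.choice(["I", "II", "IV"], n, p=[0.5, 0.3, 0.2])
    stage_num = pd.Series(stage).map({"I": 0, "II": 1, "IV": 2}).to_numpy()
    if confounded:
        p = 1 / (1 + np.exp(-(1.0 - 1.0 * stage_num)))
    else:
        p = np.full(n, 0.5)
    e = (rng.random(n) < p).astype(int)
    rate = 0.08 * np.exp(0.4 * stage_num + log_hr * e)
    t = rng.exponential(1 / rate)
    event = (t <= 10).astype(int)
    t = np.minimum(t, 10)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "exposure": e, "time_days": t * 365.25, "event": event,
        "sex": sex, "race_ethnicity": "x", "stage": stage,
        "histology": rng.choice(["adeno", "squam"], n),
    })


class TestWeightedKM:
    def test_three_patient_closed_form(self):
        rec = pd.DataFrame({"exposure": [1, 1, 1], "time_days": [1.0, 2.0, 3.0],
                            "event": [1, 1, 0]})
        curve = weighted_km(rec)[1]
        s = dict(zip(curve["time"], curve["survival"]))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert curve["survival"].iloc[0] == 1.0

    def test_no_events_flat_at_one(self):
        rec = pd.DataFrame({"exposure": [0, 0], "time_days": [5.0, 8.0],
                            "event": [0, 0]})
        curve = weighted_km(rec)[0]
        assert list(curve["survival"]) == [1.0]

    def test_unit_weights_match_classical_km(self):
        from lifelines import KaplanMeierFitter

        rec = _records(300, seed=3)
        ours = weighted_km(rec, weights=np.ones(len(rec)))[1]
        grp = rec[rec["exposure"] == 1]
        kmf = KaplanMeierFitter().fit(grp["time_days"], grp["event"])
        for t, s in zip(ours["time"], ours["survival"]):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-8)

    def test_steps_only_at_event_times(self):
        rec = _records(200, seed=4)
        curve = weighted_km(rec)[0]
        event_times = set(rec.loc[(rec["exposure"] == 0) & (rec["event"] == 1),
                                  "time_days"])
        assert set(curve["time"]) - {0.0} <= event_times


class TestWeightedCox:
    def test_unit_weights_reduce_to_unweighted(self):
        rec = _records(800, seed=5)
        fit_w = weighted_cox(rec, weights=np.ones(len(rec)))
        fit_u = weighted_cox(rec)
        assert fit_w.log_hr == pytest.approx(fit_u.log_hr, abs=1e-8)
        assert not fit_w.robust and not fit_u.robust

    def test_no_events_rejected(self):
        rec = _records(50, seed=6)
        rec["event"] = 0
        with pytest.raises(ValueError, match="events"):
            weighted_cox(rec)

    def test_null_exposure_log_hr_near_zero(self):
        logs = [weighted_cox(_records(2500, seed=s, log_hr=0.0)).log_hr
                for s in range(5)]
        assert abs(np.mean(logs)) < 0.05

    def test_adjusted_fit_recovers_conditional_hr(self):
        rec = _records(4000, seed=7, confounded=True)
        fit = weighted_cox(rec)
        assert fit.log_hr == pytest.approx(np.log(0.6), abs=0.12)
        assert fit.ci[0] < fit.hazard_ratio < fit.ci[1]


class TestFollowupMatching:
    def test_shifted_pool_ks_improves(self):
        rng = np.random.default_rng(8)
        exposed = rng.uniform(1000, 4000, 400)
        pool = pd.DataFrame({"patient_id": [f"C{i}" for i in range(600)],
                             "time_days": rng.uniform(0, 2500, 600)})
        with pytest.warns(UserWarning):
            matched, diag = match_followup_controls(exposed, pool, seed=0)
        assert diag["ks_post"] < diag["ks_pre"]

    def test_identical_pool_is_plain_subsample(self):
        rng = np.random.default_rng(9)
        fu = rng.uniform(0, 3000, 500)
        pool = pd.DataFrame({"patient_id": [f"C{i}" for i in range(500)],
                             "time_days": fu})
        matched, diag = match_followup_controls(fu, pool, seed=0)
        assert diag["ks_post"] <= diag["ks_pre"] + 0.08

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        exposed = rng.uniform(0, 3000, 200)
        pool = pd.DataFrame({"patient_id": [f"C{i}" for i in range(300)],
                             "time_days": rng.uniform(0, 3000, 300)})
        a, _ = match_followup_controls(exposed, pool, seed=5)
        b, _ = match_followup_controls(exposed, pool, seed=5)
        assert a.equals(b)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            match_followup_controls([1.0], pd.DataFrame({"time_days": []}))


class TestPropensityWeights:
    def test_unconfounded_weights_near_one(self):
        rec = _records(5000, seed=11, confounded=False)
        pw = fit_propensity_and_weights(rec)
        assert np.all(np.abs(pw.weights - 1.0) < 0.15)

    def test_confounded_balance_restored(self):
        rec = _records(4000, seed=12, confounded=True)
        pw = fit_propensity_and_weights(rec, covariates=("sex", "stage", "histology"))
        assert pw.balance["smd_unweighted"].max() > 0.2
        assert pw.balance["smd_weighted"].max() < 0.1

    def test_degenerate_truncation_equalizes_weights(self):
        rec = _records(500, seed=13, confounded=True)
        pw = fit_propensity_and_weights(rec, truncation=(0.5, 0.5))
        for arm in (0, 1):
            w = pw.weights[rec["exposure"] == arm]
            assert np.allclose(w, w[0])

    def test_single_arm_rejected(self):
        rec = _records(100, seed=14)
        rec["exposure"] = 1
        with pytest.raises(ValueError):
            fit_propensity_and_weights(rec)

    def test_stabilized_weights_mean_near_one_per_arm(self):
        rec = _records(4000, seed=15, confounded=True)
        pw = fit_propensity_and_weights(rec)
        for arm in (0, 1):
            assert np.mean(pw.weights[rec["exposure"] == arm]) == pytest.approx(
                1.0, abs=0.1)


class TestRaking:
    def test_self_margins_fixed_point(self):
        rec = _records(1000, seed=16)
        margins = {"sex": rec["sex"].value_counts(normalize=True).to_dict()}
        sw = standardize_to_reference(rec, margins)
        assert np.allclose(sw.weights, 1.0, atol=1e-6)

    def test_shift_to_even_sex_ratio(self):
        rec = _records(1000, seed=17)
        sw = standardize_to_reference(rec, {"sex": {"m": 0.5, "f": 0.5}})
        assert sw.achieved_margins["sex"]["m"] == pytest.approx(0.5, abs=0.01)
        assert sw.weights.sum() == pytest.approx(len(rec), rel=1e-6)

    def test_two_margin_raking_converges(self):
        rec = _records(2000, seed=18)
        sw = standardize_to_reference(rec, {
            "sex": {"m": 0.45, "f": 0.55},
            "stage": {"I": 0.6, "II": 0.25, "IV": 0.15},
        })
        assert sw.converged
        for var, margins in sw.reference_margins.items():
            for lvl, target in margins.items():
                assert sw.achieved_margins[var][lvl] == pytest.approx(target, abs=0.01)

    def test_zero_mass_cell_names_the_cell(self):
        rec = _records(100, seed=19)
        with pytest.raises(ValueError, match="unknown_level"):
            standardize_to_reference(rec, {"sex": {"m": 0.4, "f": 0.5,
                                                   "unknown_level": 0.1}})


def _fixture_bundle():
    """Eight patients: S1,S2 surveillance-predicted; O1,O2 other-only scans;
    N1..N3 no CT; Z1 no CT with non-positive follow-up (excluded)."""
    pids = ["S1", "S2", "O1", "O2", "N1", "N2", "N3", "Z1"]
    ct = pd.DataFrame({
        "patient_id": ["S1", "S2", "O1", "O2"],
        "date": ["2015-06-01"] * 4,
        "report_id": ["R1", "R2", "R3", "R4"],
    })
    demo = pd.DataFrame({
        "patient_id": pids,
        "sex": ["f", "m"] * 4,
        "race_ethnicity": ["w"] * 8,
        "stage": ["I", "II", "I", "II", "I", "II", "I", "II"],
        "histology": ["a"] * 8,
    })
    outcomes = pd.DataFrame({
        "patient_id": pids,
        "time_origin_date": ["2015-01-01"] * 8,
        "last_followup_date": ["2019-01-01"] * 7 + ["2015-01-01"],
        "death_indicator": [0, 1, 0, 1, 0, 1, 0, 0],
    })
    empty = pd.DataFrame(columns=["patient_id", "date", "icd_code"])
    orders = pd.DataFrame(columns=["report_id", "provider_specialty"])
    bundle = EHRBundle(ct_events=ct, diagnoses=empty, orders=orders,
                       demographics=demo, outcomes=outcomes)
    preds = pd.DataFrame({
        "report_id": ["R1", "R2", "R3", "R4"],
        "patient_id": ["S1", "S2", "O1", "O2"],
        "scan_date": ["2015-06-01"] * 4,
        "probability": [0.9, 0.8, 0.2, 0.1],
        "label": ["surveillance", "surveillance", "other", "other"],
    })
    return bundle, preds


class TestBuildRecords:
    def test_group_sizes_match_hand_enumeration(self):
        bundle, preds = _fixture_bundle()
        surv = build_survival_records(bundle, preds, exposure_def="surveillance")
        assert sorted(surv.loc[surv["exposure"] == 1, "patient_id"]) == ["S1", "S2"]
        assert sorted(surv.loc[surv["exposure"] == 0, "patient_id"]) == \
            ["N1", "N2", "N3"]  # O1,O2 excluded; Z1 dropped (zero follow-up)
        any_ct = build_survival_records(bundle, preds, exposure_def="any")
        assert sorted(any_ct.loc[any_ct["exposure"] == 1, "patient_id"]) == \
            ["O1", "O2", "S1", "S2"]

    def test_annual_definition_uses_adherence(self):
        bundle, preds = _fixture_bundle()
        rec = build_survival_records(bundle, preds,
                                     adherence={"S1": True, "S2": False},
                                     exposure_def="annual")
        assert sorted(rec.loc[rec["exposure"] == 1, "patient_id"]) == ["S1"]

    def test_unknown_exposure_def_rejected(self):
        bundle, preds = _fixture_bundle()
        with pytest.raises(Exception, match="exposure_def"):
            build_survival_records(bundle, preds, exposure_def="bogus")


class TestSensitivitySubsets:
    def test_identity_subset_matches_primary(self):
        rec = _records(2000, seed=20, confounded=True)
        rec["surgery"] = "yes"
        fits = run_sensitivity_subsets(rec, subsets=("all",),
                                       covariates=("sex", "stage", "histology"))
        pw = fit_propensity_and_weights(rec, covariates=("sex", "stage", "histology"))
        direct = weighted_cox(rec, weights=pw.weights,
                              covariates=("sex", "stage", "histology"))
        assert fits["all"].log_hr == pytest.approx(direct.log_hr, abs=1e-10)

    def test_empty_subset_rejected(self):
        rec = _records(200, seed=21)
        rec["stage"] = "IV"
        rec["surgery"] = "no"
        with pytest.raises(ValueError, match="empty"):
            run_sensitivity_subsets(rec, subsets=("surgical_stage12",),
                                    covariates=("sex",))

    def test_subset_without_events_surfaces_error(self):
        rec = _records(400, seed=22)
        rec.loc[rec["stage"].isin(["I", "II", "IIIA"]), "event"] = 0
        with pytest.raises(ValueError):
            run_sensitivity_subsets(rec, subsets=("early_stage",),
                                    covariates=("sex",))


class TestSMD:
    def test_weighting_toward_balance_reduces_smd(self):
        rec = _records(3000, seed=23, confounded=True)
        un = standardized_mean_differences(rec, rec["exposure"] == 1, ("stage",))
        pw = fit_propensity_and_weights(rec, covariates=("stage",))
        w = standardized_mean_differences(rec, rec["exposure"] == 1, ("stage",),
                                          weights=pw.weights)
        assert w["smd"].iloc[0] < un["smd"].iloc[0]
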