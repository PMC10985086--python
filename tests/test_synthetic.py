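"""Cohort generator: counts, risk calibration, planted structure, dates,
matching and splitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from riskcarver import synthetic
from riskcarver.synthetic import (
    ArchetypeSpec,
    BiomarkerSpec,
    CohortConfig,
    CohortTable,
    FeatureSpec,
    MedicationSpec,
    generate_subjects,
    match_controls,
    simulate_longitudinal,
    split_populations,
)


def test_row_counts_match_configured_cohort_sizes():
    cfg = CohortConfig(19120, 19252, (FeatureSpec("x"),), seed=1)
    cohort = generate_subjects(cfg)
    assert len(cohort) == 38372
    assert cohort.labels.sum() == 19120


def test_no_signal_cohort_has_chance_auc_and_flat_risk():
    cfg = CohortConfig(5000, 5000, (FeatureSpec("x"),), seed=2)
    cohort = generate_subjects(cfg)
    assert cohort.frame["true_risk"].nunique() == 1
    assert abs(roc_auc_score(cohort.labels, cohort.frame["true_risk"]) - 0.5) <= 0.02
    assert abs(roc_auc_score(cohort.labels, cohort.features["x"]) - 0.5) <= 0.02


def test_single_gaussian_feature_auc_matches_binormal_closed_form():
    d = 1.19
    cfg = CohortConfig(5000, 5000, (FeatureSpec("x", effect=d),), seed=3)
    cohort = generate_subjects(cfg)
    expected = norm.cdf(d / np.sqrt(2))
    assert abs(roc_auc_score(cohort.labels, cohort.features["x"]) - expected) <= 0.02


def test_generation_is_bit_reproducible_for_fixed_seed():
    cfg = CohortConfig(300, 300, (FeatureSpec("x", effect=0.5), FeatureSpec("b", kind="binary")),
                       archetypes=(ArchetypeSpec(0, (("x", ">", 1.0),), 1.0, 0.1),), seed=11)
    a, b = generate_subjects(cfg), generate_subjects(cfg)
    pd.testing.assert_frame_equal(a.frame, b.frame)


def test_archetype_members_satisfy_their_rule_and_carry_extra_risk():
    arch = ArchetypeSpec(0, (("x", ">", 1.5),), 2.0, 0.15)
    cfg = CohortConfig(2000, 2000, (FeatureSpec("x"),), archetypes=(arch,), seed=4)
    cohort = generate_subjects(cfg)
    members = cohort.frame["true_archetype"] == 0
    assert (cohort.features.loc[members, "x"] > 1.5).all()
    # ground truth is the rule itself: non-members never satisfy it
    assert not (cohort.features.loc[~members, "x"] > 1.5).any()
    assert cohort.frame.loc[members, "is_case"].mean() > cohort.frame.loc[~members, "is_case"].mean()


def test_realized_case_fraction_calibrated_with_archetype_shifts():
    arch = ArchetypeSpec(0, (("x", ">", 1.0),), 3.0, 0.2)
    cfg = CohortConfig(3000, 7000, (FeatureSpec("x"),), archetypes=(arch,), seed=5)
    cohort = generate_subjects(cfg)
    assert cohort.labels.mean() == pytest.approx(0.3, abs=1e-9)  # counts are exact by design


def test_missingness_inserted_at_configured_rate():
    cfg = CohortConfig(2000, 2000, (FeatureSpec("x", missing_rate=0.3),), seed=6)
    cohort = generate_subjects(cfg)
    assert cohort.features["x"].isna().mean() == pytest.approx(0.3, abs=0.03)


@pytest.mark.parametrize("bad", [
    dict(n_cases=0, n_controls=10),
    dict(assessment_to_index_years=(5.0, 5.0)),
    dict(archetypes=(ArchetypeSpec(0, (("y", ">", 0),), 1.0, 0.1),)),
    dict(archetypes=(ArchetypeSpec(0, (("x", ">", 0),), 1.0, 0.6),
                     ArchetypeSpec(1, (("x", ">", 1),), 1.0, 0.6))),
])
def test_invalid_configs_are_rejected(bad):
    kwargs = dict(n_cases=10, n_controls=10, features=(FeatureSpec("x"),), seed=0)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        CohortConfig(**kwargs)


def _cohort_with_gaps(gap_days):
    n = len(gap_days)
    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "is_case": [1] * n,
            "assessment_date": [1000] * n,
            "index_date": [1000 + g for g in gap_days],
            "obs_start_date": [0] * n,
            "obs_end_date": [99999] * n,
            "death_date": [np.nan] * n,
            "true_archetype": [-1] * n,
            "true_risk": [0.5] * n,
            "x": [0.0] * n,
        }
    )
    return CohortTable(frame, ["x"])


def test_split_populations_window_boundaries():
    # 4.9y -> discovery; 5.1y -> holdout; 12y -> dropped; exact 5y -> discovery
    gaps = [int(4.9 * 365), int(5.1 * 365), 12 * 365, 5 * 365, 11 * 365, 11 * 365 + 1]
    cohort = _cohort_with_gaps(gaps)
    disc, hold = split_populations(cohort)
    assert list(disc.frame["subject_id"]) == ["S0", "S3"]
    assert list(hold.frame["subject_id"]) == ["S1", "S4"]
    assert len(disc) + len(hold) == len(cohort) - 2  # the two out-of-window rows drop


def test_split_populations_partitions_generated_cohort():
    cfg = CohortConfig(500, 500, (FeatureSpec("x"),), assessment_to_index_years=(0, 12), seed=7)
    cohort = generate_subjects(cfg)
    disc, hold = split_populations(cohort)
    gap = cohort.frame["index_date"] - cohort.frame["assessment_date"]
    dropped = ((gap <= 0) | (gap > 11 * 365)).sum()
    assert len(disc) + len(hold) + dropped == len(cohort)
    assert not set(disc.frame["subject_id"]) & set(hold.frame["subject_id"])


def test_split_empty_cohort_gives_two_empty_tables():
    cohort = _cohort_with_gaps([])
    disc, hold = split_populations(cohort)
    assert len(disc) == 0 and len(hold) == 0


def _pool(rows):
    frame = pd.DataFrame(rows)
    frame["is_case"] = 0
    frame["assessment_date"] = 0
    frame["true_archetype"] = -1
    frame["true_risk"] = 0.1
    frame["x"] = 0.0
    return CohortTable(frame, ["x"])


def test_match_controls_assigns_case_index_dates_bijectively():
    cases = _cohort_with_gaps([400, 500, 600])
    pool = _pool(
        {
            "subject_id": ["C1", "C2", "C3"],
            "index_date": [0, 0, 0],
            "obs_start_date": [-9000] * 3,
            "obs_end_date": [99999] * 3,
            "death_date": [np.nan] * 3,
        }
    )
    matched = match_controls(cases, pool, seed=1)
    assert sorted(matched.frame["index_date"]) == sorted(cases.frame["index_date"])
    assert matched.frame["subject_id"].nunique() == 3


def test_control_without_five_year_coverage_is_ineligible():
    cases = _cohort_with_gaps([1000])  # index date 2000
    # observation starts 2 years before the index date: not enough coverage
    pool = _pool(
        {
            "subject_id": ["C1", "C2"],
            "index_date": [0, 0],
            "obs_start_date": [2000 - 2 * 365, -9000],
            "obs_end_date": [99999, 99999],
            "death_date": [np.nan, np.nan],
        }
    )
    matched = match_controls(cases, pool, seed=1)
    assert list(matched.frame["subject_id"]) == ["C2"]


def test_death_within_lookback_window_disqualifies_control():
    cases = _cohort_with_gaps([1000])
    pool = _pool(
        {
            "subject_id": ["C1"],
            "index_date": [0],
            "obs_start_date": [-9000],
            "obs_end_date": [99999],
            "death_date": [1500.0],  # inside the 5y window before day 2000
        }
    )
    with pytest.raises(ValueError, match="S0"):
        match_controls(cases, pool, seed=1)


def test_matching_is_deterministic_under_seed():
    cases = _cohort_with_gaps([100] * 50)
    pool = _pool(
        {
            "subject_id": [f"C{i}" for i in range(300)],
            "index_date": [0] * 300,
            "obs_start_date": [-9000] * 300,
            "obs_end_date": [99999] * 300,
            "death_date": [np.nan] * 300,
        }
    )
    a = match_controls(cases, pool, seed=9)
    b = match_controls(cases, pool, seed=9)
    assert list(a.frame["subject_id"]) == list(b.frame["subject_id"])


def test_zero_noise_biomarker_is_constant_at_subject_mean():
    cfg = CohortConfig(20, 20, (FeatureSpec("x"),), seed=8)
    cohort = generate_subjects(cfg)
    rec = simulate_longitudinal(cohort, [BiomarkerSpec("crp", mean=7.0)], [], seed=1)
    assert (rec["value"] == 7.0).all()
    assert (rec["date"] < rec["subject_id"].map(
        cohort.frame.set_index("subject_id")["index_date"]
    )).all()


def test_certain_prescription_reaches_every_case_in_that_year():
    cfg = CohortConfig(100, 100, (FeatureSpec("x"),), seed=9)
    cohort = generate_subjects(cfg)
    rec = simulate_longitudinal(
        cohort, [], [MedicationSpec("nsaid", yearly_prob_case=(1.0, 0, 0, 0, 0))], seed=2
    )
    cases = cohort.frame.loc[cohort.frame["is_case"] == 1, "subject_id"]
    assert set(cases) == set(rec["subject_id"])
    idx = cohort.frame.set_index("subject_id")["index_date"]
    delta = rec["subject_id"].map(idx) - rec["date"]
    assert ((delta >= 1) & (delta <= 365)).all()


def test_ar1_series_reproduces_specified_autocorrelation():
    cfg = CohortConfig(500, 500, (FeatureSpec("x"),), seed=10)
    cohort = generate_subjects(cfg)
    rec = simulate_longitudinal(
        cohort, [BiomarkerSpec("hb", rho=0.5, sigma=1.0)], [], seed=3
    )
    rec = rec.sort_values(["subject_id", "date"])
    vals = rec["value"].to_numpy().reshape(len(cohort), -1)  # 60 monthly values each
    x0, x1 = vals[:, :-1].ravel(), vals[:, 1:].ravel()
    r = np.corrcoef(x0, x1)[0, 1]
    assert abs(r - 0.5) <= 0.05


def test_empty_longitudinal_specs_give_empty_records():
    cfg = CohortConfig(10, 10, (FeatureSpec("x"),), seed=11)
    cohort = generate_subjects(cfg)
    rec = simulate_longitudinal(cohort, [], [], seed=4)
    assert len(rec) == 0


def test_cohort_tsv_roundtrip(tmp_path):
    cfg = CohortConfig(50, 50, (FeatureSpec("x", missing_rate=0.2),), seed=12)
    cohort = generate_subjects(cfg)
    path = tmp_path / "cohort.tsv"
    synthetic.write_cohort(cohort, path)
    back = synthetic.read_cohort(path)
    assert back.feature_names == ["x"]
    pd.testing.assert_frame_equal(back.frame, cohort.frame, check_dtype=False)
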