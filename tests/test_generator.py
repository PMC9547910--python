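import dataclasses

import numpy as np
import pandas as pd
import pytest

from ccval import classifier, gcps
from ccval.data_model import TABLE_COLUMNS, read_tables, write_tables
from ccval.generator import (
    CostCategoryParams,
    GeneratorConfig,
    generate,
    generate_with_truth,
    implied_binary_metrics,
    implied_grade_marginal,
)

ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


def test_same_seed_gives_byte_identical_bundles(tmp_path):
    cfg = GeneratorConfig(n_persons=300, seed=9)
    generate(cfg, tmp_path / "one")
    generate(cfg, tmp_path / "two")
    for name in TABLE_COLUMNS:
        assert (tmp_path / "one" / f"{name}.csv").read_bytes() == \
            (tmp_path / "two" / f"{name}.csv").read_bytes()


def test_different_seed_changes_output(tmp_path):
    generate(GeneratorConfig(n_persons=100, seed=1), tmp_path / "one")
    generate(GeneratorConfig(n_persons=100, seed=2), tmp_path / "two")
    assert (tmp_path / "one" / "diagnoses.csv").read_bytes() != \
        (tmp_path / "two" / "diagnoses.csv").read_bytes()


def test_zero_persons_yields_header_only_files(tmp_path):
    _, manifest = generate(GeneratorConfig(n_persons=0, seed=0), tmp_path)
    assert manifest["n_persons"] == 0
    for name in TABLE_COLUMNS:
        lines = (tmp_path / f"{name}.csv").read_text().strip().splitlines()
        assert len(lines) == 1


def test_manifest_counts_sum_to_population(gen_run):
    _, _, manifest, persons = gen_run
    assert sum(manifest["by_path"].values()) == manifest["n_persons"] == len(persons)
    assert sum(manifest["grade"].values()) == manifest["n_persons"]
    assert sum(manifest["latent_cc_invited"].values()) == \
        manifest["by_path"]["invited"]


def test_classifier_round_trip_on_generated_claims(gen_run):
    _, bundle, _, persons = gen_run
    enrol = bundle.enrolment
    idx = pd.Series(
        np.where(enrol["path"] == "invited",
                 pd.to_datetime(enrol["invitation_date"]).to_numpy(),
                 pd.to_datetime(enrol["enrolment_date"]).to_numpy()),
        index=enrol["person_id"].astype(str).to_numpy(),
    )
    classes = classifier.classify_table(
        bundle.diagnoses, bundle.prescriptions, bundle.sick_leave, idx
    )
    merged = classes.merge(persons[["person_id", "latent_cc"]], on="person_id")
    assert (merged["cc"].astype(int) == merged["latent_cc"]).all()


def test_scorer_round_trip_on_generated_items(gen_run):
    _, bundle, _, persons = gen_run
    scores = gcps.score_frame(bundle.gcps_items)
    merged = scores.merge(persons[["person_id", "grade"]], on="person_id",
                          suffixes=("", "_latent"))
    assert (merged["grade"].map(ROMAN) == merged["grade_latent"]).all()


def test_grade_iv_preimage_has_high_disability_points(gen_run):
    _, bundle, _, persons = gen_run
    scores = gcps.score_frame(bundle.gcps_items).set_index("person_id")
    iv = persons.loc[persons["grade"] == 4, "person_id"]
    assert scores.loc[iv, "disability_points"].isin([5, 6]).all()
    ii = persons.loc[persons["grade"] == 2, "person_id"]
    assert (scores.loc[ii, "pain_intensity"] >= 50).all()
    assert (scores.loc[ii, "disability_points"] <= 2).all()


def test_sampled_marginals_match_closed_form(gen_run):
    cfg, _, _, persons = gen_run
    # grade marginal vs the mixture implied by the config (n=2000,
    # multinomial SE ~1.1%, so a 3-sigma band of +/-3.5%)
    expected = implied_grade_marginal(cfg)
    observed = persons["grade"].value_counts(normalize=True).sort_index().to_numpy()
    assert np.abs(observed - expected).max() < 0.035
    invited = persons[persons["path"] == "invited"]
    cc_obs = invited["latent_cc"].value_counts(normalize=True).sort_index().to_numpy()
    assert np.abs(cc_obs - np.asarray(cfg.cc_marginal)).max() < 0.035


def test_degenerate_grade_conditionals_force_one_grade():
    row = (1.0, 0.0, 0.0, 0.0)
    cfg = GeneratorConfig(
        n_persons=200, seed=3,
        gcps_given_cc=(row, row, row), gcps_given_self=row,
    )
    _, _, persons = generate_with_truth(cfg)
    assert (persons["grade"] == 1).all()


def test_invalid_probability_rows_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(cc_marginal=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        GeneratorConfig(gcps_given_self=(0.9, 0.2, -0.1, 0.0))


def test_conditional_rows_are_stochastic_and_split_by_marginal():
    cfg = GeneratorConfig()
    m = cfg.conditional_matrix()
    assert m.shape == (3, 4)
    assert np.allclose(m.sum(axis=1), 1.0)
    # the unprinted cells of rows 2 and 3 split proportionally to the
    # overall grade marginal
    r3, r4 = m[1, 2], m[1, 3]
    assert r3 / r4 == pytest.approx(cfg.grade_marginal[2] / cfg.grade_marginal[3])
    s1, s2 = m[2, 0], m[2, 1]
    assert s1 / s2 == pytest.approx(cfg.grade_marginal[0] / cfg.grade_marginal[1])


def test_implied_binary_metrics_are_probabilities():
    out = implied_binary_metrics(GeneratorConfig())
    assert 0 < out["sensitivity"] < 1
    assert 0 < out["specificity"] < 1


def test_zero_variance_costs_equal_configured_mean():
    params = {
        "total_health": CostCategoryParams(
            p_present=(1.0, 1.0, 1.0, 1.0),
            mean=(1000.0, 2000.0, 3000.0, 4000.0),
            sigma=0.0,
        )
    }
    cfg = GeneratorConfig(n_persons=400, seed=5, cost_params=params,
                          p_no_invoice=0.0)
    bundle, _, persons = generate_with_truth(cfg)
    from ccval.costs import aggregate_costs

    enrol_dates = pd.Series(
        pd.to_datetime(bundle.enrolment["enrolment_date"]).to_numpy(),
        index=bundle.enrolment["person_id"].astype(str).to_numpy(),
    )
    vectors = aggregate_costs(bundle.invoices, enrol_dates).set_index("person_id")
    merged = vectors.join(persons.set_index("person_id")["grade"])
    for g, mean in zip((1, 2, 3, 4), (1000.0, 2000.0, 3000.0, 4000.0)):
        got = merged.loc[merged["grade"] == g, "total_health"]
        if len(got):
            # rounding to invoice cents introduces sub-euro jitter
            assert got.to_numpy() == pytest.approx(mean, abs=1.0)


def test_cost_means_increase_with_grade(gen_run):
    cfg, bundle, _, persons = gen_run
    from ccval.costs import aggregate_costs

    enrol_dates = pd.Series(
        pd.to_datetime(bundle.enrolment["enrolment_date"]).to_numpy(),
        index=bundle.enrolment["person_id"].astype(str).to_numpy(),
    )
    vectors = aggregate_costs(bundle.invoices, enrol_dates).set_index("person_id")
    merged = vectors.join(persons.set_index("person_id")[["grade", "zero_invoice"]])
    merged = merged[~merged["zero_invoice"]]
    means = merged.groupby("grade")["total_health"].mean()
    assert means.loc[1] < means.loc[4]


def test_generated_bundle_survives_interchange_round_trip(tmp_path):
    bundle, _ = generate(GeneratorConfig(n_persons=60, seed=21), tmp_path)
    back, errors = read_tables(tmp_path)
    assert errors == []
    for name in TABLE_COLUMNS:
        assert len(back.table(name)) == len(bundle.table(name))
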