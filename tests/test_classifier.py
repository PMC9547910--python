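import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from ccval.classifier import (
    CcConfig,
    CcFeatures,
    ChronicityClass,
    NOT_CLASSIFIABLE,
    classify,
    classify_person,
    classify_table,
    dichotomize_cc,
    extract_features,
    is_bp_code,
    is_f_code,
)
from ccval.data_model import (
    ClaimsHistory,
    DiagnosisRecord,
    PrescriptionRecord,
    SickLeaveEpisode,
)

INDEX = dt.date(2020, 6, 1)
CONFIG = CcConfig()


def _history(person="p", diagnoses=(), prescriptions=(), sick_leave=()):
    return ClaimsHistory(
        person,
        diagnoses=[DiagnosisRecord(person, c, d) for c, d in diagnoses],
        prescriptions=[PrescriptionRecord(person, a, d) for a, d in prescriptions],
        sick_leave=[SickLeaveEpisode(person, s, e, c) for s, e, c in sick_leave],
    )


def _days_ago(n):
    return INDEX - dt.timedelta(days=n)


# --- independent oracles ----------------------------------------------------


def brute_force_features(history, index_date, config=CONFIG):
    """Day-by-day / all-pairs re-computation of the lookback features."""
    window = {index_date - dt.timedelta(days=k)
              for k in range(config.lookback_days)}
    m = sum(1 for r in history.diagnoses
            if r.date in window and is_bp_code(r.code, config))
    f = sum(1 for r in history.diagnoses
            if r.date in window and is_f_code(r.code, config))
    opioids = [r.date for r in history.prescriptions
               if r.date in window and r.atc_code.startswith("N02A")]
    pair = any(abs((a - b).days) <= config.opioid_window_days
               for a, b in itertools.combinations(opioids, 2))
    sl = 0
    for ep in history.sick_leave:
        if is_bp_code(ep.attributed_code, config):
            day = ep.start
            while day <= ep.end:
                if day in window:
                    sl += 1
                day += dt.timedelta(days=1)
    return m, f, pair, len(opioids), sl


def test_empty_history_has_zero_features():
    feats = extract_features(_history(), INDEX)
    assert (feats.m_diag_count, feats.f_diag_count, feats.opioid_rx_count,
            feats.bp_sickleave_days) == (0, 0, 0, 0)
    assert not feats.opioid_rx_pair_within_window
    assert classify(feats).cc == NOT_CLASSIFIABLE


def test_two_bp_diagnoses_counted():
    h = _history(diagnoses=[("M54.5", _days_ago(10)), ("M54.5", _days_ago(40))])
    assert extract_features(h, INDEX).m_diag_count == 2


def test_window_boundaries_are_closed():
    h = _history(diagnoses=[
        ("M54.5", INDEX),                 # on the index date: inside
        ("M54.5", _days_ago(364)),        # first day of the window: inside
        ("M54.5", _days_ago(365)),        # one day before the window: outside
        ("M54.5", INDEX + dt.timedelta(days=1)),  # after index: outside
    ])
    feats = extract_features(h, INDEX)
    assert feats.m_diag_count == 2
    assert feats.m_diag_count == brute_force_features(h, INDEX)[0]


def test_opioid_pair_requires_dates_within_window_length():
    far = _history(prescriptions=[("N02AA01", _days_ago(300)),
                                  ("N02AA01", _days_ago(100))])
    near = _history(prescriptions=[("N02AA01", _days_ago(250)),
                                   ("N02AA01", _days_ago(67))])
    assert not extract_features(far, INDEX).opioid_rx_pair_within_window
    assert extract_features(near, INDEX).opioid_rx_pair_within_window
    assert extract_features(far, INDEX).opioid_rx_pair_within_window == \
        brute_force_features(far, INDEX)[2]


def test_opioid_pair_boundary_exactly_183_days():
    h = _history(prescriptions=[("N02AA01", _days_ago(200)),
                                ("N02AA01", _days_ago(17))])
    assert extract_features(h, INDEX).opioid_rx_pair_within_window


def test_non_opioid_prescriptions_ignored():
    h = _history(prescriptions=[("M01AE01", _days_ago(10)),
                                ("M01AE01", _days_ago(20))])
    assert extract_features(h, INDEX).opioid_rx_count == 0


def test_sickleave_days_counted_with_overlap():
    # 50-day episode fully inside
    h = _history(sick_leave=[(_days_ago(120), _days_ago(71), "M51.1")])
    assert extract_features(h, INDEX).bp_sickleave_days == 50
    # episode straddling the window start is clipped
    h2 = _history(sick_leave=[(_days_ago(400), _days_ago(350), "M54.5")])
    feats = extract_features(h2, INDEX)
    assert feats.bp_sickleave_days == brute_force_features(h2, INDEX)[4] == 15
    # non back-pain attribution does not count
    h3 = _history(sick_leave=[(_days_ago(120), _days_ago(71), "J06.9")])
    assert extract_features(h3, INDEX).bp_sickleave_days == 0


def test_features_match_brute_force_on_random_histories():
    rng = np.random.default_rng(42)
    codes = ["M54.5", "M40.1", "M55.1", "F32.1", "F43.21", "J06.9", "M39.9"]
    for _ in range(50):
        diagnoses = [(codes[rng.integers(len(codes))],
                      _days_ago(int(rng.integers(0, 500))))
                     for _ in range(rng.integers(0, 8))]
        prescriptions = [(("N02AA01", "M01AE01")[rng.integers(2)],
                          _days_ago(int(rng.integers(0, 500))))
                         for _ in range(rng.integers(0, 5))]
        sick = []
        for _ in range(rng.integers(0, 3)):
            start = _days_ago(int(rng.integers(0, 450)))
            sick.append((start, start + dt.timedelta(int(rng.integers(0, 80))),
                         ("M54.5", "J06.9")[rng.integers(2)]))
        h = _history(diagnoses=diagnoses, prescriptions=prescriptions,
                     sick_leave=sick)
        feats = extract_features(h, INDEX)
        m, f, pair_all, n_op, sl = brute_force_features(h, INDEX)
        assert feats.m_diag_count == m
        assert feats.f_diag_count == f
        assert feats.opioid_rx_count == n_op
        assert feats.bp_sickleave_days == sl
        # consecutive-gap pair detection implies the all-pairs oracle and,
        # for sorted dates, is implied by it
        assert feats.opioid_rx_pair_within_window == pair_all


@pytest.mark.parametrize(
    "features,expected",
    [
        (CcFeatures(2, 0, False, 0, 42), 3),   # six weeks of sick leave
        (CcFeatures(2, 0, True, 2, 0), 3),     # opioid pair
        (CcFeatures(2, 2, False, 0, 0), 2),    # two F diagnoses
        (CcFeatures(2, 0, False, 0, 1), 2),    # 1-41 sick-leave days
        (CcFeatures(2, 0, False, 0, 41), 2),
        (CcFeatures(2, 1, False, 1, 0), 1),    # nothing qualifying
        (CcFeatures(2, 0, False, 0, 0), 1),
        (CcFeatures(1, 5, True, 4, 100), NOT_CLASSIFIABLE),  # below threshold
        (CcFeatures(2, 2, False, 0, 50), 3),   # precedence: CC3 before CC2
    ],
)
def test_classification_rules(features, expected):
    assert classify(features).cc == expected


def test_class_conditions_mutually_exclusive_on_feature_grid():
    for m, f, pair, sl in itertools.product(
        (0, 1, 2, 5), (0, 1, 2, 4), (False, True), (0, 1, 41, 42, 100)
    ):
        rx = 2 if pair else 0
        c = classify(CcFeatures(m, f, pair, rx, sl))
        assert c.cc in (1, 2, 3, NOT_CLASSIFIABLE)
        assert c.severe == (c.cc == 3)


def test_adding_evidence_never_moves_class_toward_one():
    rank = {1: 1, 2: 2, 3: 3}
    base_cases = [CcFeatures(2, f, False, 0, sl)
                  for f in (0, 1, 2) for sl in (0, 1, 20, 41, 42)]
    for feats in base_cases:
        before = rank[classify(feats).cc]
        with_pair = CcFeatures(feats.m_diag_count, feats.f_diag_count, True, 2,
                               feats.bp_sickleave_days)
        longer_sl = CcFeatures(feats.m_diag_count, feats.f_diag_count, False, 0,
                               feats.bp_sickleave_days + 30)
        assert rank[classify(with_pair).cc] >= before
        assert rank[classify(longer_sl).cc] >= before


def test_dichotomisation():
    assert not dichotomize_cc(1) and not dichotomize_cc(2)
    assert dichotomize_cc(3)
    with pytest.raises(ValueError):
        dichotomize_cc(NOT_CLASSIFIABLE)


def test_invalid_feature_combinations_rejected():
    with pytest.raises(ValueError):
        CcFeatures(2, 0, True, 1, 0)   # pair without two prescriptions
    with pytest.raises(ValueError):
        CcFeatures(-1, 0, False, 0, 0)
    with pytest.raises(ValueError):
        ChronicityClass(3, False)


def test_table_route_matches_scalar_route(gen_run):
    _, bundle, _, persons = gen_run
    from ccval.data_model import claims_histories

    enrol = bundle.enrolment
    idx = pd.Series(
        np.where(enrol["path"] == "invited",
                 pd.to_datetime(enrol["invitation_date"]).to_numpy(),
                 pd.to_datetime(enrol["enrolment_date"]).to_numpy()),
        index=enrol["person_id"].astype(str).to_numpy(),
    )
    table = classify_table(bundle.diagnoses, bundle.prescriptions,
                           bundle.sick_leave, idx).set_index("person_id")
    histories = claims_histories(bundle)
    rng = np.random.default_rng(3)
    sample = rng.choice(idx.index.to_numpy(), 150, replace=False)
    for pid in sample:
        scalar = classify_person(histories[pid], pd.Timestamp(idx[pid]).date())
        assert table.loc[pid, "cc"] == scalar.cc
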