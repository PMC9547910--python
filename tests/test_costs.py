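import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ccval.costs import (
    DEFAULT_CPI,
    aggregate_costs,
    cost_table_by_group,
    cpi_adjust,
    flag_low_cost,
    skewness,
    truncated_mean,
    tukey_upper_fence,
)


def _invoices(rows):
    df = pd.DataFrame(rows, columns=["person_id", "date", "category", "amount",
                                     "year"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def test_aggregation_sums_categories_in_window():
    enrol = pd.Series(pd.to_datetime(["2020-12-31"]), index=["a"])
    invoices = _invoices(
        [
            ("a", "2020-06-01", "bp_outpatient", 100.0, 2020),
            ("a", "2020-07-01", "bp_outpatient", 50.0, 2020),
            ("a", "2020-08-01", "bp_inpatient", 200.0, 2020),
            ("a", "2019-12-31", "bp_outpatient", 999.0, 2019),  # outside window
            ("a", "2020-05-01", "total_health", 400.0, 2020),
        ]
    )
    out = aggregate_costs(invoices, enrol).set_index("person_id")
    assert out.loc["a", "bp_outpatient"] == 150.0
    assert out.loc["a", "bp_inpatient"] == 200.0
    assert out.loc["a", "bp_total"] == 350.0
    assert out.loc["a", "total_health"] == 400.0
    assert out.loc["a", "n_invoices_bp_total"] == 3


def test_aggregation_no_invoices_gives_zeros():
    enrol = pd.Series(pd.to_datetime(["2020-12-31"]), index=["a"])
    out = aggregate_costs(_invoices([]), enrol).set_index("person_id")
    assert out.loc["a", ["total_health", "bp_total"]].tolist() == [0.0, 0.0]


def test_cpi_adjustment():
    assert cpi_adjust(100.0, 2020, {2020: 100.0}, 2020) == 100.0
    assert cpi_adjust(100.0, 2019, {2019: 100.0, 2020: 105.0}, 2020) == \
        pytest.approx(105.0)
    with pytest.raises(KeyError):
        cpi_adjust(100.0, 1999, {2020: 100.0}, 2020)
    with pytest.raises(KeyError):
        cpi_adjust(100.0, 2020, {}, 2020)
    # default table is anchored at the base year
    assert cpi_adjust(100.0, 2020) == 100.0
    assert cpi_adjust(100.0, 2015) == pytest.approx(100.0 * 100.0 / DEFAULT_CPI[2015])


def test_tukey_fence_hand_example():
    # sorted (1,2,3,4,100): Q1=2, Q3=4 under linear interpolation,
    # fence = 4 + 1.5*2 = 7 -> only 100 flagged
    fence, flags = tukey_upper_fence(np.array([1, 2, 3, 4, 100.0]))
    assert fence == pytest.approx(7.0)
    assert flags.tolist() == [False, False, False, False, True]


def test_tukey_fence_constant_and_tame_vectors():
    fence, flags = tukey_upper_fence(np.full(10, 5.0))
    assert fence == 5.0 and not flags.any()
    fence, flags = tukey_upper_fence(np.arange(8.0))
    assert not flags.any()
    with pytest.raises(ValueError):
        tukey_upper_fence(np.array([1.0, 2.0]))


@given(
    values=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=4, max_size=30),
    shift=st.floats(-1e4, 1e4, allow_nan=False),
    scale=st.floats(0.01, 100, allow_nan=False),
)
def test_fence_equivariance_under_shift_and_scale(values, shift, scale):
    v = np.array(values)
    fence, _ = tukey_upper_fence(v)
    shifted, _ = tukey_upper_fence(v + shift)
    scaled, _ = tukey_upper_fence(v * scale)
    assert shifted == pytest.approx(fence + shift, rel=1e-9, abs=1e-6)
    assert scaled == pytest.approx(fence * scale, rel=1e-9, abs=1e-6)


def test_low_cost_is_presence_not_amount():
    assert flag_low_cost(np.array([0, 1, 3])).tolist() == [True, False, False]


def test_truncated_mean_enumeration():
    values = np.array([0.0, 10.0, 20.0, 1e6])
    low = np.array([True, False, False, False])     # zero-invoice person
    high = np.array([False, False, False, True])    # outlier
    assert truncated_mean(values, high, low) == 15.0
    none = np.zeros(4, bool)
    assert truncated_mean(values, none, none) == values.mean()
    with pytest.raises(ValueError):
        truncated_mean(values, np.ones(4, bool), none)


def test_removing_only_above_fence_values_never_increases_mean():
    rng = np.random.default_rng(0)
    for _ in range(20):
        v = rng.lognormal(6, 1.2, size=200)
        _, high = tukey_upper_fence(v)
        if high.any():
            assert truncated_mean(v, high, np.zeros_like(high)) <= v.mean()


def test_skewness_against_moment_oracle():
    rng = np.random.default_rng(1)
    v = rng.lognormal(0, 1, 500)
    n = len(v)
    m2 = ((v - v.mean()) ** 2).sum() / n
    m3 = ((v - v.mean()) ** 3).sum() / n
    g1 = m3 / m2**1.5
    adjusted = g1 * np.sqrt(n * (n - 1)) / (n - 2)
    assert skewness(v) == pytest.approx(adjusted, rel=1e-12)
    assert skewness(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(skewness(np.full(5, 3.0)))


def test_truncation_reduces_skew_on_lognormal_replicates():
    """Dropping above-fence values tames the right tail in >= 95% of 1000
    lognormal replicates."""
    rng = np.random.default_rng(7)
    wins = 0
    for _ in range(1000):
        v = rng.lognormal(6.5, 1.0, size=250)
        _, high = tukey_upper_fence(v)
        keep = v[~high]
        if len(keep) >= 3 and abs(skewness(keep)) < abs(skewness(v)):
            wins += 1
    assert wins >= 950


def test_cost_table_two_groups_hand_computed():
    vectors = pd.DataFrame(
        {
            "person_id": list("abcd"),
            "total_health": [100.0, 200.0, 300.0, 400.0],
            "bp_inpatient": [0.0, 0.0, 0.0, 0.0],
            "bp_outpatient": [10.0, 20.0, 30.0, 40.0],
            "bp_total": [10.0, 20.0, 30.0, 40.0],
            "n_invoices_total_health": [1, 1, 1, 1],
            "n_invoices_bp_inpatient": [0, 0, 0, 0],
            "n_invoices_bp_outpatient": [1, 1, 1, 1],
            "n_invoices_bp_total": [1, 1, 1, 1],
        }
    )
    groups = pd.Series(["I", "I", "II", "II"], index=list("abcd"))
    table = cost_table_by_group(vectors, groups, categories=("total_health",))
    rows = table.set_index("group")
    assert rows.loc["overall", "mean"] == 250.0
    assert rows.loc["I", "mean"] == 150.0
    assert rows.loc["II", "mean"] == 350.0
    assert rows.loc["overall", "n"] == 4


def test_cost_table_constant_group():
    vectors = pd.DataFrame(
        {
            "person_id": list("abcd"),
            "total_health": [100.0] * 4,
            "bp_inpatient": [0.0] * 4,
            "bp_outpatient": [0.0] * 4,
            "bp_total": [0.0] * 4,
            "n_invoices_total_health": [1] * 4,
            "n_invoices_bp_inpatient": [0] * 4,
            "n_invoices_bp_outpatient": [0] * 4,
            "n_invoices_bp_total": [0] * 4,
        }
    )
    groups = pd.Series(["I"] * 4, index=list("abcd"))
    table = cost_table_by_group(vectors, groups, categories=("total_health",))
    row = table[table["group"] == "I"].iloc[0]
    assert row["mean"] == 100.0 and row["sd"] == 0.0
    assert row["n_high_cost"] == 0
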