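"""Performance models: table rates, corrections, d', A', empirical AUC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from forensicsdt import (
    DIFFERENT,
    SAME,
    BinaryTable,
    RatePair,
    TernaryTable,
    a_prime,
    correct_rates,
    d_prime,
    diagnosticity_ratio,
    empirical_auc,
    metrics_table,
    participant_metrics,
    proportion_correct,
    rates_and_predictive_values,
    tabulate,
    ternary_predictive_values,
)

EXPERT = BinaryTable(396, 119, 64, 477)
NOVICE = BinaryTable(362, 153, 282, 259)
EXPERT_TERNARY = TernaryTable(359, 87, 69, 43, 420, 78)


def brute_force_auc(same, diff):
    """Pairwise wins-plus-half-ties oracle for the empirical ROC area."""
    s = np.asarray(same, dtype=float)[:, None]
    d = np.asarray(diff, dtype=float)[None, :]
    return (np.sum(s > d) + 0.5 * np.sum(s == d)) / (s.size * d.size)


@pytest.mark.parametrize(
    "table,expected",
    [
        (EXPERT, (0.7689, 0.8817, 0.8609, 0.8003, 0.8267)),
        (NOVICE, (0.7029, 0.4787, 0.5621, 0.6286, 0.5881)),
        (BinaryTable(10, 0, 0, 10), (1.0, 1.0, 1.0, 1.0, 1.0)),
    ],
)
def test_binary_rates_and_predictive_values(table, expected):
    ms = rates_and_predictive_values(table)
    got = (ms.sensitivity, ms.specificity, ms.ppv, ms.npv, ms.proportion_correct)
    assert got == pytest.approx(expected, abs=5e-5)


def test_zero_denominator_yields_marker_not_number():
    ms = rates_and_predictive_values(BinaryTable(0, 0, 3, 7))
    assert math.isnan(ms.sensitivity)
    assert ms.specificity == 0.7


def test_ternary_predictive_values_expert_table():
    ms = ternary_predictive_values(EXPERT_TERNARY)
    assert ms.sensitivity == pytest.approx(0.6971, abs=5e-5)
    assert ms.specificity == pytest.approx(0.7763, abs=5e-5)
    assert ms.ppv == pytest.approx(0.8930, abs=5e-5)
    assert ms.npv == pytest.approx(0.8284, abs=5e-5)
    assert ms.ippv == pytest.approx(0.4694, abs=5e-5)
    assert ms.inpv == pytest.approx(0.5306, abs=5e-5)


def test_ternary_without_inconclusives_matches_binary():
    t = TernaryTable(10, 3, 0, 2, 9, 0)
    tv = ternary_predictive_values(t)
    bv = rates_and_predictive_values(t.collapse())
    for f in ("sensitivity", "specificity", "ppv", "npv"):
        assert getattr(tv, f) == getattr(bv, f)
    assert math.isnan(tv.ippv) and math.isnan(tv.inpv)


def test_balanced_inconclusives_split_evenly():
    tv = ternary_predictive_values(TernaryTable(5, 2, 4, 1, 6, 4))
    assert tv.ippv == tv.inpv == 0.5


@pytest.mark.parametrize(
    "table,method,expected_h,expected_f",
    [
        # rate of 1 replaced by (n - 0.5)/n, rate of 0 by 0.5/n
        (BinaryTable(12, 0, 0, 12), "macmillan_kaplan", 11.5 / 12, 0.5 / 12),
        # log-linear transforms every rate as (count + 0.5)/(n + 1)
        (BinaryTable(12, 0, 0, 12), "loglinear", 12.5 / 13, 0.5 / 13),
        (BinaryTable(6, 6, 3, 9), "macmillan_kaplan", 0.5, 0.25),
        (BinaryTable(6, 6, 3, 9), "none", 0.5, 0.25),
    ],
)
def test_extreme_rate_corrections(table, method, expected_h, expected_f):
    pair = correct_rates(table, method)
    assert pair.hit_rate == pytest.approx(expected_h, abs=1e-12)
    assert pair.fa_rate == pytest.approx(expected_f, abs=1e-12)


def test_proportion_correct_table_values():
    assert proportion_correct(EXPERT) == pytest.approx(873 / 1056)
    assert proportion_correct(NOVICE) == pytest.approx(621 / 1056)
    assert proportion_correct(BinaryTable(0, 5, 5, 0)) == 0.0


def test_diagnosticity_ratio_published_values():
    assert diagnosticity_ratio(correct_rates(EXPERT, "none")) == pytest.approx(
        6.50, abs=5e-3
    )
    assert diagnosticity_ratio(correct_rates(NOVICE, "none")) == pytest.approx(
        1.35, abs=5e-3
    )
    assert diagnosticity_ratio(RatePair(0.4, 0.4, 10, 10)) == 1.0
    assert math.isnan(diagnosticity_ratio(RatePair(0.4, 0.0, 10, 10)))


def test_d_prime_values():
    assert d_prime(RatePair(0.8413, 0.1587, 100, 100)) == pytest.approx(2.0, abs=1e-3)
    assert d_prime(RatePair(0.5, 0.5, 10, 10)) == 0.0
    # aggregate expert rates, uncorrected
    assert d_prime(correct_rates(EXPERT, "none")) == pytest.approx(1.92, abs=5e-3)
    with pytest.raises(ValueError):
        d_prime(RatePair(1.0, 0.2, 10, 10))


@pytest.mark.parametrize(
    "h,f,expected",
    [
        (1.0, 0.0, 1.0),
        (0.3, 0.3, 0.5),
        (0.9, 0.9, 0.5),
        # hand-evaluated F <= 0.5 <= H branch: 3/4 + (H-F)/4 - F(1-H)
        (0.75, 0.25, 0.8125),
    ],
)
def test_a_prime_values(h, f, expected):
    assert a_prime(h, f) == pytest.approx(expected, abs=1e-12)


@given(st.floats(0, 1), st.floats(0, 1))
def test_a_prime_bounds_and_reflection(h, f):
    a = a_prime(h, f)
    assert 0.0 <= a <= 1.0
    assert a_prime(f, h) == pytest.approx(1.0 - a, abs=1e-12)
    if h > f:
        assert a >= 0.5


@pytest.mark.parametrize(
    "same,diff,expected",
    [
        ([12, 12, 12], [1, 1, 1], 1.0),
        ([3, 7, 9], [3, 7, 9], 0.5),
        ([8, 10, 6], [4, 7, 6], 7.5 / 9),  # brute-force over the 9 ordered pairs
    ],
)
def test_empirical_auc_examples(same, diff, expected):
    assert empirical_auc(same, diff) == pytest.approx(expected, abs=1e-12)


def test_empirical_auc_rejects_empty_lists():
    with pytest.raises(ValueError):
        empirical_auc([], [1.0])


@given(
    st.lists(st.integers(1, 12), min_size=1, max_size=25),
    st.lists(st.integers(1, 12), min_size=1, max_size=25),
)
def test_auc_equals_pairwise_statistic_and_sklearn(same, diff):
    """The trapezoidal ROC area equals the Mann-Whitney pairwise statistic and
    the independent sklearn implementation."""
    auc = empirical_auc(same, diff)
    assert auc == pytest.approx(brute_force_auc(same, diff), abs=1e-12)
    y = [1] * len(same) + [0] * len(diff)
    assert auc == pytest.approx(roc_auc_score(y, same + diff), abs=1e-10)
    # antisymmetry under swapping signal and noise
    assert empirical_auc(diff, same) == pytest.approx(1.0 - auc, abs=1e-12)


@st.composite
def binary_tables(draw):
    return BinaryTable(
        hits=draw(st.integers(0, 12)),
        misses=draw(st.integers(0, 12)),
        false_alarms=draw(st.integers(0, 12)),
        correct_rejections=draw(st.integers(0, 12)),
    )


@given(binary_tables(), st.sampled_from(["macmillan_kaplan", "loglinear"]))
def test_corrections_remove_degeneracy(table, method):
    """With either correction active, d' and the diagnosticity ratio are finite
    for every possible table, and corrected rates are strictly inside (0, 1)."""
    if table.n_same == 0 or table.n_diff == 0:
        return
    pair = correct_rates(table, method)
    assert 0.0 < pair.hit_rate < 1.0
    assert 0.0 < pair.fa_rate < 1.0
    assert math.isfinite(d_prime(pair))
    assert math.isfinite(diagnosticity_ratio(pair))
    # antisymmetry of d'
    assert d_prime(
        RatePair(pair.fa_rate, pair.hit_rate, pair.n_noise, pair.n_signal)
    ) == pytest.approx(-d_prime(pair), abs=1e-12)


def test_balanced_pc_is_mean_of_sens_and_spec():
    t = BinaryTable(9, 3, 5, 7)  # 12 + 12 trials
    ms = rates_and_predictive_values(t)
    assert ms.proportion_correct == pytest.approx(
        (ms.sensitivity + ms.specificity) / 2
    )


def _records(pid, ratings_same, ratings_diff, group="g"):
    rows = [(pid, group, f"s{i}", SAME, float(r)) for i, r in enumerate(ratings_same)]
    rows += [
        (pid, group, f"d{i}", DIFFERENT, float(r)) for i, r in enumerate(ratings_diff)
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "trial_id", "truth", "rating"]
    )


def test_participant_metrics_perfect_performer():
    df = _records("p", [12] * 12, [1] * 12)
    ms = participant_metrics(df)
    assert ms.proportion_correct == 1.0
    assert ms.auc == 1.0
    assert ms.a_prime == 1.0
    expected_d = d_prime(correct_rates(BinaryTable(12, 0, 0, 12)))
    assert ms.d_prime == pytest.approx(expected_d)


def test_participant_metrics_at_chance():
    df = _records("p", [8, 8, 2, 2], [8, 8, 2, 2])
    ms = participant_metrics(df)
    assert ms.proportion_correct == 0.5
    assert ms.d_prime == 0.0
    assert ms.a_prime == 0.5
    assert ms.auc == 0.5


def test_participant_metrics_composition_oracle():
    """participant_metrics equals tabulate -> rates -> each model composed
    manually, on random fixtures."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        same = rng.integers(1, 13, size=rng.integers(2, 15))
        diff = rng.integers(1, 13, size=rng.integers(2, 15))
        df = _records("p", same, diff)
        ms = participant_metrics(df, correction="macmillan_kaplan")
        table = tabulate(df)
        rv = rates_and_predictive_values(table)
        pair = correct_rates(table, "macmillan_kaplan")
        assert ms.proportion_correct == pytest.approx(proportion_correct(table))
        assert ms.sensitivity == pytest.approx(rv.sensitivity)
        assert ms.specificity == pytest.approx(rv.specificity)
        assert ms.d_prime == pytest.approx(d_prime(pair))
        assert ms.diagnosticity == pytest.approx(diagnosticity_ratio(pair))
        assert ms.a_prime == pytest.approx(a_prime(rv.sensitivity, 1 - rv.specificity))
        assert ms.auc == pytest.approx(empirical_auc(same, diff))


def test_exclusion_can_empty_a_class_leaving_markers():
    df = _records("p", [6.6, 6.8], [2, 3, 10])
    ms = participant_metrics(df, window=(6.0, 7.0), policy="exclude")
    assert math.isnan(ms.sensitivity)
    assert math.isnan(ms.auc)
    # different-source trials remain scoreable
    assert ms.specificity == pytest.approx(2 / 3)


def test_midpoint_policy_half_credit():
    # 2 same trials inconclusive, 2 same hits, 2 diff CRs, 2 diff inconclusive
    df = _records("p", [10, 10, 6.5, 6.5], [2, 2, 7, 7])
    ms = participant_metrics(df, window=(6.0, 7.0), policy="midpoint")
    assert ms.proportion_correct == pytest.approx((2 + 2 + 0.5 * 4) / 8)
    assert ms.sensitivity == pytest.approx((2 + 1) / 4)
    assert ms.specificity == pytest.approx((2 + 1) / 4)
    assert ms.ippv == 0.5 and ms.inpv == 0.5
    # AUC computed on ratings with inconclusive values replaced by 6.5
    assert ms.auc == pytest.approx(
        empirical_auc([10, 10, 6.5, 6.5], [2, 2, 6.5, 6.5]), abs=1e-12
    )


def test_metrics_table_matches_single_participant_route(small_dataset):
    mt = metrics_table(small_dataset)
    one = small_dataset[
        (small_dataset["replicate"] == 0)
        & (small_dataset["participant_id"] == "expert-01")
    ]
    ms = participant_metrics(one)
    row = mt[
        (mt["replicate"] == 0) & (mt["participant_id"] == "expert-01")
    ].iloc[0]
    for name, value in ms.as_dict().items():
        if math.isnan(value):
            assert math.isnan(row[name])
        else:
            assert row[name] == pytest.approx(value)


def test_metrics_table_pooled_mode(expert_records):
    pooled = metrics_table(expert_records, unit="group")
    assert len(pooled) == 1
    assert pooled.iloc[0]["proportion_correct"] == pytest.approx(873 / 1056)
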