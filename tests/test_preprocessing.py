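"""Contracts of the preprocessing stages, checked against hand computations
and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from ratioage import (
    filter_batch_missingness,
    fourth_root,
    impute_missing,
    quantile_normalize,
    remove_pca_outliers,
    row_normalize,
    select_robust_features,
    split_data,
)
from tests.conftest import make_table


# ---------------------------------------------------------------------------
# fourth root


def test_fourth_root_values():
    table = make_table([[16.0, 0.0, 81.0]])
    out = fourth_root(table)
    assert out.values().tolist() == [[2.0, 0.0, 3.0]]


def test_fourth_root_preserves_missingness():
    table = make_table([[16.0, np.nan], [1.0, 4.0]])
    out = fourth_root(table)
    assert np.isnan(out.values()[0, 1])
    assert out.values()[1, 1] == pytest.approx(np.sqrt(2))


def test_fourth_root_rejects_negative():
    values = np.array([[1.0, 2.0]])
    table = make_table(values)
    table.intensities.iloc[0, 0] = -1.0  # bypass constructor check
    with pytest.raises(ValueError, match="non-negative"):
        fourth_root(table)


def test_fourth_root_preserves_ranks_hence_robust_selection(noisy_cohort):
    table, _ = noisy_cohort
    before = select_robust_features(table)
    after = select_robust_features(fourth_root(table))
    assert before.ids == after.ids


# ---------------------------------------------------------------------------
# batch missingness filter


def _brute_force_missingness(table, threshold):
    removed = []
    for fid in table.feature_ids:
        for batch in table.batches.unique():
            col = table.intensities.loc[table.batches == batch, fid]
            if col.isna().mean() > threshold:
                removed.append(fid)
                break
    return removed


def test_missingness_strictly_above_threshold_removed():
    # feature 0: missing 2/5 (40%) in batch B0 -> removed
    # feature 1: missing exactly 1/5 (20%) in both batches -> kept (strict >)
    values = np.ones((10, 3))
    values[0, 0] = values[1, 0] = np.nan
    values[0, 1] = values[5, 1] = np.nan
    table = make_table(values, batches=["B0"] * 5 + ["B1"] * 5)
    filtered, removed = filter_batch_missingness(table, threshold=0.20)
    assert removed == [table.feature_ids[0]]
    assert filtered.n_features == 2
    assert removed == _brute_force_missingness(table, 0.20)


def test_no_missing_values_means_no_removals(noisy_cohort):
    table, _ = noisy_cohort
    complete = table.with_intensities(np.nan_to_num(table.values(), nan=1.0))
    _, removed = filter_batch_missingness(complete)
    assert removed == []


def test_missingness_filter_matches_brute_force(noisy_cohort):
    table, _ = noisy_cohort
    _, removed = filter_batch_missingness(table, threshold=0.05)
    assert removed == _brute_force_missingness(table, 0.05)


# ---------------------------------------------------------------------------
# PCA outliers


def test_extreme_sample_removed():
    rng = np.random.default_rng(0)
    values = rng.lognormal(2, 0.2, size=(60, 20))
    values[13] *= 100.0
    table = make_table(values)
    _, removed = remove_pca_outliers(table, n_components=5)
    assert removed == [table.sample_ids[13]]


def test_no_removals_when_threshold_infinite():
    rng = np.random.default_rng(1)
    table = make_table(rng.normal(10, 1, size=(50, 15)) ** 2)
    _, removed = remove_pca_outliers(table, n_components=5, k=1e12)
    assert removed == []


def test_single_pass_is_deterministic():
    rng = np.random.default_rng(2)
    values = rng.lognormal(2, 0.3, size=(40, 10))
    values[5] *= 50
    table = make_table(values)
    kept1, removed1 = remove_pca_outliers(table, n_components=3)
    kept2, removed2 = remove_pca_outliers(table, n_components=3)
    assert removed1 == removed2
    # the rule is decided in one pass: a second application runs on the
    # survivors and is a *new* computation, not guaranteed to be a no-op
    _, removed_again = remove_pca_outliers(kept1, n_components=3)
    assert set(removed_again).isdisjoint(removed1)


def test_too_few_features_rejected():
    table = make_table(np.ones((20, 3)) + np.arange(20)[:, None])
    with pytest.raises(ValueError, match="features"):
        remove_pca_outliers(table, n_components=12)


# ---------------------------------------------------------------------------
# robust feature selection


def _brute_force_robust(table, lo=0.20, hi=0.80):
    values = table.values()
    ranks = np.array([rankdata(row) for row in values])
    med = np.median(ranks, axis=0)
    rng_ = ranks.max(axis=0) - ranks.min(axis=0)
    med_lo, med_hi = np.quantile(med, [lo, hi])
    r_lo, r_hi = np.quantile(rng_, [lo, hi])
    sel = (med >= med_lo) & (med <= med_hi) & (rng_ >= r_lo) & (rng_ <= r_hi)
    return [table.feature_ids[j] for j in range(len(sel)) if sel[j]]


def test_toy_selection_matches_hand_enumeration():
    values = np.array(
        [
            [1.0, 5.0, 3.0, 2.0, 9.0, 4.0],
            [2.0, 6.0, 3.0, 1.0, 9.0, 5.0],
            [1.0, 7.0, 4.0, 2.0, 9.0, 3.0],
            [2.0, 5.0, 4.0, 1.0, 9.0, 3.0],
        ]
    )
    table = make_table(values)
    result = select_robust_features(table)
    assert result.ids == _brute_force_robust(table)
    # every selected feature satisfies both criteria by construction
    b = result.quantile_bounds
    assert result.median_ranks.between(*b["median_rank_bounds"]).all()
    assert result.rank_ranges.between(*b["rank_range_bounds"]).all()


def test_random_tables_match_brute_force():
    rng = np.random.default_rng(4)
    for _ in range(5):
        table = make_table(rng.lognormal(0, 1, size=(12, 9)))
        assert select_robust_features(table).ids == _brute_force_robust(table)


def test_all_tied_features_all_selected():
    # every rank tied at (p+1)/2, every range 0: with inclusive bounds all
    # features sit exactly on the quantiles, so all are selected
    table = make_table(np.ones((4, 6)))
    assert select_robust_features(table).ids == list(table.feature_ids)


def test_always_maximal_feature_excluded_by_median_criterion():
    rng = np.random.default_rng(5)
    values = rng.uniform(1, 2, size=(30, 9))
    values[:, 0] = 100.0  # always the top rank; range 0 but median rank = p
    table = make_table(values)
    result = select_robust_features(table)
    assert table.feature_ids[0] not in result.ids


def test_too_few_features_for_selection():
    with pytest.raises(ValueError, match="5 features"):
        select_robust_features(make_table(np.ones((3, 4))))


# ---------------------------------------------------------------------------
# row normalization


def _robust_set(ids):
    from ratioage import RobustFeatureSet

    return RobustFeatureSet(
        ids=list(ids),
        median_ranks=pd.Series(0.0, index=list(ids)),
        rank_ranges=pd.Series(0.0, index=list(ids)),
    )


def test_row_normalize_hand_computation(toy_table):
    robust = _robust_set(toy_table.feature_ids[:2])  # anchor on first two features
    out = row_normalize(toy_table, robust)
    sums = toy_table.values()[:, :2].sum(axis=1)
    assert np.allclose(out.values(), toy_table.values() / sums[:, None])
    assert np.allclose(out.values()[:, :2].sum(axis=1), 1.0)


def test_row_normalize_cancels_sample_scaling(noisy_cohort):
    table, _ = noisy_cohort
    robust = select_robust_features(table)
    rng = np.random.default_rng(6)
    scales = rng.uniform(0.2, 5.0, size=table.n_samples)
    scaled = table.with_intensities(table.values() * scales[:, None])
    a = row_normalize(table, robust).values()
    b = row_normalize(scaled, robust).values()
    ok = ~np.isnan(a)
    assert np.allclose(a[ok], b[ok], rtol=1e-12, atol=0)


def test_row_normalize_scalar_multiple_rows_become_identical():
    table = make_table([[1.0, 2.0, 3.0, 4.0, 5.0], [3.0, 6.0, 9.0, 12.0, 15.0]])
    robust = select_robust_features(table)
    out = row_normalize(table, robust).values()
    assert np.allclose(out[0], out[1], rtol=1e-12)


def test_row_normalize_zero_sum_names_sample():
    table = make_table([[0.0, 0.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0, 1.0]])
    robust = _robust_set(table.feature_ids[:2])
    with pytest.raises(ValueError, match="S0"):
        row_normalize(table, robust)


# ---------------------------------------------------------------------------
# quantile normalization


def test_quantile_normalize_two_sample_example():
    table = make_table([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    out = quantile_normalize(table).values()
    assert np.allclose(out, [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])


def test_quantile_normalize_respects_within_sample_order():
    table = make_table([[3.0, 1.0, 2.0], [10.0, 30.0, 20.0]])
    out = quantile_normalize(table).values()
    assert np.allclose(np.sort(out[0]), np.sort(out[1]))
    assert np.argsort(out[0]).tolist() == [1, 2, 0]
    assert np.argsort(out[1]).tolist() == [0, 2, 1]


def test_quantile_normalize_identical_samples_unchanged():
    table = make_table([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]])
    assert np.allclose(quantile_normalize(table).values(), table.values())


def test_quantile_normalize_idempotent(noisy_cohort):
    table, _ = noisy_cohort
    complete = impute_missing(table)
    once = quantile_normalize(complete)
    twice = quantile_normalize(once)
    assert np.allclose(once.values(), twice.values(), rtol=1e-12)


def test_quantile_normalize_ties_averaged():
    table = make_table([[1.0, 1.0, 5.0], [2.0, 4.0, 6.0]])
    out = quantile_normalize(table).values()
    # tied values share the average of their tied positions' reference values
    assert out[0, 0] == out[0, 1]
    assert np.allclose(out.sum(axis=1), out.sum(axis=1)[0])


def test_quantile_normalize_requires_complete_data():
    table = make_table([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(ValueError, match="complete"):
        quantile_normalize(table)


# ---------------------------------------------------------------------------
# imputation


def test_impute_uses_batch_minimum():
    values = np.array([[1.0, 10.0], [np.nan, 20.0], [5.0, np.nan], [7.0, 40.0]])
    table = make_table(values, batches=["B0", "B0", "B1", "B1"])
    out = impute_missing(table).values()
    assert out[1, 0] == 1.0  # batch B0 minimum of feature 0
    assert out[2, 1] == 40.0  # batch B1 minimum of feature 1
    half = impute_missing(table, half_minimum=True).values()
    assert half[1, 0] == 0.5


# ---------------------------------------------------------------------------
# partitioning


def test_split_sizes_and_coverage(noisy_cohort):
    table, _ = noisy_cohort
    split = split_data(table, (0.8, 0.1, 0.1), seed=0)
    assert len(split.train_ids) == 320
    assert len(split.dev_ids) == 40
    assert len(split.test_ids) == 40
    split.validate(table.sample_ids)


def test_split_deterministic_and_seed_sensitive(noisy_cohort):
    table, _ = noisy_cohort
    a = split_data(table, seed=5)
    b = split_data(table, seed=5)
    assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
    differing = sum(
        split_data(table, seed=s).train_ids != split_data(table, seed=s + 100).train_ids
        for s in range(10)
    )
    assert differing == 10


def test_split_rejects_bad_fractions(noisy_cohort):
    table, _ = noisy_cohort
    with pytest.raises(ValueError, match="sum to 1"):
        split_data(table, (0.8, 0.1, 0.2), seed=0)
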