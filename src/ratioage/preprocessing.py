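"""Preprocessing for QC-less untargeted feature tables.

The stages, in pipeline order: fourth-root variance stabilization, sex filter,
PCA-based sample outlier removal, batch-wise missingness filter, robust-subset
row normalization, quantile normalization (optional alternative), and the
train/development/test partition.

Design notes
------------
* Rank computations use average ("fractional") ranks so tied intensities get
  a continuous statistic; all quantiles use linear interpolation between order
  statistics.
* The PCA outlier rule flags a sample when, on any of the first
  ``n_components`` score vectors, its absolute deviation from the component
  median exceeds ``k`` times the ``q``-th quantile of those absolute
  deviations.  An alternative reading — threshold on the quantile of the raw
  scores rather than of the deviations — is exposed via
  ``deviation_quantile=False``.  The rule is applied in a single pass.
* Missing values are imputed (where a stage requires complete data) with the
  per-feature, per-batch minimum observed value; ``half_minimum=True`` halves
  it.  Features unobserved in an entire batch fall back to the global
  per-feature minimum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .table import FeatureTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transforms


def fourth_root(table: FeatureTable) -> FeatureTable:
    """Replace every non-missing intensity by its principal fourth root.

    A stronger-than-sqrt variance stabilizer for peak intensities spanning
    orders of magnitude; monotone, so it does not affect any rank-based stage.
    """
    values = table.values()
    with np.errstate(invalid="ignore"):
        if (values < 0).any():
            raise ValueError("fourth_root requires non-negative intensities")
    return table.with_intensities(values**0.25)


def filter_sex(table: FeatureTable, keep: str = "M") -> tuple[FeatureTable, list]:
    """Drop samples whose sex differs from ``keep`` (confounder control)."""
    keep_ids = table.sample_ids[table.sample_meta["sex"] == keep]
    removed = table.sample_ids.difference(keep_ids).tolist()
    logger.info("sex filter: %d samples removed, %d kept", len(removed), len(keep_ids))
    return table.select_samples(keep_ids), removed


def filter_batch_missingness(
    table: FeatureTable, threshold: float = 0.20
) -> tuple[FeatureTable, list]:
    """Remove features whose missing fraction strictly exceeds ``threshold``
    in at least one batch.

    A feature that cannot be measured reliably in some analytical batch is
    unusable for cross-batch modelling even if globally well observed.
    """
    batches = table.batches
    if (batches.value_counts() == 0).any():
        raise ValueError("empty batch encountered")
    miss = table.intensities.isna().groupby(batches, observed=True).mean()
    removed_mask = (miss > threshold).any(axis=0)
    removed = table.feature_ids[removed_mask].tolist()
    kept = table.feature_ids[~removed_mask]
    logger.info(
        "batch-missingness filter (> %.0f%% in any batch): %d features removed, %d kept",
        100 * threshold, len(removed), len(kept),
    )
    return table.select_features(kept), removed


def impute_missing(
    table: FeatureTable, half_minimum: bool = False
) -> FeatureTable:
    """Fill NaNs with the per-feature, per-batch minimum observed value."""
    values = table.intensities
    if not values.isna().to_numpy().any():
        return table.copy()
    fill = values.groupby(table.batches, observed=True).transform("min")
    global_min = values.min(axis=0)
    fill = fill.fillna(global_min)
    if half_minimum:
        fill = fill / 2
    out = values.fillna(fill)
    if out.isna().to_numpy().any():
        raise ValueError("fully-missing feature cannot be imputed")
    return table.with_intensities(out)


def remove_pca_outliers(
    table: FeatureTable,
    n_components: int = 12,
    k: float = 1.5,
    q: float = 0.95,
    deviation_quantile: bool = True,
) -> tuple[FeatureTable, list]:
    """Single-pass removal of samples extreme in any leading PCA component.

    A sample is removed iff for some component c among the first
    ``n_components``, ``|score_c - median(score_c)| > k * Q_q`` where ``Q_q``
    is the q-th quantile of the absolute deviations (default) or of the raw
    scores (``deviation_quantile=False``).
    """
    if table.n_features < n_components:
        raise ValueError(
            f"need at least {n_components} features for {n_components} components"
        )
    if table.n_samples < n_components + 1:
        raise ValueError("need more samples than components")
    values = impute_missing(table).values()
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(values)
    dev = np.abs(scores - np.median(scores, axis=0))
    if deviation_quantile:
        cut = k * np.quantile(dev, q, axis=0)
    else:
        cut = k * np.quantile(scores, q, axis=0)
    outlier = (dev > cut).any(axis=1)
    removed = table.sample_ids[outlier].tolist()
    kept = table.sample_ids[~outlier]
    logger.info("PCA outlier filter: %d samples removed, %d kept", len(removed), len(kept))
    return table.select_samples(kept), removed


# ---------------------------------------------------------------------------
# robust-subset row normalization


@dataclass
class RobustFeatureSet:
    """Features whose within-sample rank is both central and stable.

    Selected iff (a) the median of the feature's within-sample ranks lies
    between the ``lower_q`` and ``upper_q`` quantiles of all features' median
    ranks, and (b) its max-min rank range lies between the same quantiles of
    all features' rank ranges (bounds inclusive).
    """

    ids: list
    median_ranks: pd.Series
    rank_ranges: pd.Series
    quantile_bounds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ids": list(self.ids),
                    "median_ranks": self.median_ranks.to_dict(),
                    "rank_ranges": self.rank_ranges.to_dict(),
                    "quantile_bounds": self.quantile_bounds,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "RobustFeatureSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            ids=d["ids"],
            median_ranks=pd.Series(d["median_ranks"]),
            rank_ranges=pd.Series(d["rank_ranges"]),
            quantile_bounds=d["quantile_bounds"],
        )


def select_robust_features(
    table: FeatureTable, lower_q: float = 0.20, upper_q: float = 0.80
) -> RobustFeatureSet:
    """Pick the rank-stable feature subset used as a row-normalization anchor.

    Ranks are average ranks of intensities within each sample (missing values
    excluded from the ranking).  When all features are tied everywhere, every
    feature has an identical (median rank, range) pair equal to the quantile
    bounds, and the inclusive-bounds rule deterministically selects *all*
    features.
    """
    if table.n_features < 5:
        raise ValueError("need at least 5 features to select a robust subset")
    if table.intensities.notna().sum(axis=0).eq(0).any():
        raise ValueError("fully-missing feature present")
    # rank features within each sample; pandas `rank` leaves NaN unranked
    ranks = table.intensities.rank(axis=1, method="average")
    median_ranks = ranks.median(axis=0)
    rank_ranges = ranks.max(axis=0) - ranks.min(axis=0)
    med_lo, med_hi = np.quantile(median_ranks, [lower_q, upper_q])
    rng_lo, rng_hi = np.quantile(rank_ranges, [lower_q, upper_q])
    selected = (
        median_ranks.between(med_lo, med_hi) & rank_ranges.between(rng_lo, rng_hi)
    )
    ids = table.feature_ids[selected].tolist()
    logger.info("robust feature selection: %d of %d features", len(ids), table.n_features)
    return RobustFeatureSet(
        ids=ids,
        median_ranks=median_ranks[selected],
        rank_ranges=rank_ranges[selected],
        quantile_bounds={
            "lower_q": lower_q,
            "upper_q": upper_q,
            "median_rank_bounds": [float(med_lo), float(med_hi)],
            "rank_range_bounds": [float(rng_lo), float(rng_hi)],
        },
    )


def row_normalize(table: FeatureTable, robust: RobustFeatureSet) -> FeatureTable:
    """Divide each sample by its summed intensity over the robust subset.

    Cancels per-sample multiplicative effects (dilution, injection volume)
    exactly: scaling a sample by c > 0 leaves its normalized row unchanged.
    """
    robust_ids = pd.Index(robust.ids)
    missing = robust_ids.difference(table.feature_ids)
    if len(missing):
        raise ValueError(f"robust features absent from table: {list(missing)[:5]}")
    sums = table.intensities[robust_ids].sum(axis=1, min_count=1)
    bad = sums.index[(sums <= 0) | sums.isna()]
    if len(bad):
        raise ValueError(f"zero robust-subset sum for sample(s): {bad.tolist()[:5]}")
    return table.with_intensities(table.intensities.div(sums, axis=0))


def quantile_normalize(table: FeatureTable) -> FeatureTable:
    """Force every sample onto the common (mean) intensity distribution.

    After normalization each sample's sorted value vector equals the mean of
    all samples' sorted vectors; tied values receive the average of their tied
    positions' reference values.  Requires complete data.
    """
    values = table.values()
    if np.isnan(values).any():
        raise ValueError("quantile_normalize requires complete data; impute first")
    n, p = values.shape
    reference = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values)
    for i in range(n):
        r = rankdata(values[i], method="average")  # 1..p, ties averaged
        out[i] = np.interp(r, np.arange(1, p + 1), reference)
    return table.with_intensities(out)


# ---------------------------------------------------------------------------
# partitioning


@dataclass
class SplitSpec:
    """Disjoint, exhaustive train/development/test sample-id partition."""

    train_ids: list
    dev_ids: list
    test_ids: list
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def validate(self, sample_ids=None) -> None:
        parts = [set(self.train_ids), set(self.dev_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        union = set().union(*parts)
        if len(union) != total:
            raise ValueError("split partitions overlap")
        if sample_ids is not None and union != set(sample_ids):
            raise ValueError("split does not cover the sample ids")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "train_ids": list(self.train_ids),
                    "dev_ids": list(self.dev_ids),
                    "test_ids": list(self.test_ids),
                    "fractions": list(self.fractions),
                    "seed": self.seed,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "SplitSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            train_ids=d["train_ids"],
            dev_ids=d["dev_ids"],
            test_ids=d["test_ids"],
            fractions=tuple(d["fractions"]),
            seed=d["seed"],
        )


def split_data(
    table: FeatureTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitSpec:
    """Random train/dev/test partition, sizes within 1 of the fraction targets."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = table.n_samples
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_dev = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_dev = min(n_dev, n - n_train)
    ids = table.sample_ids.to_numpy()
    split = SplitSpec(
        train_ids=ids[order[:n_train]].tolist(),
        dev_ids=ids[order[n_train : n_train + n_dev]].tolist(),
        test_ids=ids[order[n_train + n_dev :]].tolist(),
        fractions=tuple(fractions),
        seed=seed,
    )
    split.validate(table.sample_ids)
    return split
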