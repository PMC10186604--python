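"""Feature-wise association with age: Spearman screening, BH-FDR, decile profiles.

The univariate view complements the network: a monotone, tie-robust
correlation per feature, multiplicity-corrected by the Benjamini-Hochberg
step-up, plus an age-decile z-score profile per feature for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import rankdata

from .table import FeatureTable

__all__ = ["CorrelationResult", "spearman_vs_age", "bh_fdr", "decile_profile"]

_EXACT_N = 10  # below this, p-values come from the exact permutation null


@dataclass
class CorrelationResult:
    """Per-feature Spearman rho vs age with BH-adjusted q-values."""

    table: pd.DataFrame  # index feature_id; columns rho, p_value, q_value, n, flagged

    def significant(self, fdr: float = 0.01) -> pd.DataFrame:
        return self.table[self.table["q_value"] <= fdr]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rho with a two-sided p-value.

    Large samples use the t approximation t = rho*sqrt((n-2)/(1-rho^2));
    for n < 10 the p-value is exact, from full enumeration of the rank
    permutation null.
    """
    n = len(x)
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < _EXACT_N:
        idx = np.array(list(permutations(range(n))), dtype=np.int8)
        # rho is affine in sum(rx_perm * ry), so compare on that scale
        null = (rx[idx] @ ry - n * rx.mean() * ry.mean()) / (n * sx * sy)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def spearman_vs_age(table: FeatureTable) -> CorrelationResult:
    """Spearman correlation of every feature with age.

    Missing intensities are pairwise-excluded per feature; features with
    fewer than 3 observed pairs (or constant values) are flagged rather than
    given a correlation.  q-values are BH step-up over the computable
    p-values.
    """
    if "age" not in table.sample_meta.columns or table.sample_meta["age"].isna().all():
        raise ValueError("sample metadata carries no age")
    age = table.ages.to_numpy(dtype=float)
    if len(age) < 3:
        raise ValueError("need at least 3 samples with age")
    rows = []
    for fid in table.feature_ids:
        x = table.intensities[fid].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(age)
        n_ok = int(ok.sum())
        if n_ok < 3:
            rows.append((fid, np.nan, np.nan, n_ok, True))
            continue
        rho, p = _spearman(x[ok], age[ok])
        rows.append((fid, rho, p, n_ok, not np.isfinite(p)))
    out = pd.DataFrame(
        rows, columns=["feature_id", "rho", "p_value", "n", "flagged"]
    ).set_index("feature_id")
    out["q_value"] = np.nan
    computable = out.index[~out["flagged"]]
    if len(computable):
        out.loc[computable, "q_value"] = bh_fdr(out.loc[computable, "p_value"].to_numpy())
    return CorrelationResult(table=out)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def decile_profile(
    table: FeatureTable, feature_ids=None, n_bins: int = 10
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean intensity per age decile, standardized to z-scores per feature.

    Deciles are sample-count quantile bins of age.  Per feature the decile
    means are centered and scaled (SD over the deciles, denominator n-1) to a
    z-profile; constant features yield zero profiles and are flagged.  The
    returned frame is ordered by hierarchical clustering of the profiles
    (average linkage on euclidean distance) for heatmap display.

    Returns ``(profiles, flagged)``: profiles indexed by feature with one
    column per decile, and a boolean flag series.
    """
    if table.n_samples < n_bins:
        raise ValueError(f"need at least {n_bins} samples")
    ids = list(feature_ids) if feature_ids is not None else list(table.feature_ids)
    age = table.ages
    deciles = pd.qcut(age.rank(method="first"), n_bins, labels=False)
    means = (
        table.intensities[ids]
        .groupby(deciles.to_numpy(), observed=True)
        .mean()
    )  # bins x features
    centered = means - means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    flagged = sd == 0
    sd_safe = sd.replace(0, 1.0)
    z = (centered / sd_safe).T  # features x bins
    z.loc[flagged[flagged].index] = 0.0
    z.columns = [f"decile_{c + 1}" for c in z.columns]
    z.index.name = "feature_id"
    if len(ids) > 2:
        order = leaves_list(linkage(z.to_numpy(), method="average"))
        z = z.iloc[order]
    flagged = flagged.reindex(z.index)
    flagged.name = "constant"
    return z, flagged
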