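"""Model-agnostic feature attribution for the ensemble.

Local importance is a Shapley value: the attribution of feature ``i`` for one
sample is the average, over orderings of the features, of how much the model
output moves when ``i``'s value is switched from a background value to the
sample's value.  Positive attribution means the feature's intensity pushes the
predicted age *up* relative to the background expectation.

Two estimators are provided behind one interface:

* exact subset enumeration for small feature counts (the oracle — cost
  2^p model evaluations), and
* antithetic permutation sampling for real tables: each sampled feature
  ordering is walked forwards and backwards, replacing background values by
  the sample's values one feature at a time and averaging the model output
  over the whole background set at every step.  The telescoping sum makes
  additivity exact: baseline + row sum = model prediction for every sample,
  whatever the number of permutations.

Per-member attribution matrices are averaged elementwise into an ensemble
matrix; global importance of a feature is the variance of its attribution
column (samples with near-zero attribution everywhere contribute nothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .table import FeatureTable

__all__ = [
    "AttributionMatrix",
    "attribute_member",
    "attribute_ensemble",
    "average_attributions",
    "global_importance",
    "shap_intensity_concordance",
]


@dataclass
class AttributionMatrix:
    """samples x features signed attributions, in years of predicted-age shift."""

    values: pd.DataFrame
    baseline: float
    member: str = "ensemble-mean"

    def check_additivity(self, predictions, tol: float) -> None:
        """baseline + row sums must reconstruct the predictions within tol."""
        recon = self.baseline + self.values.sum(axis=1).to_numpy()
        err = np.max(np.abs(recon - np.asarray(predictions, dtype=float)))
        if err > tol:
            raise AssertionError(f"additivity violated: max error {err:.3g} > {tol:.3g}")


def _as_matrix(data) -> tuple[np.ndarray, list, list]:
    if isinstance(data, FeatureTable):
        x = data.values()
        if np.isnan(x).any():
            raise ValueError("attribution requires complete data; impute first")
        return x, list(data.sample_ids), list(data.feature_ids)
    x = np.asarray(data, dtype=float)
    return x, list(range(len(x))), list(range(x.shape[1]))


def _as_function(model):
    if callable(model):
        return model
    if hasattr(model, "predict"):
        return lambda x: np.asarray(model.predict(x), dtype=float).ravel()
    raise TypeError("model must be callable or expose .predict")


def attribute_member(
    model,
    background,
    samples,
    n_permutations: int = 4,
    exact_threshold: int = 12,
    seed: int = 0,
    member: str = "member",
) -> AttributionMatrix:
    """Shapley attributions of one model on the given samples.

    ``model`` is any callable / ``.predict`` object mapping a (batch, p) array
    to predictions.  With p <= ``exact_threshold`` features the exact
    enumeration is used; otherwise ``n_permutations`` antithetic permutation
    walks (must be even).  The baseline is the mean model output over the
    background set.
    """
    f = _as_function(model)
    bg, _, bg_features = _as_matrix(background)
    x, sample_ids, feature_ids = _as_matrix(samples)
    if bg.shape[1] != x.shape[1]:
        raise ValueError("background and samples have different feature counts")
    if bg.shape[0] == 0:
        raise ValueError("background must be non-empty")
    p = x.shape[1]
    if p <= exact_threshold:
        phi, baseline = _exact_shapley(f, x, bg)
    else:
        if n_permutations < 2 or n_permutations % 2:
            raise ValueError("n_permutations must be an even number >= 2")
        phi, baseline = _permutation_shapley(f, x, bg, n_permutations, seed)
    return AttributionMatrix(
        values=pd.DataFrame(phi, index=pd.Index(sample_ids), columns=feature_ids),
        baseline=baseline,
        member=member,
    )


def _coalition_values(f, x, bg, p):
    """v(S) for every coalition S (bitmask-indexed), per explained sample."""
    s, b = x.shape[0], bg.shape[0]
    values = np.empty((2**p, s))
    z = np.tile(bg, (s, 1))  # rows: sample-major blocks of the background
    for mask in range(2**p):
        z[...] = np.tile(bg, (s, 1))
        for i in range(p):
            if mask >> i & 1:
                z[:, i] = np.repeat(x[:, i], b)
        values[mask] = f(z).reshape(s, b).mean(axis=1)
    return values


def _exact_shapley(f, x, bg):
    p = x.shape[1]
    v = _coalition_values(f, x, bg, p)
    phi = np.zeros_like(x)
    fact_w = [1.0 / (p * comb(p - 1, k)) for k in range(p)]
    for mask in range(2**p):
        size = bin(mask).count("1")
        for i in range(p):
            if not mask >> i & 1:
                phi[:, i] += fact_w[size] * (v[mask | (1 << i)] - v[mask])
    baseline = float(v[0].mean())
    # v(empty) is identical for every sample; use the per-sample exact value
    return phi, baseline


def _permutation_shapley(f, x, bg, n_permutations, seed):
    s, p = x.shape
    b = bg.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x_rep = np.repeat(x, b, axis=0)
    phi = np.zeros_like(x)
    base_z = np.tile(bg, (s, 1))
    baseline_vals = f(base_z).reshape(s, b).mean(axis=1)
    for _ in range(n_permutations // 2):
        perm = rng.permutation(p)
        for order in (perm, perm[::-1]):
            z = base_z.copy()
            prev = baseline_vals.copy()
            for feat in order:
                z[:, feat] = x_rep[:, feat]
                cur = f(z).reshape(s, b).mean(axis=1)
                phi[:, feat] += cur - prev
                prev = cur
    phi /= n_permutations
    return phi, float(baseline_vals.mean())


def attribute_ensemble(
    model,
    background,
    samples,
    n_permutations: int = 4,
    exact_threshold: int = 12,
    seed: int = 0,
) -> tuple[AttributionMatrix, list[AttributionMatrix]]:
    """Per-member attributions plus their elementwise average.

    All members are explained with the same permutations and background
    (same seed), so the average equals attributing the ensemble-mean function
    directly.
    """
    per_member = [
        attribute_member(
            member, background, samples,
            n_permutations=n_permutations, exact_threshold=exact_threshold,
            seed=seed, member=f"member_{k}",
        )
        for k, member in enumerate(model.members)
    ]
    return average_attributions(per_member), per_member


def average_attributions(matrices: list[AttributionMatrix]) -> AttributionMatrix:
    """Elementwise mean of attribution matrices; baselines averaged likewise."""
    if not matrices:
        raise ValueError("need at least one attribution matrix")
    first = matrices[0].values
    for m in matrices[1:]:
        if m.values.shape != first.shape:
            raise ValueError("attribution matrices have mismatched shapes")
    stacked = np.stack([m.values.to_numpy() for m in matrices])
    return AttributionMatrix(
        values=pd.DataFrame(stacked.mean(axis=0), index=first.index, columns=first.columns),
        baseline=float(np.mean([m.baseline for m in matrices])),
        member="ensemble-mean",
    )


def global_importance(m: AttributionMatrix) -> pd.DataFrame:
    """Per-feature variance of the attribution column, descending.

    Sample variance with denominator n-1; a feature whose attribution never
    varies across samples scores 0.
    """
    if m.values.shape[0] < 2:
        raise ValueError("global importance needs at least 2 samples")
    var = m.values.var(axis=0, ddof=1)
    out = var.sort_values(ascending=False).to_frame("importance")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def shap_intensity_concordance(
    m: AttributionMatrix,
    table: FeatureTable,
    ages=None,
    min_abs_rho: float = 0.1,
) -> pd.DataFrame:
    """Does the model read each feature the way the raw data trend points?

    Per feature: Spearman correlation of attribution vs intensity (over the
    explained samples) and of intensity vs age.  A feature is *concordant*
    when the two correlation signs agree — the model predicts older for
    intensities that rise with age — and *discordant* when they disagree
    (inverse interpretation, e.g. via interactions or normalizing roles).
    Correlations below ``min_abs_rho`` in magnitude are labelled ``weak``;
    constant features are ``incomputable`` rather than dropped.
    """
    ids = m.values.index
    intens = table.intensities.loc[ids, m.values.columns]
    if ages is None:
        ages = table.sample_meta.loc[ids, "age"]
    age = np.asarray(ages, dtype=float)
    rows = []
    for fid in m.values.columns:
        attr = m.values[fid].to_numpy()
        inten = intens[fid].to_numpy(dtype=float)
        ok = ~np.isnan(inten)
        if ok.sum() < 3 or np.nanstd(inten) == 0 or attr.std() == 0:
            rows.append((fid, np.nan, np.nan, 0, 0, "incomputable", False))
            continue
        rho_ai = spearmanr(attr[ok], inten[ok]).statistic
        rho_ia = spearmanr(inten[ok], age[ok]).statistic
        s_ai = int(np.sign(rho_ai)) if abs(rho_ai) >= min_abs_rho else 0
        s_ia = int(np.sign(rho_ia)) if abs(rho_ia) >= min_abs_rho else 0
        if s_ai == 0 or s_ia == 0:
            status, disc = "weak", False
        elif s_ai == s_ia:
            status, disc = "concordant", False
        else:
            status, disc = "discordant", True
        rows.append((fid, rho_ai, rho_ia, s_ai, s_ia, status, disc))
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "rho_attr_intensity", "rho_intensity_age",
            "sign_attr_intensity", "sign_intensity_age", "status", "discordant",
        ],
    ).set_index("feature_id")
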