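"""Synthetic cohorts with the statistical structure of routine LC-MS screening data.

Routine forensic screening data have no pooled QCs, span hundreds of analytical
batches, and carry strong technical variance: multiplicative batch offsets,
per-sample dilution, batch-wise missingness, and a right-skewed donor age
distribution.  This module generates feature tables with exactly that
structure plus a planted minority of age-associated features, so every
downstream stage (filtering, normalization, the ratio network, attribution,
univariate screening) can be validated against a known ground truth.

Generative model, per sample *i*, feature *j*::

    log x_ij = log b_j  +  beta_j * z_i  +  e_ij          (biology + noise)
    x_ij     = exp(log x_ij) * d_i * g_{batch(i), j}      (technical effects)

where ``b_j`` is a feature baseline spanning several orders of magnitude,
``z_i`` the standardized age, ``beta_j`` nonzero only for the planted
informative features (sign per ground truth), ``e_ij`` lognormal feature
noise, ``d_i`` a per-sample dilution factor (lognormal, mean 1, CV =
``dilution_cv``) and ``g`` a per-(batch, feature) multiplicative offset with
log-scale SD ``batch_shift_sd``.  Entries are finally set missing (NaN)
completely at random with a per-(feature, batch) rate drawn from
``missing_rate_range``.

Ages follow a shifted lognormal: ``age = 15 + LogNormal(mu, sigma)`` truncated
to [15, 95], with (mu, sigma) solved in closed form so that the *untruncated*
mean and SD hit ``age_mean``/``age_sd``; the truncation tail mass is
negligible at the default (28.9, 9.2).

Each stochastic component draws from its own child RNG stream spawned from
``seed``, so e.g. setting ``dilution_cv = 0`` changes dilution factors to 1
while leaving every other draw bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .table import FeatureTable

_AGE_SHIFT = 15.0
_AGE_CAP = 95.0


@dataclass
class SyntheticSpec:
    """Full generative description of a simulated cohort."""

    n_samples: int = 1000
    n_features: int = 300
    n_batches: int = 20
    n_informative: int = 20
    age_mean: float = 28.9
    age_sd: float = 9.2
    age_skew: float = 1.0  # >1 stretches the right tail (scales sigma of the lognormal)
    effect_size_range: tuple[float, float] = (0.3, 0.6)  # target |Spearman rho| vs age
    dilution_cv: float = 0.3
    batch_shift_sd: float = 0.5
    missing_rate_range: tuple[float, float] = (0.0, 0.1)
    inverse_fraction: float = 0.3
    feature_noise_sd: float = 0.5  # log-scale SD of e_ij
    male_fraction: float = 0.93
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_batches < 1 or self.n_batches > self.n_samples:
            raise ValueError("n_batches must be in [1, n_samples]")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if self.age_skew <= 0:
            raise ValueError("age_skew must be positive")
        if self.dilution_cv < 0:
            raise ValueError("dilution_cv must be >= 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        lo, hi = self.missing_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("missing_rate_range must be ordered probabilities in [0, 1]")
        if not 0 <= self.inverse_fraction <= 1:
            raise ValueError("inverse_fraction must be a probability in [0, 1]")
        lo, hi = self.effect_size_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("effect_size_range must be ordered values in [0, 1)")
        if self.feature_noise_sd <= 0:
            raise ValueError("feature_noise_sd must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_size_range"] = list(self.effect_size_range)
        d["missing_rate_range"] = list(self.missing_rate_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for key in ("effect_size_range", "missing_rate_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PlantedTruth:
    """Ground truth of the planted age signal: which features, which direction."""

    informative_ids: list = field(default_factory=list)
    signs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    per_feature_effect: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        self.per_feature_effect = np.asarray(self.per_feature_effect, dtype=float)
        n = len(self.informative_ids)
        if len(self.signs) != n or len(self.per_feature_effect) != n:
            raise ValueError("one sign and one effect per informative feature required")
        if n and not np.isin(self.signs, (-1, 1)).all():
            raise ValueError("signs must be +1 or -1")


def _solve_age_params(mean: float, sd: float, skew: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal part so that shift + lognormal hits mean/sd."""
    m = mean - _AGE_SHIFT
    if m <= 0:
        raise ValueError("age_mean must exceed the 15-year distribution shift")
    sigma2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    return mu, float(np.sqrt(sigma2) * skew)


def _draw_ages(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = _solve_age_params(spec.age_mean, spec.age_sd, spec.age_skew)
    ages = _AGE_SHIFT + rng.lognormal(mu, sigma, size=spec.n_samples)
    # resample the (tiny) mass beyond the cap rather than clipping, to avoid a spike
    over = ages > _AGE_CAP
    while over.any():
        ages[over] = _AGE_SHIFT + rng.lognormal(mu, sigma, size=int(over.sum()))
        over = ages > _AGE_CAP
    return ages


def _beta_for_target_rho(target_rho: np.ndarray, noise_sd: float) -> np.ndarray:
    """Log-scale slope giving a target Spearman correlation with age.

    ``log x = beta * z + e`` with z, e independent normals is bivariate normal
    with ``z``; for bivariate normals Spearman's rho relates to Pearson's r by
    rho = (6/pi) * asin(r/2), and monotone transforms (exp, adding the
    baseline) leave Spearman untouched.  Inverting gives the required Pearson
    correlation and hence beta.
    """
    r = 2 * np.sin(np.pi * np.asarray(target_rho) / 6)
    return noise_sd * r / np.sqrt(1 - r**2)


def simulate_cohort(spec: SyntheticSpec) -> tuple[FeatureTable, PlantedTruth]:
    """Generate one cohort plus its planted ground truth.

    Deterministic in ``spec.seed``: the same spec yields a bit-identical table.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(8)
    rng_age, rng_base, rng_plant, rng_noise, rng_dil, rng_batch, rng_miss, rng_meta = (
        np.random.default_rng(s) for s in streams
    )

    n, p = spec.n_samples, spec.n_features
    ages = _draw_ages(spec, rng_age)
    z = (ages - ages.mean()) / ages.std()

    # feature identities: m/z and retention time only label the features
    mz = rng_base.uniform(60, 1200, size=p)
    rt = rng_base.uniform(30, 900, size=p)
    feature_ids = [f"M{mz[j]:.1f}T{rt[j]:.1f}_{j}" for j in range(p)]
    feature_meta = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(feature_ids))

    log_baseline = rng_base.normal(np.log(1e5), 1.5, size=p)

    # planted signal
    informative = rng_plant.choice(p, size=spec.n_informative, replace=False)
    n_inv = int(round(spec.inverse_fraction * spec.n_informative))
    signs = np.ones(spec.n_informative, dtype=int)
    if spec.n_informative:
        inv_idx = rng_plant.choice(spec.n_informative, size=n_inv, replace=False)
        signs[inv_idx] = -1
    effects = rng_plant.uniform(*spec.effect_size_range, size=spec.n_informative)
    beta = np.zeros(p)
    beta[informative] = signs * _beta_for_target_rho(effects, spec.feature_noise_sd)

    log_x = (
        log_baseline[None, :]
        + np.outer(z, beta)
        + rng_noise.normal(0, spec.feature_noise_sd, size=(n, p))
    )

    # per-sample dilution: lognormal with mean 1 and CV = dilution_cv
    if spec.dilution_cv > 0:
        s2 = np.log1p(spec.dilution_cv**2)
        dilution = rng_dil.lognormal(-s2 / 2, np.sqrt(s2), size=n)
    else:
        dilution = np.ones(n)

    # batches assigned in acquisition order (contiguous blocks of samples)
    batch_of = np.minimum((np.arange(n) * spec.n_batches) // n, spec.n_batches - 1)
    batch_offset = np.exp(
        rng_batch.normal(0, 1, size=(spec.n_batches, p)) * spec.batch_shift_sd
    )

    x = np.exp(log_x) * dilution[:, None] * batch_offset[batch_of, :]

    # batch-wise missing completely at random
    lo, hi = spec.missing_rate_range
    rates = rng_miss.uniform(lo, hi, size=(spec.n_batches, p))
    mask = rng_miss.random(size=(n, p)) < rates[batch_of, :]
    x[mask] = np.nan

    sample_ids = pd.Index([f"S{i:05d}" for i in range(n)])
    dates = pd.Timestamp("2017-01-02") + pd.to_timedelta(batch_of * 3, unit="D")
    sex = np.where(rng_meta.random(n) < spec.male_fraction, "M", "F")
    sample_meta = pd.DataFrame(
        {
            "age": ages,
            "batch": [f"B{b:03d}" for b in batch_of],
            "sex": sex,
            "date": dates,
            "dilution": dilution,
        },
        index=sample_ids,
    )

    table = FeatureTable(
        pd.DataFrame(x, index=sample_ids, columns=feature_meta.index),
        sample_meta,
        feature_meta,
    )
    truth = PlantedTruth(
        informative_ids=[feature_ids[j] for j in informative],
        signs=signs,
        per_feature_effect=effects,
    )
    return table, truth


def describe_truth(truth: PlantedTruth) -> pd.DataFrame:
    """One row per planted feature: id, direction of age association, effect size."""
    return pd.DataFrame(
        {
            "feature_id": truth.informative_ids,
            "sign": truth.signs,
            "effect": truth.per_feature_effect,
        }
    )


def write_truth(truth: PlantedTruth, path) -> None:
    describe_truth(truth).to_csv(path, index=False)


def read_truth(path) -> PlantedTruth:
    df = pd.read_csv(path)
    return PlantedTruth(
        informative_ids=df["feature_id"].astype(str).tolist(),
        signs=df["sign"].to_numpy(),
        per_feature_effect=df["effect"].to_numpy(),
    )
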