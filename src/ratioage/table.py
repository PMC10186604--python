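"""The feature table: the universal currency of the pipeline.

An untargeted LC-MS experiment is summarised as a samples x features matrix of
peak intensities plus two metadata frames.  Features are named by their
mass-to-charge ratio and retention time (``M<mz>T<rt>``, e.g. ``M250T142``).
Missing peaks are encoded as NaN — explicitly distinct from zero, because the
batch-missingness filter counts *missing*, not *zero*, intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_META_COLUMNS = ("age", "batch", "sex", "date")
FEATURE_META_COLUMNS = ("mz", "rt")


@dataclass
class FeatureTable:
    """Intensity matrix with aligned sample and feature metadata.

    Parameters
    ----------
    intensities
        samples x features frame of non-negative intensities; the index holds
        sample ids, the columns feature ids, and NaN marks a missing peak.
    sample_meta
        One row per sample (same index as ``intensities``) with at least
        ``age`` (years), ``batch`` (categorical label), ``sex`` and ``date``.
    feature_meta
        One row per feature (index = feature ids) with ``mz`` and ``rt``
        (retention time, seconds).
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = _meta_from_ids(self.intensities.columns)
        self.validate()

    def validate(self) -> None:
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValueError("sample ids of intensities and sample_meta differ")
        if not self.intensities.columns.equals(self.feature_meta.index):
            raise ValueError("feature ids of intensities and feature_meta differ")
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative intensities are not allowed")

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def ages(self) -> pd.Series:
        return self.sample_meta["age"]

    @property
    def batches(self) -> pd.Series:
        return self.sample_meta["batch"]

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.sample_meta.copy(), self.feature_meta.copy()
        )

    def with_intensities(self, values: np.ndarray | pd.DataFrame) -> "FeatureTable":
        """Same metadata, new intensity values (shape must match)."""
        if isinstance(values, pd.DataFrame):
            frame = values
        else:
            frame = pd.DataFrame(
                values, index=self.intensities.index, columns=self.intensities.columns
            )
        return FeatureTable(frame, self.sample_meta.copy(), self.feature_meta.copy())

    def select_samples(self, sample_ids) -> "FeatureTable":
        ids = pd.Index(sample_ids)
        return FeatureTable(
            self.intensities.loc[ids],
            self.sample_meta.loc[ids],
            self.feature_meta.copy(),
        )

    def select_features(self, feature_ids) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        return FeatureTable(
            self.intensities[ids], self.sample_meta.copy(), self.feature_meta.loc[ids]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.intensities.equals(other.intensities)
            and self.sample_meta.equals(other.sample_meta)
            and self.feature_meta.equals(other.feature_meta)
        )


def feature_id(mz: float, rt: float) -> str:
    """Canonical ``M<mz>T<rt>`` identifier, rounded to integers."""
    return f"M{int(round(mz))}T{int(round(rt))}"


def _meta_from_ids(ids: pd.Index) -> pd.DataFrame:
    """Parse m/z and retention time back out of M<mz>T<rt> identifiers."""
    mz, rt = [], []
    for fid in ids:
        try:
            m, t = fid[1:].split("T")
            mz.append(float(m))
            rt.append(float(t))
        except (ValueError, IndexError):
            mz.append(np.nan)
            rt.append(np.nan)
    return pd.DataFrame({"mz": mz, "rt": rt}, index=ids)
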