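"""Reading and writing the feature-table CSV/TSV dialect.

Samples are rows.  Leading columns hold the sample metadata — ``sample_id``,
``age``, ``batch``, ``sex``, ``date`` (plus any extras such as a known
``dilution`` in synthetic cohorts) — and every remaining column is a feature
intensity.  Missing peaks are written as empty cells and read back as NaN;
they are never coerced to zero.  Feature m/z and retention time travel in an
optional sidecar CSV (``<stem>.features.csv``); absent that, they are parsed
from ``M<mz>T<rt>`` column names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .table import FeatureTable, SAMPLE_META_COLUMNS

META_COLUMNS = ("sample_id",) + SAMPLE_META_COLUMNS
_EXTRA_META = ("dilution",)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".features.csv")


def write_feature_table(table: FeatureTable, path, feature_sidecar: bool = True) -> None:
    path = Path(path)
    out = table.sample_meta.copy()
    out.insert(0, "sample_id", table.sample_ids)
    out = pd.concat([out.reset_index(drop=True),
                     table.intensities.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=_sep_for(path), index=False)
    if feature_sidecar:
        table.feature_meta.rename_axis("feature_id").to_csv(_sidecar(path))


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path))
    for col in META_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"malformed header: required metadata column '{col}' missing")
    if raw["sample_id"].duplicated().any():
        dup = raw["sample_id"][raw["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id '{dup}'")
    raw = raw.set_index("sample_id")
    raw.index.name = None  # round-trip fidelity: in-memory tables use bare indexes
    meta_cols = [c for c in SAMPLE_META_COLUMNS + _EXTRA_META if c in raw.columns]
    feature_cols = [c for c in raw.columns if c not in meta_cols]
    intensities = raw[feature_cols]
    for col in feature_cols:
        if not pd.api.types.is_numeric_dtype(intensities[col]):
            bad = intensities[col][pd.to_numeric(intensities[col], errors="coerce").isna()
                                   & intensities[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric intensity in column '{col}', sample '{row}'"
            )
    meta = raw[meta_cols].copy()
    if "date" in meta:
        meta["date"] = pd.to_datetime(meta["date"])
    sidecar = _sidecar(path)
    feature_meta = None
    if sidecar.exists():
        feature_meta = pd.read_csv(sidecar, index_col="feature_id")
        feature_meta = feature_meta.loc[feature_cols]
        feature_meta.index.name = None
    return FeatureTable(intensities.astype(float), meta, feature_meta)
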