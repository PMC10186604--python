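"""End-to-end pipeline: simulate/ingest -> preprocess -> split -> train ->
predict -> explain -> correlate, with a reproducibility manifest.

One global seed expands deterministically into per-stage seeds (and, inside
training, per-member seeds), so a run is reproducible from its manifest alone.
Every artifact lands in ``out_dir`` and is checksummed into ``manifest.json``;
a stage failure leaves a ``<stage>.failed`` marker and aborts with the stage
name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .importance import attribute_ensemble, global_importance, shap_intensity_concordance
from .io import read_feature_table, write_feature_table
from .preprocessing import (
    filter_batch_missingness,
    filter_sex,
    fourth_root,
    impute_missing,
    remove_pca_outliers,
    row_normalize,
    select_robust_features,
    split_data,
)
from .ratio_net import (
    RatioNetConfig,
    predict_ensemble,
    rmse,
    train_ensemble,
)
from .synthetic import SyntheticSpec, simulate_cohort, write_truth
from .univariate import spearman_vs_age

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "split", "train", "predict", "explain", "correlate")


def _strict(cls, d: dict):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class PreprocessParams:
    enabled: bool = True
    fourth_root: bool = True
    sex_filter: str | None = "M"
    pca_outliers: bool = True
    pca_components: int = 12
    pca_k: float = 1.5
    pca_q: float = 0.95
    missingness_threshold: float = 0.20
    row_normalize: bool = True


@dataclass
class TrainParams:
    enabled: bool = True
    k: int = 25
    net: dict = field(default_factory=dict)  # RatioNetConfig overrides


@dataclass
class ExplainParams:
    enabled: bool = True
    background_size: int = 100
    n_permutations: int = 4


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for a full run; unknown keys rejected."""

    out_dir: str = "ratioage_run"
    seed: int = 0
    input_table: str | None = None  # if None, a cohort is simulated
    simulate: dict = field(default_factory=dict)  # SyntheticSpec overrides
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    train: TrainParams = field(default_factory=TrainParams)
    predict: bool = True
    explain: ExplainParams = field(default_factory=ExplainParams)
    correlate: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.preprocess, dict):
            self.preprocess = _strict(PreprocessParams, self.preprocess)
        if isinstance(self.train, dict):
            self.train = _strict(TrainParams, self.train)
        if isinstance(self.explain, dict):
            self.explain = _strict(ExplainParams, self.explain)
        self.fractions = tuple(self.fractions)
        self.validate()

    def validate(self) -> None:
        if self.input_table is None and self.simulate is None:
            raise ValueError("either input_table or simulate settings required")
        if self.predict and not self.train.enabled:
            raise ValueError("predict requires the train stage")
        if self.explain.enabled and not self.train.enabled:
            raise ValueError("explain requires the train stage")
        known = {f.name for f in dc_fields(SyntheticSpec)}
        unknown = set(self.simulate) - known
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _strict(cls, d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write all artifacts.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
        "checksums": {},
        "metrics": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["checksums"][p.name] = _sha256(p)

    current_stage = "simulate"
    try:
        # -- simulate / ingest ---------------------------------------------
        if config.input_table is None:
            spec = SyntheticSpec(**{"seed": seeds["simulate"], **config.simulate})
            table, truth = simulate_cohort(spec)
            tpath = out / "cohort.csv"
            write_feature_table(table, tpath)
            write_truth(truth, out / "truth.csv")
            record("simulate", tpath, out / "truth.csv")
        else:
            table = read_feature_table(config.input_table)
            record("simulate", Path(config.input_table))

        # -- preprocess ------------------------------------------------------
        current_stage = "preprocess"
        pp = config.preprocess
        if pp.enabled:
            if pp.fourth_root:
                table = fourth_root(table)
            if pp.sex_filter:
                table, _ = filter_sex(table, keep=pp.sex_filter)
            if pp.pca_outliers:
                table, removed_s = remove_pca_outliers(
                    table, n_components=pp.pca_components, k=pp.pca_k, q=pp.pca_q
                )
                manifest["metrics"]["pca_outliers_removed"] = len(removed_s)
            table, removed_f = filter_batch_missingness(
                table, threshold=pp.missingness_threshold
            )
            manifest["metrics"]["features_removed_missingness"] = len(removed_f)
            if pp.row_normalize:
                robust = select_robust_features(table)
                robust.to_json(out / "robust_features.json")
                table = row_normalize(table, robust)
            table = impute_missing(table)
            ppath = out / "preprocessed.csv"
            write_feature_table(table, ppath)
            record("preprocess", ppath,
                   *([out / "robust_features.json"] if pp.row_normalize else []))
        else:
            table = impute_missing(table)
            manifest["stages"].append("preprocess")

        # -- split -----------------------------------------------------------
        current_stage = "split"
        split = split_data(table, fractions=config.fractions, seed=seeds["split"])
        split.to_json(out / "split.json")
        record("split", out / "split.json")
        train_t = table.select_samples(split.train_ids)
        dev_t = table.select_samples(split.dev_ids)
        test_t = table.select_samples(split.test_ids)

        model = None
        if config.train.enabled:
            current_stage = "train"
            net_cfg = RatioNetConfig.from_dict(
                {"seed": seeds["train"], **config.train.net}
            )
            model = train_ensemble(train_t, dev_t, net_cfg, k=config.train.k)
            model.save(out / "ensemble.npz")
            hist = pd.concat(
                [h.assign(member=k) for k, h in enumerate(model.histories)],
                ignore_index=True,
            )
            hist.to_csv(out / "history.csv", index=False)
            record("train", out / "ensemble.npz", out / "history.csv")

        if config.predict and model is not None:
            current_stage = "predict"
            preds = predict_ensemble(model, test_t)
            preds.per_sample.to_csv(out / "predictions.csv")
            manifest["metrics"]["test_rmse"] = rmse(
                preds.mean.to_numpy(), test_t.ages.to_numpy()
            )
            record("predict", out / "predictions.csv")

        if config.explain.enabled and model is not None:
            current_stage = "explain"
            rng = np.random.default_rng(seeds["explain"])
            n_bg = min(config.explain.background_size, train_t.n_samples)
            bg_ids = rng.choice(train_t.sample_ids, size=n_bg, replace=False)
            ens_attr, _ = attribute_ensemble(
                model, train_t.select_samples(bg_ids), test_t,
                n_permutations=config.explain.n_permutations,
                seed=seeds["explain"],
            )
            ens_attr.values.to_csv(out / "attributions.csv")
            global_importance(ens_attr).to_csv(out / "importance.csv")
            shap_intensity_concordance(ens_attr, test_t).to_csv(
                out / "concordance.csv"
            )
            record("explain", out / "attributions.csv", out / "importance.csv",
                   out / "concordance.csv")

        if config.correlate:
            current_stage = "correlate"
            corr = spearman_vs_age(table)
            corr.to_csv(out / "correlations.csv")
            record("correlate", out / "correlations.csv")
    except Exception as exc:
        (out / f"{current_stage}.failed").write_text(str(exc))
        raise RuntimeError(f"pipeline stage '{current_stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
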