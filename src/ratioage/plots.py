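"""Summary plots: attribution beeswarm and age-decile heatmap."""

from __future__ import annotations

import numpy as np
import matplotlib.pyplot as plt

from .importance import AttributionMatrix, global_importance
from .table import FeatureTable


def attribution_beeswarm(
    m: AttributionMatrix,
    table: FeatureTable | None = None,
    top_k: int = 10,
    ax=None,
    seed: int = 0,
):
    """One row per top feature; each point one sample's attribution, colored
    by its scaled intensity (blue low, red high).  Positive attribution means
    the feature pushes the predicted age up."""
    imp = global_importance(m)
    feats = list(imp.index[:top_k])
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * len(feats) + 1.5))
    rng = np.random.default_rng(seed)
    for row, fid in enumerate(reversed(feats)):
        vals = m.values[fid].to_numpy()
        if table is not None:
            inten = table.intensities.loc[m.values.index, fid].to_numpy(dtype=float)
            lo, hi = np.nanmin(inten), np.nanmax(inten)
            color = (inten - lo) / (hi - lo) if hi > lo else np.full_like(inten, 0.5)
        else:
            color = np.full(len(vals), 0.5)
        jitter = rng.uniform(-0.25, 0.25, size=len(vals))
        ax.scatter(vals, row + jitter, c=color, cmap="coolwarm", s=8,
                   vmin=0, vmax=1, linewidths=0)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(range(len(feats)))
    ax.set_yticklabels(list(reversed(feats)))
    ax.set_xlabel("attribution (years of predicted-age shift)")
    return ax


def decile_heatmap(profiles, ax=None):
    """Heatmap of per-feature age-decile z-score profiles (features x deciles),
    in the hierarchical display order returned by ``decile_profile``."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.25 * len(profiles) + 1.5))
    im = ax.imshow(profiles.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(profiles.shape[1]))
    ax.set_xticklabels(range(1, profiles.shape[1] + 1))
    ax.set_yticks(range(len(profiles)))
    ax.set_yticklabels(profiles.index, fontsize=7)
    ax.set_xlabel("age decile")
    plt.colorbar(im, ax=ax, label="z-score of decile mean intensity")
    return ax
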