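"""The ratio network: age regression that normalizes itself.

Feature tables without pooled QCs carry per-sample multiplicative effects
(dilution, injection volume, instrument response) that no external reference
can remove.  Ratios of compounds cancel any factor common to numerator and
denominator, so instead of normalizing the data we build the cancellation into
the model: a narrow linear compression layer (default 12 nodes) condenses the
features, a *ratio layer* emits every unique pairwise quotient of those nodes
(n(n-1)/2 = 66 for n = 12), and a small dense head maps the ratios to an age.
If one compression node learns an age score and another a sample-baseline
score, their quotient is a dilution-free age score.

Because single fits of the network vary from run to run, the estimator is an
ensemble: the same architecture is refitted K times from independent seeds and
the per-sample predictions are averaged; the spread across members gives a
standard error per prediction.

Everything here is plain numpy with hand-written backpropagation: mini-batch
SGD with Adam, per-layer weight decay (L2 added to the gradient, applied to
weight matrices only), inverted dropout, and standard batch normalization
(batch statistics during training, frozen running statistics at prediction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .table import FeatureTable

__all__ = [
    "RatioNetConfig",
    "EnsembleModel",
    "PredictionSet",
    "ratio_expand",
    "ratio_pairs",
    "build_ratio_net",
    "build_dense_net",
    "train_single",
    "train_ensemble",
    "predict_ensemble",
    "rmse",
    "age_group_bias",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RatioNetConfig:
    """Architecture and training hyperparameters of one network.

    ``weight_decays`` holds the per-layer L2 coefficients in layer order:
    (compression layer, ratio layer, hidden 1, hidden 2, output).  The ratio
    layer has no weights, so its slot is only used by the architecture-matched
    dense variant.  ``checkpoint_policy`` selects which parameters a fit
    returns: those of the final epoch, or of the epoch with the best
    development loss.
    """

    n_compress: int = 12
    hidden_sizes: tuple[int, ...] = (33, 33)
    dropout: float = 0.1
    weight_decays: tuple[float, ...] = (0.5, 0.0, 0.1, 0.01, 0.0)
    learning_rate: float = 3e-4
    batch_size: int = 500
    epochs: int = 1000
    seed: int = 0
    ratio_epsilon: float = 1e-6
    checkpoint_policy: str = "final_epoch"
    first_layer_bias: bool = True

    def validate(self) -> None:
        if self.n_compress < 2:
            raise ValueError("n_compress must be >= 2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if any(d < 0 for d in self.weight_decays):
            raise ValueError("weight decays must be >= 0")
        if len(self.weight_decays) != len(self.hidden_sizes) + 3:
            raise ValueError(
                "need one weight decay per layer "
                f"({len(self.hidden_sizes) + 3}), got {len(self.weight_decays)}"
            )
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid optimizer settings")
        if self.ratio_epsilon < 0:
            raise ValueError("ratio_epsilon must be >= 0")
        if self.checkpoint_policy not in ("final_epoch", "best_dev"):
            raise ValueError("checkpoint_policy must be 'final_epoch' or 'best_dev'")

    @property
    def ratio_width(self) -> int:
        return self.n_compress * (self.n_compress - 1) // 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["weight_decays"] = list(self.weight_decays)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RatioNetConfig":
        d = dict(d)
        for key in ("hidden_sizes", "weight_decays"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# the ratio operation


def ratio_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Numerator/denominator index vectors of the n(n-1)/2 unique pairs,
    enumerated lexicographically: (0,1), (0,2), ..., (n-2, n-1)."""
    i, j = np.triu_indices(n, k=1)
    return i, j


def _stabilize(d: np.ndarray, eps: float) -> np.ndarray:
    """sign(d) * max(|d|, eps); sign(0) treated as +1 so a zero denominator
    becomes +eps rather than 0."""
    if eps == 0:
        return d
    s = np.where(d < 0, -1.0, 1.0)
    return s * np.maximum(np.abs(d), eps)


def ratio_expand(v: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """All unique pairwise ratios v_i / v_j (i < j) of a vector or batch.

    For an n-vector the output has length n(n-1)/2 in lexicographic pair
    order; denominators are stabilized to sign(d) * max(|d|, epsilon).
    Ratios cancel any common positive scale: ratio_expand(c * v) equals
    ratio_expand(v) exactly when epsilon = 0.
    """
    v = np.asarray(v, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[None, :]
    n = v.shape[1]
    if n < 2:
        raise ValueError("ratio_expand requires at least 2 values")
    i, j = ratio_pairs(n)
    out = v[:, i] / _stabilize(v[:, j], epsilon)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# layers (numpy, manual backprop)


class _Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: float = 0.0):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 decay: float = 0.0, bias: bool = True):
        bound = 1.0 / np.sqrt(n_in)
        self.W = _Param(rng.uniform(-bound, bound, size=(n_in, n_out)), decay)
        self.b = _Param(rng.uniform(-bound, bound, size=n_out)) if bias else None
        self._x = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, training, rng):
        self._x = x if training else None
        out = x @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class _Ratio:
    """Unique pairwise ratios of the incoming activations; no parameters."""

    def __init__(self, n: int, epsilon: float):
        self.i, self.j = ratio_pairs(n)
        self.eps = epsilon
        self._cache = None

    def params(self):
        return []

    def forward(self, x, training, rng):
        d = _stabilize(x[:, self.j], self.eps)
        out = x[:, self.i] / d
        if training:
            # d/dx of the stabilized denominator is 0 inside the clamp
            active = np.abs(x[:, self.j]) >= self.eps if self.eps else None
            self._cache = (x.shape, x[:, self.i], d, active)
        return out

    def backward(self, dout):
        shape, num, den, active = self._cache
        dx = np.zeros(shape)
        dnum = dout / den
        dden = -dout * num / den**2
        if active is not None:
            dden = dden * active
        np.add.at(dx, (slice(None), self.i), dnum)
        np.add.at(dx, (slice(None), self.j), dden)
        return dx


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = _Param(np.ones(n))
        self.beta = _Param(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training, rng):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, inv_std = self._cache
        n = dout.shape[0]
        self.gamma.grad += (dout * xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


class _ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, training, rng):
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class _Dropout:
    def __init__(self, p: float):
        self.p = p
        self._mask = None

    def params(self):
        return []

    def forward(self, x, training, rng):
        if not training or self.p == 0:
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask if self.p else dout


class Network:
    """A sequential stack of layers with Adam training support."""

    def __init__(self, layers: list, n_features: int, config: RatioNetConfig):
        self.layers = layers
        self.n_features = n_features
        self.config = config
        # additive output offset; training centers the target here so the
        # optimizer only learns deviations from the mean age
        self.y_offset = 0.0

    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode prediction (no dropout, frozen batch statistics)."""
        return self.forward(np.asarray(x, dtype=float), training=False).ravel() + self.y_offset

    def get_state(self) -> list[np.ndarray]:
        state = [np.array([self.y_offset])] + [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        self.y_offset = float(state[0][0])
        params = self.params()
        for p, v in zip(params, state[1 : len(params) + 1]):
            p.value[...] = v
        extra = iter(state[len(params) + 1 :])
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class _Adam:
    def __init__(self, params: list[_Param], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad
            if p.decay:
                g = g + p.decay * p.value
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# builders


def build_ratio_net(config: RatioNetConfig, n_features: int) -> Network:
    """Assemble the untrained ratio network.

    Layer sequence: dropout on the inputs -> linear compression
    (n_features -> n_compress, no activation, no normalization) -> ratio
    expansion -> batch norm + ReLU -> hidden linear blocks (batch norm, ReLU,
    dropout) -> linear output.  Initial parameters are a deterministic
    function of ``config.seed``.
    """
    return _build(config, n_features, use_ratio=True)


def build_dense_net(config: RatioNetConfig, n_features: int) -> Network:
    """Architecture-matched control: the ratio expansion is replaced by a
    plain linear layer of the same width (n_compress -> n(n-1)/2), everything
    else identical.  Used to isolate what the ratio operation itself buys."""
    return _build(config, n_features, use_ratio=False)


def _build(config: RatioNetConfig, n_features: int, use_ratio: bool) -> Network:
    config.validate()
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    wd = config.weight_decays
    layers: list = [
        _Dropout(config.dropout),
        _Linear(n_features, config.n_compress, rng, decay=wd[0],
                bias=config.first_layer_bias),
    ]
    width = config.ratio_width
    if use_ratio:
        layers.append(_Ratio(config.n_compress, config.ratio_epsilon))
    else:
        layers.append(_Linear(config.n_compress, width, rng, decay=wd[1]))
    layers += [_BatchNorm(width), _ReLU()]
    prev = width
    for size, decay in zip(config.hidden_sizes, wd[2:-1]):
        layers += [
            _Linear(prev, size, rng, decay=decay),
            _BatchNorm(size),
            _ReLU(),
            _Dropout(config.dropout),
        ]
        prev = size
    layers.append(_Linear(prev, 1, rng, decay=wd[-1]))
    return Network(layers, n_features, config)


# ---------------------------------------------------------------------------
# training


def _as_xy(data) -> tuple[np.ndarray, np.ndarray, list]:
    """(X, ages, sample_ids) from a FeatureTable or an (X, y) pair."""
    if isinstance(data, FeatureTable):
        x = data.values()
        if np.isnan(x).any():
            raise ValueError("training/prediction data contain missing values; impute first")
        return x, data.ages.to_numpy(dtype=float), list(data.sample_ids)
    x, y = data
    x = np.asarray(x, dtype=float)
    return x, np.asarray(y, dtype=float), list(range(len(x)))


def train_single(net: Network, train, dev, config: RatioNetConfig | None = None
                 ) -> tuple[Network, pd.DataFrame]:
    """Fit one network by mini-batch Adam on the mean squared error.

    The development partition is evaluated once per epoch in evaluation mode
    and never contributes gradients; the returned parameters follow
    ``config.checkpoint_policy``.  Fully deterministic given the seed.
    """
    config = config or net.config
    x_train, y_train, _ = _as_xy(train)
    x_dev, y_dev, _ = _as_xy(dev)
    if x_train.shape[1] != net.n_features or x_dev.shape[1] != net.n_features:
        raise ValueError("feature count mismatch between data and network")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = _Adam(net.params(), lr=config.learning_rate)
    n = x_train.shape[0]
    history = []
    best = (np.inf, None)
    if config.epochs > 0:
        net.y_offset = float(y_train.mean())  # center the target
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            net.zero_grad()
            pred = net.forward(xb, training=True, rng=rng).ravel()
            resid = pred - (yb - net.y_offset)
            epoch_loss += float(resid @ resid)
            net.backward((2.0 * resid / len(idx))[:, None])
            opt.step()
        dev_pred = net.predict(x_dev)
        dev_loss = float(np.mean((dev_pred - y_dev) ** 2))
        history.append((epoch, epoch_loss / n, dev_loss))
        if dev_loss < best[0]:
            best = (dev_loss, net.get_state())
    if config.checkpoint_policy == "best_dev" and best[1] is not None:
        net.set_state(best[1])
    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "dev_loss"])
    return net, hist


@dataclass
class EnsembleModel:
    """K independently fitted networks sharing one architecture."""

    members: list = field(default_factory=list)
    member_seeds: list = field(default_factory=list)
    histories: list = field(default_factory=list)
    config: RatioNetConfig = field(default_factory=RatioNetConfig)

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("an ensemble needs at least one member")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def save(self, path) -> None:
        """Single-archive checkpoint: all member states + config + seeds."""
        arrays = {}
        for k, member in enumerate(self.members):
            for a, arr in enumerate(member.get_state()):
                arrays[f"member{k}_state{a}"] = arr
        meta = json.dumps(
            {
                "config": self.config.to_dict(),
                "member_seeds": list(self.member_seeds),
                "n_features": self.members[0].n_features,
                "histories": [h.to_dict(orient="list") for h in self.histories],
            }
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, builder=build_ratio_net) -> "EnsembleModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = RatioNetConfig.from_dict(meta["config"])
        members = []
        for k, seed in enumerate(meta["member_seeds"]):
            cfg = RatioNetConfig.from_dict({**config.to_dict(), "seed": seed})
            net = builder(cfg, meta["n_features"])
            state = []
            a = 0
            while f"member{k}_state{a}" in data:
                state.append(data[f"member{k}_state{a}"])
                a += 1
            net.set_state(state)
            members.append(net)
        histories = [pd.DataFrame(h) for h in meta["histories"]]
        return cls(members=members, member_seeds=list(meta["member_seeds"]),
                   histories=histories, config=config)


def member_seeds(base_seed: int, k: int) -> list[int]:
    """K distinct member seeds derived deterministically from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]


def train_ensemble(train, dev, config: RatioNetConfig, k: int = 25,
                   builder=build_ratio_net) -> EnsembleModel:
    """Refit the architecture ``k`` times from independent derived seeds."""
    if k < 1:
        raise ValueError("ensemble size must be >= 1")
    seeds = member_seeds(config.seed, k)
    members, histories = [], []
    base = config.to_dict()
    for seed in seeds:
        cfg = RatioNetConfig.from_dict({**base, "seed": seed})
        net = builder(cfg, _as_xy(train)[0].shape[1])
        net, hist = train_single(net, train, dev, cfg)
        members.append(net)
        histories.append(hist)
    return EnsembleModel(members=members, member_seeds=seeds,
                         histories=histories, config=config)


# ---------------------------------------------------------------------------
# prediction and evaluation


@dataclass
class PredictionSet:
    """Ensemble predictions: per-sample mean, standard error, member columns."""

    per_sample: pd.DataFrame  # index: sample id; columns: mean, se, member_0..K-1

    @property
    def mean(self) -> pd.Series:
        return self.per_sample["mean"]

    @property
    def se(self) -> pd.Series:
        return self.per_sample["se"]

    def member_predictions(self) -> pd.DataFrame:
        cols = [c for c in self.per_sample.columns if c.startswith("member_")]
        return self.per_sample[cols]


def predict_ensemble(model: EnsembleModel, table) -> PredictionSet:
    """Mean and standard error of the member predictions, evaluation mode."""
    x, _, ids = _as_xy(table)
    if x.shape[1] != model.members[0].n_features:
        raise ValueError("feature count mismatch between data and ensemble")
    preds = np.column_stack([m.predict(x) for m in model.members])
    k = preds.shape[1]
    se = preds.std(axis=1, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(len(x))
    frame = pd.DataFrame(
        {"mean": preds.mean(axis=1), "se": se}, index=pd.Index(ids, name="sample_id")
    )
    for j in range(k):
        frame[f"member_{j}"] = preds[:, j]
    return PredictionSet(per_sample=frame)


def rmse(pred, truth) -> float:
    """Root mean squared error, in years."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def age_group_bias(pred, truth, bin_width: float = 5.0
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-age-bin mean residual and per-sample accelerated-aging scores.

    A regression-to-the-mean bias (old under-, young over-predicted) is
    expected under a skewed age distribution, so accelerated aging must be
    read as the deviation from the *bin mean prediction*, not from the
    chronological age: score_i = prediction_i - mean prediction of i's bin.
    """
    if isinstance(pred, PredictionSet):
        pred = pred.mean
    pred = pd.Series(np.asarray(pred, dtype=float))
    truth = np.asarray(truth, dtype=float)
    bins = np.floor(truth / bin_width).astype(int)
    frame = pd.DataFrame({
        "pred": pred.to_numpy(), "truth": truth, "bin": bins,
        "resid": pred.to_numpy() - truth,
    }, index=pred.index)
    grouped = frame.groupby("bin")
    table = pd.DataFrame({
        "bin_start": grouped.size().index * bin_width,
        "n": grouped.size(),
        "mean_residual": grouped["resid"].mean(),
        "mean_prediction": grouped["pred"].mean(),
    })
    accel = frame["pred"] - frame["bin"].map(table["mean_prediction"])
    accel.name = "accelerated_aging"
    return table.reset_index(drop=True), accel
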