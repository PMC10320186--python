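"""Siamese regression network for stability changes.

One sub-network maps a feature record (cutoff-scanning signature blocks
plus complementary features) to a raw ddG; the same weights are applied to
the forward- and reverse-orientation records of a mutation, giving raw
outputs f and r. The served prediction is (f - r)/2, which is exactly
anti-symmetric under swapping the two orientations at any weights. The
training loss combines a log-cosh accuracy term on (f - r)/2 against the
experimental label with an absolute-value anti-symmetry penalty on f + r:

    loss = logcosh((f - r)/2 - y) + |f + r|

so a perfectly accurate, perfectly anti-symmetric model (f = y, r = -y)
attains exactly zero.

Inside the sub-network, signature channels are convolved along the
distance-bin axis and passed through a transformer encoder attending over
bins; complementary features go through two dense layers; both branch
outputs are concatenated together with a linear projection of the raw
inputs (the residual connection) and reduced by a final dense head. Each
sub-block can be ablated to an identity/pass-through for architecture
ablation studies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, Conv1d, Linear, Module, Tensor, TransformerEncoderLayer, concat

__all__ = [
    "ModelConfig",
    "PredictionPair",
    "contrastive_loss",
    "contrastive_loss_grad",
    "ablate",
    "SiameseDDGRegressor",
]

_ABLATABLE = ("conv", "transformer", "dense_comp", "head")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    The published method does not print its tuned values; these defaults
    are this package's own, sized for CPU training, and every one is
    exposed for tuning.
    """

    sig_channels: int = 36
    n_bins: int = 5
    conv_channels: tuple[int, ...] = (32, 64)
    conv_kernel: int = 3
    transformer_layers: int = 1
    attention_heads: int = 4
    transformer_dim: int = 64
    dense_units_comp: tuple[int, int] = (128, 64)
    dense_units_head: int = 64
    residual_dim: int = 32
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0
    ablated: tuple[str, ...] = ()

    def __post_init__(self):
        if self.transformer_dim % self.attention_heads != 0:
            raise ValueError("transformer_dim must be divisible by attention_heads")
        for name in self.ablated:
            if name not in _ABLATABLE:
                raise ValueError(f"unknown ablatable block {name!r}")


@dataclass(frozen=True)
class PredictionPair:
    ddg_forward_raw: float
    ddg_reverse_raw: float

    @property
    def ddg_final(self) -> float:
        return (self.ddg_forward_raw - self.ddg_reverse_raw) / 2.0


def contrastive_loss(f, r, y):
    """Training loss: logcosh((f - r)/2 - y) + |f + r|, averaged over the
    batch. Accepts scalars or arrays; the log-cosh is overflow-safe."""
    f = np.asarray(f, dtype=float)
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    e = (f - r) / 2.0 - y
    ae = np.abs(e)
    logcosh = ae + np.log1p(np.exp(-2.0 * ae)) - np.log(2.0)
    return float(np.mean(logcosh + np.abs(f + r)))


def contrastive_loss_grad(f, r, y):
    """Analytic gradient of the per-example loss w.r.t. (f, r).

    d/df = tanh(e)/2 + sign(f + r), d/dr = -tanh(e)/2 + sign(f + r) with
    e = (f - r)/2 - y; the subgradient of |f + r| is 0 exactly at the kink.
    """
    f = np.asarray(f, dtype=float)
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.tanh((f - r) / 2.0 - y)
    sg = np.sign(f + r)
    return t / 2.0 + sg, -t / 2.0 + sg


def ablate(cfg: ModelConfig, block: str) -> ModelConfig:
    """Return a config with the named sub-block replaced by a pass-through
    (one of 'conv', 'transformer', 'dense_comp', 'head')."""
    if block not in _ABLATABLE:
        raise ValueError(f"unknown block {block!r}; choose from {_ABLATABLE}")
    if block in cfg.ablated:
        return cfg
    return replace(cfg, ablated=cfg.ablated + (block,))


class _SubNetwork(Module):
    """The weight-shared sub-network applied to each orientation."""

    def __init__(self, cfg: ModelConfig, comp_dim: int, rng: np.random.Generator):
        self.cfg = cfg
        self.comp_dim = comp_dim
        sig_flat = cfg.sig_channels * cfg.n_bins

        channels = cfg.sig_channels
        self.convs: list[Conv1d] = []
        if "conv" not in cfg.ablated:
            for out_ch in cfg.conv_channels:
                self.convs.append(Conv1d(channels, out_ch, cfg.conv_kernel, rng))
                channels = out_ch
        self.proj = Linear(channels, cfg.transformer_dim, rng)
        self.encoders: list[TransformerEncoderLayer] = []
        if "transformer" not in cfg.ablated:
            self.encoders = [
                TransformerEncoderLayer(cfg.transformer_dim, cfg.attention_heads, rng)
                for _ in range(cfg.transformer_layers)
            ]

        if "dense_comp" not in cfg.ablated:
            u1, u2 = cfg.dense_units_comp
            self.comp1 = Linear(comp_dim, u1, rng)
            self.comp2 = Linear(u1, u2, rng)
            comp_out = u2
        else:
            self.comp1 = self.comp2 = None
            comp_out = comp_dim

        self.residual = Linear(sig_flat + comp_dim, cfg.residual_dim, rng)
        fused = cfg.transformer_dim + comp_out + cfg.residual_dim
        if "head" not in cfg.ablated:
            self.head1 = Linear(fused, cfg.dense_units_head, rng)
            self.out = Linear(cfg.dense_units_head, 1, rng)
        else:
            self.head1 = None
            self.out = Linear(fused, 1, rng)

    def __call__(self, x: Tensor, training: bool = False,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        n = x.shape[0]
        sig_flat = self.cfg.sig_channels * self.cfg.n_bins
        x_sig = x[:, :sig_flat].reshape(n, self.cfg.sig_channels, self.cfg.n_bins)
        x_comp = x[:, sig_flat:]

        h = x_sig
        for conv in self.convs:
            h = conv(h).relu()
        h = h.transpose(0, 2, 1)  # (n, bins, channels)
        h = self.proj(h)
        for enc in self.encoders:
            h = enc(h)
        sig_out = h.mean(axis=1)  # pool over bins

        if self.comp1 is not None:
            c = self.comp1(x_comp).relu()
            c = self.comp2(c).relu()
        else:
            c = x_comp

        res = self.residual(concat([x_sig.reshape(n, sig_flat), x_comp], axis=1))
        fused = concat([sig_out, c, res], axis=1)
        if training and self.cfg.dropout > 0 and drop_rng is not None:
            keep = 1.0 - self.cfg.dropout
            mask = (drop_rng.random(fused.shape) < keep) / keep
            fused = fused * Tensor(mask)
        if self.head1 is not None:
            fused = self.head1(fused).relu()
        return self.out(fused).reshape(n)


class SiameseDDGRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator around the siamese network.

    ``X`` is a 2-D array whose row is the concatenation of the forward-
    and reverse-orientation feature records (each of width
    ``sig_channels * n_bins + comp_dim``); ``y`` is the forward ddG in
    kcal/mol. ``predict`` returns the served prediction (f - r)/2.
    """

    def __init__(self, sig_channels: int = 36, n_bins: int = 5,
                 conv_channels: tuple[int, ...] = (32, 64), conv_kernel: int = 3,
                 transformer_layers: int = 1, attention_heads: int = 4,
                 transformer_dim: int = 64,
                 dense_units_comp: tuple[int, int] = (128, 64),
                 dense_units_head: int = 64, residual_dim: int = 32,
                 dropout: float = 0.1, learning_rate: float = 1e-3,
                 batch_size: int = 64, epochs: int = 100, patience: int = 10,
                 validation_fraction: float = 0.1, seed: int = 0,
                 ablated: tuple[str, ...] = ()):
        self.sig_channels = sig_channels
        self.n_bins = n_bins
        self.conv_channels = conv_channels
        self.conv_kernel = conv_kernel
        self.transformer_layers = transformer_layers
        self.attention_heads = attention_heads
        self.transformer_dim = transformer_dim
        self.dense_units_comp = dense_units_comp
        self.dense_units_head = dense_units_head
        self.residual_dim = residual_dim
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.ablated = ablated

    # ------------------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(
            sig_channels=self.sig_channels, n_bins=self.n_bins,
            conv_channels=tuple(self.conv_channels), conv_kernel=self.conv_kernel,
            transformer_layers=self.transformer_layers,
            attention_heads=self.attention_heads,
            transformer_dim=self.transformer_dim,
            dense_units_comp=tuple(self.dense_units_comp),
            dense_units_head=self.dense_units_head,
            residual_dim=self.residual_dim, dropout=self.dropout,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, patience=self.patience,
            validation_fraction=self.validation_fraction, seed=self.seed,
            ablated=tuple(self.ablated),
        )

    def _split_x(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 * self._record_dim:
            raise ValueError(
                f"X must be (n, {2 * self._record_dim}): forward and reverse "
                f"records of width {self._record_dim} side by side"
            )
        return X[:, : self._record_dim], X[:, self._record_dim:]

    def _init_net(self, comp_dim: int) -> None:
        cfg = self._config()
        rng = np.random.default_rng(cfg.seed)
        self.net_ = _SubNetwork(cfg, comp_dim, rng)
        self.config_ = cfg
        self._record_dim = cfg.sig_channels * cfg.n_bins + comp_dim

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "SiameseDDGRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of records")
        cfg = self._config()
        sig_flat = cfg.sig_channels * cfg.n_bins
        if X.shape[1] % 2 != 0 or X.shape[1] // 2 <= sig_flat:
            raise ValueError(
                "each X row must hold two records wider than the signature block"
            )
        comp_dim = X.shape[1] // 2 - sig_flat
        self._init_net(comp_dim)
        self.n_features_in_ = X.shape[1]
        x_fwd, x_rev = self._split_x(X)

        rng = np.random.default_rng(cfg.seed + 1)
        n = X.shape[0]
        n_val = max(1, int(round(cfg.validation_fraction * n))) if n > 4 else 0
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]

        params = self.net_.parameters()
        opt = Adam(params, lr=cfg.learning_rate)
        drop_rng = np.random.default_rng(cfg.seed + 2)

        history: list[dict] = []
        best_val = np.inf
        best_state = [p.copy() for p in self.net_.state_arrays()]
        best_epoch = 0
        stale = 0
        for epoch in range(cfg.epochs):
            rng.shuffle(train_idx)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(train_idx), cfg.batch_size):
                idx = train_idx[start : start + cfg.batch_size]
                loss = self._batch_loss(x_fwd[idx], x_rev[idx], y[idx],
                                        training=True, drop_rng=drop_rng)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; consider "
                        "a smaller learning rate or normalised features"
                    )
                self.net_.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item()
                n_batches += 1
            train_loss = epoch_loss / max(1, n_batches)
            if n_val:
                val_loss = self._batch_loss(x_fwd[val_idx], x_rev[val_idx],
                                            y[val_idx]).item()
                if not np.isfinite(val_loss):
                    raise FloatingPointError(
                        f"non-finite validation loss at epoch {epoch}; consider "
                        "a smaller learning rate or normalised features"
                    )
            else:
                val_loss = train_loss
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss,
                            "best_val_loss": min(best_val, val_loss)})
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = [p.copy() for p in self.net_.state_arrays()]
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        self.net_.load_state_arrays(best_state)
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_val if n_val else history[-1]["train_loss"]
        return self

    def _batch_loss(self, xf, xr, y, training=False, drop_rng=None) -> Tensor:
        f = self.net_(Tensor(xf), training=training, drop_rng=drop_rng)
        r = self.net_(Tensor(xr), training=training, drop_rng=drop_rng)
        err = (f - r) * 0.5 - Tensor(y)
        return (err.logcosh() + (f + r).abs()).mean()

    # ------------------------------------------------------------------
    def predict_pair(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Raw sub-network outputs (f, r) for each record pair."""
        check_is_fitted(self, "net_")
        xf, xr = self._split_x(X)
        f = self.net_(Tensor(xf)).data
        r = self.net_(Tensor(xr)).data
        return f, r

    def predict(self, X: np.ndarray) -> np.ndarray:
        f, r = self.predict_pair(X)
        return (f - r) / 2.0

    def forward_pass(self, feat_fwd: np.ndarray, feat_rev: np.ndarray) -> PredictionPair:
        """Single-record convenience wrapper returning a PredictionPair."""
        X = np.concatenate([np.atleast_1d(feat_fwd), np.atleast_1d(feat_rev)])[None, :]
        f, r = self.predict_pair(X)
        return PredictionPair(float(f[0]), float(r[0]))

    # ------------------------------------------------------------------
    def save(self, path, scaler_json: str | None = None) -> None:
        """Persist weights + config (+ optional feature scaler) as .npz."""
        check_is_fitted(self, "net_")
        arrays = {f"w{i}": a for i, a in enumerate(self.net_.state_arrays())}
        meta = {"config": asdict(self.config_), "comp_dim": self.net_.comp_dim,
                "scaler": scaler_json}
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> tuple["SiameseDDGRegressor", str | None]:
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = meta["config"]
        for key in ("conv_channels", "dense_units_comp", "ablated"):
            cfg[key] = tuple(cfg[key])
        est = cls(**{k: v for k, v in cfg.items()})
        est._init_net(meta["comp_dim"])
        n_arrays = len([k for k in data.files if k.startswith("w")])
        est.net_.load_state_arrays([data[f"w{i}"] for i in range(n_arrays)])
        est.n_features_in_ = 2 * est._record_dim
        est.history_ = []
        return est, meta.get("scaler")
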