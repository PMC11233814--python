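"""Two-phase training: contrastive pretraining and frozen-encoder fine-tuning.

Phase 1 trains the encoder Enc and projection head Proj with the supervised
contrastive loss: each mini-batch is augmented by random feature corruption,
positives/negatives are determined from label differences, and the loss is
computed on L2-normalized projector outputs. Phase 2 freezes Enc, discards
Proj, and fits the regression head Reg on Enc's output with an MSE loss.
Both phases use Adam (lr 0.001) and early stopping with patience 3 on the
validation loss, returning the best-validation-epoch parameters.

A plain MLP baseline (same Enc+Reg stack trained from scratch with MSE) is
included as the reference model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .augmentation import CorruptionConfig, corrupt_batch
from .data import FeatureTable, ScoreVector, SplitSpec, Standardizer, check_aligned, fit_standardizer
from .losses import _supcon_value_and_grad
from .pairing import DEFAULT_THETA, build_pair_mask

# seed-stream tags so the phases draw independent randomness from one seed
_INIT, _EPOCH, _VAL_AUG, _FINETUNE, _BASELINE = 11, 13, 17, 19, 23


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class NetworkConfig:
    """Layer counts and width of the Enc/Proj/Reg stacks.

    Enc is ``encoder_layers`` affine layers, each followed by ReLU; Proj has
    ReLU between its layers but none after the last (its output is then
    L2-normalized); Reg ends in a single linear output unit.
    """

    hidden_dim: int = 256
    encoder_layers: int = 4
    projector_layers: int = 2
    regressor_layers: int = 2

    def __post_init__(self) -> None:
        if min(self.encoder_layers, self.projector_layers, self.regressor_layers) < 1:
            raise ValueError("all layer counts must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")

    def encoder_dims(self, input_dim: int) -> list[int]:
        return [input_dim] + [self.hidden_dim] * self.encoder_layers

    def projector_dims(self) -> list[int]:
        return [self.hidden_dim] * (self.projector_layers + 1)

    def regressor_dims(self) -> list[int]:
        return [self.hidden_dim] * self.regressor_layers + [1]


@dataclass
class TrainConfig:
    """Hyperparameters of both training phases."""

    pretrain_batch: int = 2048
    finetune_batch: int = 128
    learning_rate: float = 1e-3
    patience: int = 3
    corruption_rate: float = 0.5
    theta: float = DEFAULT_THETA
    temperature: float = 1.0
    max_epochs: int = 200
    pretrain_monitor: str = "probe"  # "probe" or "contrastive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pretrain_batch < 2 or self.finetune_batch < 2:
            raise ValueError("batch sizes must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.pretrain_monitor not in ("probe", "contrastive"):
            raise ValueError("pretrain_monitor must be 'probe' or 'contrastive'")
        CorruptionConfig(rate=self.corruption_rate)  # validates the rate


class EarlyStopper:
    """Patience-based stopping on a validation loss, tracking the best epoch.

    ``update`` returns True once the loss has failed to improve on the best
    value for ``patience`` consecutive epochs.
    """

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, loss: float, epoch: int) -> bool:
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start : start + batch_size]


def _contrastive_pass(
    x: np.ndarray,
    y: np.ndarray,
    enc: list[np.ndarray],
    proj: list[np.ndarray],
    cfg: TrainConfig,
    aug_rng: np.random.Generator,
    want_grad: bool,
):
    """One contrastive forward (and optionally backward) pass on a batch.

    Builds the corrupted copy, embeds originals + copies through Enc then
    Proj, normalizes, and evaluates the supervised contrastive loss with the
    pair mask over the doubled label vector.
    """
    x_tilde = corrupt_batch(x, CorruptionConfig(rate=cfg.corruption_rate), rng=aug_rng)
    combined = np.vstack([x, x_tilde])
    labels = np.concatenate([y, y])
    mask = build_pair_mask(labels, cfg.theta)

    if want_grad:
        h, enc_cache = nn.mlp_forward(enc, combined, relu_last=True, want_cache=True)
        u, proj_cache = nn.mlp_forward(proj, h, relu_last=False, want_cache=True)
    else:
        h = nn.mlp_forward(enc, combined, relu_last=True)
        u = nn.mlp_forward(proj, h, relu_last=False)
    z, norms = nn.normalize_forward(u)
    loss, grad_z = _supcon_value_and_grad(
        z.astype(np.float64), mask.positives, cfg.temperature, want_grad=want_grad
    )
    if not want_grad:
        return loss, None, None
    grad_u = nn.normalize_backward(z, norms, grad_z.astype(nn.DTYPE))
    proj_grads, grad_h = nn.mlp_backward(proj, proj_cache, grad_u)
    enc_grads, _ = nn.mlp_backward(enc, enc_cache, grad_h)
    return loss, enc_grads, proj_grads


def _probe_val_mse(
    enc: list[np.ndarray],
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
) -> float:
    """Validation MSE of a ridge readout fitted on frozen encoder features.

    The linear probe measures how regression-useful the current
    representation is, which is what the downstream fine-tuning phase will
    consume; the contrastive loss itself is a poor proxy for that. Closed
    form on the (hidden_dim x hidden_dim) normal equations, so it is cheap
    relative to an epoch.
    """
    h_tr = nn.mlp_forward(enc, x_train, relu_last=True).astype(np.float64)
    h_va = nn.mlp_forward(enc, x_val, relu_last=True).astype(np.float64)
    mu = h_tr.mean(axis=0)
    h_tr = h_tr - mu
    y_mu = y_train.mean()
    alpha = 0.03 * len(h_tr)  # mild shrinkage, scaled with the sample count
    gram = h_tr.T @ h_tr + alpha * np.eye(h_tr.shape[1])
    coef = np.linalg.solve(gram, h_tr.T @ (y_train - y_mu))
    pred = (h_va - mu) @ coef + y_mu
    return float(np.mean((pred - y_val) ** 2))


@dataclass
class PretrainResult:
    encoder: list[np.ndarray]
    projector: list[np.ndarray]
    history: dict


def pretrain_encoder(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    net: NetworkConfig | None = None,
) -> PretrainResult:
    """Contrastive representation learning on standardized features.

    Per epoch the training set is reshuffled into mini-batches of at most
    ``cfg.pretrain_batch``; batches that collapse below 2 samples are
    skipped. Early stopping (patience on the validation signal) returns the
    parameters from the best-validation epoch. The monitored signal is
    chosen by ``cfg.pretrain_monitor``: ``"probe"`` (default) tracks the
    validation MSE of a ridge readout on the frozen embeddings — a direct
    measure of downstream usefulness; ``"contrastive"`` tracks the
    validation contrastive loss itself, computed with a fixed augmentation
    seed so epochs compare like with like.
    """
    if net is None:
        net = NetworkConfig()
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    x_train = np.ascontiguousarray(x_train, dtype=nn.DTYPE)
    x_val = np.ascontiguousarray(x_val, dtype=nn.DTYPE)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)

    init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _INIT]))
    epoch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _EPOCH]))
    enc = nn.init_mlp(net.encoder_dims(x_train.shape[1]), init_rng)
    proj = nn.init_mlp(net.projector_dims(), init_rng)
    opt = nn.Adam(enc + proj, lr=cfg.learning_rate)

    stopper = EarlyStopper(cfg.patience)
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_enc, best_proj = nn.clone_params(enc), nn.clone_params(proj)

    for epoch in range(cfg.max_epochs):
        epoch_losses, epoch_sizes = [], []
        for idx in _iter_batches(len(x_train), cfg.pretrain_batch, epoch_rng):
            if len(idx) < 2:
                continue  # cannot corrupt or pair a single sample
            loss, enc_grads, proj_grads = _contrastive_pass(
                x_train[idx], y_train[idx], enc, proj, cfg, epoch_rng, want_grad=True
            )
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite contrastive loss at epoch {epoch}")
            opt.step(enc_grads + proj_grads)
            epoch_losses.append(loss)
            epoch_sizes.append(len(idx))
        train_loss = float(np.sum(epoch_losses) / max(np.sum(epoch_sizes), 1))

        if cfg.pretrain_monitor == "probe":
            val_loss = _probe_val_mse(enc, x_train, y_train, x_val, y_val)
        else:
            val_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _VAL_AUG]))
            val_loss, _, _ = _contrastive_pass(
                x_val, y_val, enc, proj, cfg, val_rng, want_grad=False
            )
            val_loss = float(val_loss / len(x_val))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        improved = val_loss < stopper.best
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_enc, best_proj = nn.clone_params(enc), nn.clone_params(proj)
        if stop:
            break
    history["best_epoch"] = stopper.best_epoch
    return PretrainResult(encoder=best_enc, projector=best_proj, history=history)


def _mse_value_and_grad(pred: np.ndarray, y: np.ndarray):
    resid = pred - y
    return float(np.mean(resid**2)), (2.0 / len(y)) * resid


def finetune_regressor(
    encoder: list[np.ndarray],
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    net: NetworkConfig | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Fit the regression head on the frozen encoder's output with MSE loss.

    Only Reg parameters are updated; because the encoder is frozen its
    outputs are computed once and cached. Early stopping (patience 3) on the
    validation MSE; returns best-epoch Reg parameters and the history.
    """
    if net is None:
        net = NetworkConfig()
    # frozen encoder => its features are fixed; cache them
    h_train = nn.mlp_forward(encoder, np.asarray(x_train, dtype=nn.DTYPE), relu_last=True)
    h_val = nn.mlp_forward(encoder, np.asarray(x_val, dtype=nn.DTYPE), relu_last=True)
    y_train = np.asarray(y_train, dtype=nn.DTYPE)
    y_val = np.asarray(y_val, dtype=nn.DTYPE)

    init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _FINETUNE, _INIT]))
    epoch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _FINETUNE, _EPOCH]))
    reg = nn.init_mlp(net.regressor_dims(), init_rng)
    opt = nn.Adam(reg, lr=cfg.learning_rate)

    stopper = EarlyStopper(cfg.patience)
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_reg = nn.clone_params(reg)

    for epoch in range(cfg.max_epochs):
        epoch_losses, epoch_sizes = [], []
        for idx in _iter_batches(len(h_train), cfg.finetune_batch, epoch_rng):
            pred, cache = nn.mlp_forward(reg, h_train[idx], relu_last=False, want_cache=True)
            loss, grad_pred = _mse_value_and_grad(pred[:, 0], y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite MSE at epoch {epoch}")
            grads, _ = nn.mlp_backward(reg, cache, grad_pred[:, None])
            opt.step(grads)
            epoch_losses.append(loss * len(idx))
            epoch_sizes.append(len(idx))
        train_loss = float(np.sum(epoch_losses) / max(np.sum(epoch_sizes), 1))

        val_pred = nn.mlp_forward(reg, h_val, relu_last=False)[:, 0]
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        improved = val_loss < stopper.best
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_reg = nn.clone_params(reg)
        if stop:
            break
    history["best_epoch"] = stopper.best_epoch
    return best_reg, history


@dataclass
class TrainedRegressor:
    """Encoder + regression head + preprocessing statistics for one measure."""

    encoder: list[np.ndarray]
    regressor: list[np.ndarray]
    standardizer: Standardizer
    net_config: NetworkConfig
    train_config: TrainConfig
    measure_name: str
    score_name: str
    feature_ids: np.ndarray
    history: dict = field(default_factory=dict)
    model_kind: str = "scr"  # "scr" (contrastive) or "mlp" (baseline)

    def predict_values(self, values: np.ndarray) -> np.ndarray:
        """Predict from a raw (unstandardized) n x d matrix."""
        x = self.standardizer.transform(values).astype(nn.DTYPE)
        h = nn.mlp_forward(self.encoder, x, relu_last=True)
        return np.asarray(nn.mlp_forward(self.regressor, h, relu_last=False)[:, 0], dtype=float)

    def predict(self, table: FeatureTable) -> np.ndarray:
        if not np.array_equal(table.feature_ids, self.feature_ids):
            raise ValueError(
                f"feature ids of table {table.measure_name!r} do not match the "
                f"ids this model was trained on"
            )
        return self.predict_values(table.values)

    # -- serialization: one directory holding a parameter archive + manifest --

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"enc_{i}": p for i, p in enumerate(self.encoder)}
        arrays.update({f"reg_{i}": p for i, p in enumerate(self.regressor)})
        arrays["location"] = self.standardizer.location
        arrays["scale"] = self.standardizer.scale
        np.savez(path / "params.npz", **arrays)
        manifest = {
            "measure_name": self.measure_name,
            "score_name": self.score_name,
            "model_kind": self.model_kind,
            "feature_ids": [str(f) for f in self.feature_ids],
            "net_config": asdict(self.net_config),
            "train_config": asdict(self.train_config),
            "history": self.history,
            "n_encoder_arrays": len(self.encoder),
            "n_regressor_arrays": len(self.regressor),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedRegressor":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        with np.load(path / "params.npz") as arc:
            encoder = [arc[f"enc_{i}"] for i in range(manifest["n_encoder_arrays"])]
            regressor = [arc[f"reg_{i}"] for i in range(manifest["n_regressor_arrays"])]
            std = Standardizer(location=arc["location"], scale=arc["scale"])
        return cls(
            encoder=encoder,
            regressor=regressor,
            standardizer=std,
            net_config=NetworkConfig(**manifest["net_config"]),
            train_config=TrainConfig(**manifest["train_config"]),
            measure_name=manifest["measure_name"],
            score_name=manifest["score_name"],
            feature_ids=np.asarray(manifest["feature_ids"], dtype=object),
            history=manifest["history"],
            model_kind=manifest["model_kind"],
        )


def _prepare(table: FeatureTable, scores: ScoreVector, split: SplitSpec):
    check_aligned(table, scores)
    std = fit_standardizer(table, split.train_idx)
    x = std.transform(table.values)
    y = scores.scores
    return std, x, y


def train_regressor(
    table: FeatureTable,
    scores: ScoreVector,
    split: SplitSpec,
    cfg: TrainConfig | None = None,
    net: NetworkConfig | None = None,
) -> TrainedRegressor:
    """Full two-phase pipeline for one measure table.

    Standardizes with training-row statistics, pretrains Enc/Proj with the
    contrastive objective, then fine-tunes Reg on the frozen encoder. The
    returned model's encoder is bit-identical to the pretrained one.
    """
    cfg = cfg or TrainConfig()
    net = net or NetworkConfig()
    std, x, y = _prepare(table, scores, split)
    tr, va = split.train_idx, split.val_idx
    pre = pretrain_encoder(x[tr], y[tr], x[va], y[va], cfg, net)
    encoder_before = nn.clone_params(pre.encoder)
    reg, ft_history = finetune_regressor(pre.encoder, x[tr], y[tr], x[va], y[va], cfg, net)
    for a, b in zip(encoder_before, pre.encoder):
        assert np.array_equal(a, b), "encoder parameters changed during fine-tuning"
    return TrainedRegressor(
        encoder=pre.encoder,
        regressor=reg,
        standardizer=std,
        net_config=net,
        train_config=cfg,
        measure_name=table.measure_name,
        score_name=scores.score_name,
        feature_ids=table.feature_ids,
        history={"pretrain": pre.history, "finetune": ft_history},
        model_kind="scr",
    )


def train_mlp_baseline(
    table: FeatureTable,
    scores: ScoreVector,
    split: SplitSpec,
    cfg: TrainConfig | None = None,
    net: NetworkConfig | None = None,
) -> TrainedRegressor:
    """Reference model: the same Enc+Reg stack trained from scratch with MSE.

    No contrastive phase and no frozen parameters — the whole stack is
    updated jointly (batch = ``finetune_batch``, Adam, early stopping on
    validation MSE).
    """
    cfg = cfg or TrainConfig()
    net = net or NetworkConfig()
    std, x, y = _prepare(table, scores, split)
    tr, va = split.train_idx, split.val_idx
    x_train, y_train = x[tr].astype(nn.DTYPE), y[tr].astype(nn.DTYPE)
    x_val, y_val = x[va].astype(nn.DTYPE), y[va].astype(nn.DTYPE)

    init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _BASELINE, _INIT]))
    epoch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _BASELINE, _EPOCH]))
    enc = nn.init_mlp(net.encoder_dims(x_train.shape[1]), init_rng)
    reg = nn.init_mlp(net.regressor_dims(), init_rng)
    opt = nn.Adam(enc + reg, lr=cfg.learning_rate)

    stopper = EarlyStopper(cfg.patience)
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best = (nn.clone_params(enc), nn.clone_params(reg))

    for epoch in range(cfg.max_epochs):
        epoch_losses, epoch_sizes = [], []
        for idx in _iter_batches(len(x_train), cfg.finetune_batch, epoch_rng):
            h, enc_cache = nn.mlp_forward(enc, x_train[idx], relu_last=True, want_cache=True)
            pred, reg_cache = nn.mlp_forward(reg, h, relu_last=False, want_cache=True)
            loss, grad_pred = _mse_value_and_grad(pred[:, 0], y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite MSE at epoch {epoch}")
            reg_grads, grad_h = nn.mlp_backward(reg, reg_cache, grad_pred[:, None])
            enc_grads, _ = nn.mlp_backward(enc, enc_cache, grad_h)
            opt.step(enc_grads + reg_grads)
            epoch_losses.append(loss * len(idx))
            epoch_sizes.append(len(idx))
        history["train_loss"].append(float(np.sum(epoch_losses) / max(np.sum(epoch_sizes), 1)))

        h_val = nn.mlp_forward(enc, x_val, relu_last=True)
        val_pred = nn.mlp_forward(reg, h_val, relu_last=False)[:, 0]
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        history["val_loss"].append(val_loss)

        improved = val_loss < stopper.best
        stop = stopper.update(val_loss, epoch)
        if improved:
            best = (nn.clone_params(enc), nn.clone_params(reg))
        if stop:
            break
    history["best_epoch"] = stopper.best_epoch
    return TrainedRegressor(
        encoder=best[0],
        regressor=best[1],
        standardizer=std,
        net_config=net,
        train_config=cfg,
        measure_name=table.measure_name,
        score_name=scores.score_name,
        feature_ids=table.feature_ids,
        history={"finetune": history},
        model_kind="mlp",
    )
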