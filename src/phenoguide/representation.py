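"""The guided encoder: training, encoding, prediction and evaluation.

A single-layer LSTM maps each patient's normalized 4-hour windows to a
compact per-window encoding (strictly smaller than the input dimension).
Four simple heads — 90-day mortality, remaining length of stay (days),
next-window renal replacement therapy, next-window mechanical ventilation —
are trained jointly with the encoder under a weighted aggregate loss; they
exist only to shape the encoding and are discarded at clustering time.
Mortality is supervised with the patient-level label at every window, so
the per-window risk estimate can evolve over the stay.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._nn import BINARY_HEADS, HEADS, Adam, MultiTaskLSTM, masked_loss_and_head_grads, sigmoid
from .preprocessing import TimeStepTensor


@dataclass
class EncoderConfig:
    input_dim: int = 0  # inferred from the data when 0
    hidden_dim: int = 64
    encoding_dim: int = 16
    n_recurrent_layers: int = 1
    head_hidden: int = 16
    loss_weights: dict[str, float] = field(
        default_factory=lambda: {"mort": 1.0, "los": 0.5, "rrt": 1.0, "mv": 1.0}
    )
    learning_rate: float = 5e-3
    batch_size: int = 16
    max_epochs: int = 60
    patience: int = 10
    weight_decay: float = 5e-3
    input_noise_sd: float = 0.5  # train-time Gaussian jitter on inputs
    ema_decay: float = 0.0  # epoch-level Polyak averaging (0 disables)
    seed: int = 0

    def validate(self, input_dim: int) -> None:
        if self.encoding_dim >= input_dim:
            raise ValueError(
                f"encoding_dim ({self.encoding_dim}) must be smaller than the "
                f"input dimension ({input_dim})"
            )
        w = self.loss_weights
        if any(v < 0 for v in w.values()) or all(v == 0 for v in w.values()):
            raise ValueError("loss_weights must be nonnegative and not all zero")
        if self.n_recurrent_layers != 1:
            raise NotImplementedError("only a single recurrent layer is supported")


@dataclass
class MetricReport:
    """Per-task point metrics with percentile-bootstrap 95% CIs."""

    metrics: dict[str, dict[str, tuple[float, float, float] | None]]
    n_bootstrap: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"metrics": self.metrics, "n_bootstrap": self.n_bootstrap, "seed": self.seed},
            indent=2,
            default=float,
        )


def pack_batch(tensors: list[TimeStepTensor]):
    """Pad a list of patient tensors into (X, window_mask, labels)."""
    B = len(tensors)
    T = max(t.n_windows for t in tensors)
    D = tensors[0].features.shape[1]
    X = np.zeros((B, T, D))
    wmask = np.zeros((B, T))
    los = np.full((B, T), np.nan)
    rrt = np.full((B, T), np.nan)
    mv = np.full((B, T), np.nan)
    mort = np.zeros(B)
    for b, t in enumerate(tensors):
        n = t.n_windows
        X[b, :n] = t.features
        wmask[b, :n] = 1.0
        los[b, :n] = t.remaining_los_days
        rrt[b, :n] = t.rrt_next
        mv[b, :n] = t.mv_next
        mort[b] = t.died_90d
    return X, wmask, {"mort": mort, "los": los, "rrt": rrt, "mv": mv}


class GuidedEncoder:
    """Trained (or freshly initialized) encoder + heads."""

    def __init__(self, config: EncoderConfig, input_dim: int, feature_names: list[str]):
        config.validate(input_dim)
        self.config = config
        self.feature_names = list(feature_names)
        rng = np.random.default_rng(config.seed)
        self.net = MultiTaskLSTM(
            input_dim, config.hidden_dim, config.encoding_dim, config.head_hidden, rng
        )

    # -------------------------------------------------------------- encode

    def encode_batch(self, X: np.ndarray) -> np.ndarray:
        enc, _ = self.net.forward(X)
        return enc

    def encode(self, tensors: list[TimeStepTensor]) -> pd.DataFrame:
        """Per-(patient, window) encodings; causal in the window index."""
        rows, index = [], []
        for t in tensors:
            if t.features.shape[1] != self.net.D:
                raise ValueError(
                    f"feature dimension mismatch: tensor has {t.features.shape[1]}, "
                    f"model expects {self.net.D}"
                )
            enc, _ = self.net.forward(t.features[None])
            rows.append(enc[0])
            index.extend((t.patient_id, w) for w in range(t.n_windows))
        mat = np.vstack(rows)
        return pd.DataFrame(
            mat,
            index=pd.MultiIndex.from_tuples(index, names=["patient_id", "window"]),
            columns=[f"e{j}" for j in range(mat.shape[1])],
        )

    # ------------------------------------------------------------- predict

    def predict(self, tensors: list[TimeStepTensor]) -> pd.DataFrame:
        """Per-window head outputs: probabilities for the three binary tasks
        (strictly inside (0,1) via the sigmoid) and LOS in days."""
        frames = []
        for t in tensors:
            enc, _ = self.net.forward(t.features[None])
            outs, _ = self.net.head_forward(enc)
            frames.append(
                pd.DataFrame(
                    {
                        "p_mort": sigmoid(outs["mort"][0]),
                        "los_hat": outs["los"][0],
                        "p_rrt": sigmoid(outs["rrt"][0]),
                        "p_mv": sigmoid(outs["mv"][0]),
                    },
                    index=pd.MultiIndex.from_tuples(
                        [(t.patient_id, w) for w in range(t.n_windows)],
                        names=["patient_id", "window"],
                    ),
                )
            )
        return pd.concat(frames)

    # ---------------------------------------------------------- checkpoint

    def save(self, path: str) -> None:
        meta = {"config": asdict(self.config), "feature_names": self.feature_names}
        np.savez(path, __meta__=json.dumps(meta), **self.net.params)

    @classmethod
    def load(cls, path: str) -> "GuidedEncoder":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg = EncoderConfig(**meta["config"])
        model = cls(cfg, data["W"].shape[0] - cfg.hidden_dim, meta["feature_names"])
        for k in model.net.params:
            model.net.params[k] = data[k]
        return model


def multitask_loss(
    preds: pd.DataFrame | dict,
    labels: dict[str, np.ndarray],
    weights: dict[str, float],
    eps: float = 1e-12,
) -> tuple[float, dict[str, float]]:
    """Weighted aggregate loss from probability-scale predictions.

    total = w_mort*BCE + w_los*MSE + w_rrt*BCE + w_mv*BCE, each component
    averaged over its valid cells (NaN labels are masked out).
    """
    get = preds.__getitem__
    comps = {}
    pred_key = {"mort": "p_mort", "los": "los_hat", "rrt": "p_rrt", "mv": "p_mv"}
    for h in HEADS:
        p = np.asarray(get(pred_key[h]), float)
        y = np.asarray(labels[h], float)
        valid = ~np.isnan(y)
        if valid.sum() == 0:
            if weights.get(h, 0) > 0:
                raise ValueError(f"task {h!r}: positive weight but no valid cells")
            comps[h] = np.nan
            continue
        if h == "los":
            comps[h] = float(((p[valid] - y[valid]) ** 2).mean())
        else:
            pc = np.clip(p[valid], eps, 1 - eps)
            yv = y[valid]
            comps[h] = float(-(yv * np.log(pc) + (1 - yv) * np.log(1 - pc)).mean())
    total = sum(weights.get(h, 0.0) * comps[h] for h in HEADS if not np.isnan(comps[h]))
    return float(total), comps


def train(
    train_tensors: list[TimeStepTensor],
    val_tensors: list[TimeStepTensor],
    config: EncoderConfig,
) -> tuple[GuidedEncoder, pd.DataFrame]:
    """End-to-end gradient training with early stopping on validation loss.

    Patients are shuffled into padded mini-batches each epoch; after each
    epoch the aggregated validation loss is recorded and training stops when
    it has not improved for ``patience`` epochs (or at ``max_epochs``). The
    returned model carries the best-validation parameters.
    """
    D = train_tensors[0].features.shape[1]
    model = GuidedEncoder(config, D, train_tensors[0].feature_names)
    opt = Adam(model.net.params, lr=config.learning_rate, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    weights = dict(config.loss_weights)

    def epoch_loss(tensors: list[TimeStepTensor], params=None) -> tuple[float, dict[str, float]]:
        saved = model.net.params
        if params is not None:
            model.net.params = params
        try:
            X, wmask, labels = pack_batch(tensors)
            enc, _ = model.net.forward(X)
            outs, _ = model.net.head_forward(enc)
            total, comps, _ = masked_loss_and_head_grads(outs, labels, wmask, weights)
        finally:
            model.net.params = saved
        return total, comps

    history = []
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.net.params.items()}
    ema = {k: v.copy() for k, v in model.net.params.items()}
    bad_epochs = 0
    order = np.arange(len(train_tensors))
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        for start in range(0, len(order), config.batch_size):
            batch = [train_tensors[i] for i in order[start : start + config.batch_size]]
            X, wmask, labels = pack_batch(batch)
            if config.input_noise_sd > 0:
                X = X + config.input_noise_sd * rng.standard_normal(X.shape)
            enc, cache = model.net.forward(X)
            outs, hcache = model.net.head_forward(enc)
            _, _, d_outs = masked_loss_and_head_grads(outs, labels, wmask, weights)
            grads = model.net.zero_grads()
            dE = model.net.head_backward(enc, hcache, d_outs, grads)
            model.net.backward(cache, dE, grads)
            opt.step(model.net.params, grads)
        if config.ema_decay > 0:
            d = config.ema_decay
            for k in ema:
                ema[k] = d * ema[k] + (1 - d) * model.net.params[k]
            eval_params = ema
        else:
            eval_params = model.net.params
        tr_total, tr_comps = epoch_loss(train_tensors, eval_params)
        va_total, va_comps = epoch_loss(val_tensors, eval_params)
        history.append(
            {
                "epoch": epoch,
                "train_total": tr_total,
                "val_total": va_total,
                **{f"train_{h}": tr_comps[h] for h in HEADS},
                **{f"val_{h}": va_comps[h] for h in HEADS},
            }
        )
        if va_total < best_val:
            best_val = va_total
            best_params = {k: v.copy() for k, v in eval_params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.net.params = best_params
    return model, pd.DataFrame(history)


# ----------------------------------------------------------------- metrics


def _task_frames(model: GuidedEncoder, tensors: list[TimeStepTensor]) -> pd.DataFrame:
    preds = model.predict(tensors)
    y_mort, y_rrt, y_mv, y_los = [], [], [], []
    for t in tensors:
        y_mort.extend([t.died_90d] * t.n_windows)
        y_rrt.extend(t.rrt_next)
        y_mv.extend(t.mv_next)
        y_los.extend(t.remaining_los_days)
    preds["y_mort"] = np.asarray(y_mort, float)
    preds["y_rrt"] = np.asarray(y_rrt, float)
    preds["y_mv"] = np.asarray(y_mv, float)
    preds["y_los"] = np.asarray(y_los, float)
    return preds


def _point_metrics(frame: pd.DataFrame) -> dict[str, dict[str, float | None]]:
    out: dict[str, dict[str, float | None]] = {}
    for task, (pcol, ycol) in {
        "mort": ("p_mort", "y_mort"),
        "rrt": ("p_rrt", "y_rrt"),
        "mv": ("p_mv", "y_mv"),
    }.items():
        sub = frame.dropna(subset=[ycol])
        y = sub[ycol].to_numpy()
        p = sub[pcol].to_numpy()
        acc = float(((p >= 0.5) == (y == 1)).mean()) if len(y) else None
        # AUROC is the tie-corrected rank statistic (Mann-Whitney U)
        auroc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else None
        out[task] = {"accuracy": acc, "auroc": auroc}
    out["los"] = {"mse": float(((frame["los_hat"] - frame["y_los"]) ** 2).mean())}
    return out


def evaluate(
    model: GuidedEncoder,
    tensors: list[TimeStepTensor],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Point metrics with 95% percentile-bootstrap CIs, resampling PATIENTS
    (not windows) so that within-patient correlation is respected."""
    frame = _task_frames(model, tensors)
    point = _point_metrics(frame)
    rng = np.random.default_rng(seed)
    pids = frame.index.get_level_values("patient_id").unique().to_numpy()
    groups = {pid: g for pid, g in frame.groupby(level="patient_id")}
    samples: dict[tuple[str, str], list[float]] = {}
    for _ in range(n_bootstrap):
        take = rng.choice(pids, size=len(pids), replace=True)
        boot = pd.concat([groups[p] for p in take])
        m = _point_metrics(boot)
        for task, d in m.items():
            for name, v in d.items():
                if v is not None:
                    samples.setdefault((task, name), []).append(v)
    metrics: dict[str, dict] = {}
    for task, d in point.items():
        metrics[task] = {}
        for name, v in d.items():
            if v is None:
                metrics[task][name] = None
                continue
            s = samples.get((task, name), [])
            lo, hi = (np.percentile(s, [2.5, 97.5]) if s else (np.nan, np.nan))
            metrics[task][name] = (float(v), float(lo), float(hi))
    return MetricReport(metrics=metrics, n_bootstrap=n_bootstrap, seed=seed)
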