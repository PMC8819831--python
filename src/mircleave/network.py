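"""Recurrent cut-site labeling network, implemented on numpy.

Architecture: embedding -> dropout -> bidirectional LSTM -> (optional second
bidirectional LSTM) -> time-distributed dense with a 5-way softmax per
position (DR5, DC5, DC3, DR3, O).  Training minimizes per-position
categorical cross-entropy with Adam and early stopping on validation loss.
Padding uses a reserved token with masking, so batch padding never changes
decision values.

Decoding: each of the four cut classes is called at the position where its
softmax weight peaks (leftmost position on ties); the O class is never
called, so every cut class is labeled exactly once per sequence.  An
ensemble averages the decision-value matrices of its member replicates
before the same calling rule is applied.

The implementation is deliberately framework-free: forward and backward
passes are hand-derived and checked against numerical gradients in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .encoding import (
    INPUT_MODES,
    LABEL_CLASSES,
    LabeledExample,
    O_INDEX,
    PAD,
    vocab_size,
)
from .records import CUT_CLASSES


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass
class ModelConfig:
    """Hyperparameters of one replicate.

    ``lstm1_units``/``lstm2_units`` are units per direction; ``lstm2_units``
    of 0 selects the single-recurrent-layer variant.  Adam's epsilon is
    ``10 ** epsilon_exp``.  The shipped presets (:data:`PRESETS`) are the
    tuned combinations for each input mode; the tuning search space itself
    (dropout 0-0.5, embedding {32..160}, LSTM {64..320} / {0, 64..320},
    learning rate 1e-5..0.1, epsilon 1e-10..1e-4) is documented here as
    config bounds only.
    """

    input_mode: str = "seq_bprna"
    embedding_dim: int = 32
    dropout: float = 0.417
    lstm1_units: int = 128
    lstm2_units: int = 320
    learning_rate: float = 3.57e-3
    epsilon_exp: float = -6.87
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    clip_norm: float = 5.0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if not 0.0 <= self.dropout <= 0.5:
            raise ValueError("dropout must be in [0, 0.5]")
        if self.lstm1_units <= 0:
            raise ValueError("lstm1_units must be positive")


#: tuned defaults for the three input modes
PRESETS = {
    "seq": ModelConfig("seq_only", 96, 0.315, 320, 192, 3.2e-3, -7.56),
    "db": ModelConfig("seq_dotbracket", 32, 0.213, 64, 256, 1.91e-3, -6.79),
    "bprna": ModelConfig("seq_bprna", 32, 0.417, 128, 320, 3.57e-3, -6.87),
}


@dataclass
class PredictionResult:
    """Per-position decision values and the four called cut positions."""

    decision_values: np.ndarray  # (positions, 5), rows sum to 1
    called_cuts: dict[str, int]
    record_id: str = ""


def call_cuts(decision_values: np.ndarray) -> dict[str, int]:
    """Leftmost argmax per cut-class column; O is never called."""
    return {
        cls: int(np.argmax(decision_values[:, LABEL_CLASSES.index(cls)]))
        for cls in CUT_CLASSES
    }


def normalized_binary_predict(
    result: PredictionResult, cls: str, threshold: float = 0.5
) -> np.ndarray:
    """Per-position booleans after max-normalizing one class column.

    The column is divided by its maximum over the sequence; positions whose
    normalized decision value exceeds ``threshold`` are positive.  This is
    the comparison mode used against window-classifier baselines.
    """
    col = result.decision_values[:, LABEL_CLASSES.index(cls)]
    peak = float(col.max())
    if peak <= 0.0:
        raise ValueError(f"all-zero decision values for class {cls}")
    return (col / peak) > threshold


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _orthogonal(rng, shape, dtype):
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    return (q if shape[0] >= shape[1] else q.T).astype(dtype)


def _glorot(rng, shape, dtype):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class _LSTM:
    """One LSTM direction; gates ordered (input, forget, cell, output)."""

    def __init__(self, rng, in_dim: int, units: int, dtype):
        self.units = units
        self.W = _glorot(rng, (in_dim, 4 * units), dtype)
        self.U = np.concatenate(
            [_orthogonal(rng, (units, units), dtype) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units : 2 * units] = 1.0  # forget-gate bias

    def params(self):
        return {"W": self.W, "U": self.U, "b": self.b}

    def forward(self, x, mask, reverse: bool, training: bool):
        B, T, _ = x.shape
        H = self.units
        ax = x @ self.W  # (B, T, 4H), input contribution precomputed
        hs = np.zeros((B, T, H), dtype=x.dtype)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        times = range(T - 1, -1, -1) if reverse else range(T)
        cache = None
        if training:
            cache = {
                k: np.zeros((T, B, H), dtype=x.dtype)
                for k in ("i", "f", "g", "o", "tc", "c_prev", "h_prev")
            }
        for t in times:
            a = ax[:, t] + h @ self.U + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_cell = f * c + i * g
            tc = np.tanh(c_cell)
            m = mask[:, t : t + 1]
            if training:
                cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t] = i, f, g, o
                cache["tc"][t], cache["c_prev"][t], cache["h_prev"][t] = tc, c, h
            c = m * c_cell + (1.0 - m) * c
            h = m * (o * tc) + (1.0 - m) * h
            hs[:, t] = h
        return hs, (cache, x, mask, reverse)

    def backward(self, ctx, dhs):
        cache, x, mask, reverse = ctx
        B, T, _ = x.shape
        H = self.units
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_carry = np.zeros((B, H), dtype=x.dtype)
        dc_carry = np.zeros((B, H), dtype=x.dtype)
        times = range(T - 1, -1, -1) if reverse else range(T)
        for t in reversed(list(times)):
            m = mask[:, t : t + 1]
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            tc, c_prev, h_prev = cache["tc"][t], cache["c_prev"][t], cache["h_prev"][t]
            dh = dhs[:, t] + dh_carry
            dhc = m * dh
            dh_pass = (1.0 - m) * dh
            dc_cell = m * dc_carry + dhc * o * (1.0 - tc * tc)
            dc_pass = (1.0 - m) * dc_carry
            do = dhc * tc
            di = dc_cell * g
            dg = dc_cell * i
            df = dc_cell * c_prev
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x[:, t].T @ da
            dU += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ self.W.T
            dh_carry = da @ self.U.T + dh_pass
            dc_carry = dc_cell * f + dc_pass
        return dx, {"W": dW, "U": dU, "b": db}


class _BiLSTM:
    def __init__(self, rng, in_dim: int, units: int, dtype):
        self.fwd = _LSTM(rng, in_dim, units, dtype)
        self.bwd = _LSTM(rng, in_dim, units, dtype)
        self.out_dim = 2 * units

    def forward(self, x, mask, training=False):
        hf, ctx_f = self.fwd.forward(x, mask, reverse=False, training=training)
        hb, ctx_b = self.bwd.forward(x, mask, reverse=True, training=training)
        return np.concatenate([hf, hb], axis=2), (ctx_f, ctx_b)

    def backward(self, ctx, dh):
        H = self.fwd.units
        dx_f, grads_f = self.fwd.backward(ctx[0], dh[:, :, :H])
        dx_b, grads_b = self.bwd.backward(ctx[1], dh[:, :, H:])
        return dx_f + dx_b, (grads_f, grads_b)


class CutSiteModel:
    """Embedding -> dropout -> Bi-LSTM (x1 or x2) -> per-position softmax(5)."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.vocab = vocab_size(cfg.input_mode)
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self.embedding = (
            rng.uniform(-0.05, 0.05, size=(self.vocab, cfg.embedding_dim)).astype(dtype)
        )
        self.layers = [_BiLSTM(rng, cfg.embedding_dim, cfg.lstm1_units, dtype)]
        if cfg.lstm2_units:
            self.layers.append(
                _BiLSTM(rng, self.layers[0].out_dim, cfg.lstm2_units, dtype)
            )
        self.Wd = _glorot(rng, (self.layers[-1].out_dim, len(LABEL_CLASSES)), dtype)
        self.bd = np.zeros(len(LABEL_CLASSES), dtype=dtype)

    # -- parameter bookkeeping ---------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params = {"embedding": self.embedding, "Wd": self.Wd, "bd": self.bd}
        for li, layer in enumerate(self.layers):
            for side, cell in (("f", layer.fwd), ("b", layer.bwd)):
                for name, arr in cell.params().items():
                    params[f"lstm{li}{side}_{name}"] = arr
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.embedding = params["embedding"]
        self.Wd, self.bd = params["Wd"], params["bd"]
        for li, layer in enumerate(self.layers):
            for side, cell in (("f", layer.fwd), ("b", layer.bwd)):
                cell.W = params[f"lstm{li}{side}_W"]
                cell.U = params[f"lstm{li}{side}_U"]
                cell.b = params[f"lstm{li}{side}_b"]

    # -- forward / backward ------------------------------------------------

    def _forward(self, X, mask, training=False, drop_rng=None):
        emb = self.embedding[X] * mask[:, :, None]
        drop_mask = None
        if training and self.cfg.dropout > 0.0:
            keep = 1.0 - self.cfg.dropout
            drop_mask = (
                drop_rng.random(emb.shape) < keep
            ).astype(emb.dtype) / keep
            emb = emb * drop_mask
        h = emb
        ctxs = []
        for layer in self.layers:
            h, ctx = layer.forward(h, mask, training=training)
            ctxs.append(ctx)
        logits = h @ self.Wd + self.bd
        z = logits - logits.max(axis=2, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=2, keepdims=True)
        return probs, (X, mask, emb, drop_mask, ctxs, h)

    def loss_and_grads(self, X, mask, Y, drop_rng):
        probs, ctx = self._forward(X, mask, training=True, drop_rng=drop_rng)
        _, _, emb, drop_mask, ctxs, h_last = ctx
        n_valid = mask.sum()
        p_true = np.take_along_axis(probs, Y[:, :, None], axis=2)[:, :, 0]
        loss = -(np.log(np.maximum(p_true, 1e-12)) * mask).sum() / n_valid
        if not np.isfinite(loss):
            raise TrainingDivergedError("non-finite training loss")

        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, Y[:, :, None], np.take_along_axis(dlogits, Y[:, :, None], axis=2) - 1.0, axis=2
        )
        dlogits *= (mask / n_valid)[:, :, None]
        grads = {
            "Wd": np.tensordot(h_last, dlogits, axes=([0, 1], [0, 1])),
            "bd": dlogits.sum(axis=(0, 1)),
        }
        dh = dlogits @ self.Wd.T
        for li in range(len(self.layers) - 1, -1, -1):
            dh, (gf, gb) = self.layers[li].backward(ctxs[li], dh)
            for side, g in (("f", gf), ("b", gb)):
                for name, arr in g.items():
                    grads[f"lstm{li}{side}_{name}"] = arr
        if drop_mask is not None:
            dh = dh * drop_mask
        dh = dh * mask[:, :, None]
        dE = np.zeros_like(self.embedding)
        np.add.at(dE, X, dh)
        grads["embedding"] = dE
        return float(loss), grads

    # -- inference ---------------------------------------------------------

    def predict_scores(self, token_arrays: Sequence[np.ndarray]) -> list[np.ndarray]:
        """Decision-value matrices (len, 5) for a list of token arrays."""
        out = []
        bs = self.cfg.batch_size
        for lo in range(0, len(token_arrays), bs):
            chunk = token_arrays[lo : lo + bs]
            X, mask, lens = _pad_batch(chunk, np.dtype(self.cfg.dtype))
            probs, _ = self._forward(X, mask, training=False)
            out.extend(probs[i, : lens[i]].astype(np.float64) for i in range(len(chunk)))
        return out

    def predict(self, example: LabeledExample) -> PredictionResult:
        scores = self.predict_scores([example.tokens])[0]
        return PredictionResult(scores, call_cuts(scores), example.record_id)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.json").write_text(json.dumps(asdict(self.cfg), indent=1))
        np.savez(path / "weights.npz", **self.parameters())

    @classmethod
    def load(cls, path) -> "CutSiteModel":
        path = Path(path)
        cfg = ModelConfig(**json.loads((path / "config.json").read_text()))
        model = cls(cfg)
        with np.load(path / "weights.npz") as data:
            model.set_parameters({k: data[k].copy() for k in data.files})
        return model


def build_network(cfg: ModelConfig) -> CutSiteModel:
    """Construct an untrained network for the given configuration."""
    return CutSiteModel(cfg)


def _pad_batch(token_arrays, dtype):
    lens = [len(t) for t in token_arrays]
    T = max(lens)
    X = np.full((len(token_arrays), T), PAD, dtype=np.int32)
    mask = np.zeros((len(token_arrays), T), dtype=dtype)
    for i, toks in enumerate(token_arrays):
        X[i, : lens[i]] = toks
        mask[i, : lens[i]] = 1.0
    return X, mask, lens


def _pad_labels(examples, T):
    Y = np.full((len(examples), T), O_INDEX, dtype=np.int64)
    for i, ex in enumerate(examples):
        Y[i, : len(ex.labels)] = ex.labels
    return Y


class _Adam:
    def __init__(self, params, lr, eps):
        self.lr, self.eps = lr, eps
        self.beta1, self.beta2 = 0.9, 0.999
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, clip_norm):
        gnorm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values()))
        scale = clip_norm / gnorm if (clip_norm and gnorm > clip_norm) else 1.0
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k] * scale
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            p -= (
                self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            ).astype(p.dtype)


def _epoch_loss(model, examples):
    """Masked cross-entropy of a labeled set under the current weights."""
    total, n = 0.0, 0
    bs = model.cfg.batch_size
    for lo in range(0, len(examples), bs):
        chunk = examples[lo : lo + bs]
        X, mask, _ = _pad_batch([ex.tokens for ex in chunk], np.dtype(model.cfg.dtype))
        Y = _pad_labels(chunk, X.shape[1])
        probs, _ = model._forward(X, mask, training=False)
        p_true = np.take_along_axis(probs, Y[:, :, None], axis=2)[:, :, 0]
        total += float(-(np.log(np.maximum(p_true, 1e-12)) * mask).sum())
        n += int(mask.sum())
    return total / max(n, 1)


def train_replicate(
    model: CutSiteModel,
    train: Sequence[LabeledExample],
    val: Sequence[LabeledExample],
    cfg: Optional[ModelConfig] = None,
) -> tuple[CutSiteModel, dict[str, list[float]]]:
    """Train one replicate with Adam and early stopping on validation loss.

    Returns the model (with the best-validation weights restored) and the
    loss history.  Reproducible for a fixed ``cfg.seed`` on a fixed BLAS.
    Raises :class:`TrainingDivergedError` if the loss goes non-finite.
    """
    if not train or not val:
        raise ValueError("train and validation sets must be non-empty")
    cfg = cfg or model.cfg
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    optimizer = _Adam(model.parameters(), cfg.learning_rate, 10.0**cfg.epsilon_exp)
    history: dict[str, list[float]] = {"loss": [], "val_loss": []}
    best_val = np.inf
    best_params = None
    stale = 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train))
        epoch_total, epoch_n = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            chunk = [train[i] for i in order[lo : lo + cfg.batch_size]]
            X, mask, _ = _pad_batch([ex.tokens for ex in chunk], np.dtype(cfg.dtype))
            Y = _pad_labels(chunk, X.shape[1])
            loss, grads = model.loss_and_grads(X, mask, Y, drop_rng=rng)
            params = model.parameters()
            optimizer.step(params, grads, cfg.clip_norm)
            nv = int(mask.sum())
            epoch_total += loss * nv
            epoch_n += nv
        history["loss"].append(epoch_total / epoch_n)
        vloss = _epoch_loss(model, val)
        history["val_loss"].append(vloss)
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_params = {k: v.copy() for k, v in model.parameters().items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_params is not None:
        model.set_parameters(best_params)
    return model, history


# ---------------------------------------------------------------------------
# ensembles


def ensemble_predict(
    models: Sequence[CutSiteModel], example: LabeledExample
) -> PredictionResult:
    """Average member decision values, then apply the standard calling rule."""
    if not models:
        raise ValueError("ensemble requires at least one model")
    modes = {m.cfg.input_mode for m in models}
    if len(modes) > 1:
        raise ValueError(f"ensemble members disagree on input mode: {modes}")
    scores = [m.predict_scores([example.tokens])[0] for m in models]
    mean = np.mean(scores, axis=0)
    return PredictionResult(mean, call_cuts(mean), example.record_id)


def select_ensemble(
    models: Sequence[CutSiteModel],
    val_examples: Sequence[LabeledExample],
    max_size: int = 12,
) -> list[CutSiteModel]:
    """Pick the ensemble by the validation PSE curve.

    Members are added in decreasing order of single-model validation PMF
    (averaged over the four cut classes); the ensemble size minimizing the
    mean validation PSE is returned (capped at ``max_size``, 12 by default).
    """
    from .metrics import evaluate_predictions

    def truth(ex):
        return {
            cls: int(np.flatnonzero(ex.labels == LABEL_CLASSES.index(cls))[0])
            for cls in CUT_CLASSES
            if np.any(ex.labels == LABEL_CLASSES.index(cls))
        }

    truths = {ex.record_id: truth(ex) for ex in val_examples}

    def mean_metric(preds, key):
        report = evaluate_predictions(preds, truths)
        vals = [getattr(report[c], key) for c in CUT_CLASSES if report[c].n_examples]
        return float(np.mean(vals))

    single_pmf = []
    per_model_scores = []
    for m in models:
        scores = m.predict_scores([ex.tokens for ex in val_examples])
        per_model_scores.append(scores)
        preds = {
            ex.record_id: call_cuts(s) for ex, s in zip(val_examples, scores)
        }
        single_pmf.append(mean_metric(preds, "pmf"))
    order = sorted(range(len(models)), key=lambda i: (-single_pmf[i], i))

    best_size, best_pse = 1, np.inf
    running = None
    for k, idx in enumerate(order[:max_size], start=1):
        add = per_model_scores[idx]
        running = add if running is None else [r + a for r, a in zip(running, add)]
        preds = {
            ex.record_id: call_cuts(s / k) for ex, s in zip(val_examples, running)
        }
        pse = mean_metric(preds, "pse")
        if pse < best_pse - 1e-12:
            best_pse, best_size = pse, k
    return [models[i] for i in order[:best_size]]


def save_ensemble(path, models: Sequence[CutSiteModel]) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = []
    for i, m in enumerate(models):
        name = f"replicate_{i:02d}"
        m.save(path / name)
        names.append(name)
    (path / "manifest.json").write_text(json.dumps({"replicates": names}, indent=1))


def load_ensemble(path) -> list[CutSiteModel]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    return [CutSiteModel.load(path / name) for name in manifest["replicates"]]
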