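"""Multitask sequence-to-signal convolutional regressor.

A single-convolution-layer network mapping one-hot-encoded 600 nt DNA to
per-task log2 RPKM binding levels: convolution (64 filters of width 12,
stride 2) → ReLU → average pooling (global by default) → one dense ReLU
layer (64 units) → linear head with one output per task. Average pooling is
the inductive bias matched to regression on motif content: pooled filter
activations are linear in motif copy number, and a stride no larger than
``filter_width - motif_length + 1`` still scores every motif instance at
full strength. The default task list is the seven
ChIP-seq tracks of the study design (two HOXA2-BA2 replicates, two
HOXA3-PBA replicates, MEIS in BA1/BA2/PBA). Transfer learning copies the
convolution filters from a single-task source model, optionally freezing
them for the first epochs of fine-tuning.

The network is implemented directly in numpy (forward, manual backprop,
Adam). It is small enough that one CPU trains the paper-scale 6795-region
dataset in minutes, and a fixed seed with single-threaded BLAS reproduces
the weights exactly. Sensitivity maps report the predicted change in every
task when each base is mutated to each alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .diffbind import Sample

__all__ = [
    "DEFAULT_TASKS",
    "encode",
    "decode",
    "CNNRegressor",
    "build",
    "train",
    "transfer",
    "predict",
    "sensitivity_map",
    "SensitivityMap",
    "save_checkpoint",
    "load_checkpoint",
]

DEFAULT_TASKS: tuple[Sample, ...] = (
    Sample("HOXA2", "BA2", 1), Sample("HOXA2", "BA2", 2),
    Sample("HOXA3", "PBA", 1), Sample("HOXA3", "PBA", 2),
    Sample("MEIS", "BA1", 1), Sample("MEIS", "BA2", 1), Sample("MEIS", "PBA", 1),
)

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def encode(seq: str, length: int = 600) -> np.ndarray:
    """One-hot encode a DNA string to a (length, 4) float32 matrix.

    A/C/G/T become unit rows in fixed column order; N becomes a zero row, so
    erased or unknown content contributes nothing. Sequences shorter than
    ``length`` are centre-padded with zero rows. Characters outside ACGTN
    raise.
    """
    seq = seq.upper()
    if len(seq) > length:
        raise ValueError(f"sequence length {len(seq)} exceeds {length}")
    mat = np.zeros((length, 4), dtype=np.float32)
    lead = (length - len(seq)) // 2
    for i, ch in enumerate(seq):
        if ch == "N":
            continue
        j = _BASE_IDX.get(ch)
        if j is None:
            raise ValueError(f"non-ACGTN character {ch!r} at position {i}")
        mat[lead + i, j] = 1.0
    return mat


def decode(mat: np.ndarray) -> str:
    """Inverse of :func:`encode` (zero rows decode to N)."""
    out = []
    for row in mat:
        s = row.sum()
        out.append("N" if s == 0 else _BASES[int(np.argmax(row))])
    return "".join(out)


def encode_batch(seqs, length: int = 600) -> np.ndarray:
    return np.stack([encode(s, length) for s in seqs])


@dataclass(slots=True)
class CNNRegressor:
    """Architecture, weights and provenance of the regressor.

    ``weights`` is None until :func:`train` runs (or conv weights only after
    :func:`transfer`). All hyperparameters are stand-ins exposed in config;
    the one architectural commitment is the single convolution layer.
    """

    tasks: tuple[Sample, ...]
    n_filters: int = 64
    filter_width: int = 12
    conv_stride: int = 2
    pool: int = 295
    pool_mode: str = "avg"
    dense: int = 64
    input_length: int = 600
    weights: dict | None = None
    conv_only: bool = False       # True after transfer, before fine-tune
    freeze_epochs: int = 0
    training_log: list = field(default_factory=list)
    seed: int | None = None

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_positions(self) -> int:
        return (self.input_length - self.filter_width) // self.conv_stride + 1

    @property
    def n_pool(self) -> int:
        return self.n_positions // self.pool

    def param_count(self) -> int:
        K = 4 * self.filter_width
        return (K * self.n_filters + self.n_filters
                + self.n_pool * self.n_filters * self.dense + self.dense
                + self.dense * self.n_tasks + self.n_tasks)

    @property
    def trained(self) -> bool:
        return self.weights is not None and not self.conv_only


def build(tasks=DEFAULT_TASKS, n_filters: int = 64, filter_width: int = 12,
          conv_stride: int = 2, pool: int | None = None, pool_mode: str = "avg",
          dense: int = 64, input_length: int = 600) -> CNNRegressor:
    """An untrained regressor with one linear output per task.

    ``pool_mode`` is ``"avg"`` (default; the additive inductive bias suited
    to regression on motif content — summed filter activations are linear in
    motif copy number) or ``"max"``. ``pool=None`` pools globally over all
    convolution positions. ``conv_stride`` up to ``filter_width - L + 1``
    still scores every motif of length L at full strength; the default
    stride 2 with width-12 filters covers motifs up to 11 nt.
    """
    for h in (n_filters, filter_width, conv_stride, dense, input_length):
        if h <= 0:
            raise ValueError("hyperparameters must be positive")
    if pool_mode not in ("avg", "max"):
        raise ValueError(f"pool_mode must be 'avg' or 'max', got {pool_mode!r}")
    n_positions = (input_length - filter_width) // conv_stride + 1
    if pool is None:
        pool = n_positions
    if pool <= 0:
        raise ValueError("hyperparameters must be positive")
    return CNNRegressor(tuple(tasks), n_filters, filter_width, conv_stride,
                        pool, pool_mode, dense, input_length)


def _init_weights(model: CNNRegressor, rng: np.random.Generator,
                  keep_conv: bool = False) -> dict:
    K = 4 * model.filter_width
    w = dict(model.weights) if (keep_conv and model.weights) else {}
    if not keep_conv or "Wc" not in w:
        w["Wc"] = (rng.standard_normal((K, model.n_filters)) *
                   np.sqrt(2.0 / K)).astype(np.float32)
        w["bc"] = np.zeros(model.n_filters, dtype=np.float32)
    H = model.n_pool * model.n_filters
    w["W2"] = (rng.standard_normal((H, model.dense)) *
               np.sqrt(2.0 / H)).astype(np.float32)
    w["b2"] = np.zeros(model.dense, dtype=np.float32)
    w["W3"] = (rng.standard_normal((model.dense, model.n_tasks)) *
               np.sqrt(1.0 / model.dense)).astype(np.float32)
    w["b3"] = np.zeros(model.n_tasks, dtype=np.float32)
    return w


def _im2col(X: np.ndarray, width: int, stride: int = 1) -> np.ndarray:
    # X: (B, L, 4) -> (B, (L-width)//stride+1, width*4)
    v = np.lib.stride_tricks.sliding_window_view(X, (width, 4), axis=(1, 2))
    v = v[:, ::stride]
    B, P = v.shape[0], v.shape[1]
    return np.ascontiguousarray(v.reshape(B, P, width * 4))


def _forward(w: dict, Xc: np.ndarray, model: CNNRegressor, want_grad: bool = False):
    B = Xc.shape[0]
    Z1 = Xc @ w["Wc"] + w["bc"]
    A1 = np.maximum(Z1, 0.0)
    P_used = model.n_pool * model.pool
    A1r = A1[:, :P_used].reshape(B, model.n_pool, model.pool, model.n_filters)
    if model.pool_mode == "max":
        arg = A1r.argmax(axis=2)
        pooled = np.take_along_axis(A1r, arg[:, :, None, :], axis=2)[:, :, 0, :]
    else:
        arg = None
        pooled = A1r.mean(axis=2)
    H = pooled.reshape(B, -1)
    Z2 = H @ w["W2"] + w["b2"]
    A2 = np.maximum(Z2, 0.0)
    Y = A2 @ w["W3"] + w["b3"]
    if not want_grad:
        return Y
    return Y, (Z1, arg, H, Z2, A2, P_used)


def _backward(w: dict, Xc: np.ndarray, cache, dY: np.ndarray,
              model: CNNRegressor, freeze_conv: bool) -> dict:
    Z1, arg, H, Z2, A2, P_used = cache
    B = Xc.shape[0]
    grads = {}
    grads["W3"] = A2.T @ dY
    grads["b3"] = dY.sum(axis=0)
    dA2 = dY @ w["W3"].T
    dZ2 = dA2 * (Z2 > 0)
    grads["W2"] = H.T @ dZ2
    grads["b2"] = dZ2.sum(axis=0)
    if freeze_conv:
        return grads
    dH = (dZ2 @ w["W2"].T).reshape(B, model.n_pool, model.n_filters)
    if model.pool_mode == "max":
        dA1r = np.zeros((B, model.n_pool, model.pool, model.n_filters),
                        dtype=np.float32)
        np.put_along_axis(dA1r, arg[:, :, None, :], dH[:, :, None, :], axis=2)
    else:
        dA1r = np.broadcast_to(
            (dH / model.pool)[:, :, None, :],
            (B, model.n_pool, model.pool, model.n_filters))
    dZ1 = dA1r.reshape(B, P_used, model.n_filters) * (Z1[:, :P_used] > 0)
    Xt = Xc[:, :P_used].reshape(B * P_used, -1)
    grads["Wc"] = Xt.T @ dZ1.reshape(B * P_used, -1)
    grads["bc"] = dZ1.sum(axis=(0, 1))
    return grads


def train(model: CNNRegressor, X, Y: np.ndarray, *, epochs: int = 30,
          lr: float = 3e-2, batch: int = 64, seed: int = 0,
          val_fraction: float = 0.2, weight_decay: float = 1e-5,
          mask: np.ndarray | None = None, patience: int = 25,
          augment_rc: bool = True, lr_schedule: str = "cosine",
          verbose: bool = False) -> CNNRegressor:
    """Train (or fine-tune) the regressor with Adam on mean-squared error.

    ``X`` is (n, L, 4) one-hot (or a list of sequences), ``Y`` is (n, T)
    log2 RPKM targets; ``mask`` marks observed entries (missing task values
    are simply excluded from the loss). A random ``val_fraction`` split is
    held out; the weights with the best validation loss are restored at the
    end, and the per-epoch log is stored on the model. With ``augment_rc``
    (default) half of each batch is reverse-complemented, so motifs planted on
    either strand train the same filters; pair it with the strand-averaged
    :func:`predict`. ``lr_schedule`` is "cosine" (decay to 5% of ``lr``) or
    "constant". Fixed seed plus single-threaded BLAS reproduces the weights
    exactly. Convolution weights present from :func:`transfer` are kept and
    frozen for the model's ``freeze_epochs`` first epochs.
    """
    if isinstance(X, (list, tuple)):
        X = encode_batch(X, model.input_length)
    X = np.asarray(X, dtype=np.float32)
    Y = np.asarray(Y, dtype=np.float32)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if Y.shape[1] != model.n_tasks:
        raise ValueError(f"Y has {Y.shape[1]} columns for {model.n_tasks} tasks")
    M = (np.ones_like(Y, dtype=np.float32) if mask is None
         else np.asarray(mask, dtype=np.float32))
    if lr_schedule not in ("cosine", "constant"):
        raise ValueError(f"unknown lr_schedule {lr_schedule!r}")

    rng = np.random.default_rng(seed)
    keep_conv = model.weights is not None and "Wc" in model.weights
    w = _init_weights(model, rng, keep_conv=keep_conv)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if val_fraction > 0 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ytr, Mtr = X[tr_idx], Y[tr_idx], M[tr_idx]
    Xv = (_im2col(X[val_idx], model.filter_width, model.conv_stride)
          if n_val else None)
    Yv, Mv = Y[val_idx], M[val_idx]

    mom = {k: np.zeros_like(v) for k, v in w.items()}
    vel = {k: np.zeros_like(v) for k, v in w.items()}
    b1, b2_, eps = 0.9, 0.999, 1e-8
    step = 0
    log = []
    best_val, best_w, since_best = np.inf, None, 0

    def _val_loss():
        if n_val == 0:
            return float("nan")
        preds = _forward(w, Xv, model)
        return float((((preds - Yv) ** 2) * Mv).sum() / max(Mv.sum(), 1.0))

    for epoch in range(epochs):
        freeze = keep_conv and epoch < model.freeze_epochs
        if lr_schedule == "cosine":
            frac = epoch / max(epochs - 1, 1)
            lr_t = lr * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))
        else:
            lr_t = lr
        order = rng.permutation(len(tr_idx))
        tr_loss, seen = 0.0, 0.0
        for start in range(0, len(order), batch):
            idx = order[start:start + batch]
            Xb, Yb, Mb = Xtr[idx], Ytr[idx], Mtr[idx]
            if augment_rc:
                flip = rng.random(len(idx)) < 0.5
                if flip.any():
                    Xb = Xb.copy()
                    Xb[flip] = Xb[flip][:, ::-1, ::-1]
            Xc = _im2col(Xb, model.filter_width, model.conv_stride)
            Yh, cache = _forward(w, Xc, model, want_grad=True)
            diff = (Yh - Yb) * Mb
            denom = max(float(Mb.sum()), 1.0)
            loss = float((diff ** 2).sum() / denom)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, step {step}; "
                    f"lr={lr_t}, batch={batch}")
            tr_loss += loss * denom
            seen += denom
            dY = (2.0 * diff / denom).astype(np.float32)
            grads = _backward(w, Xc, cache, dY, model, freeze)
            step += 1
            for k, g in grads.items():
                if weight_decay and k in ("Wc", "W2", "W3"):
                    g = g + weight_decay * w[k]
                mom[k] = b1 * mom[k] + (1 - b1) * g
                vel[k] = b2_ * vel[k] + (1 - b2_) * g * g
                mhat = mom[k] / (1 - b1 ** step)
                vhat = vel[k] / (1 - b2_ ** step)
                w[k] = (w[k] - lr_t * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)
        vl = _val_loss()
        log.append({"epoch": epoch, "train_loss": tr_loss / max(seen, 1.0),
                    "val_loss": vl, "lr": float(lr_t),
                    "frozen_conv": bool(freeze)})
        if verbose:
            print(f"epoch {epoch}: train {log[-1]['train_loss']:.4f} val {vl:.4f}")
        if n_val and vl < best_val - 1e-6:
            best_val, since_best = vl, 0
            best_w = {k: v.copy() for k, v in w.items()}
        elif n_val:
            since_best += 1
            if since_best >= patience:
                break
    if best_w is not None:
        w = best_w
    model.weights = w
    model.conv_only = False
    model.training_log = log
    model.seed = seed
    return model


def transfer(source: CNNRegressor, target_tasks, freeze_epochs: int = 3
             ) -> CNNRegressor:
    """New model reusing the source's convolution filters.

    The head is discarded (reinitialized at the next :func:`train` call);
    convolution weights are copied bit-identically and frozen for the first
    ``freeze_epochs`` epochs of fine-tuning. The source must be trained and
    the architectures must share convolution hyperparameters (enforced by
    construction here).
    """
    if source.weights is None:
        raise ValueError("source model has no weights to transfer")
    target = CNNRegressor(tuple(target_tasks), source.n_filters,
                          source.filter_width, source.conv_stride, source.pool,
                          source.pool_mode, source.dense, source.input_length)
    target.weights = {"Wc": source.weights["Wc"].copy(),
                      "bc": source.weights["bc"].copy()}
    target.conv_only = True
    target.freeze_epochs = freeze_epochs
    return target


def predict(model: CNNRegressor, X, batch: int = 512,
            rc_average: bool = True) -> np.ndarray:
    """Deterministic per-region per-task predictions, shape (n, T).

    With ``rc_average`` (default) the forward- and reverse-complement-strand
    predictions are averaged, matching reverse-complement-augmented training.
    """
    if not model.trained:
        raise ValueError("model is not trained")
    if isinstance(X, (list, tuple)):
        X = encode_batch(X, model.input_length)
    X = np.asarray(X, dtype=np.float32)
    single = X.ndim == 2
    if single:
        X = X[None]
    out = np.empty((X.shape[0], model.n_tasks), dtype=np.float32)
    for start in range(0, X.shape[0], batch):
        Xb = X[start:start + batch]
        Xc = _im2col(Xb, model.filter_width, model.conv_stride)
        pred = _forward(model.weights, Xc, model)
        if rc_average:
            Xc_rc = _im2col(np.ascontiguousarray(Xb[:, ::-1, ::-1]),
                            model.filter_width, model.conv_stride)
            pred = 0.5 * (pred + _forward(model.weights, Xc_rc, model))
        out[start:start + Xb.shape[0]] = pred
    return out[0] if single else out


@dataclass(slots=True)
class SensitivityMap:
    """Predicted effect of every single-base substitution in one region.

    ``delta`` has shape (L, 4, T): predicted change per position, alternative
    base and task; entries at the reference base are exactly zero.
    ``combined`` (L, T) sums |delta| over the three alternatives per task;
    ``pooled`` (L,) further sums over tasks.
    """

    region_id: str
    reference: str
    delta: np.ndarray
    combined: np.ndarray
    pooled: np.ndarray
    tasks: tuple


def sensitivity_map(model: CNNRegressor, seq: str,
                    region_id: str = "") -> SensitivityMap:
    """Per-position single-nucleotide mutational sensitivity of predictions."""
    if not model.trained:
        raise ValueError("model is not trained")
    ref = encode(seq, model.input_length)
    L = model.input_length
    base = predict(model, ref)
    mutants, where = [], []
    for pos in range(L):
        for b in range(4):
            if ref[pos, b] == 1.0:
                continue
            m = ref.copy()
            m[pos] = 0.0
            m[pos, b] = 1.0
            mutants.append(m)
            where.append((pos, b))
    preds = predict(model, np.stack(mutants)) if mutants else np.empty((0, model.n_tasks))
    delta = np.zeros((L, 4, model.n_tasks), dtype=np.float32)
    for (pos, b), pr in zip(where, preds):
        delta[pos, b] = pr - base
    combined = np.abs(delta).sum(axis=1)
    return SensitivityMap(region_id, seq, delta, combined,
                          combined.sum(axis=1), model.tasks)


# ---------------------------------------------------------------------------
# Checkpoints (self-describing JSON; weights as nested lists — text-only)


def save_checkpoint(model: CNNRegressor, path) -> None:
    payload = {
        "tasks": [[s.factor, s.tissue, s.replicate] for s in model.tasks],
        "hyper": {"n_filters": model.n_filters, "filter_width": model.filter_width,
                  "conv_stride": model.conv_stride, "pool": model.pool,
                  "pool_mode": model.pool_mode, "dense": model.dense,
                  "input_length": model.input_length},
        "seed": model.seed,
        "freeze_epochs": model.freeze_epochs,
        "conv_only": model.conv_only,
        "training_log": model.training_log,
        "weights": {k: v.tolist() for k, v in (model.weights or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> CNNRegressor:
    with open(path) as fh:
        payload = json.load(fh)
    tasks = tuple(Sample(f, t, r) for f, t, r in payload["tasks"])
    model = CNNRegressor(tasks, **payload["hyper"])
    if payload["weights"]:
        model.weights = {k: np.array(v, dtype=np.float32)
                         for k, v in payload["weights"].items()}
    model.conv_only = payload.get("conv_only", False)
    model.freeze_epochs = payload.get("freeze_epochs", 0)
    model.training_log = payload.get("training_log", [])
    model.seed = payload.get("seed")
    return model
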