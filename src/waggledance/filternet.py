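"""3D convolutional filter network for snippet sequences, in pure numpy.

The attention module is deliberately tuned for sensitivity, so its output
contains non-dance events (walking bees, grooming pulses). This module
scores each exported 50x50 px snippet sequence with a small 3D convolutional
network — two stacked 3D convolution layers with SELU nonlinearities,
global average pooling over time and space, dropout, and a single
fully connected sigmoid output — and discards sequences below a threshold.

The network, its forward/backward passes and the Adam optimizer are
implemented directly on numpy arrays (im2col convolutions; gradients are
verified against finite differences in the test suite). Training follows
the snippet-filtering protocol: random 128-frame subsequences per mini
batch, zero padding of shorter detections, random horizontal/vertical
flips, Adam on binary cross-entropy, and a held-out validation split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from waggledance.config import FilterConfig

__all__ = [
    "LabeledClip",
    "FilterNet",
    "build_network",
    "augment",
    "prepare_clip",
    "train",
    "filter_runs",
    "save_model",
    "load_model",
]

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


@dataclass
class LabeledClip:
    """A snippet sequence with a binary behavioral label."""

    frames: np.ndarray  # (T, H, W) uint8
    label: int  # 1 = waggle, 0 = non_waggle


def _selu(x):
    neg = np.exp(np.minimum(x, 0.0)) - 1.0  # clamp: where() evaluates both branches
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * neg)


def _selu_grad(x):
    neg = np.exp(np.minimum(x, 0.0))
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * neg)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _Conv3d:
    """Same-padded strided 3D convolution over (N, D, H, W, C) tensors."""

    def __init__(self, c_in, c_out, kernel, stride, rng, dtype):
        self.k = kernel
        self.stride = tuple(stride)
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel**3
        # LeCun normal initialization (standard with SELU)
        self.w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._idx_cache = {}

    def _cols(self, xp):
        k = self.k
        sd, sh, sw = self.stride
        view = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        view = view[:, ::sd, ::sh, ::sw]
        n, od, oh, ow = view.shape[:4]
        cols = view.reshape(n, od * oh * ow, self.c_in * k**3)
        return cols, (od, oh, ow)

    def forward(self, x, need_cache=True):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        cols, out_shape = self._cols(xp)
        y = cols @ self.w + self.b
        n = x.shape[0]
        if need_cache:
            self._cache = (cols, x.shape, xp.shape)
        return y.reshape(n, *out_shape, self.c_out)

    def _index_map(self, xp_shape):
        key = xp_shape[1:]
        if key not in self._idx_cache:
            flat = np.arange(int(np.prod(key)), dtype=np.int64).reshape(1, *key)
            idx, _ = self._cols(flat)
            self._idx_cache[key] = idx[0]
        return self._idx_cache[key]

    def backward(self, dy, need_dx=True):
        cols, x_shape, xp_shape = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, -1, self.c_out)
        fan = cols.shape[-1]
        self.dw = (
            cols.reshape(-1, fan).T @ dyf.reshape(-1, self.c_out)
        ).astype(self.w.dtype)
        self.db = dyf.sum(axis=(0, 1)).astype(self.b.dtype)
        if not need_dx:
            return None
        dcols = dyf @ self.w.T  # (n, out_vox, fan_in)
        idx = self._index_map(xp_shape)
        size = int(np.prod(xp_shape[1:]))
        dxp = np.empty(xp_shape, dtype=dy.dtype)
        flat_idx = idx.ravel()
        for i in range(n):
            dxp[i] = np.bincount(
                flat_idx, weights=dcols[i].ravel(), minlength=size
            ).reshape(xp_shape[1:])
        p = self.k // 2
        return dxp[:, p : p + x_shape[1], p : p + x_shape[2], p : p + x_shape[3], :]

    @property
    def params(self):
        return [("w", self), ("b", self)]


def _avg_pool(x, pool):
    """Non-overlapping (pd, ph, pw) average pooling; zero-pads to a multiple."""
    pd, ph, pw = pool
    n, d, h, w, c = x.shape
    dd, hh, ww = -d % pd, -h % ph, -w % pw
    if dd or hh or ww:
        x = np.pad(x, ((0, 0), (0, dd), (0, hh), (0, ww), (0, 0)))
        n, d, h, w, c = x.shape
    return x.reshape(n, d // pd, pd, h // ph, ph, w // pw, pw, c).mean(axis=(2, 4, 6))


class FilterNet:
    """avg pool -> conv3d -> SELU -> conv3d -> SELU -> global avg pool -> dropout -> sigmoid.

    The leading fixed average pool (``cfg.input_pool``) downsamples the raw
    clip before the learned layers; at the default (2, 2, 2) the 13 Hz
    oscillation is still sampled ~4x per cycle.
    """

    def __init__(self, cfg: FilterConfig, rng=None, dtype=np.float32):
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.dtype = dtype
        c1, c2 = cfg.conv_channels
        self.conv1 = _Conv3d(1, c1, cfg.kernel, cfg.strides[0], rng, dtype)
        self.conv2 = _Conv3d(c1, c2, cfg.kernel, cfg.strides[1], rng, dtype)
        self.w_out = rng.normal(0.0, 1.0 / np.sqrt(c2), size=(c2, 1)).astype(dtype)
        self.b_out = np.zeros(1, dtype=dtype)

    @property
    def n_params(self) -> int:
        return int(
            self.conv1.w.size
            + self.conv1.b.size
            + self.conv2.w.size
            + self.conv2.b.size
            + self.w_out.size
            + self.b_out.size
        )

    def forward_logits(self, x, train=False, rng=None, cache=False):
        """Logits for a (N, D, H, W) or (N, D, H, W, 1) batch in [0, 1]."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:
            x = x[..., None]
        if tuple(self.cfg.input_pool) != (1, 1, 1):
            x = _avg_pool(x, self.cfg.input_pool)
        z1 = self.conv1.forward(x, need_cache=cache)
        a1 = _selu(z1)
        z2 = self.conv2.forward(a1, need_cache=cache)
        a2 = _selu(z2)
        g = a2.mean(axis=(1, 2, 3))  # global average pool -> (N, C2)
        if train and self.cfg.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = 1.0 - self.cfg.dropout_rate
            mask = (rng.random(g.shape) < keep).astype(self.dtype) / keep
            d = g * mask
        else:
            mask = None
            d = g
        logits = (d @ self.w_out + self.b_out)[:, 0]
        if cache:
            self._cache = (z1, z2, a2.shape, mask, d)
        return logits

    def predict(self, x) -> np.ndarray:
        """Waggle probability in (0, 1) per clip, inference mode."""
        return _sigmoid(self.forward_logits(x, train=False))

    def backward(self, dlogits):
        z1, z2, a2_shape, mask, d = self._cache
        dl = np.asarray(dlogits, dtype=self.dtype)[:, None]  # (N,1)
        self.dw_out = d.T @ dl
        self.db_out = dl.sum(axis=0)
        dd = dl @ self.w_out.T  # (N, C2)
        if mask is not None:
            dd = dd * mask
        n_vox = int(np.prod(a2_shape[1:4]))
        da2 = np.broadcast_to(
            dd[:, None, None, None, :] / n_vox, a2_shape
        ).astype(self.dtype)
        dz2 = da2 * _selu_grad(z2)
        da1 = self.conv2.backward(dz2, need_dx=True)
        dz1 = da1 * _selu_grad(z1)
        self.conv1.backward(dz1, need_dx=False)

    def param_grads(self):
        return [
            (self.conv1, "w", "dw"),
            (self.conv1, "b", "db"),
            (self.conv2, "w", "dw"),
            (self.conv2, "b", "db"),
            (self, "w_out", "dw_out"),
            (self, "b_out", "db_out"),
        ]


def build_network(cfg: FilterConfig, rng=None, dtype=np.float32) -> FilterNet:
    """Construct the filter network; architecture is a pure function of cfg."""
    return FilterNet(cfg, rng=rng, dtype=dtype)


class _Adam:
    def __init__(self, model: FilterNet, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = {}

    def step(self):
        self.t += 1
        for obj, pname, gname in self.model.param_grads():
            p = getattr(obj, pname)
            g = getattr(obj, gname).reshape(p.shape).astype(np.float64)
            key = (id(obj), pname)
            m, v = self.state.get(key, (np.zeros_like(g), np.zeros_like(g)))
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.state[key] = (m, v)
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            setattr(
                obj,
                pname,
                (p - self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype),
            )


def augment(clip: np.ndarray, rng) -> np.ndarray:
    """Random horizontal / vertical flips (p = 0.5 each); no temporal flip."""
    out = clip
    if rng.random() < 0.5:
        out = out[:, :, ::-1]  # horizontal (image-x) flip
    if rng.random() < 0.5:
        out = out[:, ::-1, :]  # vertical (image-y) flip
    return out


def prepare_clip(frames: np.ndarray, clip_len: int, rng=None) -> np.ndarray:
    """Sample (or deterministically take) a clip_len window, zero-padded.

    With an rng, a random 128-frame subsequence is sampled from longer
    detections; without one, the head of the sequence is used. Shorter
    detections are padded with constant zeros at the end.
    """
    t = len(frames)
    if t >= clip_len:
        start = int(rng.integers(0, t - clip_len + 1)) if rng is not None else 0
        return np.asarray(frames[start : start + clip_len])
    out = np.zeros((clip_len,) + frames.shape[1:], dtype=frames.dtype)
    out[:t] = frames
    return out


def _batch_tensor(clips, cfg, rng=None, augment_rng=None):
    xs = []
    for frames in clips:
        c = prepare_clip(frames, cfg.clip_len, rng)
        if augment_rng is not None:
            c = augment(c, augment_rng)
        x = np.asarray(c, dtype=np.float32) / 255.0
        # per-clip standardization (helps SELU's self-normalizing regime)
        x = (x - x.mean()) / max(float(x.std()), 1e-6)
        xs.append(x)
    return np.stack(xs)


def train(clips, cfg: FilterConfig, verbose: bool = False):
    """Train the filter network; returns ``(model, metrics)``.

    ``metrics`` holds the held-out accuracy at ``cfg.threshold``, the
    precision–recall curve over thresholds, and the loss history. The
    validation split, initialization, subsequence sampling, augmentation
    and dropout are all driven by ``cfg.seed``, so two runs with the same
    seed produce identical results.
    """
    labels = np.array([int(c.label) for c in clips])
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    root = np.random.SeedSequence(cfg.seed)
    rng_split, rng_init, rng_train = [np.random.default_rng(s) for s in root.spawn(3)]

    n = len(clips)
    perm = rng_split.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    model = FilterNet(cfg, rng=rng_init)
    opt = _Adam(model, cfg.lr)
    loss_history = []
    for epoch in range(cfg.epochs):
        order = rng_train.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            x = _batch_tensor(
                [clips[i].frames for i in idx], cfg, rng=rng_train, augment_rng=rng_train
            )
            y = labels[idx].astype(np.float64)
            logits = model.forward_logits(x, train=True, rng=rng_train, cache=True)
            z = logits.astype(np.float64)
            # stable BCE-with-logits: softplus(z) - y z
            loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            dlogits = (_sigmoid(z) - y) / len(y)
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        loss_history.append(epoch_loss / max(n_batches, 1))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  loss {loss_history[-1]:.4f}")

    # deterministic validation pass (head subsequence, no augmentation)
    val_scores = predict_clips(model, [clips[i].frames for i in val_idx], cfg)
    val_y = labels[val_idx]
    val_pred = (val_scores >= cfg.threshold).astype(int)
    accuracy = float(np.mean(val_pred == val_y))
    from sklearn.metrics import precision_recall_curve

    precision, recall, thresholds = precision_recall_curve(val_y, val_scores)
    metrics = {
        "val_accuracy": accuracy,
        "val_scores": val_scores,
        "val_labels": val_y,
        "precision": precision,
        "recall": recall,
        "pr_thresholds": thresholds,
        "loss_history": loss_history,
        "n_train": len(train_idx),
        "n_val": len(val_idx),
    }
    return model, metrics


def predict_clips(model: FilterNet, frame_sequences, cfg: FilterConfig) -> np.ndarray:
    """Inference-mode scores for a list of (T, H, W) sequences."""
    scores = []
    bs = max(1, cfg.batch_size)
    for s in range(0, len(frame_sequences), bs):
        x = _batch_tensor(frame_sequences[s : s + bs], cfg)
        scores.append(model.predict(x))
    return np.concatenate(scores) if scores else np.array([])


def filter_runs(runs, model: FilterNet, threshold: float, cfg: FilterConfig = None):
    """Annotate runs with confidence; flag (never drop) those below threshold.

    Returns ``(runs, errors)`` where ``errors`` records runs whose snippet
    sequence is missing; processing continues past them.
    """
    if cfg is None:
        cfg = model.cfg
    errors = []
    with_snippets = [r for r in runs if r.snippet is not None]
    for r in runs:
        if r.snippet is None:
            errors.append((r.id, "missing snippet sequence"))
    if with_snippets:
        scores = predict_clips(model, [r.snippet for r in with_snippets], cfg)
        for r, s in zip(with_snippets, scores):
            r.confidence = float(s)
            r.rejected = bool(s < threshold)
    return runs, errors


def save_model(path, model: FilterNet):
    """Checkpoint parameters with the embedded FilterConfig."""
    import json

    np.savez(
        path,
        conv1_w=model.conv1.w,
        conv1_b=model.conv1.b,
        conv2_w=model.conv2.w,
        conv2_b=model.conv2.b,
        w_out=model.w_out,
        b_out=model.b_out,
        config=json.dumps(model.cfg.to_dict()),
    )


def load_model(path) -> FilterNet:
    import json

    data = np.load(path, allow_pickle=False)
    cfg = FilterConfig.from_dict(json.loads(str(data["config"])))
    model = FilterNet(cfg)
    model.conv1.w = data["conv1_w"]
    model.conv1.b = data["conv1_b"]
    model.conv2.w = data["conv2_w"]
    model.conv2.b = data["conv2_b"]
    model.w_out = data["w_out"]
    model.b_out = data["b_out"]
    return model
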