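"""Twin convolutional feature extractors (histoCNN / mammoCNN).

Each extractor is a stack of conv-pool blocks — two 3×3 stride-1
convolutions plus a max-pool per block, filter counts doubling per block —
followed by flatten, a dense layer with dropout 0.5, and a softmax head.
The penultimate dense activation is the per-image feature vector handed to
the BEOSA feature selector.

The networks are implemented directly on numpy (im2col convolutions,
Adam updates, softmax cross-entropy): the full-size specs mirror the
299×299 / 224×224 reference layouts, while tests and the desk-scale
pipeline use a mini 32×32 spec that trains in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .datatypes import FeatureMatrix, ImageBatch

__all__ = [
    "ExtractorSpec",
    "TrainConfig",
    "mammo_spec",
    "histo_spec",
    "mini_spec",
    "softmax",
    "build_extractor",
    "stratified_split",
    "train",
    "extract_features",
    "save_model",
    "load_model",
    "ConvNet",
]


@dataclass
class ExtractorSpec:
    """Declarative description of a conv-pool feature extractor.

    blocks lists the filter count of each block; every block is two
    kernel×kernel stride-1 convolutions followed by a pool_kernel max-pool
    with stride pool_stride (1 in the reference layout; 2 is the common
    choice and the mini default).
    """

    name: str
    input_shape: tuple  # (H, W, C)
    blocks: tuple = (32, 64, 128, 256)
    kernel: int = 3
    conv_stride: int = 1
    pool_kernel: int = 2
    pool_stride: int = 1
    dense_units: int = 256
    dropout: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        h, w, c = self.input_shape
        if c not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must lie in [0, 1]")
        if self.conv_stride != 1:
            raise ValueError("only stride-1 convolutions are supported")

    def feature_map_shapes(self) -> list:
        """(H, W, C) after each block; raises if the input is too small."""
        h, w, c = self.input_shape
        shapes = []
        for f in self.blocks:
            for _ in range(2):  # two valid convs per block
                h, w = h - self.kernel + 1, w - self.kernel + 1
            h = (h - self.pool_kernel) // self.pool_stride + 1
            w = (w - self.pool_kernel) // self.pool_stride + 1
            if h < 1 or w < 1:
                raise ValueError(
                    f"{self.name}: input {self.input_shape[:2]} too small for "
                    f"{len(self.blocks)} blocks of {self.kernel}x{self.kernel} convs "
                    f"(feature map shrank to {h}x{w})"
                )
            c = f
            shapes.append((h, w, c))
        return shapes

    @property
    def flat_dim(self) -> int:
        h, w, c = self.feature_map_shapes()[-1]
        return h * w * c


def mammo_spec(**over) -> ExtractorSpec:
    """Reference grayscale spec: 299×299×1, blocks 32/64/128/256, 5 classes."""
    kw = dict(name="mammoCNN", input_shape=(299, 299, 1), n_classes=5)
    kw.update(over)
    return ExtractorSpec(**kw)


def histo_spec(**over) -> ExtractorSpec:
    """Reference RGB spec: 224×224×3, blocks 32/64/128/256, 12 classes."""
    kw = dict(name="histoCNN", input_shape=(224, 224, 3), n_classes=12)
    kw.update(over)
    return ExtractorSpec(**kw)


def mini_spec(channels: int = 1, n_classes: int = 2, **over) -> ExtractorSpec:
    """Desk-scale spec: 32×32 input, two blocks (8/16), pool stride 2."""
    kw = dict(name="miniCNN", input_shape=(32, 32, channels), blocks=(8, 16),
              pool_stride=2, dense_units=32, n_classes=n_classes)
    kw.update(over)
    return ExtractorSpec(**kw)


@dataclass
class TrainConfig:
    """Optimizer and split settings for extractor training."""

    learning_rate: float = 1e-6
    optimizer: str = "adam"
    beta1: float = 0.5
    beta2: float = 0.999
    epsilon: float = 1e-8
    l2: float = 2e-4
    batch_size: int = 32
    epochs: int = 10
    splits: tuple = (0.75, 0.15, 0.10)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("splits must sum to 1.0")
        if min(self.learning_rate, self.l2, self.batch_size) <= 0:
            raise ValueError("rates and batch size must be positive")


def softmax(logits) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# numpy layers


def _conv_forward_fast(x, W, b):
    # x (N,H,W,C), W (kh,kw,C,F); valid padding, stride 1

    kh, kw, cin, f = W.shape
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N,Ho,Wo,C,kh,kw)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(
        x.shape[0], win.shape[1], win.shape[2], kh * kw * cin)
    Wmat = W.reshape(kh * kw * cin, f)
    return cols @ Wmat + b, cols


def _conv_backward(dout, cols, x_shape, W):
    kh, kw, cin, f = W.shape
    n, ho, wo = dout.shape[:3]
    Wmat = W.reshape(kh * kw * cin, f)
    dW = (cols.reshape(-1, kh * kw * cin).T @ dout.reshape(-1, f)).reshape(W.shape)
    db = dout.sum(axis=(0, 1, 2))
    dcols = (dout @ Wmat.T).reshape(n, ho, wo, kh, kw, cin)
    dx = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, i:i + ho, j:j + wo, :] += dcols[:, :, :, i, j, :]
    return dx, dW, db


def _pool_forward(x, k, s):
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]  # (N,Ho,Wo,C,k,k)
    n, ho, wo, c = win.shape[:4]
    flat = win.reshape(n, ho, wo, c, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout, idx, x_shape, k, s):
    n, ho, wo, c = dout.shape
    dx = np.zeros(x_shape)
    ni, yi, xi, ci = np.indices((n, ho, wo, c))
    yy = yi * s + idx // k
    xx = xi * s + idx % k
    np.add.at(dx, (ni, yy, xx, ci), dout)
    return dx


class _Adam:
    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params, grads):
        self.t += 1
        c = self.cfg
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = c.beta1 * self.m[key] + (1 - c.beta1) * g
            self.v[key] = c.beta2 * self.v[key] + (1 - c.beta2) * g * g
            mhat = self.m[key] / (1 - c.beta1**self.t)
            vhat = self.v[key] / (1 - c.beta2**self.t)
            params[key] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.epsilon)


class ConvNet:
    """Conv-pool feature extractor with a dense + softmax head."""

    def __init__(self, spec: ExtractorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params = {}
        cin = spec.input_shape[2]
        for bi, f in enumerate(spec.blocks):
            for ci in range(2):
                fan_in = spec.kernel * spec.kernel * cin
                self.params[f"W{bi}_{ci}"] = rng.normal(
                    0.0, np.sqrt(2.0 / fan_in),
                    size=(spec.kernel, spec.kernel, cin, f))
                self.params[f"b{bi}_{ci}"] = np.zeros(f)
                cin = f
        spec.feature_map_shapes()  # raises early on impossible geometry
        self.params["Wd"] = rng.normal(
            0.0, np.sqrt(2.0 / spec.flat_dim), size=(spec.flat_dim, spec.dense_units))
        self.params["bd"] = np.zeros(spec.dense_units)
        self.params["Wo"] = rng.normal(
            0.0, np.sqrt(2.0 / spec.dense_units), size=(spec.dense_units, spec.n_classes))
        self.params["bo"] = np.zeros(spec.n_classes)
        self.classes_ = None
        self.history = {"loss": [], "acc": [], "val_loss": [], "val_acc": []}

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    # forward --------------------------------------------------------------

    def _forward(self, x, train_mode=False, drop_rng=None):
        spec, cache = self.spec, {"inputs": []}
        h = np.asarray(x, dtype=float)
        if h.shape[1:] != tuple(spec.input_shape):
            raise ValueError(
                f"{spec.name} expects images of shape {tuple(spec.input_shape)}; "
                f"got {h.shape[1:]}")
        for bi in range(len(spec.blocks)):
            for ci in range(2):
                W, b = self.params[f"W{bi}_{ci}"], self.params[f"b{bi}_{ci}"]
                z, cols = _conv_forward_fast(h, W, b)
                cache[f"conv{bi}_{ci}"] = (cols, h.shape, z > 0)
                h = np.maximum(z, 0.0)
            h, idx = _pool_forward(h, spec.pool_kernel, spec.pool_stride)
            cache[f"pool{bi}"] = (idx, cache[f"conv{bi}_1"][2].shape)
        flat = h.reshape(h.shape[0], -1)
        cache["flat"] = flat
        zd = flat @ self.params["Wd"] + self.params["bd"]
        feat = np.maximum(zd, 0.0)
        cache["dense_relu"] = zd > 0
        if train_mode and spec.dropout > 0:
            keep = 1.0 - spec.dropout
            mask = (drop_rng.random(feat.shape) < keep) / keep
            feat = feat * mask
            cache["drop_mask"] = mask
        cache["feat"] = feat
        logits = feat @ self.params["Wo"] + self.params["bo"]
        return logits, cache

    def predict_proba(self, x) -> np.ndarray:
        logits, _ = self._forward(x, train_mode=False)
        return softmax(logits)

    def features(self, x) -> np.ndarray:
        """Penultimate dense activations in eval mode (dropout off)."""
        _, cache = self._forward(x, train_mode=False)
        return cache["feat"]

    # backward -------------------------------------------------------------

    def _backward(self, cache, probs, y_onehot):
        spec, grads = self.spec, {}
        n = probs.shape[0]
        dlogits = (probs - y_onehot) / n
        feat = cache["feat"]
        grads["Wo"] = feat.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["Wo"].T
        if "drop_mask" in cache:
            dfeat = dfeat * cache["drop_mask"]
        dzd = dfeat * cache["dense_relu"]
        grads["Wd"] = cache["flat"].T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        shapes = spec.feature_map_shapes()
        dh = dflat.reshape(n, *shapes[-1])
        for bi in reversed(range(len(spec.blocks))):
            idx, pre_pool_shape = cache[f"pool{bi}"]
            dh = _pool_backward(dh, idx, pre_pool_shape, spec.pool_kernel, spec.pool_stride)
            for ci in (1, 0):
                cols, x_shape, relu_mask = cache[f"conv{bi}_{ci}"]
                dz = dh * relu_mask
                W = self.params[f"W{bi}_{ci}"]
                dh, dW, db = _conv_backward(dz, cols, x_shape, W)
                grads[f"W{bi}_{ci}"] = dW
                grads[f"b{bi}_{ci}"] = db
        return grads


def build_extractor(spec: ExtractorSpec, seed: int = 0) -> ConvNet:
    """Instantiate a trainable extractor from its spec."""
    return ConvNet(spec, seed=seed)


def stratified_split(labels, splits=(0.75, 0.15, 0.10), seed: int = 0):
    """Deterministic stratified train/eval/test index split."""
    from sklearn.model_selection import train_test_split

    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    train_idx, rest_idx = train_test_split(
        idx, train_size=splits[0], stratify=labels, random_state=seed)
    eval_frac = splits[1] / (splits[1] + splits[2])
    eval_idx, test_idx = train_test_split(
        rest_idx, train_size=eval_frac, stratify=labels[rest_idx], random_state=seed)
    return np.sort(train_idx), np.sort(eval_idx), np.sort(test_idx)


def _encode_labels(labels, classes):
    lut = {c: i for i, c in enumerate(classes)}
    return np.asarray([lut[l] for l in labels])


def _xent(probs, y):
    return -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean()


def train(model: ConvNet, images, labels=None, cfg: TrainConfig | None = None):
    """Train an extractor; returns (model, history).

    images may be an ImageBatch (labels taken from it) or an (n,H,W,C)
    array with an explicit labels list.  Splitting, shuffling, dropout and
    initialization are all functions of cfg.seed, so identical configs give
    identical trained weights.  epochs=0 leaves the model untouched.
    """
    if isinstance(images, ImageBatch):
        labels = images.labels
        images = images.pixels
    if cfg is None:
        cfg = TrainConfig()
    x = np.asarray(images, dtype=float)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")
    y = _encode_labels(labels, classes)
    model.classes_ = classes
    if model.spec.n_classes != len(classes):
        raise ValueError(
            f"spec declares {model.spec.n_classes} classes but data has {len(classes)}")

    train_idx, eval_idx, _ = stratified_split(y, cfg.splits, cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(cfg)
    onehot = np.eye(len(classes))

    for _ in range(cfg.epochs):
        order = train_idx.copy()
        rng.shuffle(order)
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            logits, cache = model._forward(x[batch], train_mode=True, drop_rng=rng)
            probs = softmax(logits)
            grads = model._backward(cache, probs, onehot[y[batch]])
            for key in grads:  # L2 weight decay on matrices only
                if key.startswith(("W",)):
                    grads[key] += cfg.l2 * model.params[key]
            opt.step(model.params, grads)
            losses.append(_xent(probs, y[batch]))
            hits += (probs.argmax(axis=1) == y[batch]).sum()
            seen += len(batch)
        val_probs = model.predict_proba(x[eval_idx])
        model.history["loss"].append(float(np.mean(losses)))
        model.history["acc"].append(hits / seen)
        model.history["val_loss"].append(_xent(val_probs, y[eval_idx]))
        model.history["val_acc"].append(
            float((val_probs.argmax(axis=1) == y[eval_idx]).mean()))
    return model, model.history


def save_model(model: ConvNet, path) -> None:
    """Persist weights + spec + class list to an NPZ archive."""
    import dataclasses
    import json

    meta = json.dumps({"spec": dataclasses.asdict(model.spec),
                       "classes": model.classes_})
    np.savez(path, __meta__=np.array(meta), **model.params)


def load_model(path) -> ConvNet:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        params = {k: z[k] for k in z.files if k != "__meta__"}
    spec_dict = meta["spec"]
    for key in ("input_shape", "blocks"):
        spec_dict[key] = tuple(spec_dict[key])
    model = ConvNet(ExtractorSpec(**spec_dict), seed=0)
    if set(model.params) != set(params):
        raise ValueError("archive does not match the stored spec")
    model.params = params
    model.classes_ = meta["classes"]
    return model


def extract_features(model: ConvNet, images, sample_ids=None, labels=None) -> FeatureMatrix:
    """Penultimate-layer feature matrix, one row per image (eval mode)."""
    if isinstance(images, ImageBatch):
        labels = images.labels if labels is None else labels
        images = images.pixels
    x = np.asarray(images, dtype=float)
    feats = model.features(x)
    n = len(x)
    if sample_ids is None:
        sample_ids = [f"img{i}" for i in range(n)]
    if labels is None:
        labels = [""] * n
    return FeatureMatrix(X=feats, sample_ids=list(sample_ids), labels=list(labels))
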