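"""Pluggable 3-class patch classifiers.

Three interchangeable backends, all scikit-learn estimators operating on
stacks of 96x96x3 uint8 patches:

* :class:`SmallCNNClassifier` — a compact convolutional network written in
  numpy (3 conv blocks, global average pooling, dropout 0.5, softmax) and
  trained with the pipeline's standard recipe: SGD with learning rate
  0.005 and momentum 0.9, categorical cross-entropy.  Deterministic given
  its seed.
* :class:`TextureBaselineClassifier` — a closed-form nearest-prototype
  model over hand-crafted texture features (channel means, local-contrast
  energy, bright-blob density, edge density).  It trains in one pass and
  serves as a fast, exactly reproducible oracle for the downstream
  point-mapping machinery.
* :class:`OracleClassifier` — returns the ground-truth label of each crop
  region from a :class:`~tonguemap.dataset.LabelMask`; used to validate
  the end-to-end identity (perfect classifier => predicted point map equals
  the ground-truth point map).

Argmax ties break by class order ABNORMAL > NORMAL > OTHER everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import yaml
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted
from skimage.color import rgb2gray
from skimage.filters import sobel

from .dataset import ClassLabel, N_CLASSES, PatchRecord, records_to_arrays
from .imaging import PATCH_SIZE, augment


# --------------------------------------------------------------------------
# configuration

@dataclass
class ClassifierConfig:
    """Training configuration shared by all backends.

    The optimizer settings (SGD, learning rate 0.005, momentum 0.9),
    dropout 0.5, categorical cross-entropy and 50 epochs are the pipeline's
    standard recipe; batch size and early stopping are not part of it, so
    batch_size defaults to 32 and no early stopping is applied.
    """

    backbone: str = "small-cnn"  # small-cnn | texture-baseline
    learning_rate: float = 0.005
    momentum: float = 0.9
    dropout_rate: float = 0.5
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    input_size: tuple[int, int, int] = (PATCH_SIZE, PATCH_SIZE, 3)
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassifierConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("input_size", None)
        raw.pop("n_classes", None)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["input_size"] = list(d["input_size"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _check_patches(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4 or X.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(f"expected (n, {PATCH_SIZE}, {PATCH_SIZE}, 3) patches, "
                         f"got {X.shape}")
    return X


# --------------------------------------------------------------------------
# texture features

def texture_features(patch: np.ndarray) -> np.ndarray:
    """Deterministic 6-vector of texture statistics for one 96x96 patch.

    Components (all invariant under flips and 90-degree rotation):

    0-2  mean R, G, B intensity (scaled to [0, 1]);
    3    local-contrast energy: standard deviation of the Laplacian of the
         gray image;
    4    bright-blob density: fraction of pixels whose gray level exceeds a
         Gaussian-smoothed (sigma=3) background by more than 0.06 — high on
         papillary dot lattices, zero on smooth or solid patches;
    5    edge density: fraction of pixels with Sobel gradient magnitude
         above 0.06 — high on fissured (groove) textures.
    """
    patch = _check_patches(patch)[0]
    rgb = patch.astype(np.float64) / 255.0
    gray = rgb2gray(rgb)
    lap = ndimage.laplace(gray, mode="reflect")
    blobs = gray - ndimage.gaussian_filter(gray, sigma=3.0, mode="reflect")
    return np.array([
        rgb[..., 0].mean(), rgb[..., 1].mean(), rgb[..., 2].mean(),
        lap.std(),
        float(np.mean(blobs > 0.06)),
        float(np.mean(sobel(gray) > 0.06)),
    ])


def texture_feature_matrix(X: np.ndarray) -> np.ndarray:
    X = _check_patches(X)
    return np.stack([texture_features(x) for x in X])


# --------------------------------------------------------------------------
# texture-baseline backend

class TextureBaselineClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-prototype classifier over texture features.

    Fitting standardizes the feature matrix and places ``n_prototypes``
    centroids per class (deterministic k-means; classes with fewer samples
    than prototypes get one centroid per sample).  Prediction scores each
    class by its nearest prototype's squared distance and maps scores to
    probabilities with a softmax.  Closed-form, single-pass and exactly
    reproducible; its train report has one effective epoch.

    Multiple prototypes matter because the abnormal class is a union of
    visually distinct texture families (atrophic, fissured, keratotic,
    coated) that no single centroid represents well.
    """

    def __init__(self, n_prototypes: int = 3, temperature: float = 0.5):
        self.n_prototypes = n_prototypes
        self.temperature = temperature

    def fit(self, X, y, X_val=None, y_val=None):
        X = _check_patches(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.arange(N_CLASSES)
        present = np.unique(y)
        if len(present) < N_CLASSES:
            missing = set(range(N_CLASSES)) - set(present.tolist())
            names = ", ".join(ClassLabel(m).name for m in sorted(missing))
            raise ValueError(f"training data has no examples of: {names}")
        F = texture_feature_matrix(X)
        self.feature_mean_ = F.mean(axis=0)
        self.feature_std_ = F.std(axis=0) + 1e-9
        Z = (F - self.feature_mean_) / self.feature_std_
        protos = []
        for c in range(N_CLASSES):
            Zc = Z[y == c]
            k = min(self.n_prototypes, len(Zc))
            if k == 1 or len(Zc) <= k:
                centers = Zc if len(Zc) <= k else Zc.mean(axis=0, keepdims=True)
            else:
                km = KMeans(n_clusters=k, n_init=1, random_state=0).fit(Zc)
                centers = km.cluster_centers_
            protos.append(centers)
        self.prototypes_ = protos
        acc = float(np.mean(self.predict(X) == y))
        self.train_report_ = [{"epoch": 1, "train_loss": float("nan"),
                               "train_accuracy": acc}]
        if X_val is not None:
            self.train_report_[0]["val_accuracy"] = \
                float(np.mean(self.predict(X_val) == np.asarray(y_val)))
        return self

    def _scores(self, X) -> np.ndarray:
        check_is_fitted(self, "prototypes_")
        Z = (texture_feature_matrix(X) - self.feature_mean_) / self.feature_std_
        d = np.stack([((Z[:, None, :] - P[None]) ** 2).sum(-1).min(1)
                      for P in self.prototypes_], axis=1)
        return -d / (2.0 * self.temperature)

    def predict_proba(self, X) -> np.ndarray:
        s = self._scores(X)
        s -= s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


# --------------------------------------------------------------------------
# small numpy CNN backend

def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding neighborhoods: (B,H,W,C) -> (B,H,W,9C)."""
    B, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((B, H, W, 9 * C), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[..., k * C:(k + 1) * C] = xp[:, di:di + H, dj:dj + W, :]
            k += 1
    return cols


def _col2im3(dcols: np.ndarray, C: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    B, H, W, _ = dcols.shape
    dxp = np.zeros((B, H + 2, W + 2, C), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di:di + H, dj:dj + W, :] += dcols[..., k * C:(k + 1) * C]
            k += 1
    return dxp[:, 1:-1, 1:-1, :]


def _maxpool(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    B, H, W, C = x.shape
    xr = x.reshape(B, H // k, k, W // k, k, C)
    y = xr.max(axis=(2, 4))
    mask = (xr == y[:, :, None, :, None, :])
    return y, mask


def _maxpool_back(dy: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    B, Hk, _, Wk, _, C = mask.shape
    d = mask * dy[:, :, None, :, None, :]
    return d.reshape(B, Hk * k, Wk * k, C)


class SmallCNNClassifier(ClassifierMixin, BaseEstimator):
    """Compact convolutional patch classifier, implemented in numpy.

    Architecture (96x96x3 input):

    =====  ==========================================  ===========
    block  operation                                   output
    =====  ==========================================  ===========
    1      conv 3x3 x8, ReLU, maxpool 2                48x48x8
    2      conv 3x3 x16, ReLU, maxpool 4               12x12x16
    3      conv 3x3 x32, ReLU, global average pool     32
    head   dropout(rate), dense 32->3, softmax         3
    =====  ==========================================  ===========

    Trained with plain SGD + momentum on categorical cross-entropy.  All
    randomness (weight init, epoch shuffling, dropout) flows from ``seed``,
    so identical data and seed reproduce the fit bit-for-bit.
    """

    def __init__(self, learning_rate: float = 0.005, momentum: float = 0.9,
                 dropout_rate: float = 0.5, epochs: int = 50,
                 batch_size: int = 32, seed: int = 0,
                 channels: tuple[int, int, int] = (8, 16, 32)):
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.channels = channels

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _prep(X: np.ndarray) -> np.ndarray:
        return _check_patches(X).astype(np.float32) / 255.0 - 0.5

    def _init_weights(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c1, c2, c3 = self.channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        return {
            "W1": he((9 * 3, c1), 9 * 3), "b1": np.zeros(c1, np.float32),
            "W2": he((9 * c1, c2), 9 * c1), "b2": np.zeros(c2, np.float32),
            "W3": he((9 * c2, c3), 9 * c2), "b3": np.zeros(c3, np.float32),
            "W4": he((c3, N_CLASSES), c3), "b4": np.zeros(N_CLASSES, np.float32),
        }

    def _forward(self, x: np.ndarray, w: dict, drop_mask: np.ndarray | None = None,
                 want_cache: bool = False):
        c1, c2, c3 = self.channels
        cols1 = _im2col3(x)
        a1 = np.maximum(cols1 @ w["W1"] + w["b1"], 0.0)
        p1, m1 = _maxpool(a1, 2)
        cols2 = _im2col3(p1)
        a2 = np.maximum(cols2 @ w["W2"] + w["b2"], 0.0)
        p2, m2 = _maxpool(a2, 4)
        cols3 = _im2col3(p2)
        a3 = np.maximum(cols3 @ w["W3"] + w["b3"], 0.0)
        g = a3.mean(axis=(1, 2))
        h = g if drop_mask is None else g * drop_mask
        logits = h @ w["W4"] + w["b4"]
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        if not want_cache:
            return probs
        cache = dict(cols1=cols1, a1=a1, m1=m1, cols2=cols2, a2=a2, m2=m2,
                     cols3=cols3, a3=a3, h=h, drop_mask=drop_mask)
        return probs, cache

    def _backward(self, probs, y, w, cache):
        B = len(y)
        c1, c2, c3 = self.channels
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        g = {}
        g["W4"] = cache["h"].T @ dlogits
        g["b4"] = dlogits.sum(axis=0)
        dh = dlogits @ w["W4"].T
        if cache["drop_mask"] is not None:
            dh = dh * cache["drop_mask"]
        H3 = cache["a3"].shape[1] * cache["a3"].shape[2]
        da3 = (dh[:, None, None, :] / H3) * np.ones_like(cache["a3"])
        da3 *= (cache["a3"] > 0)
        g["W3"] = cache["cols3"].reshape(-1, 9 * c2).T @ da3.reshape(-1, c3)
        g["b3"] = da3.sum(axis=(0, 1, 2))
        dp2 = _col2im3(da3 @ w["W3"].T, c2)
        da2 = _maxpool_back(dp2, cache["m2"], 4) * (cache["a2"] > 0)
        g["W2"] = cache["cols2"].reshape(-1, 9 * c1).T @ da2.reshape(-1, c2)
        g["b2"] = da2.sum(axis=(0, 1, 2))
        dp1 = _col2im3(da2 @ w["W2"].T, c1)
        da1 = _maxpool_back(dp1, cache["m1"], 2) * (cache["a1"] > 0)
        g["W1"] = cache["cols1"].reshape(-1, 9 * 3).T @ da1.reshape(-1, c1)
        g["b1"] = da1.sum(axis=(0, 1, 2))
        return g

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._prep(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        present = np.unique(y)
        if len(present) < N_CLASSES:
            missing = set(range(N_CLASSES)) - set(present.tolist())
            names = ", ".join(ClassLabel(m).name for m in sorted(missing))
            raise ValueError(f"training data has no examples of: {names}")
        self.classes_ = np.arange(N_CLASSES)
        rng = np.random.default_rng(self.seed)
        w = self._init_weights(rng)
        vel = {k: np.zeros_like(v) for k, v in w.items()}
        n = len(X)
        keep = 1.0 - self.dropout_rate
        report = []
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            losses, hits = [], 0
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                if self.dropout_rate > 0:
                    dm = (rng.random((len(xb), self.channels[2])) < keep)
                    dm = dm.astype(np.float32) / keep
                else:
                    dm = None
                probs, cache = self._forward(xb, w, drop_mask=dm, want_cache=True)
                p_true = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
                losses.append(float(-np.log(p_true).mean()) * len(yb))
                hits += int(np.sum(np.argmax(probs, axis=1) == yb))
                grads = self._backward(probs, yb, w, cache)
                for k in w:
                    vel[k] = self.momentum * vel[k] - self.learning_rate * grads[k]
                    w[k] = w[k] + vel[k]
            entry = {"epoch": epoch + 1, "train_loss": sum(losses) / n,
                     "train_accuracy": hits / n}
            if X_val is not None:
                vp = self._predict_proba_prepped(self._prep(X_val), w)
                yv = np.asarray(y_val, dtype=np.int64)
                p_true = np.clip(vp[np.arange(len(yv)), yv], 1e-12, None)
                entry["val_loss"] = float(-np.log(p_true).mean())
                entry["val_accuracy"] = float(np.mean(np.argmax(vp, 1) == yv))
            report.append(entry)
        self.weights_ = w
        self.train_report_ = report
        return self

    def _predict_proba_prepped(self, X: np.ndarray, w: dict) -> np.ndarray:
        out = []
        for start in range(0, len(X), max(self.batch_size, 1)):
            out.append(self._forward(X[start:start + self.batch_size], w))
        return np.concatenate(out) if out else np.empty((0, N_CLASSES))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return self._predict_proba_prepped(self._prep(X), self.weights_)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


# --------------------------------------------------------------------------
# oracle backend

class OracleClassifier:
    """Ground-truth "classifier": labels each crop from a pixel mask.

    Not trainable and not image-driven — it answers from the region
    geometry via the plurality rule, returning one-hot probabilities.  Used
    to test that a perfect patch classifier makes the predicted point map
    identical to the ground-truth point map.
    """

    def __init__(self, mask):
        self.mask_ = mask

    def predict_regions(self, regions) -> tuple[np.ndarray, np.ndarray]:
        from .dataset import label_region

        labels = np.array([int(label_region(self.mask_, r)) for r in regions])
        probs = np.zeros((len(labels), N_CLASSES))
        probs[np.arange(len(labels)), labels] = 1.0
        return labels, probs


# --------------------------------------------------------------------------
# training orchestration

def build_classifier(config: ClassifierConfig):
    if config.backbone == "small-cnn":
        return SmallCNNClassifier(
            learning_rate=config.learning_rate, momentum=config.momentum,
            dropout_rate=config.dropout_rate, epochs=config.epochs,
            batch_size=config.batch_size, seed=config.seed)
    if config.backbone == "texture-baseline":
        return TextureBaselineClassifier()
    raise ValueError(f"unknown backbone {config.backbone!r}")


def train(records: Sequence[PatchRecord], config: ClassifierConfig,
          augment_training: bool = True):
    """Train a backend on the train split, monitoring the valid split.

    Training patches are expanded x4 by the standard augmentations
    (identity, hflip, vflip, rot90); validation patches are not.  Returns
    ``(estimator, train_report)``.
    """
    train_recs = [r for r in records if r.split == "train"]
    valid_recs = [r for r in records if r.split == "valid"]
    if not train_recs:
        raise ValueError("no training records")
    if augment_training:
        train_recs = [r.__class__(p, r.label, r.split, r.source_id)
                      for r in train_recs for p in augment(r.patch)]
    X, y = records_to_arrays(train_recs)
    kwargs = {}
    if valid_recs:
        kwargs["X_val"], kwargs["y_val"] = records_to_arrays(valid_recs)
    est = build_classifier(config)
    est.fit(X, y, **kwargs)
    return est, est.train_report_


def save_checkpoint(est, path: str | Path) -> None:
    """Persist a fitted estimator to a single file."""
    joblib.dump(est, path)


def load_checkpoint(path: str | Path):
    return joblib.load(path)


def predictions_to_frame(probs: np.ndarray, regions, source_id: str = ""):
    """Prediction batch as a table (source_id, row, col, p_*, predicted)."""
    import pandas as pd

    pred = np.argmax(probs, axis=1)
    return pd.DataFrame(
        [{"source_id": source_id, "row": r.row_index, "col": r.col_index,
          "p_abnormal": p[0], "p_normal": p[1], "p_other": p[2],
          "predicted": ClassLabel(int(k)).name.lower()}
         for r, p, k in zip(regions, probs, pred)])
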