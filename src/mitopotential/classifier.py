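"""Marker-free population classification from nuclear feature tables.

A dense feed-forward network assigns each cell a score in [0, 1] — the
probability of belonging to population A — from its nuclear feature
vector.  The architecture is a batch-normalisation layer on the input
followed by five dense+dropout pairs (350, 224, 128, 96, 96 rectified
units, dropout 0.01 each) and a single sigmoid output unit, trained
with plain stochastic gradient descent (learning rate 0.01, batch 128)
on class-weighted binary cross-entropy for at most 250 epochs with
early stopping (patience 25) on the held-out loss.  Cells whose score
falls in the ambiguous band — below the threshold for A (default 0.6)
and above 1−threshold for B — are discarded from downstream analyses.

The network is implemented directly on numpy arrays (forward and
backward passes, Glorot-uniform initialisation); training is
deterministic given the seed.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict
from io import BytesIO

import numpy as np
import pandas as pd

from .features import feature_schema_hash


@dataclass
class ClassifierSpec:
    """Hyper-parameters of the dense network; serialized with the model."""

    hidden_layers: tuple[int, ...] = (350, 224, 128, 96, 96)
    dropout_rate: float = 0.01
    batch_norm_first: bool = True
    learning_rate: float = 0.01
    max_epochs: int = 250
    early_stopping_patience: int = 25
    batch_size: int = 128
    bn_momentum: float = 0.99
    class_weighted: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_layers) != 5:
            raise ValueError("the architecture uses exactly 5 hidden layers")


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DenseNetClassifier:
    """Feed-forward binary classifier over standardized feature vectors.

    Holds the feature schema (names + hash) used at training time;
    scoring a table with a different schema raises.
    """

    def __init__(self, spec: ClassifierSpec | None = None):
        self.spec = spec or ClassifierSpec()
        self.feature_names: list[str] | None = None
        self.schema_hash: str | None = None
        self.classes_ = ("B", "A")  # index 1 = positive = A
        self._fitted = False

    # -- initialisation ------------------------------------------------
    def _init_params(self, input_dim: int, rng: np.random.Generator):
        sizes = [input_dim, *self.spec.hidden_layers, 1]
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.W.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.bn_gamma = np.ones(input_dim)
        self.bn_beta = np.zeros(input_dim)
        self.bn_mean = np.zeros(input_dim)
        self.bn_var = np.ones(input_dim)

    # -- forward/backward ---------------------------------------------
    def _forward(self, X, rng=None, training=False):
        cache = {"drop_masks": [], "acts": []}
        eps = 1e-5
        if self.spec.batch_norm_first:
            if training:
                mu = X.mean(axis=0)
                var = X.var(axis=0)
                m = self.spec.bn_momentum
                self.bn_mean = m * self.bn_mean + (1 - m) * mu
                self.bn_var = m * self.bn_var + (1 - m) * var
            else:
                mu, var = self.bn_mean, self.bn_var
            xhat = (X - mu) / np.sqrt(var + eps)
            h = self.bn_gamma * xhat + self.bn_beta
            cache["bn_xhat"] = xhat
        else:
            h = X
        cache["acts"].append(h)
        p = self.spec.dropout_rate
        for li in range(len(self.spec.hidden_layers)):
            z = h @ self.W[li] + self.b[li]
            h = np.maximum(z, 0.0)
            if training and p > 0:
                mask = (rng.random(h.shape) >= p) / (1.0 - p)
                h = h * mask
                cache["drop_masks"].append(mask)
            else:
                cache["drop_masks"].append(None)
            cache["acts"].append(h)
        z_out = h @ self.W[-1] + self.b[-1]
        prob = _sigmoid(z_out)[:, 0]
        cache["prob"] = prob
        return prob, cache

    def _backward(self, X, y, w, cache):
        """Gradients of weighted BCE; returns lists matching W/b plus BN grads."""
        n = len(y)
        prob = cache["prob"]
        delta = ((prob - y) * w / w.sum())[:, None]  # d(loss)/d(z_out)
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        gW[-1] = cache["acts"][-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        dh = delta @ self.W[-1].T
        for li in reversed(range(len(self.spec.hidden_layers))):
            mask = cache["drop_masks"][li]
            if mask is not None:
                dh = dh * mask
            dz = dh * (cache["acts"][li + 1] > 0)
            gW[li] = cache["acts"][li].T @ dz
            gb[li] = dz.sum(axis=0)
            dh = dz @ self.W[li].T
        if self.spec.batch_norm_first:
            g_gamma = (dh * cache["bn_xhat"]).sum(axis=0)
            g_beta = dh.sum(axis=0)
        else:
            g_gamma = g_beta = None
        return gW, gb, g_gamma, g_beta

    @staticmethod
    def _bce(prob, y, w):
        eps = 1e-12
        ll = y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)
        return float(-(w * ll).sum() / w.sum())

    # -- training ------------------------------------------------------
    def fit(self, X_train, y_train, X_val, y_val):
        """Train with SGD + early stopping; returns the history dict.

        ``y`` arrays are 0/1 (1 = population A).  Validation loss is
        monitored each epoch; the best weights are restored at the end.
        """
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        X_train = np.asarray(X_train, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y_train = np.asarray(y_train, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if np.isnan(X_train).any():
            raise ValueError("NaN in training features")
        self._init_params(X_train.shape[1], rng)

        if spec.class_weighted:
            n_pos = max(y_train.sum(), 1)
            n_neg = max(len(y_train) - y_train.sum(), 1)
            w_pos = len(y_train) / (2 * n_pos)
            w_neg = len(y_train) / (2 * n_neg)
        else:
            w_pos = w_neg = 1.0
        wt = np.where(y_train == 1, w_pos, w_neg)
        wv = np.where(y_val == 1, w_pos, w_neg)

        history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
        best_loss, best_params, patience_left = np.inf, None, spec.early_stopping_patience
        n = len(X_train)
        for epoch in range(spec.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, spec.batch_size):
                idx = order[start:start + spec.batch_size]
                Xb, yb, wb = X_train[idx], y_train[idx], wt[idx]
                prob, cache = self._forward(Xb, rng=rng, training=True)
                epoch_loss += self._bce(prob, yb, wb) * len(idx)
                gW, gb, gg, gbeta = self._backward(Xb, yb, wb, cache)
                lr = spec.learning_rate
                for li in range(len(self.W)):
                    self.W[li] -= lr * gW[li]
                    self.b[li] -= lr * gb[li]
                if gg is not None:
                    self.bn_gamma -= lr * gg
                    self.bn_beta -= lr * gbeta
            val_prob, _ = self._forward(X_val, training=False)
            val_loss = self._bce(val_prob, y_val, wv)
            history["train_loss"].append(epoch_loss / n)
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(float(((val_prob >= 0.5) == y_val).mean()))
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_params = self._snapshot()
                patience_left = spec.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_params is not None:
            self._restore(best_params)
        history["n_epochs"] = len(history["val_loss"])
        self._fitted = True
        return history

    def _snapshot(self):
        return ([w.copy() for w in self.W], [b.copy() for b in self.b],
                self.bn_gamma.copy(), self.bn_beta.copy(),
                self.bn_mean.copy(), self.bn_var.copy())

    def _restore(self, snap):
        self.W = [w.copy() for w in snap[0]]
        self.b = [b.copy() for b in snap[1]]
        self.bn_gamma, self.bn_beta = snap[2].copy(), snap[3].copy()
        self.bn_mean, self.bn_var = snap[4].copy(), snap[5].copy()

    def predict_proba(self, X) -> np.ndarray:
        prob, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return prob

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Single-archive serialization: weights + spec + feature schema."""
        meta = {
            "spec": asdict(self.spec),
            "feature_names": self.feature_names,
            "schema_hash": self.schema_hash,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
        }
        buf = BytesIO()
        arrays = {f"W{i}": w for i, w in enumerate(self.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.b)})
        arrays.update(bn_gamma=self.bn_gamma, bn_beta=self.bn_beta,
                      bn_mean=self.bn_mean, bn_var=self.bn_var)
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "DenseNetClassifier":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            npz = np.load(BytesIO(zf.read("weights.npz")))
        spec_d = meta["spec"]
        spec_d["hidden_layers"] = tuple(spec_d["hidden_layers"])
        model = cls(ClassifierSpec(**spec_d))
        nl = len(model.spec.hidden_layers) + 1
        model.W = [npz[f"W{i}"] for i in range(nl)]
        model.b = [npz[f"b{i}"] for i in range(nl)]
        model.bn_gamma, model.bn_beta = npz["bn_gamma"], npz["bn_beta"]
        model.bn_mean, model.bn_var = npz["bn_mean"], npz["bn_var"]
        model.feature_names = meta["feature_names"]
        model.schema_hash = meta["schema_hash"]
        model.scaler_mean = np.asarray(meta["scaler_mean"])
        model.scaler_sd = np.asarray(meta["scaler_sd"])
        model._fitted = True
        return model


# ---------------------------------------------------------------------
# high-level API


def _feature_matrix(features: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in features.columns if c != "object_id"]
    X = features[cols].to_numpy(dtype=float)
    return X, cols


def train_classifier(features: pd.DataFrame, labels, split_fraction: float = 0.2,
                     spec: ClassifierSpec | None = None):
    """Standardize, split stratified, train the dense network.

    ``labels`` holds two classes ("A"/"B" or any pair; the
    lexicographically later one is mapped to the positive class A
    score of 1 when labels are A/B, otherwise the second unique
    value).  Returns ``(model, history)`` where history carries loss
    curves and held-out accuracy.  Deterministic given ``spec.seed``.
    """
    spec = spec or ClassifierSpec()
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {list(uniq)}")
    pos = "A" if "A" in uniq else uniq[1]
    y = (labels == pos).astype(float)
    X, cols = _feature_matrix(features)
    if np.isnan(X).any():
        bad = [c for c, isna in zip(cols, np.isnan(X).any(axis=0)) if isna]
        raise ValueError(f"NaN features in columns {bad}")

    rng = np.random.default_rng(spec.seed)
    # stratified split
    test_idx = []
    for cls in (0.0, 1.0):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        test_idx.extend(idx[: int(round(split_fraction * len(idx)))])
    test_mask = np.zeros(len(y), dtype=bool)
    test_mask[test_idx] = True

    mu = X[~test_mask].mean(axis=0)
    sd = X[~test_mask].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    model = DenseNetClassifier(spec)
    model.feature_names = cols
    model.schema_hash = feature_schema_hash() if cols == _schema_columns() else _hash_cols(cols)
    model.scaler_mean = mu
    model.scaler_sd = sd
    history = model.fit(Xs[~test_mask], y[~test_mask], Xs[test_mask], y[test_mask])
    val_prob = model.predict_proba(Xs[test_mask])
    history["holdout_accuracy"] = float(((val_prob >= 0.5) == y[test_mask]).mean())
    history["positive_class"] = str(pos)
    return model, history


def _schema_columns():
    from .features import FEATURE_COLUMNS
    return list(FEATURE_COLUMNS)


def _hash_cols(cols):
    import hashlib
    return hashlib.sha256(",".join(cols).encode()).hexdigest()[:16]


def score_cells(model: DenseNetClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Score each cell (probability of population A); schema-checked.

    Scores are in [0, 1] and independent of row order and batching.
    """
    X, cols = _feature_matrix(features)
    if model.feature_names is not None and cols != model.feature_names:
        missing = [c for c in model.feature_names if c not in cols]
        extra = [c for c in cols if c not in model.feature_names]
        raise ValueError(f"feature schema mismatch: missing={missing}, unexpected={extra}")
    Xs = (X - model.scaler_mean) / model.scaler_sd
    scores = model.predict_proba(Xs)
    oid = features["object_id"].to_numpy() if "object_id" in features else np.arange(1, len(X) + 1)
    return pd.DataFrame({"object_id": oid, "score": scores})


def filter_by_score(scores: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Assign A / B / discarded from scores at ambiguity threshold θ.

    A cell is population A iff score ≥ θ and population B iff
    score ≤ 1−θ (a score of exactly θ is retained — only scores
    strictly below the threshold for both classes are discarded);
    everything between is discarded.
    """
    if not (0.5 < threshold <= 1):
        raise ValueError("threshold must lie in (0.5, 1]")
    s = scores["score"].to_numpy()
    assigned = np.where(s >= threshold, "A", np.where(s <= 1 - threshold, "B", "discarded"))
    out = scores.copy()
    out["assigned"] = assigned
    out["threshold"] = threshold
    return out


def permutation_importance(model: DenseNetClassifier, features: pd.DataFrame, labels,
                           n_repeats: int = 5, seed: int = 0) -> pd.DataFrame:
    """Rank features by the accuracy drop when each column is permuted.

    For every feature the column is shuffled ``n_repeats`` times
    (seeded) within the evaluation set and the mean decrease of
    classification accuracy is reported, in descending order.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    pos = "A" if "A" in labels else np.unique(labels)[1]
    y = (labels == pos).astype(float)
    X, cols = _feature_matrix(features)
    Xs = (X - model.scaler_mean) / model.scaler_sd
    base_acc = float(((model.predict_proba(Xs) >= 0.5) == y).mean())
    rows = []
    for j, col in enumerate(cols):
        drops = []
        for _ in range(n_repeats):
            Xp = Xs.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            acc = float(((model.predict_proba(Xp) >= 0.5) == y).mean())
            drops.append(base_acc - acc)
        rows.append({"feature": col, "importance": float(np.mean(drops)),
                     "importance_sd": float(np.std(drops))})
    out = pd.DataFrame(rows).sort_values("importance", ascending=False, ignore_index=True)
    out.attrs["baseline_accuracy"] = base_acc
    return out


def pca_explore(features: pd.DataFrame, n_components: int = 2):
    """PCA on standardized features; returns (loadings, explained_variance_ratio).

    Constant features are dropped with a warning.  Explained-variance
    fractions are non-increasing and sum to ≤ 1.
    """
    import logging
    from sklearn.decomposition import PCA

    X, cols = _feature_matrix(features)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 3 rows and >= 2 features")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logging.getLogger(__name__).warning(
            "dropping constant features: %s", [c for c, k in zip(cols, keep) if not k])
    cols = [c for c, k in zip(cols, keep) if k]
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=min(n_components, len(cols)))
    pca.fit(Xs)
    loadings = pd.DataFrame(pca.components_.T, index=cols,
                            columns=[f"PC{i+1}" for i in range(pca.n_components_)])
    return loadings, pca.explained_variance_ratio_
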