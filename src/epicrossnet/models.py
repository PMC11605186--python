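"""Deep cross network classifier and the sequence-only convolutional baseline.

The deep cross network maps an input vector x (flattened 41x4 one-hot
sequence concatenated with 52 normalized genomic features) through

    x_embed = W_embed . x + b_embed                          (embedding)
    h_k     = ReLU(W_k . h_{k-1} + b_k), final layer width 1 (deep stack)
    x_cross = W_cross . (x_embed (.) x_embed) + b_cross + x_embed   (cross)
    out     = deep(x_embed) + (W_proj . x_cross + b_proj)
    y_pred  = sigmoid(out)

where (.) is elementwise multiplication.  The cross branch keeps an
explicit residual, so with zero weights it is the identity on its input;
because the deep branch ends at width 1 while the cross branch has
embedding width, a learned scalar projection (W_proj, b_proj) reconciles
the two before the sum.  Training is mini-batch Adam on binary cross
entropy with per-epoch seeded shuffling; the returned parameters are the
checkpoint with minimum validation loss.

Everything is plain numpy with hand-derived backpropagation, so gradients
can be (and are) verified against central finite differences.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ParameterError, TrainingError

EPS_CLIP = 1e-7


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross entropy; predictions clipped to [1e-7, 1-1e-7]."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), EPS_CLIP, 1.0 - EPS_CLIP)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


# ---------------------------------------------------------------------------
# functional forward passes over a parameter dict (weights stored (in, out))


def embed(params: dict, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W, b = params["W_embed"], params["b_embed"]
    if X.shape[1] != W.shape[0]:
        raise ParameterError(f"input width {X.shape[1]} != embed fan-in {W.shape[0]}")
    return X @ W + b


def deep_forward(params: dict, x_embed: np.ndarray) -> np.ndarray:
    """ReLU stack ending in a width-1 affine layer (no ReLU after it)."""
    H = np.atleast_2d(np.asarray(x_embed, dtype=float))
    n_layers = params["n_deep_layers"]
    for k in range(n_layers):
        H = H @ params[f"W_deep_{k}"] + params[f"b_deep_{k}"]
        if k < n_layers - 1:
            H = np.maximum(H, 0.0)
    return H[:, 0]


def cross_forward(params: dict, x_embed: np.ndarray) -> np.ndarray:
    E = np.atleast_2d(np.asarray(x_embed, dtype=float))
    W, b = params["W_cross"], params["b_cross"]
    if W.shape[0] != W.shape[1] or W.shape[0] != E.shape[1]:
        raise ParameterError("W_cross must be square of embedding width")
    return (E * E) @ W + b + E


def forward_logit(params: dict, X: np.ndarray) -> np.ndarray:
    E = embed(params, X)
    deep = deep_forward(params, E)
    C = cross_forward(params, E)
    proj = C @ params["W_proj"] + params["b_proj"]
    return deep + proj[:, 0]


def predict_proba_fn(params: dict, X: np.ndarray) -> np.ndarray:
    """P(label=1 | x) = sigmoid(deep + projected cross output)."""
    out = forward_logit(params, X)
    if not np.isfinite(out).all():
        raise ParameterError("non-finite model output")
    return sigmoid(out)


def _dcn_forward_backward(params: dict, X: np.ndarray, y: np.ndarray):
    """Mean BCE loss and its analytic gradients for one mini-batch."""
    n = X.shape[0]
    E = X @ params["W_embed"] + params["b_embed"]
    # deep stack with caches
    n_layers = params["n_deep_layers"]
    hs = [E]
    zs = []
    H = E
    for k in range(n_layers):
        Z = H @ params[f"W_deep_{k}"] + params[f"b_deep_{k}"]
        zs.append(Z)
        H = np.maximum(Z, 0.0) if k < n_layers - 1 else Z
        hs.append(H)
    deep = H[:, 0]
    S = E * E
    C = S @ params["W_cross"] + params["b_cross"] + E
    proj = (C @ params["W_proj"] + params["b_proj"])[:, 0]
    logit = deep + proj
    p = sigmoid(logit)
    loss = bce_loss(y, p)

    grads = {}
    dlogit = ((p - y) / n)[:, None]  # d(mean BCE)/d logit
    # projection
    grads["W_proj"] = C.T @ dlogit
    grads["b_proj"] = dlogit.sum(axis=0)
    dC = dlogit @ params["W_proj"].T
    # cross layer
    grads["W_cross"] = S.T @ dC
    grads["b_cross"] = dC.sum(axis=0)
    dE = dC + 2.0 * E * (dC @ params["W_cross"].T)
    # deep stack
    dH = dlogit
    for k in range(n_layers - 1, -1, -1):
        dZ = dH if k == n_layers - 1 else dH * (zs[k] > 0)
        grads[f"W_deep_{k}"] = hs[k].T @ dZ
        grads[f"b_deep_{k}"] = dZ.sum(axis=0)
        dH = dZ @ params[f"W_deep_{k}"].T
    dE = dE + dH
    # embedding
    grads["W_embed"] = X.T @ dE
    grads["b_embed"] = dE.sum(axis=0)
    return loss, grads


def init_dcn_params(
    input_dim: int,
    embedding_dim: int,
    hidden_dims: tuple[int, ...],
    rng: np.random.Generator,
) -> dict:
    """Fan-in-scaled uniform initialization of all DCN parameters."""
    if hidden_dims[-1] != 1:
        raise ParameterError("hidden_dims must end in 1")

    def layer(fan_in, fan_out):
        lim = 1.0 / np.sqrt(fan_in)
        return (rng.uniform(-lim, lim, size=(fan_in, fan_out)),
                rng.uniform(-lim, lim, size=fan_out))

    params: dict = {"n_deep_layers": len(hidden_dims)}
    params["W_embed"], params["b_embed"] = layer(input_dim, embedding_dim)
    prev = embedding_dim
    for k, width in enumerate(hidden_dims):
        params[f"W_deep_{k}"], params[f"b_deep_{k}"] = layer(prev, width)
        prev = width
    params["W_cross"], params["b_cross"] = layer(embedding_dim, embedding_dim)
    params["W_proj"], params["b_proj"] = layer(embedding_dim, 1)
    return params


# ---------------------------------------------------------------------------
# Adam + generic training loop


class AdamOptimizer:
    """Adam with bias-corrected first and second moment estimates."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1 ** self.t)
            v_hat = self.v[key] / (1 - b2 ** self.t)
            params[key] = params[key] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _train_loop(
    params, forward_backward, predict, X, y, X_val, y_val,
    epochs, batch_size, optimizer, rng, checkpoint,
):
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, copy.deepcopy(params), 0)
    n = X.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = forward_backward(params, X[idx], y[idx])
            optimizer.step(params, grads)
            losses.append(loss)
            weights.append(len(idx))
        train_loss = float(np.average(losses, weights=weights))
        val_loss = bce_loss(y_val, predict(params, X_val))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(params), epoch)
    if checkpoint == "best_val":
        return best[1], history, best[2]
    return params, history, epochs - 1


class _BinaryNetMixin:
    """Shared sklearn plumbing for the two numpy classifiers."""

    def _validate_y(self, y):
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all() or len(classes) < 2:
            raise TrainingError("training labels must contain both classes 0 and 1")
        return y

    def _split_val(self, X, y, X_val, y_val, rng):
        if X_val is not None:
            return X, y, np.asarray(X_val, dtype=float), self._validate_y(y_val)
        # carve a stratified validation fraction out of the training data
        idx_val = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            k = max(1, int(round(len(idx) * self.val_fraction)))
            idx_val.extend(idx[:k])
        mask = np.zeros(len(y), dtype=bool)
        mask[idx_val] = True
        if mask.all() or (~mask).sum() < 2:
            raise TrainingError("training split too small after validation carve-out")
        return X[~mask], y[~mask], X[mask], y[mask]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y).astype(int)))


class CrossNetClassifier(_BinaryNetMixin, ClassifierMixin, BaseEstimator):
    """Deep cross network for binary classification of m6A sites.

    Parameters mirror the published training recipe: embedding width 128,
    deep stack (64, 64, 1), Adam at learning rate 1e-3, 10 epochs, batch
    size 64, binary cross entropy loss.

    Attributes set by :meth:`fit` end in an underscore; ``params_`` holds
    the weight arrays of the best-validation-loss epoch.
    """

    def __init__(
        self,
        embedding_dim: int = 128,
        hidden_dims: tuple[int, ...] = (64, 64, 1),
        learning_rate: float = 1e-3,
        epochs: int = 10,
        batch_size: int = 64,
        beta1: float = 0.9,
        beta2: float = 0.999,
        adam_eps: float = 1e-8,
        val_fraction: float = 0.1,
        checkpoint: str = "best_val",
        random_state: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.hidden_dims = hidden_dims
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.adam_eps = adam_eps
        self.val_fraction = val_fraction
        self.checkpoint = checkpoint
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ParameterError("epochs >= 1 and learning_rate > 0 required")
        if self.checkpoint not in ("best_val", "last"):
            raise ParameterError("checkpoint must be 'best_val' or 'last'")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2-dimensional")
        y = self._validate_y(y)
        rng = np.random.default_rng(self.random_state)
        X_tr, y_tr, X_va, y_va = self._split_val(X, y, X_val, y_val, rng)
        params = init_dcn_params(X.shape[1], self.embedding_dim,
                                 tuple(self.hidden_dims), rng)
        opt = AdamOptimizer(self.learning_rate, self.beta1, self.beta2, self.adam_eps)
        params, history, best_epoch = _train_loop(
            params, _dcn_forward_backward, predict_proba_fn,
            X_tr, y_tr, X_va, y_va,
            self.epochs, self.batch_size, opt, rng, self.checkpoint,
        )
        self.params_ = params
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return forward_logit(self.params_, X)

    def predict_proba(self, X):
        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])


# ---------------------------------------------------------------------------
# sequence-only convolutional baseline


def _im2col(X: np.ndarray, k: int) -> np.ndarray:
    """(n, L, C) -> (n, L-k+1, k*C) sliding windows."""
    n, L, C = X.shape
    out = np.empty((n, L - k + 1, k * C))
    for j in range(k):
        out[:, :, j * C:(j + 1) * C] = X[:, j:j + L - k + 1, :]
    return out


def _col2im(dP: np.ndarray, k: int, L: int, C: int) -> np.ndarray:
    n = dP.shape[0]
    dX = np.zeros((n, L, C))
    for j in range(k):
        dX[:, j:j + L - k + 1, :] += dP[:, :, j * C:(j + 1) * C]
    return dX


def _cnn_forward(params: dict, X: np.ndarray, cache: bool = False):
    k = params["kernel_size"]
    P1 = _im2col(X, k)
    Z1 = P1 @ params["W_conv1"] + params["b_conv1"]
    A1 = np.maximum(Z1, 0.0)
    P2 = _im2col(A1, k)
    Z2 = P2 @ params["W_conv2"] + params["b_conv2"]
    A2 = np.maximum(Z2, 0.0)
    arg = A2.argmax(axis=1)  # (n, C2) global max-pool positions
    G = np.take_along_axis(A2, arg[:, None, :], axis=1)[:, 0, :]
    logit = (G @ params["W_out"] + params["b_out"])[:, 0]
    if cache:
        return logit, (P1, Z1, A1, P2, Z2, A2, arg, G)
    return logit


def _cnn_forward_backward(params: dict, X: np.ndarray, y: np.ndarray):
    n, L, C = X.shape
    k = params["kernel_size"]
    logit, (P1, Z1, A1, P2, Z2, A2, arg, G) = _cnn_forward(params, X, cache=True)
    p = sigmoid(logit)
    loss = bce_loss(y, p)
    grads = {}
    dlogit = ((p - y) / n)[:, None]
    grads["W_out"] = G.T @ dlogit
    grads["b_out"] = dlogit.sum(axis=0)
    dG = dlogit @ params["W_out"].T
    dA2 = np.zeros_like(A2)
    np.put_along_axis(dA2, arg[:, None, :], dG[:, None, :], axis=1)
    dZ2 = dA2 * (Z2 > 0)
    grads["W_conv2"] = np.tensordot(P2, dZ2, axes=([0, 1], [0, 1]))
    grads["b_conv2"] = dZ2.sum(axis=(0, 1))
    dP2 = dZ2 @ params["W_conv2"].T
    dA1 = _col2im(dP2, k, A1.shape[1], A1.shape[2])
    dZ1 = dA1 * (Z1 > 0)
    grads["W_conv1"] = np.tensordot(P1, dZ1, axes=([0, 1], [0, 1]))
    grads["b_conv1"] = dZ1.sum(axis=(0, 1))
    return loss, grads


def _cnn_predict(params: dict, X: np.ndarray) -> np.ndarray:
    return sigmoid(_cnn_forward(params, X))


class SequenceConvClassifier(_BinaryNetMixin, ClassifierMixin, BaseEstimator):
    """Sequence-only baseline: two 1-D conv blocks, global max-pool, sigmoid.

    Accepts one-hot input of shape (n, 41, 4) or flattened (n, 164).
    Trained with the same Adam/BCE recipe as the cross network.
    """

    def __init__(
        self,
        n_filters: tuple[int, int] = (32, 64),
        kernel_size: int = 5,
        learning_rate: float = 1e-3,
        epochs: int = 10,
        batch_size: int = 64,
        beta1: float = 0.9,
        beta2: float = 0.999,
        adam_eps: float = 1e-8,
        val_fraction: float = 0.1,
        checkpoint: str = "best_val",
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.adam_eps = adam_eps
        self.val_fraction = val_fraction
        self.checkpoint = checkpoint
        self.random_state = random_state

    def _as_tensor(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] % 4 != 0:
                raise ParameterError("flattened one-hot width must be divisible by 4")
            X = X.reshape(X.shape[0], -1, 4)
        if X.ndim != 3 or X.shape[2] != 4:
            raise ParameterError("expect one-hot input of shape (n, L, 4)")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._as_tensor(X)
        y = self._validate_y(y)
        rng = np.random.default_rng(self.random_state)
        if X_val is not None:
            X_val = self._as_tensor(X_val)
        X_tr, y_tr, X_va, y_va = self._split_val(X, y, X_val, y_val, rng)
        c1, c2 = self.n_filters
        k = self.kernel_size

        def layer(fan_in, shape):
            lim = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-lim, lim, size=shape)

        params = {
            "kernel_size": k,
            "W_conv1": layer(k * 4, (k * 4, c1)),
            "b_conv1": layer(k * 4, (c1,)),
            "W_conv2": layer(k * c1, (k * c1, c2)),
            "b_conv2": layer(k * c1, (c2,)),
            "W_out": layer(c2, (c2, 1)),
            "b_out": layer(c2, (1,)),
        }
        opt = AdamOptimizer(self.learning_rate, self.beta1, self.beta2, self.adam_eps)
        params, history, best_epoch = _train_loop(
            params, _cnn_forward_backward, _cnn_predict,
            X_tr, y_tr, X_va, y_va,
            self.epochs, self.batch_size, opt, rng, self.checkpoint,
        )
        self.params_ = params
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_features_in_ = X.shape[1] * 4
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        return _cnn_forward(self.params_, self._as_tensor(X))

    def predict_proba(self, X):
        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])
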