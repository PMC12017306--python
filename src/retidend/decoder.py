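"""Convolutional decoder for cricket detection, in pure numpy.

The decoder reads a k x k RGC population response and outputs the
probability that the encoded frame contained a cricket.  Architecture:
five 2D convolution layers (three 3 x 3 filters each, ReLU, zero "same"
padding, L2 weight penalty 0.001), one 2 x 2 max-pool (zero padded to an
even grid), a dense layer of eight ReLU units (L2 0.003) and a single
sigmoid output.  Training minimizes binary cross-entropy with Adam and
early stopping on the validation loss, restoring the best parameters.

No deep-learning framework is assumed: forward and backward passes are
written with im2col-style numpy operations, which is fast enough for the
tiny (9 x 9 or 19 x 19) inputs this decoder sees.  Decoders are deployed
as ensembles whose mean sigmoid output is thresholded at 0.5.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["ConvNetDecoder", "DecoderEnsemble", "train_decoder"]


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution.  x: (N,H,W,Cin), w: (9*Cin, Cout)."""
    n, h, wd, cin = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,Cin,3,3)
    cols = cols.reshape(n, h, wd, cin * 9)
    out = cols @ w + b
    return out, cols


def _conv_backward(dout, cols, w, x_shape):
    n, h, wd, cin = x_shape
    dw = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2]))
    db = dout.sum(axis=(0, 1, 2))
    dcols = dout @ w.T                       # (N,H,W,9*Cin)
    dcols = dcols.reshape(n, h, wd, cin, 3, 3)
    dxp = np.zeros((n, h + 2, wd + 2, cin))
    for u in range(3):
        for v in range(3):
            dxp[:, u:u + h, v:v + wd, :] += dcols[:, :, :, :, u, v]
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _pool_forward(x: np.ndarray):
    n, h, w, c = x.shape
    ph, pw = (-h) % 2, (-w) % 2
    xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)))
    ho, wo = xp.shape[1] // 2, xp.shape[2] // 2
    win = xp.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 2, 4, 5)
    win = win.reshape(n, ho, wo, 4, c)
    idx = np.argmax(win, axis=3)
    out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (idx, x.shape, xp.shape)


def _pool_backward(dout, cache):
    idx, x_shape, xp_shape = cache
    n, ho, wo = dout.shape[:3]
    c = dout.shape[3]
    dwin = np.zeros((n, ho, wo, 4, c))
    np.put_along_axis(dwin, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dxp = dwin.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    dxp = dxp.reshape(n, xp_shape[1], xp_shape[2], c)
    return dxp[:, : x_shape[1], : x_shape[2], :]


class _Net:
    """Parameter container with forward/backward for the fixed architecture."""

    def __init__(self, input_side: int, n_conv: int, n_filters: int,
                 rng: np.random.Generator):
        self.n_conv = n_conv
        self.params = {}
        cin = 1
        for i in range(n_conv):
            fan_in = 9 * cin
            self.params[f"wc{i}"] = rng.normal(
                0, np.sqrt(2.0 / fan_in), size=(fan_in, n_filters))
            self.params[f"bc{i}"] = np.zeros(n_filters)
            cin = n_filters
        side = (input_side + 1) // 2
        flat = side * side * n_filters
        self.params["wd"] = rng.normal(0, np.sqrt(2.0 / flat), size=(flat, 8))
        self.params["bd"] = np.zeros(8)
        self.params["wo"] = rng.normal(0, np.sqrt(1.0 / 8), size=(8, 1))
        self.params["bo"] = np.zeros(1)

    def forward(self, x: np.ndarray):
        caches = []
        a = x[..., None] if x.ndim == 3 else x
        for i in range(self.n_conv):
            z, cols = _conv_forward(a, self.params[f"wc{i}"], self.params[f"bc{i}"])
            r = np.maximum(0.0, z)
            caches.append(("conv", a.shape, cols, z))
            a = r
        p, pc = _pool_forward(a)
        caches.append(("pool", pc))
        flat = p.reshape(len(p), -1)
        zd = flat @ self.params["wd"] + self.params["bd"]
        rd = np.maximum(0.0, zd)
        zo = rd @ self.params["wo"] + self.params["bo"]
        prob = 1.0 / (1.0 + np.exp(-zo[:, 0]))
        caches.append(("dense", flat, zd, rd, p.shape))
        return prob, caches

    def backward(self, prob, y, caches, l2_conv, l2_dense):
        n = len(y)
        grads = {}
        dzo = (prob - y)[:, None] / n        # BCE + sigmoid
        _, flat, zd, rd, p_shape = caches[-1]
        grads["wo"] = rd.T @ dzo
        grads["bo"] = dzo.sum(axis=0)
        drd = dzo @ self.params["wo"].T
        dzd = drd * (zd > 0)
        grads["wd"] = flat.T @ dzd + 2 * l2_dense * self.params["wd"]
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["wd"].T
        da = _pool_backward(dflat.reshape(p_shape), caches[-2][1])
        for i in range(self.n_conv - 1, -1, -1):
            _, x_shape, cols, z = caches[i]
            dz = da * (z > 0)
            da, dw, db = _conv_backward(dz, cols, self.params[f"wc{i}"], x_shape)
            grads[f"wc{i}"] = dw + 2 * l2_conv * self.params[f"wc{i}"]
            grads[f"bc{i}"] = db
        return grads


def _bce(prob, y, eps=1e-9):
    p = np.clip(prob, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class ConvNetDecoder(BaseEstimator, ClassifierMixin):
    """One CNN decoder member (see module docstring for the architecture).

    ``fit(X, y, validation=(X_val, y_val))`` trains with Adam on BCE.
    Early stopping starts after ``es_start`` epochs: training stops when
    the validation loss has not improved by at least ``min_delta`` over
    ``patience`` epochs, and the best-validation parameters are restored.
    The original batch size (16,384) and tracking start (200 epochs) are
    scaled down by default for desk-scale data volumes.
    """

    def __init__(self, n_conv=5, n_filters=3, l2_conv=0.001, l2_dense=0.003,
                 lr=3e-3, batch_size=512, max_epochs=120, es_start=20,
                 patience=10, min_delta=0.001, seed=0):
        self.n_conv = n_conv
        self.n_filters = n_filters
        self.l2_conv = l2_conv
        self.l2_dense = l2_dense
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.es_start = es_start
        self.patience = patience
        self.min_delta = min_delta
        self.seed = seed

    def fit(self, X, y, validation=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        # standardize inputs with training-set statistics (encoder outputs
        # have arbitrary scale; the net trains on z-scored responses)
        self.input_mean_ = float(X.mean())
        self.input_sd_ = float(X.std()) or 1.0
        X = (X - self.input_mean_) / self.input_sd_
        rng = np.random.default_rng(self.seed)
        net = _Net(X.shape[1], self.n_conv, self.n_filters, rng)
        m = {k: np.zeros_like(v) for k, v in net.params.items()}
        v = {k: np.zeros_like(w) for k, w in net.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        if validation is None:
            xv, yv = X, y
        else:
            xv = (np.asarray(validation[0], dtype=float)
                  - self.input_mean_) / self.input_sd_
            yv = np.asarray(validation[1], dtype=float)

        best_loss, best_params, stall = np.inf, None, 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X), self.batch_size):
                idx = order[start: start + self.batch_size]
                prob, caches = net.forward(X[idx])
                if not np.all(np.isfinite(prob)):
                    raise RuntimeError("non-finite decoder loss")
                grads = net.backward(prob, y[idx], caches,
                                     self.l2_conv, self.l2_dense)
                step += 1
                for k in net.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1**step)
                    vh = v[k] / (1 - b2**step)
                    net.params[k] -= self.lr * mh / (np.sqrt(vh) + eps)
            val_loss = _bce(net.forward(xv)[0], yv)
            self.history_.append(val_loss)
            if val_loss < best_loss - self.min_delta:
                best_loss = val_loss
                best_params = {k: w.copy() for k, w in net.params.items()}
                stall = 0
            else:
                stall += 1
            if epoch + 1 >= self.es_start and stall >= self.patience:
                break
        if best_params is not None:
            net.params = best_params
        self.net_ = net
        self.best_val_loss_ = best_loss
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        Xz = (np.asarray(X, dtype=float) - self.input_mean_) / self.input_sd_
        p = self.net_.forward(Xz)[0]
        return np.c_[1 - p, p]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class DecoderEnsemble(BaseEstimator, ClassifierMixin):
    """Ensemble of independently initialized decoder CNNs.

    The prediction is the mean of the member sigmoid outputs, thresholded
    at 0.5.  The reference configuration uses 10 members; desk-scale runs
    use fewer.
    """

    def __init__(self, n_members=10, seed=0, **member_kwargs):
        self.n_members = n_members
        self.seed = seed
        self.member_kwargs = member_kwargs

    def fit(self, X, y, validation=None):
        self.members_ = []
        for i in range(self.n_members):
            dec = ConvNetDecoder(seed=self.seed + 1000 * i + 1,
                                 **self.member_kwargs)
            dec.fit(X, y, validation=validation)
            self.members_.append(dec)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.mean([d.predict_proba(X)[:, 1] for d in self.members_], axis=0)
        return np.c_[1 - p, p]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_decoder(X_train, y_train, X_val, y_val, n_members=10, seed=0,
                  **member_kwargs) -> DecoderEnsemble:
    """Train a decoder ensemble on encoded frames (thin functional wrapper)."""
    ens = DecoderEnsemble(n_members=n_members, seed=seed, **member_kwargs)
    return ens.fit(X_train, y_train, validation=(X_val, y_val))
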