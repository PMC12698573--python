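"""Minimal recurrent sequence regressors (LSTM / bidirectional LSTM).

Spectra are presented as ordered sequences of scalar reflectance steps in
wavelength order, so the recurrence runs along the band axis.  A single
LSTM layer (optionally bidirectional) feeds a linear readout on the final
hidden state(s); training minimises mean squared error with the Adam
optimiser, mini-batches, and optional early stopping on a validation set.

Implemented directly on numpy with explicit backpropagation through time:
the cell follows the standard formulation (input/forget/cell/output gates,
tanh activations) and is fully deterministic given its seed.  Inputs and
targets are standardised internally; predictions are returned on the
original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hypyield.errors import DataError, DimensionError


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Cell:
    """One direction's LSTM parameters, gates ordered [i, f, g, o]."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        h = hidden
        s_in = 1.0  # scalar input per step
        scale_x = 1.0 / np.sqrt(s_in + h)
        self.Wx = rng.standard_normal((1, 4 * h)) * scale_x
        self.Wh = rng.standard_normal((h, 4 * h)) * scale_x
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias init keeps gradients alive
        self.h = h

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """X: (batch, T). Returns final hidden (batch, h) and the BPTT cache."""
        B, T = X.shape
        h = self.h
        hs = np.zeros((B, h))
        cs = np.zeros((B, h))
        cache = []
        for t in range(T):
            x_t = X[:, t : t + 1]
            a = x_t @ self.Wx + hs @ self.Wh + self.b
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c_new = f * cs + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x_t, hs, cs, i, f, g, o, tanh_c))
            hs, cs = h_new, c_new
        return hs, cache

    def backward(self, d_h_final: np.ndarray, cache: list) -> list[np.ndarray]:
        """Accumulate parameter gradients from the loss gradient on the final h."""
        h = self.h
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dh = d_h_final
        dc = np.zeros_like(d_h_final)
        for x_t, h_prev, c_prev, i, f, g, o, tanh_c in reversed(cache):
            dc = dc + dh * o * (1.0 - tanh_c**2)
            da = np.empty((x_t.shape[0], 4 * h))
            da[:, :h] = dc * g * i * (1.0 - i)
            da[:, h : 2 * h] = dc * c_prev * f * (1.0 - f)
            da[:, 2 * h : 3 * h] = dc * i * (1.0 - g**2)
            da[:, 3 * h :] = dh * tanh_c * o * (1.0 - o)
            dWx += x_t.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dh = da @ self.Wh.T
            dc = dc * f
        return [dWx, dWh, db]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class LSTMRegressor:
    """Sequence regressor over the band axis.

    Parameters
    ----------
    hidden_size : width of the recurrent layer.
    bidirectional : run a second pass over the reversed sequence and read
        out from the concatenated final hidden states.
    learning_rate, max_epochs, batch_size, patience : Adam training
        schedule; early stopping monitors validation MSE when a validation
        set is supplied and restores the best parameters.
    seed : controls initialisation and mini-batch shuffling.
    """

    hidden_size: int = 50
    bidirectional: bool = False
    learning_rate: float = 0.01
    max_epochs: int = 200
    batch_size: int = 16
    patience: int = 20
    seed: int = 0
    _fitted: dict = field(default_factory=dict, repr=False)

    # -- scaling -----------------------------------------------------------
    def _scale_X(self, X: np.ndarray) -> np.ndarray:
        return (X - self._fitted["x_mean"]) / self._fitted["x_sd"]

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "LSTMRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise DataError("non-finite values in training data")
        if X.shape[0] != y.size:
            raise DimensionError("X rows must match y length")
        rng = np.random.default_rng(self.seed)
        x_sd = X.std(axis=0)
        self._fitted = {
            "x_mean": X.mean(axis=0),
            "x_sd": np.where(x_sd == 0, 1.0, x_sd),
            "y_mean": y.mean(),
            "y_sd": y.std() if y.std() > 0 else 1.0,
            "n_steps": X.shape[1],
        }
        Xs = self._scale_X(X)
        ys = (y - self._fitted["y_mean"]) / self._fitted["y_sd"]

        h = self.hidden_size
        self._fwd = _Cell(h, rng)
        self._bwd = _Cell(h, rng) if self.bidirectional else None
        n_out = 2 * h if self.bidirectional else h
        self._w_out = rng.standard_normal((n_out, 1)) / np.sqrt(n_out)
        self._b_out = np.zeros(1)

        params = self._fwd.params() + (self._bwd.params() if self._bwd else [])
        params += [self._w_out, self._b_out]
        opt = _Adam(params, self.learning_rate)

        use_val = X_val is not None and y_val is not None and len(np.asarray(y_val)) > 0
        if use_val:
            Xv = self._scale_X(np.atleast_2d(np.asarray(X_val, dtype=float)))
            yv = (np.asarray(y_val, dtype=float).ravel() - self._fitted["y_mean"]) / self._fitted["y_sd"]
        best_val = np.inf
        best_state = None
        stale = 0

        n = Xs.shape[0]
        for _epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                self._train_batch(Xs[idx], ys[idx], opt)
            if use_val:
                val_mse = float(np.mean((self._forward(Xv) - yv) ** 2))
                if val_mse < best_val - 1e-12:
                    best_val = val_mse
                    best_state = [p.copy() for p in params]
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if use_val and best_state is not None:
            for p, s in zip(params, best_state):
                p[...] = s
        return self

    def _forward(self, Xs: np.ndarray) -> np.ndarray:
        h_f, _ = self._fwd.forward(Xs)
        feats = h_f
        if self._bwd is not None:
            h_b, _ = self._bwd.forward(Xs[:, ::-1])
            feats = np.concatenate([h_f, h_b], axis=1)
        return (feats @ self._w_out + self._b_out).ravel()

    def _train_batch(self, Xb: np.ndarray, yb: np.ndarray, opt: _Adam) -> None:
        h_f, cache_f = self._fwd.forward(Xb)
        feats = h_f
        if self._bwd is not None:
            h_b, cache_b = self._bwd.forward(Xb[:, ::-1])
            feats = np.concatenate([h_f, h_b], axis=1)
        pred = (feats @ self._w_out + self._b_out).ravel()
        B = Xb.shape[0]
        dpred = (2.0 / B) * (pred - yb)[:, None]
        d_w_out = feats.T @ dpred
        d_b_out = dpred.sum(axis=0)
        d_feats = dpred @ self._w_out.T
        h = self.hidden_size
        grads = self._fwd.backward(d_feats[:, :h], cache_f)
        if self._bwd is not None:
            grads += self._bwd.backward(d_feats[:, h:], cache_b)
        grads += [d_w_out, d_b_out]
        params = self._fwd.params() + (self._bwd.params() if self._bwd else [])
        params += [self._w_out, self._b_out]
        opt.step(params, grads)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise DataError("model not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self._fitted["n_steps"]:
            raise DimensionError(
                f"expected {self._fitted['n_steps']} sequence steps, got {X.shape[1]}"
            )
        ys = self._forward(self._scale_X(X))
        return ys * self._fitted["y_sd"] + self._fitted["y_mean"]
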