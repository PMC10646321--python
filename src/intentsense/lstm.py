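"""A compact bidirectional LSTM sequence classifier in pure numpy.

Architecture: sequence input -> single bidirectional LSTM layer (15
hidden units per direction by default) -> fully connected layer ->
softmax over the 3 intent classes.  Trained with Adam on cross-entropy,
default 50 epochs, learning rate 0.001, mini-batch 512.  The final
hidden state of each direction (forward pass over the sequence, and a
pass over the reversed sequence) feeds the fully connected layer.

Forward and backward passes (truncated nowhere: full BPTT over the
25-step windows) are implemented directly; initialisation is seeded
Glorot with a +1 forget-gate bias.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMClassifier"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _LSTMDirection:
    """One direction's parameters and full-BPTT gradients. Gate order i,f,g,o."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        lim_w = np.sqrt(6.0 / (n_in + 4 * n_hidden))
        lim_u = np.sqrt(6.0 / (n_hidden + 4 * n_hidden))
        self.W = rng.uniform(-lim_w, lim_w, size=(n_in, 4 * n_hidden))
        self.U = rng.uniform(-lim_u, lim_u, size=(n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray):
        """x: (B, T, n_in). Returns last hidden state (B, H) and a cache."""
        B, T, _ = x.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            z = x[:, t, :] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x[:, t, :], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        return h, cache

    def backward(self, dh_last: np.ndarray, cache):
        H = self.n_hidden
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dh = dh_last
        dc = np.zeros_like(dh_last)
        for t in range(len(cache) - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ self.U.T
        return [dW, dU, db]


class BiLSTMClassifier:
    """Bidirectional LSTM window classifier with softmax output.

    Parameters
    ----------
    n_features : input width (18 per-sensor, 108 combined)
    n_classes : number of intent classes
    hidden_units : LSTM units per direction
    epochs, learning_rate, batch_size : Adam training schedule
    seed : seeds initialisation and mini-batch shuffling
    """

    def __init__(
        self,
        n_features: int,
        n_classes: int = 3,
        hidden_units: int = 15,
        epochs: int = 50,
        learning_rate: float = 1e-3,
        batch_size: int = 512,
        seed: int = 0,
    ):
        self.n_features = n_features
        self.n_classes = n_classes
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.fwd = _LSTMDirection(n_features, hidden_units, rng)
        self.bwd = _LSTMDirection(n_features, hidden_units, rng)
        lim = np.sqrt(6.0 / (2 * hidden_units + n_classes))
        self.W_out = rng.uniform(-lim, lim, size=(2 * hidden_units, n_classes))
        self.b_out = np.zeros(n_classes)
        self._adam_state = None
        self.loss_history_: list[float] = []

    # ---- parameter plumbing -------------------------------------------------

    def _params(self):
        return self.fwd.params() + self.bwd.params() + [self.W_out, self.b_out]

    def _forward(self, x: np.ndarray):
        h_f, cache_f = self.fwd.forward(x)
        h_b, cache_b = self.bwd.forward(x[:, ::-1, :])
        h = np.concatenate([h_f, h_b], axis=1)
        logits = h @ self.W_out + self.b_out
        return _softmax(logits), (h, cache_f, cache_b)

    def _gradients(self, x: np.ndarray, y: np.ndarray):
        """Cross-entropy loss and gradients for a batch. y: int labels (B,)."""
        B = x.shape[0]
        probs, (h, cache_f, cache_b) = self._forward(x)
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-300))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dW_out = h.T @ dlogits
        db_out = dlogits.sum(axis=0)
        dh = dlogits @ self.W_out.T
        H = self.hidden_units
        grads_f = self.fwd.backward(dh[:, :H], cache_f)
        grads_b = self.bwd.backward(dh[:, H:], cache_b)
        return loss, grads_f + grads_b + [dW_out, db_out]

    # ---- training / inference ----------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray) -> "BiLSTMClassifier":
        """x: (N, T, n_features) windows; y: (N,) integer class labels."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if x.ndim != 3 or x.shape[2] != self.n_features:
            raise ValueError(f"expected (N, T, {self.n_features}) input, got {x.shape}")
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        rng = np.random.default_rng(self.seed + 1)
        n = x.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, grads = self._gradients(x[idx], y[idx])
                epoch_loss += loss * len(idx)
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g**2
                    m_hat = mi / (1 - beta1**step)
                    v_hat = vi / (1 - beta2**step)
                    p -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, ...]
        if x.shape[2] != self.n_features:
            raise ValueError(
                f"window width {x.shape[2]} does not match classifier "
                f"input width {self.n_features}"
            )
        probs, _ = self._forward(x)
        return probs
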