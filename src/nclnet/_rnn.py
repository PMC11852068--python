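"""A compact recurrent sequence classifier (numpy, Adam-trained).

Single Elman-style recurrent layer (tanh) read out at the final step through
a logistic unit; trained with mini-batch Adam on binary cross-entropy using
backpropagation through time.  Sequences here are short (the 7 sliding
windows of one condition), so a single ungated recurrent layer suffices to
pick up the temporal structure of the network features.

The interface follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``) so it can stand beside the sklearn decoders in the
cross-validation loop.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RecurrentClassifier"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class RecurrentClassifier:
    """Elman recurrent network for binary classification of short sequences.

    Parameters
    ----------
    n_hidden : hidden units (default 16).
    n_epochs : full passes over the training set (default 50).
    lr : Adam learning rate (default 1e-2).
    batch_size : mini-batch size (default 16).
    random_state : seed for initialization and batch shuffling.
    """

    def __init__(
        self,
        n_hidden: int = 16,
        n_epochs: int = 50,
        lr: float = 1e-2,
        batch_size: int = 16,
        random_state: int = 0,
    ) -> None:
        self.n_hidden = n_hidden
        self.n_epochs = n_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (hidden states (B, T+1, H) with h[0]=0, probabilities (B,))."""
        b, t, _ = x.shape
        h = np.zeros((b, t + 1, self.n_hidden))
        for step in range(t):
            h[:, step + 1] = np.tanh(
                x[:, step] @ self.wxh_ + h[:, step] @ self.whh_ + self.bh_
            )
        logits = h[:, -1] @ self.wo_ + self.bo_
        return h, _sigmoid(logits)

    def _grads(self, x: np.ndarray, y: np.ndarray):
        b, t, _ = x.shape
        h, p = self._forward(x)
        dlogit = (p - y) / b
        g_wo = h[:, -1].T @ dlogit
        g_bo = dlogit.sum()
        g_wxh = np.zeros_like(self.wxh_)
        g_whh = np.zeros_like(self.whh_)
        g_bh = np.zeros_like(self.bh_)
        dh = np.outer(dlogit, self.wo_)
        for step in range(t - 1, -1, -1):
            dpre = dh * (1.0 - h[:, step + 1] ** 2)
            g_wxh += x[:, step].T @ dpre
            g_whh += h[:, step].T @ dpre
            g_bh += dpre.sum(axis=0)
            dh = dpre @ self.whh_.T
        return [g_wxh, g_whh, g_bh, g_wo, g_bo]

    # -- sklearn-style API -------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "RecurrentClassifier":
        """``X``: (n_samples, n_steps, n_inputs); ``y``: 0/1 labels."""
        x = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 3:
            raise ValueError("X must be (n_samples, n_steps, n_inputs)")
        rng = np.random.default_rng(self.random_state)
        n, _, d = x.shape
        h = self.n_hidden
        self.wxh_ = rng.standard_normal((d, h)) / np.sqrt(d)
        self.whh_ = rng.standard_normal((h, h)) / np.sqrt(h)
        self.bh_ = np.zeros(h)
        self.wo_ = rng.standard_normal(h) / np.sqrt(h)
        self.bo_ = 0.0
        params = [self.wxh_, self.whh_, self.bh_, self.wo_, np.array(self.bo_)]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                grads = self._grads(x[idx], y[idx])
                step += 1
                new = []
                for i, (p, g) in enumerate(zip(params, grads)):
                    g = np.asarray(g, dtype=float)
                    m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
                    v_t[i] = beta2 * v_t[i] + (1 - beta2) * g * g
                    m_hat = m_t[i] / (1 - beta1**step)
                    v_hat = v_t[i] / (1 - beta2**step)
                    new.append(p - self.lr * m_hat / (np.sqrt(v_hat) + eps))
                params = new
                self.wxh_, self.whh_, self.bh_, self.wo_ = params[:4]
                self.bo_ = float(params[4])
                params = [self.wxh_, self.whh_, self.bh_, self.wo_, np.array(self.bo_)]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        _, p = self._forward(x)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
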