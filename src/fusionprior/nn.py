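"""NumPy implementation of the sequence-scoring network.

Architecture: token embedding -> 1-D convolution (same padding, ReLU) ->
temporal max-pooling -> bidirectional LSTM (final hidden states of both
directions concatenated) -> dropout -> dense sigmoid head emitting one
probability in [0, 1].

Forward and backward passes are written explicitly; parameters are updated
with Adam.  Everything is deterministic given the seed: initialization uses
a dedicated ``numpy.random.Generator`` and dropout masks are drawn from a
separate generator owned by the training loop.
"""

from __future__ import annotations

import numpy as np

from .errors import ModelError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


class NeuralScorer:
    """CNN -> biLSTM binary classifier over integer-encoded sequences.

    Parameters
    ----------
    vocab_size:
        Number of token indices including the pad token 0.
    max_len:
        Fixed input length T; must be divisible by ``pool_size`` after
        convolution (enforced by truncating the pooled tail).
    """

    def __init__(
        self,
        vocab_size: int,
        max_len: int,
        embedding_dim: int = 16,
        conv_filters: int = 64,
        conv_kernel: int = 7,
        pool_size: int = 4,
        lstm_units: int = 64,
        dropout: float = 0.3,
        seed: int = 0,
    ):
        for name, v in [
            ("vocab_size", vocab_size),
            ("max_len", max_len),
            ("embedding_dim", embedding_dim),
            ("conv_filters", conv_filters),
            ("conv_kernel", conv_kernel),
            ("pool_size", pool_size),
            ("lstm_units", lstm_units),
        ]:
            if v <= 0:
                raise ModelError(f"{name} must be positive, got {v}")
        if not 0.0 <= dropout < 1.0:
            raise ModelError(f"dropout must be in [0, 1), got {dropout}")
        self.vocab_size = vocab_size
        self.max_len = max_len
        self.embedding_dim = embedding_dim
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.pool_size = pool_size
        self.lstm_units = lstm_units
        self.dropout = dropout
        self.seed = seed
        self.params = self._init_params(np.random.default_rng(seed))
        self._adam_state: dict | None = None

    # ------------------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        E, F, K, H = self.embedding_dim, self.conv_filters, self.conv_kernel, self.lstm_units
        p: dict[str, np.ndarray] = {}
        p["emb"] = rng.normal(0.0, 0.05, size=(self.vocab_size, E))
        p["conv_w"] = _glorot(rng, K * E, F, (K * E, F))
        p["conv_b"] = np.zeros(F)
        for d in ("fwd", "bwd"):
            p[f"lstm_{d}_wx"] = _glorot(rng, F, 4 * H, (F, 4 * H))
            p[f"lstm_{d}_wh"] = _glorot(rng, H, 4 * H, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            p[f"lstm_{d}_b"] = b
        p["dense_w"] = _glorot(rng, 2 * H, 1, (2 * H, 1))
        p["dense_b"] = np.zeros(1)
        return p

    # ------------------------------------------------------------------
    def _conv_windows(self, emb: np.ndarray) -> np.ndarray:
        """(B, T, K*E) sliding windows with same padding."""
        B, T, E = emb.shape
        K = self.conv_kernel
        left = (K - 1) // 2
        right = K - 1 - left
        padded = np.zeros((B, T + K - 1, E))
        padded[:, left : left + T] = emb
        windows = np.lib.stride_tricks.sliding_window_view(padded, K, axis=1)
        # windows: (B, T, E, K) -> (B, T, K*E) with kernel-major layout
        return np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(B, T, K * E)

    def _lstm_forward(self, x: np.ndarray, d: str):
        """x: (T2, B, F) in the direction's time order; returns final h and cache."""
        p = self.params
        Wx, Wh, b = p[f"lstm_{d}_wx"], p[f"lstm_{d}_wh"], p[f"lstm_{d}_b"]
        T2, B, _ = x.shape
        H = self.lstm_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates = np.empty((T2, B, 4 * H))
        cs = np.empty((T2, B, H))
        hs_prev = np.empty((T2, B, H))
        cs_prev = np.empty((T2, B, H))
        for t in range(T2):
            hs_prev[t] = h
            cs_prev[t] = c
            z = x[t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t] = np.concatenate([i, f, g, o], axis=1)
            cs[t] = c
        return h, {"x": x, "gates": gates, "cs": cs, "hs_prev": hs_prev, "cs_prev": cs_prev}

    def _lstm_backward(self, dh_last: np.ndarray, cache: dict, d: str):
        p = self.params
        Wx, Wh = p[f"lstm_{d}_wx"], p[f"lstm_{d}_wh"]
        x, gates, cs = cache["x"], cache["gates"], cache["cs"]
        hs_prev, cs_prev = cache["hs_prev"], cache["cs_prev"]
        T2, B, _ = x.shape
        H = self.lstm_units
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.empty_like(x)
        dh = dh_last
        dc = np.zeros((B, H))
        for t in range(T2 - 1, -1, -1):
            i = gates[t][:, :H]
            f = gates[t][:, H : 2 * H]
            g = gates[t][:, 2 * H : 3 * H]
            o = gates[t][:, 3 * H :]
            tanh_c = np.tanh(cs[t])
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * cs_prev[t]
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[t].T @ dz
            dWh += hs_prev[t].T @ dz
            db += dz.sum(axis=0)
            dx[t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        return dx, dWx, dWh, db

    # ------------------------------------------------------------------
    def forward(self, ids: np.ndarray, train: bool = False, drop_rng: np.random.Generator | None = None):
        """ids: (B, T) int array. Returns (probs (B,), cache)."""
        p = self.params
        B, T = ids.shape
        if T != self.max_len:
            raise ModelError(f"input length {T} != max_len {self.max_len}")
        emb = p["emb"][ids]  # (B, T, E)
        windows = self._conv_windows(emb)  # (B, T, K*E)
        pre = windows @ p["conv_w"] + p["conv_b"]  # (B, T, F)
        act = np.maximum(pre, 0.0)
        P = self.pool_size
        T2 = T // P
        pooled_in = act[:, : T2 * P].reshape(B, T2, P, self.conv_filters)
        arg = pooled_in.argmax(axis=2)
        pooled = np.take_along_axis(pooled_in, arg[:, :, None, :], axis=2)[:, :, 0, :]
        x_fwd = pooled.transpose(1, 0, 2)  # (T2, B, F)
        x_bwd = x_fwd[::-1]
        h_fwd, cache_fwd = self._lstm_forward(x_fwd, "fwd")
        h_bwd, cache_bwd = self._lstm_forward(x_bwd, "bwd")
        h = np.concatenate([h_fwd, h_bwd], axis=1)  # (B, 2H)
        if train and self.dropout > 0.0:
            if drop_rng is None:
                raise ModelError("training forward pass needs a dropout generator")
            mask = (drop_rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(h)
        hd = h * mask
        logit = (hd @ p["dense_w"] + p["dense_b"])[:, 0]
        prob = _sigmoid(logit)
        cache = {
            "ids": ids,
            "windows": windows,
            "pre": pre,
            "arg": arg,
            "cache_fwd": cache_fwd,
            "cache_bwd": cache_bwd,
            "h": h,
            "mask": mask,
            "hd": hd,
            "prob": prob,
        }
        return prob, cache

    def loss_and_grads(self, ids: np.ndarray, y: np.ndarray, drop_rng: np.random.Generator):
        """Mean binary cross-entropy and gradients for one minibatch."""
        p = self.params
        B, T = ids.shape
        prob, cache = self.forward(ids, train=True, drop_rng=drop_rng)
        eps = 1e-12
        loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = (prob - y) / B  # (B,)
        grads["dense_w"] = cache["hd"].T @ dlogit[:, None]
        grads["dense_b"] = np.array([dlogit.sum()])
        dhd = dlogit[:, None] @ p["dense_w"].T  # (B, 2H)
        dh = dhd * cache["mask"]
        H = self.lstm_units
        dx_fwd, dWx_f, dWh_f, db_f = self._lstm_backward(dh[:, :H], cache["cache_fwd"], "fwd")
        dx_bwd, dWx_b, dWh_b, db_b = self._lstm_backward(dh[:, H:], cache["cache_bwd"], "bwd")
        grads["lstm_fwd_wx"], grads["lstm_fwd_wh"], grads["lstm_fwd_b"] = dWx_f, dWh_f, db_f
        grads["lstm_bwd_wx"], grads["lstm_bwd_wh"], grads["lstm_bwd_b"] = dWx_b, dWh_b, db_b
        dpooled = (dx_fwd + dx_bwd[::-1]).transpose(1, 0, 2)  # (B, T2, F)
        P = self.pool_size
        T2 = T // P
        dact = np.zeros((B, T2, P, self.conv_filters))
        np.put_along_axis(dact, cache["arg"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        dact_full = np.zeros((B, T, self.conv_filters))
        dact_full[:, : T2 * P] = dact.reshape(B, T2 * P, self.conv_filters)
        dpre = dact_full * (cache["pre"] > 0.0)
        KE = self.conv_kernel * self.embedding_dim
        grads["conv_w"] = cache["windows"].reshape(-1, KE).T @ dpre.reshape(-1, self.conv_filters)
        grads["conv_b"] = dpre.sum(axis=(0, 1))
        dwindows = dpre @ p["conv_w"].T  # (B, T, K*E)
        E, K = self.embedding_dim, self.conv_kernel
        left = (K - 1) // 2
        dpadded = np.zeros((B, T + K - 1, E))
        dwin = dwindows.reshape(B, T, K, E)
        for k in range(K):
            dpadded[:, k : k + T] += dwin[:, :, k, :]
        demb = dpadded[:, left : left + T]
        np.add.at(grads["emb"], cache["ids"], demb)
        return loss, grads

    # ------------------------------------------------------------------
    def adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                "v": {k: np.zeros_like(v) for k, v in self.params.items()},
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for k, g in grads.items():
            st["m"][k] = beta1 * st["m"][k] + (1 - beta1) * g
            st["v"][k] = beta2 * st["v"][k] + (1 - beta2) * g * g
            mhat = st["m"][k] / (1 - beta1**t)
            vhat = st["v"][k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def predict(self, ids: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Probabilities for (N, T) encoded sequences, evaluated in batches."""
        out = np.empty(len(ids))
        for i in range(0, len(ids), batch_size):
            out[i : i + batch_size] = self.forward(ids[i : i + batch_size])[0]
        return out

    # ------------------------------------------------------------------
    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            if k not in params:
                raise ModelError(f"missing parameter {k!r} in weight bundle")
            if params[k].shape != self.params[k].shape:
                raise ModelError(
                    f"shape mismatch for {k!r}: {params[k].shape} vs {self.params[k].shape}"
                )
            self.params[k] = params[k].astype(np.float64).copy()
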