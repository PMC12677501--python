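"""Numpy Q-networks: convolutional torso, dueling streams, optional LSTM.

Three variants share a convolutional torso over a stack of grayscale frames:

* ``baseline``        conv stack -> fully connected -> linear Q head.
* ``dueling_double``  conv stack -> separate value and advantage streams,
                      combined as Q_a = V + (A_a - mean(A)).
* ``recurrent``       conv stack -> fully connected -> LSTM (fed auxiliary
                      inputs: last reward, terminal flag, one-hot action) ->
                      linear dueling heads on the hidden state.

Everything is plain numpy with hand-written backward passes, so training and
feature extraction are dependency-free and bit-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ShapeMismatchError

VARIANTS = ("baseline", "dueling_double", "recurrent")


@dataclass
class QNetworkConfig:
    """Architecture of one Q-network.

    The default conv stack and fully-connected width follow the classic Atari
    network: 32 filters 8x8 stride 4, 64 filters 4x4 stride 2, 64 filters 3x3
    stride 1, then 512 hidden units on 84x84 inputs.  The ``mini`` preset
    (see :func:`mini_config`) shrinks everything for 12x12 toy frames.
    """

    n_actions: int = 3
    variant: str = "baseline"
    conv_specs: tuple = ((32, 8, 4), (64, 4, 2), (64, 3, 1))  # (filters, kernel, stride)
    fc_width: int = 512
    recurrent_width: int = 64
    input_frames: int = 4
    input_size: int = 84

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_actions < 2:
            raise ValueError("n_actions must be >= 2")

    @property
    def aux_size(self) -> int:
        # last reward, terminal flag, one-hot previous action
        return 2 + self.n_actions


def mini_config(variant: str = "baseline", n_actions: int = 3, input_size: int = 12,
                input_frames: int = 4) -> QNetworkConfig:
    """Small preset for 12x12 toy frames; same contracts as the full network."""
    return QNetworkConfig(
        n_actions=n_actions,
        variant=variant,
        conv_specs=((8, 3, 1),),
        fc_width=64,
        recurrent_width=32,
        input_frames=input_frames,
        input_size=input_size,
    )


@dataclass
class RecurrentState:
    """LSTM carry: hidden/cell plus the auxiliary inputs for the next step."""

    h: np.ndarray
    c: np.ndarray
    aux: np.ndarray  # (batch, 2 + n_actions): last reward, terminal, action one-hot

    @classmethod
    def zeros(cls, config: QNetworkConfig, batch: int = 1) -> "RecurrentState":
        return cls(
            h=np.zeros((batch, config.recurrent_width)),
            c=np.zeros((batch, config.recurrent_width)),
            aux=np.zeros((batch, config.aux_size)),
        )


# ---------------------------------------------------------------------------
# layer primitives


def _im2col(x: np.ndarray, k: int, stride: int):
    """(B, C, H, W) -> (B, oh*ow, C*k*k) patch matrix."""
    b, c, h, w = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, oh, ow, k, k)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def conv_forward(x, w, bias, stride):
    """Valid convolution; w is (F, C, k, k)."""
    f, c, k, _ = w.shape
    cols, oh, ow = _im2col(x, k, stride)
    out = cols @ w.reshape(f, -1).T + bias  # (B, oh*ow, F)
    out = out.transpose(0, 2, 1).reshape(x.shape[0], f, oh, ow)
    cache = (cols, x.shape, w.shape, stride, oh, ow)
    return out, cache


def conv_backward(dout, cache, w, need_dx=True):
    cols, x_shape, w_shape, stride, oh, ow = cache
    b = x_shape[0]
    f, c, k, _ = w_shape
    dflat = dout.reshape(b, f, oh * ow).transpose(0, 2, 1)  # (B, oh*ow, F)
    dw = np.tensordot(dflat, cols, axes=([0, 1], [0, 1])).reshape(w_shape)
    dbias = dflat.sum(axis=(0, 1))
    dx = None
    if need_dx:
        dcols = dflat @ w.reshape(f, -1)  # (B, oh*ow, C*k*k)
        dcols = dcols.reshape(b, oh, ow, c, k, k)
        dx = np.zeros(x_shape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
    return dx, dw, dbias


def dense_forward(x, w, b):
    return x @ w + b, x


def dense_backward(dout, x, w):
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def relu_forward(x):
    out = np.maximum(x, 0.0)
    return out, out


def relu_backward(dout, out):
    return dout * (out > 0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step_forward(x, h_prev, c_prev, wx, wh, b):
    """One LSTM step; gate order i, f, g, o."""
    hid = h_prev.shape[1]
    z = x @ wx + h_prev @ wh + b
    i = _sigmoid(z[:, :hid])
    f = _sigmoid(z[:, hid : 2 * hid])
    g = np.tanh(z[:, 2 * hid : 3 * hid])
    o = _sigmoid(z[:, 3 * hid :])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    cache = (x, h_prev, c_prev, i, f, g, o, c, tc)
    return h, c, cache


def lstm_step_backward(dh, dc, cache, wx, wh):
    x, h_prev, c_prev, i, f, g, o, c, tc = cache
    do = dh * tc
    dc = dc + dh * o * (1 - tc**2)
    di = dc * g
    df = dc * c_prev
    dg = dc * i
    dc_prev = dc * f
    dz = np.concatenate(
        [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
    )
    dx = dz @ wx.T
    dh_prev = dz @ wh.T
    dwx = x.T @ dz
    dwh = h_prev.T @ dz
    db = dz.sum(axis=0)
    return dx, dh_prev, dc_prev, dwx, dwh, db


def dueling_combine(state_value, advantages):
    """Q_a = V + (A_a - mean(A)); invariant to a constant shift of A."""
    advantages = np.asarray(advantages, dtype=np.float64)
    v = np.asarray(state_value, dtype=np.float64)
    return v + advantages - advantages.mean(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the network


class QNetwork:
    """A Q-network of one of the three variants, with manual backprop."""

    def __init__(self, config: QNetworkConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._build(np.random.default_rng(seed))

    # -- construction -------------------------------------------------------

    def _build(self, rng):
        cfg = self.config
        c_in = cfg.input_frames
        size = cfg.input_size
        for li, (filters, kernel, stride) in enumerate(cfg.conv_specs):
            fan_in = c_in * kernel * kernel
            self.params[f"conv{li}_w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (filters, c_in, kernel, kernel)
            )
            self.params[f"conv{li}_b"] = np.zeros(filters)
            size = (size - kernel) // stride + 1
            if size < 1:
                raise ShapeMismatchError(
                    f"conv stack collapses a {cfg.input_size}x{cfg.input_size} input"
                )
            c_in = filters
        self.flat_dim = c_in * size * size

        def dense(name, n_in, n_out):
            self.params[f"{name}_w"] = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
            self.params[f"{name}_b"] = np.zeros(n_out)

        if cfg.variant == "baseline":
            dense("fc", self.flat_dim, cfg.fc_width)
            dense("out", cfg.fc_width, cfg.n_actions)
        elif cfg.variant == "dueling_double":
            dense("fc_v", self.flat_dim, cfg.fc_width)
            dense("fc_a", self.flat_dim, cfg.fc_width)
            dense("v", cfg.fc_width, 1)
            dense("a", cfg.fc_width, cfg.n_actions)
        else:  # recurrent
            dense("fc", self.flat_dim, cfg.fc_width)
            n_in = cfg.fc_width + cfg.aux_size
            hid = cfg.recurrent_width
            self.params["lstm_wx"] = rng.normal(0.0, np.sqrt(1.0 / n_in), (n_in, 4 * hid))
            self.params["lstm_wh"] = rng.normal(0.0, np.sqrt(1.0 / hid), (hid, 4 * hid))
            self.params["lstm_b"] = np.zeros(4 * hid)
            dense("v", hid, 1)
            dense("a", hid, cfg.n_actions)

    # -- forward ------------------------------------------------------------

    def _check_input(self, stacks: np.ndarray) -> np.ndarray:
        cfg = self.config
        x = np.asarray(stacks, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        expected = (cfg.input_frames, cfg.input_size, cfg.input_size)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ShapeMismatchError(
                f"expected frame stack of shape {expected} (optionally batched), got {np.shape(stacks)}"
            )
        return x

    def _torso(self, x, keep_cache):
        caches = []
        out = x
        for li, (_f, _k, stride) in enumerate(self.config.conv_specs):
            out, cc = conv_forward(out, self.params[f"conv{li}_w"], self.params[f"conv{li}_b"], stride)
            out, rc = relu_forward(out)
            caches.append((cc, rc) if keep_cache else None)
        flat = out.reshape(out.shape[0], -1)
        return flat, caches

    def q_values(self, stacks, rec_state: RecurrentState | None = None, keep_cache=False):
        """Q-vector per batch row; recurrent nets also return the advanced state.

        Returns ``(q, new_rec_state, cache)``; for feed-forward variants
        ``new_rec_state`` is None.  `stacks` is (frames, size, size) or a
        leading-batch version of it.
        """
        cfg = self.config
        x = self._check_input(stacks)
        single = np.asarray(stacks).ndim == 3
        p = self.params
        flat, conv_caches = self._torso(x, keep_cache)

        if cfg.variant == "baseline":
            h_pre, c1 = dense_forward(flat, p["fc_w"], p["fc_b"])
            h, rh = relu_forward(h_pre)
            q, c2 = dense_forward(h, p["out_w"], p["out_b"])
            cache = (conv_caches, c1, rh, c2) if keep_cache else None
            new_state = None
        elif cfg.variant == "dueling_double":
            hv_pre, cv1 = dense_forward(flat, p["fc_v_w"], p["fc_v_b"])
            hv, rv = relu_forward(hv_pre)
            ha_pre, ca1 = dense_forward(flat, p["fc_a_w"], p["fc_a_b"])
            ha, ra = relu_forward(ha_pre)
            v, cv2 = dense_forward(hv, p["v_w"], p["v_b"])
            adv, ca2 = dense_forward(ha, p["a_w"], p["a_b"])
            q = dueling_combine(v, adv)
            cache = (conv_caches, cv1, rv, ca1, ra, cv2, ca2) if keep_cache else None
            new_state = None
        else:
            if rec_state is None:
                raise ShapeMismatchError("recurrent variant requires a RecurrentState")
            h_pre, c1 = dense_forward(flat, p["fc_w"], p["fc_b"])
            h, rh = relu_forward(h_pre)
            lstm_in = np.concatenate([h, rec_state.aux], axis=1)
            hh, cc, lc = lstm_step_forward(
                lstm_in, rec_state.h, rec_state.c, p["lstm_wx"], p["lstm_wh"], p["lstm_b"]
            )
            v, cv = dense_forward(hh, p["v_w"], p["v_b"])
            adv, ca = dense_forward(hh, p["a_w"], p["a_b"])
            q = dueling_combine(v, adv)
            new_state = RecurrentState(h=hh, c=cc, aux=rec_state.aux)
            cache = (conv_caches, c1, rh, lc, cv, ca) if keep_cache else None

        if single:
            q = q[0]
        return q, new_state, cache

    # -- backward -----------------------------------------------------------

    def _torso_backward(self, dflat, conv_caches, x_batch, grads):
        cfg = self.config
        # reshape dflat to the last conv output shape
        _, last_relu = conv_caches[-1]
        dout = dflat.reshape(last_relu.shape)
        for li in reversed(range(len(cfg.conv_specs))):
            cc, rc = conv_caches[li]
            dout = relu_backward(dout, rc)
            dout, dw, db = conv_backward(dout, cc, self.params[f"conv{li}_w"], need_dx=li > 0)
            grads[f"conv{li}_w"] = grads.get(f"conv{li}_w", 0) + dw
            grads[f"conv{li}_b"] = grads.get(f"conv{li}_b", 0) + db

    def backward(self, dq: np.ndarray, cache, grads: dict | None = None,
                 drec: tuple | None = None):
        """Accumulate parameter gradients for a batch given dLoss/dQ.

        For the recurrent variant `drec` carries (dh, dc) flowing in from the
        next time step; the return value is (grads, (dh_prev, dc_prev)).
        """
        cfg = self.config
        p = self.params
        grads = grads if grads is not None else {}
        dq = np.atleast_2d(dq)

        def acc(name, val):
            grads[name] = grads.get(name, 0) + val

        if cfg.variant == "baseline":
            conv_caches, c1, rh, c2 = cache
            dh, dw, db = dense_backward(dq, c2, p["out_w"])
            acc("out_w", dw), acc("out_b", db)
            dh = relu_backward(dh, rh)
            dflat, dw, db = dense_backward(dh, c1, p["fc_w"])
            acc("fc_w", dw), acc("fc_b", db)
            self._torso_backward(dflat, conv_caches, None, grads)
            return grads, None

        # dueling combine backward: dV = sum_a dq_a ; dA = dq - mean_a(dq)
        dv = dq.sum(axis=1, keepdims=True)
        da = dq - dq.mean(axis=1, keepdims=True)

        if cfg.variant == "dueling_double":
            conv_caches, cv1, rv, ca1, ra, cv2, ca2 = cache
            dhv, dw, db = dense_backward(dv, cv2, p["v_w"])
            acc("v_w", dw), acc("v_b", db)
            dha, dw, db = dense_backward(da, ca2, p["a_w"])
            acc("a_w", dw), acc("a_b", db)
            dhv = relu_backward(dhv, rv)
            dha = relu_backward(dha, ra)
            dflat_v, dw, db = dense_backward(dhv, cv1, p["fc_v_w"])
            acc("fc_v_w", dw), acc("fc_v_b", db)
            dflat_a, dw, db = dense_backward(dha, ca1, p["fc_a_w"])
            acc("fc_a_w", dw), acc("fc_a_b", db)
            self._torso_backward(dflat_v + dflat_a, conv_caches, None, grads)
            return grads, None

        conv_caches, c1, rh, lc, cv, ca = cache
        dh_head, dw, db = dense_backward(dv, cv, p["v_w"])
        acc("v_w", dw), acc("v_b", db)
        dh2, dw, db = dense_backward(da, ca, p["a_w"])
        acc("a_w", dw), acc("a_b", db)
        dh = dh_head + dh2
        if drec is not None:
            dh = dh + drec[0]
            dc_in = drec[1]
        else:
            dc_in = np.zeros_like(dh)
        dx, dh_prev, dc_prev, dwx, dwh, db_l = lstm_step_backward(
            dh, dc_in, lc, p["lstm_wx"], p["lstm_wh"]
        )
        acc("lstm_wx", dwx), acc("lstm_wh", dwh), acc("lstm_b", db_l)
        dfc = relu_backward(dx[:, : cfg.fc_width], rh)
        dflat, dw, db = dense_backward(dfc, c1, p["fc_w"])
        acc("fc_w", dw), acc("fc_b", db)
        self._torso_backward(dflat, conv_caches, None, grads)
        return grads, (dh_prev, dc_prev)

    # -- misc ---------------------------------------------------------------

    def copy(self) -> "QNetwork":
        clone = QNetwork.__new__(QNetwork)
        clone.config = self.config
        clone.flat_dim = self.flat_dim
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float = 2.5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
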