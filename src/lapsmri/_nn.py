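"""Minimal neural-network core on numpy.

Implements just enough machinery for the toy score networks used at fixture
scale: dense and 3x3 same-padding convolution layers, SiLU activations,
sinusoidal timestep embeddings, explicit reverse-mode (VJP) passes, and an
Adam optimizer.  All forward passes are functional (parameters in, caches
out) so the same code serves both training and input-gradient queries from
the data-consistency term.

Shapes: convolutional nets operate on (B, H, W, C) arrays; dense nets on
(B, D).  Single samples may be passed without the batch axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Adam",
    "ConvNet",
    "MLPNet",
    "sinusoidal_embedding",
]


def silu(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s


def silu_grad(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def sinusoidal_embedding(t, dim, max_period=10000.0):
    """Standard transformer-style embedding of (integer) timesteps.

    t: scalar or (B,) array. Returns (B, dim).
    """
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


# ---------------------------------------------------------------------------
# layers (functional)
# ---------------------------------------------------------------------------

def _he_init(rng, shape, fan_in):
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def conv3x3_init(rng, c_in, c_out):
    return {"W": _he_init(rng, (9 * c_in, c_out), 9 * c_in), "b": np.zeros(c_out)}


def conv3x3_forward(p, x):
    """x: (B,H,W,Cin) -> (B,H,W,Cout), zero-padded 'same' convolution."""
    B, H, W, Ci = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (B,H,W,Ci,3,3)
    col = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * H * W, 9 * Ci)
    out = col @ p["W"] + p["b"]
    return out.reshape(B, H, W, -1), (col, x.shape)


def conv3x3_backward(p, cache, dout):
    col, xshape = cache
    B, H, W, Ci = xshape
    dflat = dout.reshape(B * H * W, -1)
    dW = col.T @ dflat
    db = dflat.sum(axis=0)
    dcol = (dflat @ p["W"].T).reshape(B, H, W, 3, 3, Ci)
    dxp = np.zeros((B, H + 2, W + 2, Ci))
    for i in range(3):
        for j in range(3):
            dxp[:, i:i + H, j:j + W, :] += dcol[:, :, :, i, j, :]
    return dxp[:, 1:-1, 1:-1, :], {"W": dW, "b": db}


def dense_init(rng, d_in, d_out):
    return {"W": _he_init(rng, (d_in, d_out), d_in), "b": np.zeros(d_out)}


def dense_forward(p, x):
    return x @ p["W"] + p["b"], x


def dense_backward(p, x, dout):
    return dout @ p["W"].T, {"W": x.T @ dout, "b": dout.sum(axis=0)}


# ---------------------------------------------------------------------------
# score networks
# ---------------------------------------------------------------------------

class _NetBase:
    """Common plumbing: parameter flattening, Adam-ready grads, VJPs."""

    params: dict

    def param_items(self):
        for lname, layer in self.params.items():
            for pname, arr in layer.items():
                yield f"{lname}.{pname}", arr

    def get_flat(self):
        return np.concatenate([a.ravel() for _, a in self.param_items()])

    def set_flat(self, vec):
        i = 0
        for lname, layer in self.params.items():
            for pname, arr in layer.items():
                layer[pname] = vec[i:i + arr.size].reshape(arr.shape)
                i += arr.size

    def grads_flat(self, grads):
        out = []
        for lname, layer in self.params.items():
            for pname, arr in layer.items():
                out.append(grads[lname][pname].ravel())
        return np.concatenate(out)


class ConvNet(_NetBase):
    """Small conditioned CNN, eps-prediction head: (B,H,W,C), t -> (B,H,W,C).

    Structure: conv C->w, then `depth` blocks of [FiLM(t), SiLU, conv w->w],
    then conv w->C.  The timestep enters through a learned projection of a
    sinusoidal embedding to a per-channel scale and shift (FiLM) applied
    before each activation, so the network can express t-dependent gains.
    """

    def __init__(self, channels, width=32, depth=2, temb_dim=16, seed=0):
        rng = np.random.default_rng(seed)
        self.channels = channels
        self.width = width
        self.depth = depth
        self.temb_dim = temb_dim
        p = {"in": conv3x3_init(rng, channels, width)}
        for k in range(depth):
            p[f"t{k}"] = dense_init(rng, temb_dim, 2 * width)
            p[f"c{k}"] = conv3x3_init(rng, width, width)
        p["out"] = conv3x3_init(rng, width, channels)
        # near-zero output head: initial eps-prediction ~ 0
        p["out"]["W"] = p["out"]["W"] * 1e-2
        # t-gained linear skip from input to output: the score of any
        # Gaussian component is linear in z, so give it a direct path
        p["skip"] = dense_init(rng, temb_dim, channels)
        p["skip"]["W"] = p["skip"]["W"] * 1e-2
        self.params = p

    def forward(self, x, t_frac):
        """x: (B,H,W,C); t_frac: (B,) timestep scaled to [0, 1000]."""
        caches = {}
        temb = sinusoidal_embedding(t_frac, self.temb_dim)
        h, caches["in"] = conv3x3_forward(self.params["in"], x)
        for k in range(self.depth):
            film, caches[f"t{k}"] = dense_forward(self.params[f"t{k}"], temb)
            scale, shift = film[:, :self.width], film[:, self.width:]
            caches[f"film{k}"] = (scale, h)
            pre = h * (1.0 + scale[:, None, None, :]) + shift[:, None, None, :]
            caches[f"pre{k}"] = pre
            h = silu(pre)
            h, caches[f"c{k}"] = conv3x3_forward(self.params[f"c{k}"], h)
        out, caches["out"] = conv3x3_forward(self.params["out"], h)
        gain, caches["skip"] = dense_forward(self.params["skip"], temb)
        caches["skip_x"] = (gain, x)
        out = out + gain[:, None, None, :] * x
        return out, caches

    def backward(self, caches, dout):
        grads = {}
        gain, x = caches["skip_x"]
        dgain = (dout * x).sum(axis=(1, 2))
        _, grads["skip"] = dense_backward(self.params["skip"], caches["skip"], dgain)
        dx_skip = dout * gain[:, None, None, :]
        dh, grads["out"] = conv3x3_backward(self.params["out"], caches["out"], dout)
        for k in reversed(range(self.depth)):
            dh, grads[f"c{k}"] = conv3x3_backward(self.params[f"c{k}"], caches[f"c{k}"], dh)
            dpre = dh * silu_grad(caches[f"pre{k}"])
            scale, h_in = caches[f"film{k}"]
            dscale = (dpre * h_in).sum(axis=(1, 2))
            dshift = dpre.sum(axis=(1, 2))
            dfilm = np.concatenate([dscale, dshift], axis=1)
            _, grads[f"t{k}"] = dense_backward(self.params[f"t{k}"], caches[f"t{k}"], dfilm)
            dh = dpre * (1.0 + scale[:, None, None, :])
        dx, grads["in"] = conv3x3_backward(self.params["in"], caches["in"], dh)
        return dx + dx_skip, grads


class MLPNet(_NetBase):
    """Small conditioned MLP for flat latents: (B,D), t -> (B,D)."""

    def __init__(self, dim, width=64, depth=2, temb_dim=16, seed=0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.width = width
        self.depth = depth
        self.temb_dim = temb_dim
        p = {"in": dense_init(rng, dim, width)}
        for k in range(depth):
            p[f"t{k}"] = dense_init(rng, temb_dim, 2 * width)
            p[f"d{k}"] = dense_init(rng, width, width)
        p["out"] = dense_init(rng, width, dim)
        p["out"]["W"] = p["out"]["W"] * 1e-2
        p["skip"] = dense_init(rng, temb_dim, dim)
        p["skip"]["W"] = p["skip"]["W"] * 1e-2
        self.params = p

    def forward(self, x, t_frac):
        caches = {}
        temb = sinusoidal_embedding(t_frac, self.temb_dim)
        h, caches["in"] = dense_forward(self.params["in"], x)
        for k in range(self.depth):
            film, caches[f"t{k}"] = dense_forward(self.params[f"t{k}"], temb)
            scale, shift = film[:, :self.width], film[:, self.width:]
            caches[f"film{k}"] = (scale, h)
            pre = h * (1.0 + scale) + shift
            caches[f"pre{k}"] = pre
            h = silu(pre)
            h, caches[f"d{k}"] = dense_forward(self.params[f"d{k}"], h)
        out, caches["out"] = dense_forward(self.params["out"], h)
        gain, caches["skip"] = dense_forward(self.params["skip"], temb)
        caches["skip_x"] = (gain, x)
        out = out + gain * x
        return out, caches

    def backward(self, caches, dout):
        grads = {}
        gain, x = caches["skip_x"]
        _, grads["skip"] = dense_backward(self.params["skip"], caches["skip"],
                                          dout * x)
        dx_skip = dout * gain
        dh, grads["out"] = dense_backward(self.params["out"], caches["out"], dout)
        for k in reversed(range(self.depth)):
            dh, grads[f"d{k}"] = dense_backward(self.params[f"d{k}"], caches[f"d{k}"], dh)
            dpre = dh * silu_grad(caches[f"pre{k}"])
            scale, h_in = caches[f"film{k}"]
            dfilm = np.concatenate([dpre * h_in, dpre], axis=1)
            _, grads[f"t{k}"] = dense_backward(self.params[f"t{k}"], caches[f"t{k}"], dfilm)
            dh = dpre * (1.0 + scale)
        dx, grads["in"] = dense_backward(self.params["in"], caches["in"], dh)
        return dx + dx_skip, grads


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, n_params_or_shape, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.m = np.zeros(n_params_or_shape)
        self.v = np.zeros(n_params_or_shape)
        self.k = 0

    def step(self, x, g):
        self.k += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1 ** self.k)
        vhat = self.v / (1 - self.b2 ** self.k)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)
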