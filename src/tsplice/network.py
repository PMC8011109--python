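"""The TSplice network: a numpy implementation with explicit gradients.

Architecture, per input branch (acceptor-side and donor-side 400×4 one-hot
matrices):

    one-hot input
      → 1D convolution, 64 filters of length 9, same padding, bias, ReLU
        (convolution parameters shared by the two branches)
      → batch normalization (shared scale/shift)
      → positional spline weighting: activation of filter f at position p is
        multiplied by w_f(p) = Σ_b θ_{f,b} · basis[p, b], with separate θ per
        branch
      → batch normalization (per branch)

then the two branches are concatenated along the position axis (800×64),
global average pooling over positions (→64), a hidden dense layer with ReLU
and batch normalization, and a linear output layer with one unit per tissue.
The output vector is the predicted Δ_tissue logit(Ψ) for each tissue.

With the default configuration the model has 8024 trainable parameters
(batch-normalization scale and shift count as trainable; running statistics
do not).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from .data_model import EncodedExon, clip_psi, logit, sigmoid
from .splines import spline_basis

__all__ = [
    "TSpliceConfig",
    "TSpliceNet",
    "build_network",
    "count_trainable_parameters",
    "predict_tissue_psi",
]

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class TSpliceConfig:
    """Architecture hyperparameters; ``seed`` fixes parameter initialization."""

    seed: int
    n_filters: int = 64
    filter_length: int = 9
    n_spline_basis: int = 10
    spline_degree: int = 3
    hidden_units: int = 32
    n_tissues: int = 56
    branch_length: int = 400
    batchnorm: bool = True

    def __post_init__(self):
        for name in (
            "n_filters",
            "filter_length",
            "n_spline_basis",
            "hidden_units",
            "n_tissues",
            "branch_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spline_degree < 0:
            raise ValueError("spline_degree must be non-negative")
        if self.filter_length % 2 == 0:
            raise ValueError("filter_length must be odd (same-padding alignment)")
        if self.n_spline_basis < self.spline_degree + 1:
            raise ValueError("n_spline_basis must be at least spline_degree+1")


def _relu(x):
    return np.maximum(x, 0.0)


class _BatchNorm:
    """Per-channel batch normalization with trainable scale and shift."""

    def __init__(self, n_channels: int):
        self.gamma = np.ones(n_channels, dtype=np.float32)
        self.beta = np.zeros(n_channels, dtype=np.float32)
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)

    def forward(self, x, training: bool):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            std = np.sqrt(var + _BN_EPS)
            xhat = (x - mu) / std
            self.running_mean = (
                (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            ).astype(np.float32)
            cache = {"xhat": xhat, "std": std, "axes": axes, "training": True}
        else:
            scale = self.gamma / np.sqrt(self.running_var + _BN_EPS)
            y = scale * x + (self.beta - scale * self.running_mean)
            return y, {"scale": scale, "training": False}
        return self.gamma * xhat + self.beta, cache

    def backward(self, dout, cache):
        """Returns (dx, dgamma, dbeta); dgamma/dbeta are None in inference mode."""
        if not cache["training"]:
            return dout * cache["scale"], None, None
        axes = cache["axes"]
        xhat, std = cache["xhat"], cache["std"]
        m = float(np.prod([dout.shape[a] for a in axes]))
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes) / m
        ) / std
        return dx, dgamma, dbeta


class TSpliceNet:
    """Tissue-specific splicing network; maps an EncodedExon to per-tissue
    Δ_tissue logit(Ψ).

    All parameters are numpy arrays; forward and backward passes are written
    explicitly so the model trains on a single CPU without a deep-learning
    framework.
    """

    def __init__(self, config: TSpliceConfig):
        self.config = config
        c = config
        rng = np.random.default_rng(c.seed)
        k, f, h, t, b = c.filter_length, c.n_filters, c.hidden_units, c.n_tissues, c.n_spline_basis

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        # shared convolution over both branches
        self.conv_w = he((k * 4, f), k * 4)
        self.conv_b = np.zeros(f, dtype=np.float32)
        # per-branch spline coefficients; ones give w_f(p) ≡ 1 at init
        # (the basis rows are a partition of unity)
        self.theta_acc = np.ones((f, b), dtype=np.float32)
        self.theta_don = np.ones((f, b), dtype=np.float32)
        self.w1 = he((f, h), f)
        self.b1 = np.zeros(h, dtype=np.float32)
        self.w2 = he((h, t), h)
        self.b2 = np.zeros(t, dtype=np.float32)
        if c.batchnorm:
            self.bn_conv = _BatchNorm(f)
            self.bn_acc = _BatchNorm(f)
            self.bn_don = _BatchNorm(f)
            self.bn_hidden = _BatchNorm(h)
        self.basis = spline_basis(c.branch_length, b, c.spline_degree).basis.astype(np.float32)
        self._pad = (k - 1) // 2

    # -- parameter bookkeeping ------------------------------------------------

    def trainable_parameters(self) -> dict[str, np.ndarray]:
        params = {
            "conv_w": self.conv_w,
            "conv_b": self.conv_b,
            "theta_acc": self.theta_acc,
            "theta_don": self.theta_don,
            "w1": self.w1,
            "b1": self.b1,
            "w2": self.w2,
            "b2": self.b2,
        }
        if self.config.batchnorm:
            for name in ("bn_conv", "bn_acc", "bn_don", "bn_hidden"):
                bn = getattr(self, name)
                params[f"{name}.gamma"] = bn.gamma
                params[f"{name}.beta"] = bn.beta
        return params

    def set_parameter(self, name: str, value: np.ndarray):
        if "." in name:
            obj, attr = name.split(".")
            cur = getattr(getattr(self, obj), attr)
            if cur.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            setattr(getattr(self, obj), attr, value.astype(np.float32))
        else:
            cur = getattr(self, name)
            if cur.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            setattr(self, name, value.astype(np.float32))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.trainable_parameters().items()}
        if self.config.batchnorm:
            for name in ("bn_conv", "bn_acc", "bn_don", "bn_hidden"):
                bn = getattr(self, name)
                state[f"{name}.running_mean"] = bn.running_mean.copy()
                state[f"{name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, value in state.items():
            if name.endswith(("running_mean", "running_var")):
                obj, attr = name.split(".")
                setattr(getattr(self, obj), attr, value.astype(np.float32).copy())
            else:
                self.set_parameter(name, value.copy())

    # -- forward / backward ---------------------------------------------------

    def _im2col(self, x):
        """(M, L, 4) → (M, L, k*4) sliding windows with same padding."""
        k = self.config.filter_length
        xp = np.pad(x, ((0, 0), (self._pad, self._pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # win: (M, L, 4, k) → (M, L, k, 4) → flatten
        win = win.transpose(0, 1, 3, 2)
        return win.reshape(x.shape[0], x.shape[1], k * 4)

    def _forward(self, x, training: bool):
        """x: (N, 2, L, 4) float32 → (out (N, T), cache)."""
        c = self.config
        n, _, length, _ = x.shape
        if x.shape[1] != 2 or length != c.branch_length or x.shape[3] != 4:
            raise ValueError(f"expected input shape (N, 2, {c.branch_length}, 4), got {x.shape}")
        xs = x.reshape(2 * n, length, 4)
        windows = self._im2col(xs)
        z1 = windows @ self.conv_w + self.conv_b
        r1 = _relu(z1)
        if c.batchnorm:
            y1, bn1_cache = self.bn_conv.forward(r1, training)
        else:
            y1, bn1_cache = r1, None
        y1b = y1.reshape(n, 2, length, c.n_filters)
        w_acc = self.basis @ self.theta_acc.T  # (L, F)
        w_don = self.basis @ self.theta_don.T
        a_acc = y1b[:, 0] * w_acc
        a_don = y1b[:, 1] * w_don
        if c.batchnorm:
            ya, bna_cache = self.bn_acc.forward(a_acc, training)
            yd, bnd_cache = self.bn_don.forward(a_don, training)
        else:
            ya, yd, bna_cache, bnd_cache = a_acc, a_don, None, None
        concat = np.concatenate([ya, yd], axis=1)  # (N, 2L, F)
        pool = concat.mean(axis=1)
        z2 = pool @ self.w1 + self.b1
        r2 = _relu(z2)
        if c.batchnorm:
            y3, bnh_cache = self.bn_hidden.forward(r2, training)
        else:
            y3, bnh_cache = r2, None
        out = y3 @ self.w2 + self.b2
        cache = {
            "x": x,
            "windows": windows,
            "z1": z1,
            "y1b": y1b,
            "w_acc": w_acc,
            "w_don": w_don,
            "pool": pool,
            "z2": z2,
            "y3": y3,
            "bn1": bn1_cache,
            "bna": bna_cache,
            "bnd": bnd_cache,
            "bnh": bnh_cache,
        }
        return out, cache

    def _backward(self, cache, dout, need_dx: bool = False, need_dparams: bool = True):
        """Backpropagate dout (N, T); returns (grads dict, dx or None)."""
        c = self.config
        n = dout.shape[0]
        length, f = c.branch_length, c.n_filters
        grads: dict[str, np.ndarray] = {}
        if need_dparams:
            grads["w2"] = cache["y3"].T @ dout
            grads["b2"] = dout.sum(axis=0)
        dy3 = dout @ self.w2.T
        if c.batchnorm:
            dr2, dg, db = self.bn_hidden.backward(dy3, cache["bnh"])
            if need_dparams and dg is not None:
                grads["bn_hidden.gamma"], grads["bn_hidden.beta"] = dg, db
        else:
            dr2 = dy3
        dz2 = dr2 * (cache["z2"] > 0)
        if need_dparams:
            grads["w1"] = cache["pool"].T @ dz2
            grads["b1"] = dz2.sum(axis=0)
        dpool = dz2 @ self.w1.T
        dconcat = np.broadcast_to(dpool[:, None, :] / (2 * length), (n, 2 * length, f))
        dya, dyd = dconcat[:, :length], dconcat[:, length:]
        if c.batchnorm:
            da_acc, dg, db = self.bn_acc.backward(dya, cache["bna"])
            if need_dparams and dg is not None:
                grads["bn_acc.gamma"], grads["bn_acc.beta"] = dg, db
            da_don, dg, db = self.bn_don.backward(dyd, cache["bnd"])
            if need_dparams and dg is not None:
                grads["bn_don.gamma"], grads["bn_don.beta"] = dg, db
        else:
            da_acc, da_don = dya, dyd
        y1b, w_acc, w_don = cache["y1b"], cache["w_acc"], cache["w_don"]
        if need_dparams:
            dw_acc = (da_acc * y1b[:, 0]).sum(axis=0)  # (L, F)
            dw_don = (da_don * y1b[:, 1]).sum(axis=0)
            grads["theta_acc"] = dw_acc.T @ self.basis
            grads["theta_don"] = dw_don.T @ self.basis
        dy1b = np.stack([da_acc * w_acc, da_don * w_don], axis=1)
        dy1 = dy1b.reshape(2 * n, length, f)
        if c.batchnorm:
            dr1, dg, db = self.bn_conv.backward(dy1, cache["bn1"])
            if need_dparams and dg is not None:
                grads["bn_conv.gamma"], grads["bn_conv.beta"] = dg, db
        else:
            dr1 = dy1
        dz1 = dr1 * (cache["z1"] > 0)
        if need_dparams:
            grads["conv_w"] = np.einsum("mlk,mlf->kf", cache["windows"], dz1)
            grads["conv_b"] = dz1.sum(axis=(0, 1))
        dx = None
        if need_dx:
            k = self.config.filter_length
            w = self.conv_w.reshape(k, 4, f)
            dzp = np.pad(dz1, ((0, 0), (self._pad, self._pad), (0, 0)))
            dwin = np.lib.stride_tricks.sliding_window_view(dzp, k, axis=1)
            # dwin: (2N, L, F, k); dx[m,l,c] = Σ_{k',f} dz1[m, l+k'-pad, f] w[k', c, f]
            # sliding window index j corresponds to dz1 position l + j - pad,
            # matching filter tap k' = j reversed: out[l] = Σ x[l+j-pad]·w[j]
            # ⇒ dx[l] = Σ_j dz1[l - (j - pad)]·w[j] = Σ_j dwin[l, pad*2-j]... use flip
            dx_flat = np.einsum("mlfj,jcf->mlc", dwin, w[::-1])
            dx = dx_flat.reshape(n, 2, length, 4)
        return grads, dx

    # -- inference ------------------------------------------------------------

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Batched inference: x (N, 2, 400, 4) → Δ_tissue logit (N, T)."""
        out, _ = self._forward(np.asarray(x, dtype=np.float32), training=False)
        return out

    def forward(self, encoded: EncodedExon) -> np.ndarray:
        """Single-exon inference → length-T vector of Δ_tissue logit(Ψ)."""
        return self.predict(encoded.stacked()[None])[0]

    def input_gradient(self, encoded: EncodedExon, target="mean") -> np.ndarray:
        """Gradient of one output (or the tissue mean) w.r.t. the input.

        Returns a (2, 400, 4) array (acceptor branch first). Inference-mode
        batch normalization (running statistics) is used, so the gradient is
        deterministic.
        """
        x = encoded.stacked()[None].astype(np.float32)
        out, cache = self._forward(x, training=False)
        dout = np.zeros_like(out)
        if target == "mean":
            dout[0, :] = 1.0 / out.shape[1]
        else:
            dout[0, int(target)] = 1.0
        _, dx = self._backward(cache, dout, need_dx=True, need_dparams=False)
        return dx[0]

    # -- serialization --------------------------------------------------------

    def save(self, path):
        """Write a single-file archive: config JSON + parameter arrays."""
        state = self.state_dict()
        buf = io.BytesIO()
        np.savez(buf, **state)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(asdict(self.config)))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "TSpliceNet":
        with zipfile.ZipFile(path) as zf:
            config = TSpliceConfig(**json.loads(zf.read("config.json")))
            with np.load(io.BytesIO(zf.read("params.npz"))) as npz:
                state = {k: npz[k] for k in npz.files}
        net = cls(config)
        net.load_state_dict(state)
        return net


def build_network(config: TSpliceConfig) -> TSpliceNet:
    """Instantiate a TSpliceNet from a config (seeded, reproducible)."""
    return TSpliceNet(config)


def count_trainable_parameters(net: TSpliceNet) -> int:
    """Total size of all trainable tensors (batch-norm scale/shift included,
    running statistics excluded)."""
    return int(sum(v.size for v in net.trainable_parameters().values()))


def predict_tissue_psi(net, encoded: EncodedExon, psi_bar: float) -> np.ndarray:
    """Ψ̂_e,t = σ(TSplice(S_e)_t + logit(Ψ̄_e)) for every tissue.

    ``net`` may be a single network or an ensemble (anything with a
    ``forward(encoded)`` method returning the Δ_tissue logit vector).
    """
    if not 0.0 <= psi_bar <= 1.0:
        raise ValueError(f"psi_bar must be in [0, 1], got {psi_bar}")
    delta = net.forward(encoded)
    return sigmoid(delta + logit(clip_psi(psi_bar)))
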