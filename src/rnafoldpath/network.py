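"""Dual-head policy/value convolutional network, implemented in numpy.

The network shares a trunk of three 3x3 convolutions (ReLU after each,
"same" padding so the L x L spatial extent is preserved) and splits into
two heads:

* value head — 1x1 conv, ReLU, global average pooling, dense to a scalar,
  softplus (the output is a predicted error from the native state and must
  be strictly positive);
* policy head — 1x1 conv, ReLU, 1x1 conv to one channel, flatten to L^2
  logits, softmax.  The head is fully convolutional so one parameter set
  serves any sequence length.

Losses: squared error on the value head, cross-entropy between the
search-corrected target distribution and the predicted policy.  Optimizer:
Adam with learning rate 0.001.

Forward, backward and Adam are written out explicitly on numpy arrays; the
trunk is small enough (tens of thousands of parameters) that this trains a
toy RNA in minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .action_space import ActionSpace


@dataclass
class NetworkSpec:
    """Architecture/optimizer hyperparameters."""

    channels: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 3
    policy_head_channels: int = 2
    value_head_channels: int = 4
    lr: float = 0.001
    in_channels: int = 18


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


def _conv_same(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 (or kxk) correlation with same padding; x: (B,C,H,Wd), W: (O,C,k,k)."""
    k = W.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return np.einsum("bchwij,ocij->bohw", win, W, optimize=True) + b[None, :, None, None]


def _conv_same_backward(x, W, dy):
    k = W.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    dW = np.einsum("bohw,bchwij->ocij", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
    dwin = np.lib.stride_tricks.sliding_window_view(dyp, (k, k), axis=(2, 3))
    Wf = W[:, :, ::-1, ::-1]
    dx = np.einsum("bohwij,ocij->bchw", dwin, Wf, optimize=True)
    return dx, dW, db


def _conv1x1(x, W, b):
    return np.einsum("oc,bchw->bohw", W, x, optimize=True) + b[None, :, None, None]


def _conv1x1_backward(x, W, dy):
    dW = np.einsum("bohw,bchw->oc", dy, x, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.einsum("oc,bohw->bchw", W, dy, optimize=True)
    return dx, dW, db


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class PolicyValueNet:
    """Shared-trunk policy/value network with explicit numpy training."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0) -> None:
        self.spec = spec or NetworkSpec()
        rng = np.random.default_rng(seed)
        c0 = self.spec.in_channels
        c1, c2, c3 = self.spec.channels
        k = self.spec.kernel
        ph = self.spec.policy_head_channels
        vh = self.spec.value_head_channels
        self.params: dict[str, np.ndarray] = {
            "conv1_W": _he(rng, (c1, c0, k, k), c0 * k * k),
            "conv1_b": np.zeros(c1),
            "conv2_W": _he(rng, (c2, c1, k, k), c1 * k * k),
            "conv2_b": np.zeros(c2),
            "conv3_W": _he(rng, (c3, c2, k, k), c2 * k * k),
            "conv3_b": np.zeros(c3),
            "pol1_W": _he(rng, (ph, c3), c3),
            "pol1_b": np.zeros(ph),
            "pol2_W": _he(rng, (1, ph), ph),
            "pol2_b": np.zeros(1),
            "val1_W": _he(rng, (vh, c3), c3),
            "val1_b": np.zeros(vh),
            "val2_W": _he(rng, (1, vh), vh),
            "val2_b": np.zeros(1),
        }
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray, cache: dict | None = None):
        p = self.params
        h1 = _conv_same(x, p["conv1_W"], p["conv1_b"])
        a1 = np.maximum(h1, 0.0)
        h2 = _conv_same(a1, p["conv2_W"], p["conv2_b"])
        a2 = np.maximum(h2, 0.0)
        h3 = _conv_same(a2, p["conv3_W"], p["conv3_b"])
        a3 = np.maximum(h3, 0.0)
        # policy head
        ph1 = _conv1x1(a3, p["pol1_W"], p["pol1_b"])
        pa1 = np.maximum(ph1, 0.0)
        logits = _conv1x1(pa1, p["pol2_W"], p["pol2_b"])  # (B,1,L,L)
        B, _, L, _ = logits.shape
        logits_flat = logits.reshape(B, L * L)
        # value head
        vh1 = _conv1x1(a3, p["val1_W"], p["val1_b"])
        va1 = np.maximum(vh1, 0.0)
        gap = va1.mean(axis=(2, 3))  # (B, vh)
        vpre = gap @ p["val2_W"].T + p["val2_b"]  # (B,1)
        value = _softplus(vpre)[:, 0]
        if cache is not None:
            cache.update(
                x=x, h1=h1, a1=a1, h2=h2, a2=a2, h3=h3, a3=a3,
                ph1=ph1, pa1=pa1, vh1=vh1, va1=va1, gap=gap, vpre=vpre,
            )
        return logits_flat, value

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Batched forward pass.

        Parameters
        ----------
        x : array of shape (B, 18, L, L) or (18, L, L)

        Returns
        -------
        policy : softmax probabilities over the L^2 flattened (i, j) cells
        value : strictly positive scalar per sample
        """
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        logits, value = self._forward(np.asarray(x, dtype=np.float64))
        policy = _softmax(logits)
        if single:
            return policy[0], float(value[0])
        return policy, value

    # -- losses and training -----------------------------------------------

    def loss(
        self,
        x: np.ndarray,
        target_policy: np.ndarray,
        target_value: np.ndarray,
    ) -> tuple[float, float, float]:
        """(value_loss, policy_loss, total) without updating parameters."""
        logits, value = self._forward(np.asarray(x, dtype=np.float64))
        return self._losses(logits, value, target_policy, target_value)

    @staticmethod
    def _losses(logits, value, target_policy, target_value):
        if np.isnan(logits).any() or np.isnan(value).any():
            raise FloatingPointError("NaN in network outputs")
        prob = _softmax(logits)
        eps = 1e-12
        policy_loss = float(-np.sum(target_policy * np.log(prob + eps), axis=1).mean())
        value_loss = float(np.mean((value - target_value) ** 2))
        return value_loss, policy_loss, value_loss + policy_loss

    def train_step(
        self,
        x: np.ndarray,
        target_policy: np.ndarray,
        target_value: np.ndarray,
    ) -> tuple[float, float, float]:
        """One Adam update on a batch; returns (value_loss, policy_loss, total)."""
        x = np.asarray(x, dtype=np.float64)
        target_policy = np.asarray(target_policy, dtype=np.float64)
        target_value = np.asarray(target_value, dtype=np.float64)
        if np.isnan(x).any() or np.isnan(target_policy).any() or np.isnan(target_value).any():
            raise FloatingPointError("NaN in training inputs")
        cache: dict = {}
        logits, value = self._forward(x, cache)
        losses = self._losses(logits, value, target_policy, target_value)
        grads = self._backward(cache, logits, value, target_policy, target_value)
        self._adam(grads)
        return losses

    def _backward(self, c, logits, value, target_policy, target_value):
        p = self.params
        B = logits.shape[0]
        L = c["x"].shape[-1]
        g: dict[str, np.ndarray] = {}
        # policy head
        prob = _softmax(logits)
        dlogits = (prob - target_policy) / B  # (B, L*L)
        dlogits = dlogits.reshape(B, 1, L, L)
        dpa1, g["pol2_W"], g["pol2_b"] = _conv1x1_backward(c["pa1"], p["pol2_W"], dlogits)
        dph1 = dpa1 * (c["ph1"] > 0)
        da3_pol, g["pol1_W"], g["pol1_b"] = _conv1x1_backward(c["a3"], p["pol1_W"], dph1)
        # value head
        dvalue = 2.0 * (value - target_value) / B  # (B,)
        dvpre = (dvalue * _sigmoid(c["vpre"][:, 0]))[:, None]  # (B,1)
        g["val2_W"] = dvpre.T @ c["gap"]
        g["val2_b"] = dvpre.sum(axis=0)
        dgap = dvpre @ p["val2_W"]  # (B, vh)
        dva1 = dgap[:, :, None, None] * np.ones((1, 1, L, L)) / (L * L)
        dvh1 = dva1 * (c["vh1"] > 0)
        da3_val, g["val1_W"], g["val1_b"] = _conv1x1_backward(c["a3"], p["val1_W"], dvh1)
        # trunk
        da3 = da3_pol + da3_val
        dh3 = da3 * (c["h3"] > 0)
        da2, g["conv3_W"], g["conv3_b"] = _conv_same_backward(c["a2"], p["conv3_W"], dh3)
        dh2 = da2 * (c["h2"] > 0)
        da1, g["conv2_W"], g["conv2_b"] = _conv_same_backward(c["a1"], p["conv2_W"], dh2)
        dh1 = da1 * (c["h1"] > 0)
        _, g["conv1_W"], g["conv1_b"] = _conv_same_backward(c["x"], p["conv1_W"], dh1)
        return g

    def _adam(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        lr = self.spec.lr
        for k, gk in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- checkpointing -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize parameters, optimizer state and spec to one .npz file."""
        path = Path(path)
        state = dict(self.params)
        state.update({f"m__{k}": v for k, v in self._adam_m.items()})
        state.update({f"v__{k}": v for k, v in self._adam_v.items()})
        state["adam_t"] = np.array(self._adam_t)
        state["spec_json"] = np.array(json.dumps(asdict(self.spec)))
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path) -> "PolicyValueNet":
        data = np.load(Path(path), allow_pickle=False)
        spec_dict = json.loads(str(data["spec_json"]))
        spec_dict["channels"] = tuple(spec_dict["channels"])
        net = cls(NetworkSpec(**spec_dict))
        for k in net.params:
            net.params[k] = data[k]
            net._adam_m[k] = data[f"m__{k}"]
            net._adam_v[k] = data[f"v__{k}"]
        net._adam_t = int(data["adam_t"])
        return net


def mask_and_normalize(policy: np.ndarray, space: ActionSpace, L: int) -> np.ndarray:
    """Restrict a flat L^2 policy to the legal action space and renormalize.

    Entries outside the action space are zeroed; the legal entries are
    rescaled to sum to one.  If every legal entry is zero the distribution
    falls back to uniform over the legal actions.
    """
    if len(space) == 0:
        raise ValueError("cannot normalize a policy over an empty action space")
    policy = np.asarray(policy, dtype=np.float64)
    if policy.shape != (L * L,):
        raise ValueError(f"policy length {policy.size} != L^2 = {L * L}")
    mask = np.zeros(L * L)
    for i, j in space.legal:
        mask[(i - 1) * L + (j - 1)] = 1.0
    out = policy * mask
    total = out.sum()
    if total <= 0:
        out = mask / mask.sum()
    else:
        out = out / total
    return out


def policy_prior(policy: np.ndarray, space: ActionSpace, L: int) -> dict[tuple[int, int], float]:
    """Per-pair prior probabilities from a flat policy vector."""
    flat = mask_and_normalize(policy, space, L)
    return {(i, j): float(flat[(i - 1) * L + (j - 1)]) for i, j in space.legal}
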