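"""Neural building blocks on top of the autodiff core.

Layers: Linear, LayerNorm, Dropout, multi-head self-attention with a key
padding mask, post-norm transformer encoder layers, and a 3D convolution.
Optimization: Adam with cosine-annealed learning rate and L2 weight decay
(normalization and bias parameters excluded from decay).
"""

from __future__ import annotations

import math

import numpy as np

from ._autodiff import Tensor, concat, relu, softmax_lastdim

__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "MultiHeadSelfAttention",
    "TransformerEncoderLayer", "conv3d", "Adam", "cosine_lr",
]


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = False

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def train(self) -> None:
        self.training = True
        for c in self._children.values():
            c.train()

    def eval(self) -> None:
        self.training = False
        for c in self._children.values():
            c.eval()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = 1.0 / math.sqrt(in_dim)
        self.W = self.add_param("W", rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.b = self.add_param("bias", np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Self-attention over (B, T, C) with an additive key padding mask.

    Padded key positions receive a large negative logit so their softmax
    weight underflows to exactly zero, guaranteeing padded tokens cannot
    influence any output position.
    """

    MASK_FILL = -1e30

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % num_heads != 0:
            raise ValueError(f"dim {dim} not divisible by num_heads {num_heads}")
        self.dim = dim
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.wq = self.add_module("wq", Linear(dim, dim, rng))
        self.wk = self.add_module("wk", Linear(dim, dim, rng))
        self.wv = self.add_module("wv", Linear(dim, dim, rng))
        self.wo = self.add_module("wo", Linear(dim, dim, rng))

    def __call__(self, x: Tensor, key_padding_mask: np.ndarray) -> Tensor:
        # key_padding_mask: (B, T) bool, True = valid token
        B, T, C = x.shape
        H, hd = self.num_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, hd).transpose(0, 2, 1, 3)  # (B,H,T,hd)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        bias = np.where(key_padding_mask[:, None, None, :], 0.0, self.MASK_FILL)
        attn = softmax_lastdim(scores + Tensor(bias))
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, C)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: attention -> add&norm -> MLP -> add&norm."""

    def __init__(self, dim: int, num_heads: int, mlp_ratio: float,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        hidden = int(round(dim * mlp_ratio))
        self.attn = self.add_module("attn", MultiHeadSelfAttention(dim, num_heads, rng))
        self.ln1 = self.add_module("ln1", LayerNorm(dim))
        self.fc1 = self.add_module("fc1", Linear(dim, hidden, rng))
        self.fc2 = self.add_module("fc2", Linear(hidden, dim, rng))
        self.ln2 = self.add_module("ln2", LayerNorm(dim))
        self.drop1 = self.add_module("drop1", Dropout(dropout, rng))
        self.drop2 = self.add_module("drop2", Dropout(dropout, rng))

    def __call__(self, x: Tensor, key_padding_mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.drop1(self.attn(x, key_padding_mask)))
        x = self.ln2(x + self.drop2(self.fc2(relu(self.fc1(x)))))
        return x


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """3D convolution: x (B,Cin,D,H,W), w (Cout,Cin,k,k,k) -> (B,Cout,D',H',W')."""
    B, Cin, D, H, W = x.shape
    Cout, Cin_w, k, _, _ = w.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    view = view[:, :, ::s, ::s, ::s]                    # (B,Cin,Do,Ho,Wo,k,k,k)
    Do, Ho, Wo = view.shape[2:5]
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    cols2 = cols.reshape(B * Do * Ho * Wo, Cin * k ** 3)
    wmat = w.data.reshape(Cout, Cin * k ** 3)
    out_data = cols2 @ wmat.T
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.reshape(B, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(B * Do * Ho * Wo, Cout)
        if w.requires_grad:
            w._accum((gmat.T @ cols2).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(B, Do, Ho, Wo, Cin, k, k, k)
            gxp = np.zeros((B, Cin, D + 2 * p, H + 2 * p, W + 2 * p))
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gxp[:, :, i:i + s * Do:s, j:j + s * Ho:s, l:l + s * Wo:s] += \
                            gcols[..., i, j, l].transpose(0, 4, 1, 2, 3)
            gx = gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp
            x._accum(gx)

    return Tensor._make(out_data, parents, backward)


def cosine_lr(step: int, total_steps: int, lr_init: float, lr_final: float) -> float:
    """Cosine annealing from lr_init at step 0 to lr_final at the last step."""
    if total_steps <= 1:
        return lr_init
    t = step / (total_steps - 1)
    return lr_final + 0.5 * (lr_init - lr_final) * (1.0 + math.cos(math.pi * t))


_NO_DECAY_TOKENS = ("gamma", "beta", "bias", "cls")


class Adam:
    """Adam with L2 weight decay added to the gradient.

    Normalization parameters, biases and the CLS token are excluded from
    decay, matching common practice for transformer training.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0
        self._decayed = {
            k: weight_decay > 0 and not any(tok in k.lower() for tok in _NO_DECAY_TOKENS)
            for k in params
        }

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self._decayed[k]:
                g = g + self.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p.data -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
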