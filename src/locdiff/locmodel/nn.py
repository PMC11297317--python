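"""A small transformer encoder with manual backpropagation in NumPy.

Forward/backward are written for batched, padding-masked token sets
(B bags, up to T tokens of dimension D).  Architecture per layer, pre-norm:

    x = x + MHSA(LN(x));  x = x + FFN(LN(x))

followed by a final LayerNorm, masked mean pooling over tokens and a linear
head to 7 logits.  The attention inner dimension splits the model dimension
across heads (head_dim = D // heads).  Gradients are exact; the test suite
checks them against central finite differences.
"""

from __future__ import annotations

import numpy as np

_LN_EPS = 1e-5


def init_params(rng: np.random.Generator, dim: int, depth: int, heads: int,
                ff_dim: int, n_out: int, dtype=np.float32) -> dict[str, np.ndarray]:
    head_dim = dim // heads
    if head_dim < 1:
        raise ValueError(f"feature dim {dim} too small for {heads} heads")
    inner = head_dim * heads
    p: dict[str, np.ndarray] = {}

    def lin(name, fan_in, fan_out):
        p[f"{name}_w"] = (rng.normal(0, np.sqrt(1.0 / fan_in), (fan_in, fan_out))
                          .astype(dtype))
        p[f"{name}_b"] = np.zeros(fan_out, dtype=dtype)

    for l in range(depth):
        p[f"l{l}_ln1_g"] = np.ones(dim, dtype=dtype)
        p[f"l{l}_ln1_b"] = np.zeros(dim, dtype=dtype)
        lin(f"l{l}_q", dim, inner)
        lin(f"l{l}_k", dim, inner)
        lin(f"l{l}_v", dim, inner)
        lin(f"l{l}_o", inner, dim)
        p[f"l{l}_ln2_g"] = np.ones(dim, dtype=dtype)
        p[f"l{l}_ln2_b"] = np.zeros(dim, dtype=dtype)
        lin(f"l{l}_ff1", dim, ff_dim)
        lin(f"l{l}_ff2", ff_dim, dim)
    p["lnf_g"] = np.ones(dim, dtype=dtype)
    p["lnf_b"] = np.zeros(dim, dtype=dtype)
    lin("head", dim, n_out)
    return p


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def forward(params: dict, x: np.ndarray, mask: np.ndarray, depth: int, heads: int):
    """x: (B,T,D) tokens, mask: (B,T) 1/0.  Returns (logits, cache)."""
    B, T, D = x.shape
    head_dim = D // heads
    inner = head_dim * heads
    scale = 1.0 / np.sqrt(head_dim)
    neg = np.asarray(-1e9, dtype=x.dtype)
    key_bias = (1.0 - mask)[:, None, None, :] * neg  # (B,1,1,T)

    cache: dict = {"layers": []}
    for l in range(depth):
        c: dict = {}
        h, c["ln1"] = _layernorm_fwd(x, params[f"l{l}_ln1_g"], params[f"l{l}_ln1_b"])
        c["h"] = h
        q = h @ params[f"l{l}_q_w"] + params[f"l{l}_q_b"]
        k = h @ params[f"l{l}_k_w"] + params[f"l{l}_k_b"]
        v = h @ params[f"l{l}_v_w"] + params[f"l{l}_v_b"]

        def split(z):
            return z.reshape(B, T, heads, head_dim).transpose(0, 2, 1, 3)

        qh, kh, vh = split(q), split(k), split(v)
        scores = np.einsum("bhtd,bhsd->bhts", qh, kh) * scale + key_bias
        scores -= scores.max(-1, keepdims=True)
        e = np.exp(scores)
        att = e / e.sum(-1, keepdims=True)  # (B,H,T,T)
        ctx = np.einsum("bhts,bhsd->bhtd", att, vh)
        ctx_m = ctx.transpose(0, 2, 1, 3).reshape(B, T, inner)
        attn_out = ctx_m @ params[f"l{l}_o_w"] + params[f"l{l}_o_b"]
        c.update(qh=qh, kh=kh, vh=vh, att=att, ctx_m=ctx_m)
        x = x + attn_out

        h2, c["ln2"] = _layernorm_fwd(x, params[f"l{l}_ln2_g"], params[f"l{l}_ln2_b"])
        c["h2"] = h2
        z1 = h2 @ params[f"l{l}_ff1_w"] + params[f"l{l}_ff1_b"]
        a1 = np.maximum(z1, 0.0)
        c["a1"] = a1
        ff_out = a1 @ params[f"l{l}_ff2_w"] + params[f"l{l}_ff2_b"]
        x = x + ff_out
        cache["layers"].append(c)

    hf, lnf_cache = _layernorm_fwd(x, params["lnf_g"], params["lnf_b"])
    denom = mask.sum(-1, keepdims=True)
    pooled = (hf * mask[..., None]).sum(1) / denom  # (B,D)
    logits = pooled @ params["head_w"] + params["head_b"]
    cache.update(lnf=lnf_cache, mask=mask, denom=denom, pooled=pooled,
                 heads=heads, head_dim=head_dim, depth=depth, shape=(B, T, D))
    return logits, cache


def backward(params: dict, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
    """Gradients of all parameters given d(loss)/d(logits)."""
    B, T, D = cache["shape"]
    heads, head_dim, depth = cache["heads"], cache["head_dim"], cache["depth"]
    inner = heads * head_dim
    scale = 1.0 / np.sqrt(head_dim)
    mask, denom = cache["mask"], cache["denom"]

    grads: dict[str, np.ndarray] = {}
    grads["head_w"] = cache["pooled"].T @ dlogits
    grads["head_b"] = dlogits.sum(0)
    dpooled = dlogits @ params["head_w"].T  # (B,D)
    dhf = (dpooled[:, None, :] / denom[..., None]) * mask[..., None]
    dx, grads["lnf_g"], grads["lnf_b"] = _layernorm_bwd(dhf, cache["lnf"])

    for l in reversed(range(depth)):
        c = cache["layers"][l]
        # FFN branch
        dff_out = dx
        grads[f"l{l}_ff2_w"] = c["a1"].reshape(-1, c["a1"].shape[-1]).T @ \
            dff_out.reshape(-1, D)
        grads[f"l{l}_ff2_b"] = dff_out.sum((0, 1))
        da1 = dff_out @ params[f"l{l}_ff2_w"].T
        dz1 = da1 * (c["a1"] > 0)
        grads[f"l{l}_ff1_w"] = c["h2"].reshape(-1, D).T @ dz1.reshape(-1, dz1.shape[-1])
        grads[f"l{l}_ff1_b"] = dz1.sum((0, 1))
        dh2 = dz1 @ params[f"l{l}_ff1_w"].T
        dx_ln2, grads[f"l{l}_ln2_g"], grads[f"l{l}_ln2_b"] = _layernorm_bwd(dh2, c["ln2"])
        dx = dx + dx_ln2

        # attention branch
        dattn_out = dx
        grads[f"l{l}_o_w"] = c["ctx_m"].reshape(-1, inner).T @ dattn_out.reshape(-1, D)
        grads[f"l{l}_o_b"] = dattn_out.sum((0, 1))
        dctx_m = dattn_out @ params[f"l{l}_o_w"].T
        dctx = dctx_m.reshape(B, T, heads, head_dim).transpose(0, 2, 1, 3)
        att, qh, kh, vh = c["att"], c["qh"], c["kh"], c["vh"]
        datt = np.einsum("bhtd,bhsd->bhts", dctx, vh)
        dvh = np.einsum("bhts,bhtd->bhsd", att, dctx)
        dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
        dqh = np.einsum("bhts,bhsd->bhtd", dscores, kh) * scale
        dkh = np.einsum("bhts,bhtd->bhsd", dscores, qh) * scale

        def merge(z):
            return z.transpose(0, 2, 1, 3).reshape(B, T, inner)

        dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
        h = c["h"]
        h_flat = h.reshape(-1, D)
        dh = np.zeros_like(h)
        for name, dz in (("q", dq), ("k", dk), ("v", dv)):
            grads[f"l{l}_{name}_w"] = h_flat.T @ dz.reshape(-1, inner)
            grads[f"l{l}_{name}_b"] = dz.sum((0, 1))
            dh += dz @ params[f"l{l}_{name}_w"].T
        dx_ln1, grads[f"l{l}_ln1_g"], grads[f"l{l}_ln1_b"] = _layernorm_bwd(dh, c["ln1"])
        dx = dx + dx_ln1
    return grads


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean per-label binary cross-entropy; returns (loss, dlogits)."""
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dlogits = (p - y) / y.size
    return float(loss), dlogits.astype(logits.dtype)


class Adam:
    def __init__(self, params: dict, lr: float = 2e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
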