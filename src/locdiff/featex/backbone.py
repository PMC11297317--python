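"""A seeded random-weight residual CNN in NumPy.

Convolutions run as im2col + GEMM in float32.  There is no trained batch
normalization; instead every block output is RMS-normalized over channels,
which keeps activation magnitudes stable through the residual stack while
remaining deterministic and batch-independent.
"""

from __future__ import annotations

import numpy as np

from locdiff._rng import substream

STAGE_DIMS = {1: 64, 2: 128, 3: 256, 4: 512}


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(C,H,W) -> (out_h*out_w, C*kh*kw) patch matrix."""
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    h_p, w_p = x.shape[1], x.shape[2]
    out_h = (h_p - kh) // stride + 1
    out_w = (w_p - kw) // stride + 1
    s0, s1, s2 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x,
        shape=(c, out_h, out_w, kh, kw),
        strides=(s0, s1 * stride, s2 * stride, s1, s2),
        writeable=False,
    )
    cols = patches.transpose(1, 2, 0, 3, 4).reshape(out_h * out_w, c * kh * kw)
    return np.ascontiguousarray(cols), out_h, out_w


def _conv(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 1) -> np.ndarray:
    """w has shape (out_c, in_c, kh, kw)."""
    out_c, in_c, kh, kw = w.shape
    cols, out_h, out_w = _im2col(x, kh, kw, stride, pad)
    out = cols @ w.reshape(out_c, -1).T
    return out.T.reshape(out_c, out_h, out_w)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    c, _, _ = x.shape
    cols, out_h, out_w = _im2col(x, k, k, stride, pad)
    cols = cols.reshape(out_h * out_w, c, k * k)
    return cols.max(axis=2).T.reshape(c, out_h, out_w)


def _rms_norm(x: np.ndarray) -> np.ndarray:
    """Normalize each spatial position to unit RMS over channels."""
    rms = np.sqrt(np.mean(np.square(x), axis=0, keepdims=True) + 1e-6)
    return x / rms


def _he(rng, out_c, in_c, kh, kw):
    fan_in = in_c * kh * kw
    return rng.normal(0.0, np.sqrt(2.0 / fan_in),
                      size=(out_c, in_c, kh, kw)).astype(np.float32)


class ResidualBackbone:
    """Four stages of two basic residual blocks (64/128/256/512 channels)."""

    def __init__(self, weights: str = "random", seed: int = 0):
        if weights != "random":
            raise ValueError(
                f"unsupported weights {weights!r}: only seeded 'random' weights "
                "are available (no bundled pretrained checkpoint)"
            )
        self.weights = weights
        self.seed = int(seed)
        rng = substream(seed, "featex", "weights")
        self.stem = _he(rng, 64, 3, 7, 7)
        self.blocks: list[list[dict]] = []
        in_c = 64
        for stage, out_c in enumerate([64, 128, 256, 512], start=1):
            stage_blocks = []
            for b in range(2):
                downsample = stage > 1 and b == 0
                block = {
                    "conv1": _he(rng, out_c, in_c if b == 0 else out_c, 3, 3),
                    "conv2": _he(rng, out_c, out_c, 3, 3),
                    "stride": 2 if downsample else 1,
                    "proj": _he(rng, out_c, in_c, 1, 1) if (b == 0 and in_c != out_c) else None,
                }
                stage_blocks.append(block)
            self.blocks.append(stage_blocks)
            in_c = out_c

    def _block(self, x: np.ndarray, block: dict) -> np.ndarray:
        h = np.maximum(_conv(x, block["conv1"], stride=block["stride"], pad=1), 0.0)
        h = _conv(h, block["conv2"], stride=1, pad=1)
        if block["proj"] is not None or block["stride"] != 1:
            w = block["proj"]
            shortcut = _conv(x, w, stride=block["stride"], pad=0) if w is not None \
                else x[:, ::block["stride"], ::block["stride"]]
        else:
            shortcut = x
        return _rms_norm(np.maximum(h + shortcut, 0.0))

    def forward(self, img: np.ndarray, stage: int = 2) -> np.ndarray:
        """img: float32 (3,H,W), standardized.  Returns GAP vector of the stage."""
        if stage not in STAGE_DIMS:
            raise ValueError(f"stage must be in 1..4, got {stage}")
        if img.ndim != 3 or img.shape[0] != 3:
            raise ValueError("expected a (3,H,W) image tensor")
        if img.shape[1] < 8 or img.shape[2] < 8:
            raise ValueError("image too small for the backbone")
        x = _rms_norm(np.maximum(_conv(img, self.stem, stride=2, pad=3), 0.0))
        x = _maxpool(x)
        for s in range(stage):
            for block in self.blocks[s]:
                x = self._block(x, block)
        vec = x.mean(axis=(1, 2)).astype(np.float32)
        if not np.all(np.isfinite(vec)):
            raise FloatingPointError("non-finite feature vector")
        return vec
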