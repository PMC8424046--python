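"""Numba kernels for the convolution stages.

Fused direct 3x3 same-padding convolutions avoid the im2col buffers whose
memory traffic dominates GEMM-lowered convolutions on a single CPU.  All
arrays are float32, channels-last.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["conv3x3_relu_fwd", "conv3x3_bwd"]


@njit(fastmath=True, cache=True)
def conv3x3_relu_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray, out: np.ndarray) -> None:
    """out = relu(conv3x3(x, w) + b), zero-padded, stride 1."""
    B, H, W, Cin = x.shape
    Cout = w.shape[3]
    for bi in range(B):
        for h in range(H):
            for wd in range(W):
                acc = b.copy()
                for i in range(3):
                    hh = h + i - 1
                    if hh < 0 or hh >= H:
                        continue
                    for j in range(3):
                        ww = wd + j - 1
                        if ww < 0 or ww >= W:
                            continue
                        for c in range(Cin):
                            v = x[bi, hh, ww, c]
                            for co in range(Cout):
                                acc[co] += v * w[i, j, c, co]
                for co in range(Cout):
                    out[bi, h, wd, co] = acc[co] if acc[co] > 0.0 else 0.0


@njit(fastmath=True, cache=True)
def conv3x3_bwd(
    x: np.ndarray,
    dout: np.ndarray,
    w: np.ndarray,
    dx: np.ndarray,
    dw: np.ndarray,
    db: np.ndarray,
) -> None:
    """Accumulate dx, dw, db for the conv (dout already gated by the relu)."""
    B, H, W, Cin = x.shape
    Cout = w.shape[3]
    for bi in range(B):
        for h in range(H):
            for wd in range(W):
                for i in range(3):
                    hh = h + i - 1
                    if hh < 0 or hh >= H:
                        continue
                    for j in range(3):
                        ww = wd + j - 1
                        if ww < 0 or ww >= W:
                            continue
                        for c in range(Cin):
                            xv = x[bi, hh, ww, c]
                            acc = np.float32(0.0)
                            for co in range(Cout):
                                g = dout[bi, h, wd, co]
                                dw[i, j, c, co] += xv * g
                                acc += g * w[i, j, c, co]
                            dx[bi, hh, ww, c] += acc
                for co in range(Cout):
                    db[co] += dout[bi, h, wd, co]
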