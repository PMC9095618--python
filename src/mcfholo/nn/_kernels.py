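"""Patch-extraction kernels behind the convolution ops.

``im2col`` gathers k x k patches (with implicit zero padding) into a
row-major patch matrix so convolution becomes one GEMM; ``col2im`` is its
exact adjoint (scatter-add).  Compiled with numba when available — the
numpy fallbacks compute identical values, only slower.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit, prange

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco

    prange = range


@njit(parallel=True, cache=True)
def _im2col_jit(x, k, stride, pad, ho, wo, cols):
    b, c, h, w = x.shape
    kk = k * k
    for bi in prange(b):
        for i in range(ho):
            for j in range(wo):
                row = (bi * ho + i) * wo + j
                for ci in range(c):
                    base = ci * kk
                    for ki in range(k):
                        yy = i * stride + ki - pad
                        for kj in range(k):
                            xx = j * stride + kj - pad
                            if 0 <= yy < h and 0 <= xx < w:
                                cols[row, base + ki * k + kj] = x[bi, ci, yy, xx]
                            else:
                                cols[row, base + ki * k + kj] = 0.0


@njit(parallel=True, cache=True)
def _col2im_jit(cols, k, stride, pad, ho, wo, out):
    b, c, h, w = out.shape
    kk = k * k
    for bc in prange(b * c):
        bi = bc // c
        ci = bc % c
        base = ci * kk
        for i in range(ho):
            for j in range(wo):
                row = (bi * ho + i) * wo + j
                for ki in range(k):
                    yy = i * stride + ki - pad
                    if yy < 0 or yy >= h:
                        continue
                    for kj in range(k):
                        xx = j * stride + kj - pad
                        if 0 <= xx < w:
                            out[bi, ci, yy, xx] += cols[row, base + ki * k + kj]


_im2col_serial = njit(cache=True)(_im2col_jit.py_func) if HAVE_NUMBA else None
_col2im_serial = njit(cache=True)(_col2im_jit.py_func) if HAVE_NUMBA else None

# below this many patch rows the thread-pool launch costs more than it saves
_PARALLEL_ROWS = 20_000


def im2col(x: np.ndarray, k: int, stride: int, pad: int,
           ho: int, wo: int) -> np.ndarray:
    """(B, C, H, W) -> (B*ho*wo, C*k*k) patch matrix with implicit zero pad."""
    b, c = x.shape[0], x.shape[1]
    cols = np.empty((b * ho * wo, c * k * k), dtype=x.dtype)
    if HAVE_NUMBA:
        fn = _im2col_jit if b * ho * wo >= _PARALLEL_ROWS else _im2col_serial
        fn(x, k, stride, pad, ho, wo, cols)
        return cols
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    np.copyto(cols.reshape(b, ho, wo, c, k, k), win.transpose(0, 2, 3, 1, 4, 5))
    return cols


def col2im(cols: np.ndarray, out_shape, k: int, stride: int, pad: int,
           ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto the grid."""
    out = np.zeros(out_shape, dtype=cols.dtype)
    if HAVE_NUMBA:
        fn = (_col2im_jit if out_shape[0] * out_shape[1] >= 64
              else _col2im_serial)
        fn(cols, k, stride, pad, ho, wo, out)
        return out
    b, c, h, w = out_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    outp = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    g = cols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            outp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                g[..., i, j]
    if pad:
        out += outp[:, :, pad:-pad, pad:-pad]
    else:
        out += outp
    return out
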