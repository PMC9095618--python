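"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Scope: exactly the primitives the phase-encoder network and its embedded
physical forward model need — strided (transposed) convolution, batch
normalization, ReLU, concatenation, FFT-based angular-spectrum propagation,
per-core phase gathering/disk rendering, and the negative-Pearson loss.

Complex tensors use the real-pair gradient convention: for ``z = a + ib``
the stored gradient is ``dL/da + i dL/db`` (L real).  Under that convention
the backward rule of any C-linear operation is its Hermitian adjoint, so
``fft2`` back-propagates through a scaled ``ifft2`` and multiplication by a
constant ``H`` through multiplication by ``conj(H)``.

Gradient checks against central finite differences live in the test suite;
the engine works at any float precision (float32 for training speed,
float64 for the checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (pure inference)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = (requires_grad or any(p.requires_grad for p in parents)) \
            and _GRAD_ENABLED[0]
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data,
                                      dtype=_grad_dtype(self.data.dtype))
        self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.accumulate(np.ones_like(self.data, dtype=_grad_dtype(self.dtype)))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _grad_dtype(dtype):
    return dtype if dtype.kind in "fc" else np.float64


def constant(data) -> Tensor:
    return Tensor(np.asarray(data))


# ---------------------------------------------------------------------------
# real elementwise / structural ops


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    if out_data.shape != a.shape or out_data.shape != b.shape:
        raise ValueError("add requires equal shapes")

    def backward(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0)

    def backward(g):
        x.accumulate(g * (x.data > 0))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t.accumulate(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def scale_shift_channels(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """y = x * gamma[c] + beta[c] for NCHW tensors (the BN affine stage)."""
    gc = gamma.data[None, :, None, None]
    out_data = x.data * gc + beta.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * gc)
        if gamma.requires_grad:
            gamma.accumulate(np.sum(g * x.data, axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(np.sum(g, axis=(0, 2, 3)))

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def add_row(x: Tensor, row: Tensor) -> Tensor:
    """(B, K) + (K,) broadcast add (per-core bias)."""
    out_data = x.data + row.data[None, :]

    def backward(g):
        if x.requires_grad:
            x.accumulate(g)
        if row.requires_grad:
            row.accumulate(g.sum(axis=0))

    return Tensor(out_data, parents=(x, row), backward=backward)


def scaled_const(c: np.ndarray, alpha: Tensor) -> Tensor:
    """alpha * c for a constant array and a learnable scalar."""
    out_data = alpha.data.reshape(()) * c

    def backward(g):
        alpha.accumulate(np.sum(g * c).reshape(alpha.shape))

    return Tensor(out_data, parents=(alpha,), backward=backward)


def batchnorm2d(x: Tensor, eps: float) -> Tensor:
    """Normalize each channel of an NCHW tensor over (N, H, W) batch statistics."""
    data = x.data
    mu = data.mean(axis=(0, 2, 3), keepdims=True)
    var = data.var(axis=(0, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (data - mu) * inv
    m = data.shape[0] * data.shape[2] * data.shape[3]

    def backward(g):
        # standard batch-norm gradient through mean and variance
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        x.accumulate(inv * (g - sum_g / m - xhat * sum_gx / m))

    out = Tensor(xhat, parents=(x,), backward=backward)
    return out


def affine_channels(x: Tensor, a: np.ndarray, b: np.ndarray) -> Tensor:
    """y = x * a[c] + b[c] with constant coefficients (the fused eval-mode
    batch-norm path); gradients flow to x only."""
    a4 = a[None, :, None, None]
    out_data = x.data * a4 + b[None, :, None, None]

    def backward(g):
        x.accumulate(g * a4)

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# convolution


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW x (Cout, Cin, k, k)."""
    from ._kernels import col2im, im2col

    b, cin, h, wdt = x.shape
    cout, cin_w, k, k2 = w.shape
    if cin != cin_w or k != k2:
        raise ValueError("weight shape incompatible with input")
    if k == 1 and padding == 0:
        return _conv1x1(x, w, stride)
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wdt + 2 * padding - k) // stride + 1
    cols = im2col(x.data, k, stride, padding, ho, wo)
    wmat = w.data.reshape(cout, -1)
    out_data = np.ascontiguousarray(
        (cols @ wmat.T).reshape(b, ho, wo, cout).transpose(0, 3, 1, 2))

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if w.requires_grad:
            w.accumulate((gmat.T @ cols).reshape(w.shape))
        if x.requires_grad:
            gcols = gmat @ wmat
            x.accumulate(col2im(gcols, x.shape, k, stride, padding, ho, wo))

    return Tensor(out_data, parents=(x, w), backward=backward)


def _conv1x1(x: Tensor, w: Tensor, stride: int) -> Tensor:
    """Pointwise convolution: a channel matmul on (strided) pixels."""
    b, cin, h, wdt = x.shape
    cout = w.shape[0]
    xs = x.data[:, :, ::stride, ::stride]
    ho, wo = xs.shape[2], xs.shape[3]
    xmat = np.ascontiguousarray(xs.transpose(0, 2, 3, 1)).reshape(-1, cin)
    wmat = w.data.reshape(cout, cin)
    out_data = np.ascontiguousarray(
        (xmat @ wmat.T).reshape(b, ho, wo, cout).transpose(0, 3, 1, 2))

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if w.requires_grad:
            w.accumulate((gmat.T @ xmat).reshape(w.shape))
        if x.requires_grad:
            gx = np.zeros_like(x.data, dtype=gmat.dtype)
            gx[:, :, ::stride, ::stride] = (gmat @ wmat) \
                .reshape(b, ho, wo, cin).transpose(0, 3, 1, 2)
            x.accumulate(gx)

    return Tensor(out_data, parents=(x, w), backward=backward)


def conv_transpose2d(x: Tensor, w: Tensor, stride: int = 2, padding: int = 1,
                     output_padding: int = 1) -> Tensor:
    """Transposed convolution, NCHW x (Cin, Cout, k, k); doubles H, W with the
    default (k=3, stride=2, padding=1, output_padding=1) settings.

    Forward is the exact adjoint of strided patch extraction (col2im of one
    GEMM); backward re-gathers with im2col.
    """
    from ._kernels import col2im, im2col

    b, cin, h, wdt = x.shape
    cin_w, cout, k, _ = w.shape
    if cin != cin_w:
        raise ValueError("weight shape incompatible with input")
    ho = (h - 1) * stride - 2 * padding + k + output_padding
    wo = (wdt - 1) * stride - 2 * padding + k + output_padding
    xmat = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, cin)
    contrib = xmat @ w.data.reshape(cin, -1)          # (B*h*w, cout*k*k)
    out_data = col2im(contrib, (b, cout, ho, wo), k, stride, padding, h, wdt)

    def backward(g):
        gcols = im2col(g, k, stride, padding, h, wdt)  # (B*h*w, cout*k*k)
        if w.requires_grad:
            w.accumulate((xmat.T @ gcols).reshape(cin, cout, k, k))
        if x.requires_grad:
            x.accumulate((gcols @ w.data.reshape(cin, -1).T)
                         .reshape(b, h, wdt, cin).transpose(0, 3, 1, 2))

    return Tensor(out_data, parents=(x, w), backward=backward)


# ---------------------------------------------------------------------------
# physics ops (complex)


def gather_pixels(x: Tensor, iy: np.ndarray, jx: np.ndarray) -> Tensor:
    """(B, 1, H, W) -> (B, K): read the phase at each core's nearest pixel."""
    out_data = x.data[:, 0, iy, jx]

    def backward(g):
        gx = np.zeros_like(x.data, dtype=g.dtype)
        np.add.at(gx[:, 0], (slice(None), iy, jx), g)
        x.accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def render_phasor_field(p: Tensor, rows: np.ndarray, cols: np.ndarray,
                        ids: np.ndarray, shape: tuple[int, int]) -> Tensor:
    """Per-core phases (B, K) -> complex facet field (B, H, W).

    Each listed pixel gets exp(i * p[core]); amplitude zero elsewhere.  The
    disks are fixed geometry; gradients flow through the phase only.
    """
    b = p.shape[0]
    cdtype = np.complex64 if p.dtype == np.float32 else np.complex128
    phasor = np.exp(1j * p.data).astype(cdtype)       # (B, K)
    out_data = np.zeros((b, *shape), dtype=cdtype)
    out_data[:, rows, cols] = phasor[:, ids]

    def backward(g):
        # g is the real-pair gradient on the field; per-pixel phase gradient is
        # Im(conj(z) * g); pixels of one core sum into its piston phase.
        gpix = g[:, rows, cols]
        zpix = phasor[:, ids]
        gphase_pix = np.imag(np.conj(zpix) * gpix)
        gp = np.zeros_like(p.data)
        np.add.at(gp, (slice(None), ids), gphase_pix)
        p.accumulate(gp)

    return Tensor(out_data, parents=(p,), backward=backward)


def propagate_fixed(u: Tensor, H: np.ndarray) -> Tensor:
    """Angular-spectrum propagation with a precomputed transfer function.

    C-linear, so the backward pass applies the Hermitian adjoint
    ifft2(conj(H) * fft2(g)) (the numpy 1/N factors cancel).
    """
    Hc = H.astype(u.dtype) if u.dtype.kind == "c" else H
    out_data = np.fft.ifft2(Hc * np.fft.fft2(u.data, axes=(-2, -1)), axes=(-2, -1))

    def backward(g):
        u.accumulate(np.fft.ifft2(np.conj(Hc) * np.fft.fft2(g, axes=(-2, -1)),
                                  axes=(-2, -1)).astype(u.dtype))

    return Tensor(out_data.astype(u.dtype), parents=(u,), backward=backward)


def abs2(u: Tensor) -> Tensor:
    """|z|^2: complex (B, H, W) -> real intensity."""
    out_data = (u.data.real ** 2 + u.data.imag ** 2)

    def backward(g):
        u.accumulate(2.0 * u.data * g)

    return Tensor(out_data, parents=(u,), backward=backward)


def npcc_mean(intensity: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative Pearson correlation over a batch of image pairs.

    ``targets`` is a constant (B, H, W) array.  The per-image gradient of
    CC = A / B with A the centered cross sum is
    dCC/dX = (y_centered - CC * (Sy/Syx...)) — implemented in the standard
    closed form and exercised against finite differences in the tests.
    """
    X = intensity.data
    b = X.shape[0]
    Xf = X.reshape(b, -1)
    Yf = np.asarray(targets, dtype=X.dtype).reshape(b, -1)
    xc = Xf - Xf.mean(axis=1, keepdims=True)
    yc = Yf - Yf.mean(axis=1, keepdims=True)
    sx = np.sum(xc * xc, axis=1)
    sy = np.sum(yc * yc, axis=1)
    if np.any(sx == 0) or np.any(sy == 0):
        raise ValueError("correlation undefined for a constant image")
    a = np.sum(xc * yc, axis=1)
    denom = np.sqrt(sx * sy)
    cc = a / denom
    loss = -np.mean(cc)

    def backward(g):
        # d(-mean CC)/dX_i = -(yc_i / denom - cc * xc_i / sx) / b
        coeff = np.asarray(g).reshape(())
        gX = -(yc / denom[:, None] - (cc / sx)[:, None] * xc) * (coeff / b)
        intensity.accumulate(gX.reshape(X.shape))

    return Tensor(np.asarray(loss, dtype=X.dtype), parents=(intensity,),
                  backward=backward)
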