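"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the propagation oracle
uses explicit DFT matrix products (no np.fft), the correlation oracle is a
direct loop over the defining sum.
"""

from __future__ import annotations

import numpy as np


def dft_freq_index(m: int, n: int) -> float:
    """Signed frequency index for DFT bin m of an n-point transform."""
    return float(m if m < (n + 1) // 2 else m - n)


def direct_angular_spectrum(u_in: np.ndarray, pitch: float, wavelength: float,
                            z: float) -> np.ndarray:
    """O(N^4) angular-spectrum propagation by explicit summation.

    Decomposes the field with an explicit DFT matrix product, applies the
    band-limited transfer function computed scalar-by-scalar, and
    recomposes with the inverse DFT matrix.
    """
    ny, nx = u_in.shape
    du = 1.0 / (nx * pitch)
    dv = 1.0 / (ny * pitch)
    u_lim = 1.0 / (wavelength * np.sqrt((2.0 * du * z) ** 2 + 1.0))
    v_lim = 1.0 / (wavelength * np.sqrt((2.0 * dv * z) ** 2 + 1.0))

    # DFT matrices (forward uses exp(-i...), matching the FFT convention)
    wx = np.exp(-2j * np.pi * np.outer(np.arange(nx), np.arange(nx)) / nx)
    wy = np.exp(-2j * np.pi * np.outer(np.arange(ny), np.arange(ny)) / ny)
    spectrum = wy @ u_in @ wx.T

    H = np.zeros((ny, nx), dtype=complex)
    for m in range(ny):
        v = dft_freq_index(m, ny) * dv
        for n_ in range(nx):
            u = dft_freq_index(n_, nx) * du
            arg = 1.0 / wavelength ** 2 - u * u - v * v
            if arg < 0 or abs(u) > u_lim or abs(v) > v_lim:
                continue
            H[m, n_] = np.exp(2j * np.pi * z * np.sqrt(arg))

    filtered = H * spectrum
    out = (np.conj(wy) @ filtered @ np.conj(wx).T) / (nx * ny)
    return out


def direct_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Pearson correlation computed as an explicit loop over the sums."""
    xf = np.asarray(X, dtype=float).ravel()
    yf = np.asarray(Y, dtype=float).ravel()
    n = xf.size
    xb = sum(xf) / n
    yb = sum(yf) / n
    num = 0.0
    dx2 = 0.0
    dy2 = 0.0
    for i in range(n):
        num += (xf[i] - xb) * (yf[i] - yb)
        dx2 += (xf[i] - xb) ** 2
        dy2 += (yf[i] - yb) ** 2
    return num / np.sqrt(dx2 * dy2)


def fresnel_propagate(u_in: np.ndarray, pitch: float, wavelength: float,
                      z: float) -> np.ndarray:
    """Paraxial (Fresnel) transfer-function propagation."""
    ny, nx = u_in.shape
    u = np.fft.fftfreq(nx, d=pitch)[None, :]
    v = np.fft.fftfreq(ny, d=pitch)[:, None]
    H = np.exp(2j * np.pi * z / wavelength) * \
        np.exp(-1j * np.pi * wavelength * z * (u ** 2 + v ** 2))
    return np.fft.ifft2(H * np.fft.fft2(u_in))


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
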