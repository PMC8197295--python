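"""Nonuniform discrete Fourier transforms for irregular OPD sampling.

The translation stage that sweeps the optical path difference has slight
positioning nonlinearity, so interferogram samples sit on an irregular
delta axis.  The spectrum on a uniform wavenumber grid is

    F(sigma_k) = sum_j s_j exp(-2*pi*i * sigma_k * delta_j)

``nudft`` evaluates this sum directly (O(N*K), exact; used as the oracle
and for small problems).  ``nufft`` evaluates it with a Gaussian-gridding
type-1 nonuniform FFT (spread onto a 2x oversampled grid, FFT, deconvolve
by the analytic Gaussian transform), accurate to ~1e-12 relative with the
default spreading half-width.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nudft", "nufft"]


def nudft(signal: np.ndarray, x: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Direct nonuniform DFT: sum_j signal_j exp(-2 pi i sigma x_j).

    ``signal`` may be 1D (N,) or 2D (N, P) for P simultaneous series sharing
    the sample locations ``x``.  Returns complex (K,) or (K, P).
    """
    x = np.asarray(x, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    kernel = np.exp(-2j * np.pi * np.outer(sigma, x))
    return kernel @ np.asarray(signal)


def _spread(
    c: np.ndarray, y: np.ndarray, n_fine: int, tau: float, half_width: int
) -> np.ndarray:
    """Spread point masses c at angular positions y in [0, 2pi) onto a
    periodic fine grid of size n_fine with a Gaussian kernel exp(-d^2/4tau)."""
    h = 2.0 * np.pi / n_fine
    m0 = np.floor(y / h).astype(np.int64)
    multi = c.ndim == 2
    shape = (n_fine, c.shape[1]) if multi else (n_fine,)
    grid = np.zeros(shape, dtype=complex)
    for ell in range(-half_width + 1, half_width + 1):
        m = m0 + ell
        d = y - m * h
        w = np.exp(-(d * d) / (4.0 * tau))
        vals = c * (w[:, None] if multi else w)
        np.add.at(grid, m % n_fine, vals)
    return grid


def nufft(
    signal: np.ndarray,
    x: np.ndarray,
    sigma0: float,
    dsigma: float,
    n_modes: int,
    half_width: int = 14,
) -> np.ndarray:
    """Fast evaluation of F_k = sum_j s_j exp(-2 pi i (sigma0 + k dsigma) x_j),
    k = 0..n_modes-1, via Gaussian-gridding type-1 NUFFT.

    ``signal``: (N,) or (N, P); returns (n_modes,) or (n_modes, P) complex.
    """
    x = np.asarray(x, dtype=float)
    signal = np.asarray(signal)
    if signal.shape[0] != x.shape[0]:
        raise ValueError("signal and sample locations must have equal length")
    if dsigma <= 0 or n_modes < 2:
        raise ValueError("need a positive grid step and at least 2 output modes")

    k_half = n_modes // 2
    # absorb the grid offset and recenter the mode index around zero
    xi = 2.0 * np.pi * dsigma * x
    phase = np.exp(-2j * np.pi * sigma0 * x - 1j * k_half * xi)
    c = signal * (phase[:, None] if signal.ndim == 2 else phase)

    ratio = 2  # oversampling
    n_fine = ratio * n_modes
    tau = np.pi * half_width / (n_modes * n_modes * ratio * (ratio - 0.5))

    y = np.mod(xi, 2.0 * np.pi)
    grid = _spread(c, y, n_fine, tau, half_width)
    ft = np.fft.fft(grid, axis=0)

    k_centered = np.arange(n_modes) - k_half  # k' = k - n_modes//2
    h = 2.0 * np.pi / n_fine
    decon = np.exp(k_centered.astype(float) ** 2 * tau) * h / (2.0 * np.sqrt(np.pi * tau))
    picked = ft[k_centered % n_fine]
    return picked * (decon[:, None] if picked.ndim == 2 else decon)
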