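"""Local phase quantization (LPQ) descriptors.

At every position x of a real matrix the short-term Fourier transform over
an m x m neighbourhood is evaluated at four low frequencies,

    F(u, x) = sum_{y in N_mxm} f(x - y) exp(-j 2 pi u^T y),

with u taken from {(a,0), (0,a), (a,a), (a,-a)} and a = 1/m.  The signs of
the 8 real components [Re u1..u4, Im u1..u4] are packed into an 8-bit code,
and the descriptor of the matrix is the normalized 256-bin histogram of the
codes.  Because a centrally symmetric point-spread function has a real,
locally non-negative Fourier transform at low frequencies, the sign pattern
— hence the histogram — is approximately invariant to such blur.

Pair features for two proteins are the concatenation of the two 256-bin
descriptors (512 numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "LPQConfig",
    "stft_filters",
    "compute_codes",
    "lpq_histogram",
    "lpq_descriptor",
    "pair_feature",
    "histogram_intersection",
]

N_CODES = 256


@dataclass(frozen=True)
class LPQConfig:
    """Configuration of the LPQ transform.

    Parameters
    ----------
    window_size
        Odd neighbourhood side m >= 3 (default 3).
    whitening
        Decorrelate the 8 filter responses with the classic first-order
        Markov image model before quantization (default off: quantize the
        raw responses).
    border_policy
        ``"valid"`` (default): codes only where the window fits inside the
        matrix; ``"zero-pad"``: codes at every position, matrix padded
        with zeros.
    markov_rho
        Pixel correlation coefficient of the whitening model.
    """

    window_size: int = 3
    whitening: bool = False
    border_policy: str = "valid"
    markov_rho: float = 0.9

    def __post_init__(self) -> None:
        m = self.window_size
        if m < 3 or m % 2 == 0:
            raise ValueError(f"window_size must be odd and >= 3, got {m}")
        if self.border_policy not in ("valid", "zero-pad"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")

    @property
    def freq_scalar(self) -> float:
        """Lowest non-zero frequency a = 1/m."""
        return 1.0 / self.window_size

    @property
    def frequencies(self) -> np.ndarray:
        """The four 2-D frequencies, one per row."""
        a = self.freq_scalar
        return np.array([[a, 0.0], [0.0, a], [a, a], [a, -a]])

    @property
    def offsets(self) -> np.ndarray:
        """Window offsets y in [-(m-1)/2, (m-1)/2]."""
        r = (self.window_size - 1) // 2
        return np.arange(-r, r + 1)


def _complex_kernels(config: LPQConfig) -> np.ndarray:
    """The 4 complex m x m windows w_u(y) = exp(-j 2 pi u^T y).

    Axis 0 indexes the frequency; kernel element [iy, ix] corresponds to
    offset y = (offsets[iy], offsets[ix]) with u^T y = u_row*y_row +
    u_col*y_col.
    """
    offs = config.offsets
    yy, xx = np.meshgrid(offs, offs, indexing="ij")
    kernels = np.empty((4, config.window_size, config.window_size), dtype=complex)
    for k, (u_row, u_col) in enumerate(config.frequencies):
        kernels[k] = np.exp(-2j * np.pi * (u_row * yy + u_col * xx))
    return kernels


def stft_filters(config: LPQConfig | None = None) -> np.ndarray:
    """Real filter bank: 8 kernels (4 real parts then 4 imaginary parts).

    Convolving a matrix with kernel k yields component k of the 8-vector
    quantized by :func:`compute_codes`.
    """
    config = config or LPQConfig()
    kernels = _complex_kernels(config)
    return np.concatenate([kernels.real, kernels.imag], axis=0)


def _whitening_transform(config: LPQConfig) -> np.ndarray:
    """8x8 decorrelating transform under a first-order Markov image model.

    Pixel covariance is rho^d for Euclidean offset distance d; the
    transform is the (orthonormal) left factor of the SVD of the response
    covariance, applied from the left to the 8-vector of responses.
    """
    offs = config.offsets
    yy, xx = np.meshgrid(offs, offs, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    cov_pix = config.markov_rho ** dist
    kernels = _complex_kernels(config)
    w = kernels.reshape(4, -1)
    m8 = np.vstack([w.real, w.imag])  # 8 x m^2
    cov_resp = m8 @ cov_pix @ m8.T
    u, _, _ = np.linalg.svd(cov_resp)
    return u.T


def _responses(matrix: np.ndarray, config: LPQConfig) -> np.ndarray:
    """Stack of the 8 real filter responses, shape (8, H', W')."""
    mode = "valid" if config.border_policy == "valid" else "same"
    out = []
    for kernel in _complex_kernels(config):
        resp = convolve2d(matrix, kernel, mode=mode, boundary="fill", fillvalue=0.0)
        out.append(resp)
    resp = np.stack(out)  # 4 complex maps
    return np.concatenate([resp.real, resp.imag], axis=0)


def compute_codes(matrix: np.ndarray, config: LPQConfig | None = None) -> np.ndarray:
    """8-bit LPQ code map of a real 2-D matrix.

    Bit k (weight 2**k) is set where response component k is strictly
    positive; zero responses quantize to 0, so a constant matrix codes to
    all zeros.
    """
    config = config or LPQConfig()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("input must be a 2-D matrix")
    m = config.window_size
    if config.border_policy == "valid" and (
        matrix.shape[0] < m or matrix.shape[1] < m
    ):
        raise ValueError(
            f"matrix shape {matrix.shape} smaller than the {m}x{m} window; "
            f"need at least {m} along each axis"
        )
    comps = _responses(matrix, config)
    if config.whitening:
        flat = comps.reshape(8, -1)
        flat = _whitening_transform(config) @ flat
        comps = flat.reshape(comps.shape)
    # strict positivity with a scale-relative dead zone so that analytic
    # zeros (constant regions) survive convolution roundoff as bit 0
    atol = 1e-9 * max(1.0, float(np.max(np.abs(matrix))))
    bits = comps > atol
    weights = (1 << np.arange(8)).reshape(8, 1, 1)
    return np.sum(bits * weights, axis=0).astype(np.uint8).astype(int)


def lpq_histogram(codes: np.ndarray) -> np.ndarray:
    """Normalized 256-bin histogram of a code map."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty code map")
    counts = np.bincount(codes.ravel(), minlength=N_CODES).astype(float)
    return counts / counts.sum()


def lpq_descriptor(matrix: np.ndarray, config: LPQConfig | None = None) -> np.ndarray:
    """Convenience: histogram of the code map of ``matrix``."""
    return lpq_histogram(compute_codes(matrix, config))


def pair_feature(desc_a: np.ndarray, desc_b: np.ndarray) -> np.ndarray:
    """Concatenate two protein descriptors into one 512-vector."""
    desc_a = np.asarray(desc_a, dtype=float)
    desc_b = np.asarray(desc_b, dtype=float)
    if desc_a.shape != (N_CODES,) or desc_b.shape != (N_CODES,):
        raise ValueError(
            f"descriptors must have shape ({N_CODES},), "
            f"got {desc_a.shape} and {desc_b.shape}"
        )
    return np.concatenate([desc_a, desc_b])


def histogram_intersection(h1: np.ndarray, h2: np.ndarray) -> float:
    """Sum of element-wise minima; 1.0 for identical normalized histograms."""
    return float(np.minimum(h1, h2).sum())
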