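"""Statistical-analyzer metrics.

Concentration is measured two ways: the l1 norm of the spectrum (lower =
more concentrated) and the Gini index (scale-invariant, in [0, 1], higher
= sparser).  Reconstruction quality is the time-domain MSE against the
original, and PSNR for images.  All measures act on coefficient
magnitudes, so complex DFT spectra are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricReport", "l1_measure", "gini_index", "mse", "psnr",
           "quantization_error_bound"]


@dataclass
class MetricReport:
    l1: float
    gini: float
    mse: float | None = None
    psnr_db: float | None = None
    elapsed_s: float | None = None  # reported only, never asserted


def l1_measure(x) -> float:
    """Sum of coefficient magnitudes (complex modulus for DFT spectra)."""
    return float(np.sum(np.abs(np.asarray(x))))


def gini_index(x) -> float:
    """Gini sparsity index.

    With magnitudes sorted ascending as ``a[0..N-1]``:

        G = 1 - 2 * sum_i (a[i] / ||a||_1) * ((N - i - 1/2) / N)

    G = 0 for a constant-magnitude vector, 1 - 1/N for a 1-sparse one,
    and the value is invariant under positive scaling.
    """
    a = np.sort(np.abs(np.asarray(x).ravel()))
    total = a.sum()
    if total == 0:
        raise ValueError("Gini index is undefined for the all-zero vector")
    n = a.size
    i = np.arange(1, n + 1)
    return float(1.0 - 2.0 * np.sum((a / total) * ((n - i + 0.5) / n)))


def mse(x, ref) -> float:
    """Mean squared magnitude difference; shapes must match."""
    x = np.asarray(x)
    ref = np.asarray(ref)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    return float(np.mean(np.abs(x - ref) ** 2))


def psnr(img, ref, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical inputs."""
    if peak <= 0:
        raise ValueError("peak must be positive")
    err = mse(img, ref)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / err))


def quantization_error_bound(k: int, b: int) -> float:
    """Reconstruction-error bound (dB) from B-bit quantized measurements
    of a K-sparse signal: 3.01 log2(K) - 6.02 B - 7.78."""
    if k < 1 or b < 1:
        raise ValueError("K and B must be at least 1")
    return float(3.01 * np.log2(k) - 6.02 * b - 7.78)
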