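"""Synthetic ground-truth generators.

Three families of test inputs with fully known structure: K-sparse
spectra in any of the three bases, QRS-like beats built as short Hermite-
function mixtures (HT-sparse by construction), and piecewise-constant
phantoms for the 2D TV path.  Every generator records its seed and
declares the exact support/coefficients it planted, and the declared
spectrum matches the forward transform of the generated data to 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import Signal1D, TransformBasis, build_basis, hermite_function

__all__ = ["GroundTruth", "gen_sparse_signal", "gen_qrs_like", "gen_phantom"]


@dataclass
class GroundTruth:
    """A generated signal or image with its declared sparse structure."""

    data: np.ndarray
    support: np.ndarray
    coefficients: np.ndarray
    seed: int | None
    params: dict = field(default_factory=dict)

    def spectrum(self, n: int | None = None) -> np.ndarray:
        n = n or self.data.size
        out = np.zeros(n, dtype=self.coefficients.dtype)
        out[self.support] = self.coefficients
        return out


def gen_sparse_signal(
    n: int,
    k: int,
    basis: str | TransformBasis = "dft",
    amp_range: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    mode: str = "complex",
    sigma: float | None = None,
) -> GroundTruth:
    """A signal with exactly K non-zero transform coefficients.

    Component amplitudes are drawn from ``amp_range`` (time-domain
    component amplitude for the DFT, coefficient magnitude for DCT/HT) —
    bounded away from zero so exact-support recovery is well posed.  DFT
    components carry random phases; ``mode='real'`` plants conjugate
    pairs on 2K bins (DC and Nyquist excluded) so the signal is real.
    """
    if k >= n:
        raise ValueError("need K < N")
    rng = np.random.default_rng(seed)
    b = basis if isinstance(basis, TransformBasis) else build_basis(basis, n, sigma=sigma)
    lo, hi = amp_range
    if k == 0:
        sig = np.zeros(n, dtype=complex if (b.name == "dft" and mode == "complex") else float)
        return GroundTruth(sig, np.zeros(0, dtype=int), np.zeros(0), seed,
                           {"n": n, "k": 0, "basis": b.name, "mode": mode})
    amps = rng.uniform(lo, hi, size=k)
    if b.name == "dft":
        if mode == "complex":
            support = np.sort(rng.choice(n, size=k, replace=False))
            phases = rng.uniform(0, 2 * np.pi, size=k)
            coeffs = n * amps * np.exp(1j * phases)  # unnormalized-forward scale
        elif mode == "real":
            half = np.arange(1, (n + 1) // 2)  # exclude DC and Nyquist
            if k > half.size:
                raise ValueError("too many real components for this N")
            pos = np.sort(rng.choice(half, size=k, replace=False))
            phases = rng.uniform(0, 2 * np.pi, size=k)
            support = np.sort(np.concatenate([pos, n - pos]))
            pair = (n * amps / 2) * np.exp(1j * phases)
            full = np.zeros(n, dtype=complex)
            full[pos] = pair
            full[n - pos] = np.conj(pair)
            coeffs = full[support]
        else:
            raise ValueError("mode must be 'complex' or 'real'")
    else:
        support = np.sort(rng.choice(n, size=k, replace=False))
        coeffs = amps * rng.choice([-1.0, 1.0], size=k)
    spectrum = np.zeros(n, dtype=coeffs.dtype)
    spectrum[support] = coeffs
    sig = b.inverse @ spectrum
    if b.name == "dft" and mode == "real":
        sig = sig.real
    return GroundTruth(sig, support, coeffs, seed,
                       {"n": n, "k": k, "basis": b.name, "mode": mode, "sigma": b.sigma})


def gen_qrs_like(
    n: int,
    orders: np.ndarray,
    amps: np.ndarray | None = None,
    lam: float = 2.0,
    seed: int = 0,
    period: float = 1.0,
) -> GroundTruth:
    """A QRS-shaped beat: a low-order Hermite-function mixture at scale lam.

    Hermite functions share the narrow oscillatory-deflection morphology
    of QRS complexes, so a few of them reproduce a beat and the result is
    HT-sparse by construction.  ``data`` holds the uniform centred-grid
    samples; the declared coefficients are the scale-lam HT coefficients
    of the signal's exact values at the lam-scaled Hermite nodes (stored
    in ``params['node_samples']``).
    """
    orders = np.asarray(orders, dtype=int)
    if orders.size != np.unique(orders).size:
        raise ValueError("orders must be distinct")
    if orders.min() < 0 or orders.max() >= n:
        raise ValueError("orders out of range")
    rng = np.random.default_rng(seed)
    if amps is None:
        amps = rng.uniform(0.5, 1.5, size=orders.size) * rng.choice([-1.0, 1.0], orders.size)
    amps = np.asarray(amps, dtype=float)
    sig = Signal1D(np.zeros(n), period=period)
    t = sig.times
    data = np.zeros(n)
    for p, a in zip(orders, amps):
        data += a * hermite_function(int(p), t, lam)
    ht = build_basis("ht", n, sigma=lam)
    node_samples = np.zeros(n)
    for p, a in zip(orders, amps):
        node_samples += a * hermite_function(int(p), ht.nodes, lam)
    order = np.argsort(orders)
    return GroundTruth(
        data, orders[order], amps[order], seed,
        {"n": n, "lam": lam, "period": period, "node_samples": node_samples},
    )


def gen_phantom(
    shape: tuple[int, int] = (64, 64),
    n_regions: int = 2,
    levels: np.ndarray | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Piecewise-constant phantom: nested ellipses of constant gray level.

    A desk-scale stand-in for an MRI slice (synthetic): n_regions - 1
    concentric ellipses over a uniform background, 8-bit gray levels.
    """
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("phantom must be at least 16x16")
    if n_regions < 1:
        raise ValueError("need at least one region")
    rng = np.random.default_rng(seed)
    if levels is None:
        levels = np.linspace(40, 220, n_regions)
        if n_regions > 1:
            levels = rng.permutation(levels)
    levels = np.asarray(levels, dtype=float)
    if levels.size != n_regions:
        raise ValueError("need one gray level per region")
    img = np.full(shape, levels[0])
    ii, jj = np.mgrid[0:h, 0:w]
    ci, cj = (h - 1) / 2, (w - 1) / 2
    for r in range(1, n_regions):
        frac = 0.75 * (1 - r / (n_regions + 0.5))
        ai = max(2.0, frac * h / 2) * rng.uniform(0.85, 1.0)
        aj = max(2.0, frac * w / 2) * rng.uniform(0.85, 1.0)
        inside = ((ii - ci) / ai) ** 2 + ((jj - cj) / aj) ** 2 <= 1.0
        img[inside] = levels[r]
    return GroundTruth(img, np.zeros(0, dtype=int), levels, seed,
                       {"shape": shape, "n_regions": n_regions})
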