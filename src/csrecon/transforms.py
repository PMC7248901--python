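"""Sparsifying transform bases: DFT, DCT and the Hermite transform (HT).

The three bases share one matrix convention: ``X = forward @ x`` and
``x = inverse @ X``.  The DFT uses the unnormalized analysis convention
(the 1/N factor sits on the inverse), the DCT is the orthonormal DCT-II,
and the HT expands a signal sampled at the roots of the order-N Hermite
polynomial in Hermite functions.  All downstream detection thresholds
assume these conventions.

The HT comes with its resampling machinery: band-limited (sinc)
interpolation of a uniformly sampled signal onto the sigma-scaled Hermite
nodes, and the l1-driven search for the sigma that concentrates the
spectrum best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss

__all__ = [
    "Signal1D",
    "TransformBasis",
    "BASIS_NAMES",
    "build_basis",
    "hermite_function",
    "hermite_nodes",
    "sinc_resample",
    "optimize_sigma",
    "default_sigma_grid",
]

BASIS_NAMES = ("dft", "dct", "ht")

#: hard cap on Hermite orders; the stable recurrence is fine far beyond
#: any signal length this package targets, but guard against nonsense input
MAX_HERMITE_ORDER = 2000


@dataclass
class Signal1D:
    """A finite, uniformly sampled 1D signal.

    The sample grid is centred: sample ``i`` sits at time ``(i - N//2) * period``.
    Centring matters only for the Hermite machinery, whose nodes are
    symmetric about zero; the DFT/DCT paths never look at the time axis.
    """

    samples: np.ndarray
    period: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("Signal1D needs a 1D vector with at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Signal1D samples must be finite")
        if self.period <= 0:
            raise ValueError("sampling period must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Centred sample times (i - N//2) * T."""
        idx = np.arange(self.n) - self.n // 2
        return idx * self.period


@dataclass
class TransformBasis:
    """A named N x N forward/inverse transform pair.

    ``forward @ x`` produces the spectrum, ``inverse @ X`` the signal;
    the pair satisfies ``inverse @ forward == I`` to high accuracy.  For
    the HT the basis additionally records the scale ``sigma`` and the
    (sigma-scaled) Hermite nodes the signal is assumed to be sampled at.
    """

    name: str
    forward: np.ndarray
    inverse: np.ndarray
    sigma: float | None = None
    nodes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.forward.shape[0]

    def round_trip_error(self) -> float:
        eye = self.inverse @ self.forward
        return float(np.max(np.abs(eye - np.eye(self.n))))


def hermite_function(p: int, t, lam: float = 1.0):
    """Normalized Hermite function psi_p(t) at scale ``lam``.

    psi_p(t) = exp(-t^2 / (2 lam^2)) H_p(t/lam) / sqrt(lam 2^p p! sqrt(pi)),
    evaluated with the stable three-term recurrence on the *normalized*
    functions (the Gaussian is folded in from the start, so no overflow).
    """
    if p < 0:
        raise ValueError("Hermite order must be non-negative")
    if p > MAX_HERMITE_ORDER:
        raise ValueError(f"Hermite order {p} exceeds the supported maximum")
    if lam <= 0:
        raise ValueError("Hermite scale must be positive")
    u = np.asarray(t, dtype=float) / lam
    # phi_0 = pi^{-1/4} exp(-u^2/2); phi_{k+1} = u sqrt(2/(k+1)) phi_k - sqrt(k/(k+1)) phi_{k-1}
    phi_prev = np.pi ** (-0.25) * np.exp(-0.5 * u * u)
    if p == 0:
        out = phi_prev
    else:
        phi = np.sqrt(2.0) * u * phi_prev
        for k in range(1, p):
            phi, phi_prev = (
                u * np.sqrt(2.0 / (k + 1)) * phi - np.sqrt(k / (k + 1.0)) * phi_prev,
                phi,
            )
        out = phi
    out = out / np.sqrt(lam)
    if np.isscalar(t):
        return float(out)
    return out


def hermite_nodes(m: int) -> np.ndarray:
    """Roots of the order-m physicists' Hermite polynomial (ascending)."""
    nodes, _ = hermgauss(m)  # Golub-Welsch eigenvalue method
    return nodes


def _hermite_matrix(n: int, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HT forward/inverse pair of size n at scale sigma.

    Row p of the forward matrix is
        psi_p(sigma n_m; sigma) / (n * psi_{n-1}(sigma n_m; sigma)^2),
    with n_m the unit-scale Hermite roots.  The squared top-order function
    in the denominator is exactly the Gauss-Hermite quadrature weight, so
    the rows are orthonormal with respect to that quadrature and the pair
    inverts exactly: inverse[m, p] = psi_p(sigma n_m; sigma).
    """
    t = hermite_nodes(n)
    phi = np.empty((n, n))  # phi[p, m] = unit-scale psi_p(t_m)
    for p in range(n):
        phi[p] = hermite_function(p, t, 1.0)
    # scale: psi_p(sigma t; sigma) = psi_p(t; 1) / sqrt(sigma)
    inv = (phi / np.sqrt(sigma)).T  # inverse[m, p]
    weights = 1.0 / (n * (phi[n - 1] / np.sqrt(sigma)) ** 2)  # 1/(n psi_{n-1}^2)
    fwd = (phi / np.sqrt(sigma)) * weights[None, :]
    return fwd, inv, sigma * t


def build_basis(name: str, n: int, sigma: float | None = None) -> TransformBasis:
    """Construct a named transform basis of size ``n``.

    ``sigma`` applies to the HT only (scale of the Hermite functions);
    passing it for DFT/DCT is rejected to catch configuration mistakes.
    """
    if n < 2:
        raise ValueError("basis size must be at least 2")
    key = name.lower()
    if key not in BASIS_NAMES:
        raise ValueError(f"unknown basis {name!r}; expected one of {BASIS_NAMES}")
    if key != "ht" and sigma is not None:
        raise ValueError(f"sigma is a Hermite-transform parameter, not valid for {name!r}")

    if key == "dft":
        k = np.arange(n)
        # forward psi*_k(n) = exp(-j 2 pi n k / N); the 1/N factor rides on the inverse
        fwd = np.exp(-2j * np.pi * np.outer(k, k) / n)
        inv = np.exp(+2j * np.pi * np.outer(k, k) / n) / n
        return TransformBasis("dft", fwd, inv)
    if key == "dct":
        k = np.arange(n)[:, None]
        m = np.arange(n)[None, :]
        c = np.full(n, np.sqrt(2.0 / n))
        c[0] = np.sqrt(1.0 / n)
        fwd = c[:, None] * np.cos((2 * m + 1) * k * np.pi / (2 * n))
        return TransformBasis("dct", fwd, fwd.T.copy())
    # HT
    if sigma is None:
        sigma = 1.0
    if sigma <= 0:
        raise ValueError("HT sigma must be positive")
    fwd, inv, nodes = _hermite_matrix(n, float(sigma))
    return TransformBasis("ht", fwd, inv, sigma=float(sigma), nodes=nodes)


def sinc_resample(x: Signal1D, sigma: float = 1.0, nodes: np.ndarray | None = None) -> np.ndarray:
    """Band-limited interpolation of ``x`` at the points ``sigma * nodes``.

    ``nodes`` defaults to the unit-scale Hermite roots of order N.  The
    sum runs over all N uniform samples on the centred grid, so a node
    that coincides with a sample time returns that sample exactly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if nodes is None:
        nodes = hermite_nodes(x.n)
    nodes = np.asarray(nodes, dtype=float)
    if nodes.size == 0:
        raise ValueError("empty node set")
    points = sigma * nodes
    # kernel[m, i] = sinc((t_m - (i - N/2) T) / T)
    kernel = np.sinc((points[:, None] - x.times[None, :]) / x.period)
    return kernel @ x.samples


def default_sigma_grid(num: int = 50, lo: float = 0.1, hi: float = 10.0) -> np.ndarray:
    """Logarithmic sigma search grid used when the caller supplies none."""
    return np.geomspace(lo, hi, num)


def optimize_sigma(
    x: Signal1D, grid: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Pick the Hermite scale minimizing the l1 norm of the HT spectrum.

    For every candidate sigma the signal is sinc-resampled onto the
    sigma-scaled Hermite nodes and transformed; the sigma with the
    smallest l1 (first one on ties) wins.  Returns ``(sigma_opt, l1_curve)``.
    """
    if grid is None:
        grid = default_sigma_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty sigma grid")
    if np.any(grid <= 0):
        raise ValueError("sigma grid entries must be positive")
    n = x.n
    t = hermite_nodes(n)
    curve = np.empty(grid.size)
    for i, s in enumerate(grid):
        vals = sinc_resample(x, sigma=s, nodes=t)
        fwd, _, _ = _hermite_matrix(n, float(s))
        curve[i] = float(np.sum(np.abs(fwd @ vals)))
    best = int(np.argmin(curve))
    return float(grid[best]), curve
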