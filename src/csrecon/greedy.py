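"""Greedy and threshold-based recovery: OMP, SIRA and GDBRA.

These methods estimate the sparse support first and then re-fit the
coefficients by least squares on the partial transform matrix.  OMP grows
the support one (most correlated) column at a time; SIRA detects, in a
single pass, every zero-filled spectrum coefficient exceeding an
analytically calibrated missing-sample-noise threshold; GDBRA detects DFT
support through generalized deviations of the demodulated available
samples.

Missing-sample noise model
--------------------------
Zero-filling the unavailable samples perturbs every off-support transform
coefficient.  For a random mask keeping M of N samples, the perturbation
of one coefficient is a without-replacement sum of M terms from a
zero-mean population, so its variance carries the finite-population
factor M (N - M) / (N - 1) times the population variance of
``x(n) * psi_k(n)``.  The population variance is estimated from the
available samples alone (scaled by N / M), which for the unnormalized DFT
collapses to ``M (N - M) / (N - 1) * mean(|y|^2)`` and for the orthonormal
DCT to ``M (N - M) / (N^2 (N - 1)) * sum_i A_i^2`` with
``sum A_i^2 = (N / M) * sum y^2``.  For the HT, whose rows are not
constant-magnitude, the estimate uses the basis matrix directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfinv

from .sensing import SamplingMask, cs_matrix, zero_filled
from .transforms import TransformBasis

__all__ = [
    "SupportEstimate",
    "ThresholdSpec",
    "omp",
    "noise_variance",
    "sira_threshold",
    "sira",
    "generalized_deviation",
    "gdbra",
]

log = logging.getLogger(__name__)


@dataclass
class SupportEstimate:
    """Detected transform-domain positions and their coefficient estimates."""

    k: np.ndarray
    values: np.ndarray
    n: int
    residual_norm: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.values = np.asarray(self.values)
        if self.k.size != np.unique(self.k).size:
            raise ValueError("support indices must be unique")
        if self.k.size and (self.k.min() < 0 or self.k.max() >= self.n):
            raise ValueError("support indices out of range")

    def spectrum(self) -> np.ndarray:
        """Full length-N coefficient vector (zeros off support)."""
        out = np.zeros(self.n, dtype=complex if np.iscomplexobj(self.values) else float)
        out[self.k] = self.values
        return out


@dataclass
class ThresholdSpec:
    """Parameters of the SIRA detection threshold."""

    domain: str
    p: float
    sigma_ms2: float
    t: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("target probability P must lie in (0, 1)")
        if self.sigma_ms2 < 0:
            raise ValueError("noise variance must be non-negative")


def _lstsq(a: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares via a stable factorization; returns (coef, resid norm, rank)."""
    coef, _, rank, _ = np.linalg.lstsq(a, y, rcond=None)
    resid = float(np.linalg.norm(y - a @ coef))
    return coef, resid, rank


# ---------------------------------------------------------------------------
# OMP
# ---------------------------------------------------------------------------

def omp(
    y: np.ndarray,
    a: np.ndarray,
    k: int,
    pair_conjugates: bool = False,
) -> SupportEstimate:
    """Orthogonal matching pursuit: K greedy column selections.

    Each iteration picks the column of ``a`` with the largest correlation
    magnitude against the current residual (lowest index on ties),
    re-fits all selected coefficients by least squares and updates the
    residual.  ``pair_conjugates`` additionally selects the mirror column
    ``(N - j) mod N`` with each pick so real signals sparse in the DFT
    keep conjugate-symmetric spectra (one iteration then selects one
    conjugate pair, i.e. one real component).
    """
    y = np.asarray(y)
    m, n = a.shape
    if not 1 <= k <= m:
        raise ValueError("need 1 <= K <= M")
    resid = y.astype(complex if np.iscomplexobj(a) or np.iscomplexobj(y) else float)
    support: list[int] = []
    coef = np.zeros(0)
    prev_norm = np.inf
    residual_history: list[float] = []
    for it in range(k):
        corr = np.abs(a.conj().T @ resid)
        corr[support] = -1.0  # never re-pick
        j = int(np.argmax(corr))
        picks = [j]
        if pair_conjugates:
            jc = (n - j) % n
            if jc != j and jc not in support:
                picks.append(jc)
        support.extend(picks)
        cols = a[:, support]
        coef, rnorm, rank = _lstsq(cols, y)
        if rank < len(support):
            log.warning("OMP: selected columns rank-deficient at iteration %d; stopping", it + 1)
            break
        resid = y - cols @ coef
        residual_history.append(rnorm)
        if rnorm > prev_norm + 1e-12:
            log.warning("OMP: residual increased; stopping early")
            break
        prev_norm = rnorm
        if rnorm < 1e-13 * max(1.0, float(np.linalg.norm(y))):
            break
    order = np.argsort(support)
    support_arr = np.asarray(support)[order]
    return SupportEstimate(
        support_arr, np.asarray(coef)[order], n,
        residual_norm=float(np.linalg.norm(resid)),
        diagnostics={"residual_history": residual_history},
    )


# ---------------------------------------------------------------------------
# SIRA
# ---------------------------------------------------------------------------

def noise_variance(
    y: np.ndarray,
    domain: str,
    n: int,
    m: int,
    k: int | None = None,
    amplitudes: np.ndarray | None = None,
    *,
    basis: TransformBasis | None = None,
    mask: SamplingMask | None = None,
) -> float:
    """Variance of one off-support coefficient of the zero-filled spectrum.

    Domain-specific closed forms (see module docstring); ``amplitudes``
    may supply the component amplitudes ``A_i`` directly, otherwise
    ``sum A_i^2`` is estimated from the available samples.  The HT form
    requires ``basis`` and ``mask`` because its rows are not
    constant-magnitude; the returned value is the off-support average.
    """
    y = np.asarray(y)
    if m < 2:
        raise ValueError("need at least two measurements")
    fpc = m * (n - m) / (n - 1)  # finite-population factor
    key = domain.lower()
    if key == "dft":
        # sum A_i^2 over components == mean signal power, estimated by mean |y|^2
        return float(fpc * np.mean(np.abs(y) ** 2))
    if key == "dct":
        if amplitudes is not None:
            sum_a2 = float(np.sum(np.abs(amplitudes) ** 2))
        else:
            sum_a2 = float(n / m * np.sum(np.abs(y) ** 2))
        return float(fpc / (n * n) * sum_a2)
    if key == "ht":
        if basis is None or mask is None:
            raise ValueError("HT noise variance needs the basis and the mask")
        # population variance of x(n) * F[k, n], population sum estimated
        # from the available samples; averaged over k
        fy = np.abs(basis.forward[:, mask.available] * y[None, :]) ** 2
        pop_var = (n / m) * fy.sum(axis=1) / n
        return float(fpc * pop_var.mean())
    raise ValueError(f"unknown domain {domain!r}")


def sira_threshold(
    domain: str,
    p: float,
    sigma_ms2: float,
    n: int,
    k: int = 0,
) -> float:
    """Detection level T: noise-only coefficients stay below T with probability P.

    DFT coefficients of the missing-sample noise are complex Gaussian, so
    their squared magnitudes are exponential and

        T = sqrt(-sigma_MS^2 * ln(1 - P^(1/(N-K)))),

    with N - K ~ N for K << N.  DCT and HT coefficients are real
    Gaussian; the max-magnitude quantile is the half-normal quantile

        T = sigma_MS * sqrt(2) * erfinv(P^(1/N)).

    Both forms are validated against Monte-Carlo quantiles in the test
    suite (natural logarithm throughout).
    """
    if not 0 < p < 1:
        raise ValueError("P must lie in (0, 1)")
    if sigma_ms2 < 0:
        raise ValueError("variance must be non-negative")
    n_eff = max(n - k, 1)
    sigma = np.sqrt(sigma_ms2)
    key = domain.lower()
    if key == "dft":
        return float(np.sqrt(-sigma_ms2 * np.log(1.0 - p ** (1.0 / n_eff))))
    if key in ("dct", "ht"):
        return float(sigma * np.sqrt(2.0) * erfinv(p ** (1.0 / n_eff)))
    raise ValueError(f"unknown domain {domain!r}")


def sira(
    y: np.ndarray,
    basis: TransformBasis,
    mask: SamplingMask,
    k: int = 0,
    p: float = 0.99,
) -> SupportEstimate:
    """Single-iteration reconstruction: threshold, then least-squares re-fit.

    The initial spectrum is the transform of the zero-filled signal.
    Positions whose magnitude exceeds the calibrated threshold form the
    support; the coefficients are re-fit by least squares on the
    corresponding columns of the CS matrix.  ``k`` (the assumed sparsity)
    only sharpens the threshold's N - K term and may be left 0.
    """
    y = np.asarray(y)
    n, m = basis.n, mask.m
    x0 = basis.forward @ zero_filled(y, mask)
    var = noise_variance(y, basis.name, n, m, k=k, basis=basis, mask=mask)
    t = sira_threshold(basis.name, p, var, n, k=k)
    detected = np.flatnonzero(np.abs(x0) > t)
    diagnostics = {"threshold": t, "sigma_ms2": var, "p": p}
    if detected.size == 0:
        log.warning("SIRA: no coefficient exceeds the threshold %.3g", t)
        empty = np.zeros(0, dtype=complex if np.iscomplexobj(x0) else float)
        return SupportEstimate(np.zeros(0, dtype=int), empty, n,
                               diagnostics={**diagnostics, "empty": True})
    if detected.size > m:
        raise ValueError(
            f"SIRA detected {detected.size} coefficients with only {m} measurements"
        )
    a_cs = cs_matrix(basis, mask)[:, detected]
    coef, resid, _ = _lstsq(a_cs, y)
    return SupportEstimate(detected, coef, n, residual_norm=resid, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# GDBRA
# ---------------------------------------------------------------------------

def generalized_deviation(
    y: np.ndarray,
    positions: np.ndarray,
    n: int,
    k: np.ndarray | int | None = None,
    ell: int = 2,
) -> np.ndarray:
    """Generalized deviation GD(k) of the demodulated available samples.

    Demodulating at a frequency actually present in the signal turns that
    component into a constant, so the deviation of the demodulated values
    about their mean drops by that component's power.  ``ell`` selects the
    deviation norm (1 or 2).
    """
    y = np.asarray(y)
    positions = np.asarray(positions, dtype=int)
    if positions.size < 2:
        raise ValueError("need at least two available samples")
    if ell not in (1, 2):
        raise ValueError("L must be 1 or 2")
    if k is None:
        freqs = np.arange(n)
    else:
        freqs = np.atleast_1d(np.asarray(k, dtype=int))
    demod = y[None, :] * np.exp(-2j * np.pi * np.outer(freqs, positions) / n)
    dev = np.abs(demod - demod.mean(axis=1, keepdims=True)) ** ell
    out = dev.mean(axis=1)
    if np.isscalar(k) and np.ndim(k) == 0 and k is not None:
        return float(out[0])
    return out


def gdbra(
    y: np.ndarray,
    positions: np.ndarray,
    n: int,
    ell: int = 2,
    p: float = 1.0,
    c: str = "median",
    k: int | None = None,
) -> SupportEstimate:
    """Generalized-deviation-based recovery (DFT domain).

    Frequencies whose GD falls below ``p`` times the chosen statistic of
    the GD profile form the candidate support; when the sparsity ``k`` is
    supplied the support is capped/extended to the k smallest deviations.
    Coefficients are re-fit by least squares on the partial DFT matrix.
    """
    y = np.asarray(y)
    positions = np.asarray(positions, dtype=int)
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    stats = {"max": np.max, "min": np.min, "mean": np.mean, "median": np.median}
    if c not in stats:
        raise ValueError(f"c must be one of {sorted(stats)}")
    gd = generalized_deviation(y, positions, n, ell=ell)
    t = p * float(stats[c](gd))
    sel = np.flatnonzero(gd < t)
    if k is not None:
        if sel.size != k:
            sel = np.argsort(gd, kind="stable")[:k]
    if sel.size == 0:
        raise ValueError("GDBRA: empty support (threshold below all deviations)")
    if sel.size > positions.size:
        raise ValueError("GDBRA: detected support exceeds the measurement count")
    sel = np.sort(sel)
    # partial DFT synthesis matrix: rows = available positions, columns = frequencies
    a_cs = np.exp(2j * np.pi * np.outer(positions, sel) / n) / n
    coef, resid, _ = _lstsq(a_cs, y)
    return SupportEstimate(sel, coef, n, residual_norm=resid,
                           diagnostics={"threshold": t, "gd": gd})
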