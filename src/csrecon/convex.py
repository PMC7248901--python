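"""Convex recovery: basis pursuit, the gradient missing-sample algorithm,
Douglas-Rachford splitting and total-variation minimization (1D and 2D).

Basis pursuit solves min ||X||_1 s.t. A X = y as a linear program through
an interior-point method (complex systems are recast by real/imaginary
stacking).  Douglas-Rachford reaches the same minimizer by a proximal
fixed-point iteration alternating reflections of the soft-threshold
(the l1 prox) and the Euclidean projection onto the data constraint.
The gradient algorithm works in the signal domain instead: it treats the
missing samples as free variables and descends the l1 concentration of
the spectrum with a shrinking finite-difference step.  TV minimization
recovers piecewise-constant images from partial transform coefficients
(e.g. radial 2D-DFT lines) or partial pixels by the same splitting with a
TV prox.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import linprog

from .measures import l1_measure
from .sensing import SamplingMask, zero_filled
from .transforms import TransformBasis

__all__ = [
    "ProxParams",
    "GradientParams",
    "ImageMask2D",
    "basis_pursuit",
    "gradient_reconstruct",
    "soft_threshold",
    "affine_projection",
    "douglas_rachford",
    "tv_norm",
    "radial_fourier_mask",
    "lowmid_dct_mask",
    "tv_reconstruct",
    "tv_reconstruct_1d",
    "reshape_1d_to_2d",
]

log = logging.getLogger(__name__)


@dataclass
class ProxParams:
    """Douglas-Rachford / proximal-splitting controls."""

    lam: float = 1.0        # soft-threshold scale lambda
    mu: float = 1.0         # relaxation, 0 < mu < 2
    max_iter: int = 4000
    tol: float = 1e-10      # fixed-point increment tolerance

    def __post_init__(self) -> None:
        if not 0 < self.mu < 2:
            raise ValueError("relaxation mu must lie in (0, 2)")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class GradientParams:
    """Controls of the gradient missing-sample algorithm."""

    delta_init: float | None = None   # default: max |x^(0)|
    delta_shrink: float = 3.0
    inner_tol: float = 1e-3           # stop sweep when max update < delta * inner_tol
    outer_precision: float = 1e-7     # stop when delta falls below this
    max_inner: int = 150
    max_outer: int = 60

    def __post_init__(self) -> None:
        if self.delta_shrink <= 1:
            raise ValueError("delta_shrink must exceed 1")


@dataclass
class ImageMask2D:
    """Boolean availability mask over an image-shaped array."""

    available: np.ndarray
    kind: str = "pixel-random"

    def __post_init__(self) -> None:
        self.available = np.asarray(self.available, dtype=bool)
        if self.available.ndim != 2 or not self.available.any():
            raise ValueError("2D mask needs at least one available entry")

    @property
    def fraction(self) -> float:
        return float(self.available.mean())


# ---------------------------------------------------------------------------
# Basis pursuit (l1-magic replacement)
# ---------------------------------------------------------------------------

def _stack_complex(a: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real/imaginary stacking of a complex linear system."""
    top = np.hstack([a.real, -a.imag])
    bot = np.hstack([a.imag, a.real])
    return np.vstack([top, bot]), np.concatenate([y.real, y.imag])


def basis_pursuit(y: np.ndarray, a: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """min ||X||_1 subject to A X = y, via an interior-point LP.

    The l1 objective is linearized with slack variables t >= |X| and the
    program solved by an interior-point method.  Complex systems are
    stacked into an equivalent real program (the stacked objective is the
    l1 norm of the real/imaginary parts, which shares its minimizer with
    the complex-modulus objective throughout the exact-recovery regime).
    """
    y = np.asarray(y)
    a = np.asarray(a)
    complex_in = np.iscomplexobj(a) or np.iscomplexobj(y)
    if complex_in:
        a_r, y_r = _stack_complex(a.astype(complex), y.astype(complex))
    else:
        a_r, y_r = np.asarray(a, dtype=float), np.asarray(y, dtype=float)
    m, n = a_r.shape
    # variables v = [x, t]; minimize sum(t); x - t <= 0; -x - t <= 0; A x = y
    c = np.concatenate([np.zeros(n), np.ones(n)])
    eye = np.eye(n)
    a_ub = np.block([[eye, -eye], [-eye, -eye]])
    b_ub = np.zeros(2 * n)
    a_eq = np.hstack([a_r, np.zeros((m, n))])
    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=y_r,
        bounds=[(None, None)] * n + [(0, None)] * n,
        method="highs-ipm",
    )
    if not res.success:
        raise RuntimeError(f"basis pursuit LP failed: {res.message}")
    x = res.x[:n]
    if complex_in:
        half = n // 2
        x = x[:half] + 1j * x[half:]
        a_chk = a
    else:
        a_chk = a_r
    resid = float(np.max(np.abs(a_chk @ x - y)))
    if resid > 1e-6:
        raise RuntimeError(f"basis pursuit constraint residual {resid:.2e} too large")
    return x


# ---------------------------------------------------------------------------
# Gradient missing-sample algorithm
# ---------------------------------------------------------------------------

def gradient_reconstruct(
    y: np.ndarray,
    mask: SamplingMask,
    basis: TransformBasis,
    params: GradientParams | None = None,
    return_info: bool = False,
):
    """Recover missing samples by descending the spectrum's l1 norm.

    Each missing sample is perturbed by +-delta; the resulting change of
    the spectral l1 norm forms the gradient estimate

        g(n_i) = (1/N) * (||F(x + delta e_i)||_1 - ||F(x - delta e_i)||_1)

    and the sample moves by -g(n_i).  When a sweep stalls, delta shrinks
    by ``delta_shrink`` (default 3); the run ends once delta drops below
    ``outer_precision``.  Available samples are never modified.  Because
    the transform is linear, F(x +- delta e_i) = F(x) +- delta F[:, i],
    so one sweep costs a single transform plus rank-1 updates.
    """
    params = params or GradientParams()
    y = np.asarray(y)
    n = basis.n
    missing = mask.missing
    x = zero_filled(y, mask)
    complex_signal = np.iscomplexobj(y) or np.iscomplexobj(basis.forward)
    if complex_signal:
        x = x.astype(complex)
    if missing.size == 0:
        return (x, {"stage_l1": []}) if return_info else x
    fwd_missing = basis.forward[:, missing]  # N x m columns for the rank-1 updates
    delta = params.delta_init if params.delta_init is not None else float(np.max(np.abs(x)))
    if delta == 0:
        delta = 1.0
    stage_l1 = []
    for _ in range(params.max_outer):
        if delta < params.outer_precision:
            break
        prev_l1 = np.inf
        for _ in range(params.max_inner):
            spec = basis.forward @ x
            plus = np.abs(spec[:, None] + delta * fwd_missing).sum(axis=0)
            minus = np.abs(spec[:, None] - delta * fwd_missing).sum(axis=0)
            g = (plus - minus) / n
            if complex_signal:
                plus_i = np.abs(spec[:, None] + 1j * delta * fwd_missing).sum(axis=0)
                minus_i = np.abs(spec[:, None] - 1j * delta * fwd_missing).sum(axis=0)
                g = g + 1j * (plus_i - minus_i) / n
            x[missing] -= g
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("gradient reconstruction produced non-finite values")
            cur_l1 = float(np.abs(basis.forward @ x).sum())
            if np.max(np.abs(g)) < delta * params.inner_tol or cur_l1 >= prev_l1:
                break
            prev_l1 = cur_l1
        stage_l1.append(float(np.abs(basis.forward @ x).sum()))
        delta /= params.delta_shrink
    log.debug("gradient stages l1: %s", stage_l1)
    if return_info:
        return x, {"stage_l1": stage_l1}
    return x


# ---------------------------------------------------------------------------
# Proximal operators and Douglas-Rachford
# ---------------------------------------------------------------------------

def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    """prox of lam * ||.||_1: shrink each magnitude by lam (complex-safe)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    x = np.asarray(x)
    mag = np.abs(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mag > lam, 1.0 - lam / np.where(mag > 0, mag, 1.0), 0.0)
    return scale * x


def affine_projection(
    x: np.ndarray, a: np.ndarray, y: np.ndarray, factor=None
) -> np.ndarray:
    """Euclidean projection onto {x : A x = y} (A with full row rank).

    proj(x) = x + A^H (A A^H)^(-1) (y - A x); ``factor`` may carry a
    precomputed Cholesky factorization of A A^H.
    """
    if factor is None:
        gram = a @ a.conj().T
        factor = cho_factor(gram)
    return x + a.conj().T @ cho_solve(factor, y - a @ x)


def douglas_rachford(
    y: np.ndarray,
    a: np.ndarray,
    params: ProxParams | None = None,
) -> np.ndarray:
    """Basis pursuit by Douglas-Rachford splitting.

    Iterates z <- (1 - mu/2) z + (mu/2) rprox_g(rprox_f(z)) with
    f the indicator of {A x = y}, g = lam ||.||_1 and the standard
    reflection rprox h = 2 prox_h - identity; the output is prox_f of the
    fixed point, hence feasible.  Scale-free: lam is applied relative to
    the measurement magnitude.
    """
    params = params or ProxParams()
    y = np.asarray(y)
    a = np.asarray(a)
    scale = float(np.max(np.abs(y))) or 1.0
    lam = params.lam * scale * 0.1
    gram = a @ a.conj().T
    factor = cho_factor(gram)
    z = a.conj().T @ cho_solve(factor, y)  # least-norm feasible start
    if np.iscomplexobj(a) or np.iscomplexobj(y):
        z = z.astype(complex)
    converged = False
    for it in range(params.max_iter):
        x = affine_projection(z, a, y, factor=factor)
        rf = 2.0 * x - z
        rg = 2.0 * soft_threshold(rf, lam) - rf
        z_new = (1.0 - params.mu / 2.0) * z + (params.mu / 2.0) * rg
        step = float(np.max(np.abs(z_new - z)))
        z = z_new
        if step < params.tol * scale:
            converged = True
            break
    if not converged:
        log.warning("Douglas-Rachford hit the iteration cap (%d); returning best iterate",
                    params.max_iter)
    return affine_projection(z, a, y, factor=factor)


# ---------------------------------------------------------------------------
# Total variation
# ---------------------------------------------------------------------------

def _grad2d(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with zero beyond the boundary."""
    gx = np.zeros_like(img)
    gy = np.zeros_like(img)
    gx[:-1, :] = img[1:, :] - img[:-1, :]
    gy[:, :-1] = img[:, 1:] - img[:, :-1]
    return gx, gy


def _div2d(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Negative adjoint of _grad2d (discrete divergence)."""
    div = np.zeros_like(px)
    div[0, :] += px[0, :]
    div[1:-1, :] += px[1:-1, :] - px[:-2, :]
    div[-1, :] += -px[-2, :]
    div[:, 0] += py[:, 0]
    div[:, 1:-1] += py[:, 1:-1] - py[:, :-2]
    div[:, -1] += -py[:, -2]
    return div


def tv_norm(img: np.ndarray) -> float:
    """Isotropic total variation: sum of gradient-vector magnitudes."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("tv_norm expects a 2D array")
    gx, gy = _grad2d(img.astype(float))
    return float(np.sum(np.sqrt(gx * gx + gy * gy)))


def _tv_prox(w: np.ndarray, lam: float, n_iter: int = 30) -> np.ndarray:
    """prox of lam * TV by the projected dual (Chambolle) iteration."""
    px = np.zeros_like(w)
    py = np.zeros_like(w)
    tau = 0.249
    for _ in range(n_iter):
        gx, gy = _grad2d(_div2d(px, py) - w / lam)
        norm = np.sqrt(gx * gx + gy * gy)
        denom = 1.0 + tau * norm
        px = (px + tau * gx) / denom
        py = (py + tau * gy) / denom
    return w - lam * _div2d(px, py)


def radial_fourier_mask(shape: tuple[int, int], n_lines: int) -> ImageMask2D:
    """Frequency mask of equiangular diameters through the centred DC bin.

    Lines are rasterized by fine stepping along each diameter from the
    centre (index N//2 on even grids); every marked point's point
    reflection about the centre (modulo the grid) is marked too, so the
    mask is exactly centro-symmetric and compatible with conjugate
    symmetry of real images.
    """
    if n_lines < 1:
        raise ValueError("need at least one radial line")
    h, w = shape
    max_lines = int(np.ceil(np.pi * max(h, w)))
    if n_lines > max_lines:
        log.warning("n_lines=%d exceeds the ~%d distinct rasterized diameters", n_lines, max_lines)
    mask = np.zeros(shape, dtype=bool)
    ch, cw = h // 2, w // 2
    radius = np.hypot(h, w)
    steps = np.arange(0.0, radius, 0.25)
    for line in range(n_lines):
        theta = np.pi * line / n_lines
        di, dj = np.cos(theta), np.sin(theta)
        for sgn in (1.0, -1.0):  # both radii of the diameter
            ii = np.rint(ch + sgn * steps * di).astype(int)
            jj = np.rint(cw + sgn * steps * dj).astype(int)
            keep = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
            mask[ii[keep], jj[keep]] = True
            mask[(2 * ch - ii[keep]) % h, (2 * cw - jj[keep]) % w] = True
    mask[ch, cw] = True  # DC always measured
    return ImageMask2D(mask, kind="radial-fourier")


def lowmid_dct_mask(
    shape: tuple[int, int],
    r_low: int,
    fraction_mid: float = 0.3,
    seed: int = 0,
) -> ImageMask2D:
    """2D-DCT sampling pattern: the full low-frequency block plus a random
    subset of the middle band.

    Keeps every coefficient with i + j < r_low and a ``fraction_mid``
    random subset of r_low <= i + j < 2 r_low.  This is the measurement
    pattern of the DCT-domain TV route, whose inputs are the numbers of
    low- and middle-frequency components.
    """
    if r_low < 1:
        raise ValueError("r_low must be at least 1")
    if not 0 <= fraction_mid <= 1:
        raise ValueError("fraction_mid must lie in [0, 1]")
    h, w = shape
    ii, jj = np.mgrid[0:h, 0:w]
    band = ii + jj
    rng = np.random.default_rng(seed)
    avail = (band < r_low) | ((band < 2 * r_low) & (rng.random(shape) < fraction_mid))
    avail[0, 0] = True
    return ImageMask2D(avail, kind="dct-lowmid")


def _forward2d(img: np.ndarray, domain: str) -> np.ndarray:
    if domain == "2d-dft":
        return np.fft.fftshift(np.fft.fft2(img, norm="ortho"))
    if domain == "2d-dct":
        return scipy.fft.dctn(img, norm="ortho")
    raise ValueError(f"unknown 2D domain {domain!r}")


def _inverse2d(coeffs: np.ndarray, domain: str) -> np.ndarray:
    if domain == "2d-dft":
        return np.fft.ifft2(np.fft.ifftshift(coeffs), norm="ortho")
    if domain == "2d-dct":
        return scipy.fft.idctn(coeffs, norm="ortho")
    raise ValueError(f"unknown 2D domain {domain!r}")


def tv_reconstruct(
    measured: np.ndarray,
    mask: ImageMask2D,
    domain: str = "2d-dft",
    params: ProxParams | None = None,
    measure_space: str = "transform",
    real_output: bool = True,
) -> np.ndarray:
    """TV-minimizing image consistent with the measured data.

    ``measure_space='transform'``: ``measured`` holds the known transform
    coefficients at the mask positions (2D-DFT coefficients stored
    centred, DC at the array centre).  ``measure_space='pixel'``:
    ``measured`` holds known pixel values.  Both constraints are affine
    with an exact projection (orthonormal transforms), alternated with an
    inner-iterative TV prox inside a Douglas-Rachford loop.
    """
    params = params or ProxParams(max_iter=1200, tol=1e-7)
    avail = mask.available
    vals = np.asarray(measured)
    if vals.shape == avail.shape:
        vals = vals[avail]
    if vals.size != int(avail.sum()):
        raise ValueError("measured values do not match the mask")

    if measure_space == "transform":
        def project(img: np.ndarray) -> np.ndarray:
            coeffs = _forward2d(img, domain)
            coeffs[avail] = vals
            out = _inverse2d(coeffs, domain)
            return out.real if real_output else out
    elif measure_space == "pixel":
        def project(img: np.ndarray) -> np.ndarray:
            out = img.copy()
            out[avail] = vals.real if real_output else vals
            return out
    else:
        raise ValueError("measure_space must be 'transform' or 'pixel'")

    x0 = project(np.zeros(avail.shape))
    scale = float(np.max(np.abs(x0))) or 1.0
    lam = params.lam * scale * 0.05
    z = x0.copy()
    best = x0
    prev_obj = np.inf
    converged = False
    for it in range(params.max_iter):
        x = project(z)
        rf = 2.0 * x - z
        s = _tv_prox(rf, lam)
        z_new = (1.0 - params.mu / 2.0) * z + (params.mu / 2.0) * (2.0 * s - rf)
        step = float(np.max(np.abs(z_new - z)))
        z = z_new
        if (it + 1) % 25 == 0:
            obj = tv_norm(project(z))
            if obj <= prev_obj:
                best = project(z)
            prev_obj = obj
        if step < params.tol * scale:
            converged = True
            break
    out = project(z)
    if tv_norm(out) > prev_obj:
        out = best
    if not converged:
        log.info("TV reconstruction stopped at the iteration cap (%d)", params.max_iter)
    return out


def reshape_1d_to_2d(n: int) -> tuple[int, int, int]:
    """Most-square (rows, cols) factorization of n; returns (rows, cols, pad).

    When n has no factorization with both sides >= 4 (e.g. prime n), the
    length is padded up to the next one that does.
    """
    def best_pair(m: int) -> tuple[int, int] | None:
        pairs = [(d, m // d) for d in range(2, int(np.sqrt(m)) + 1) if m % d == 0]
        pairs = [p for p in pairs if min(p) >= 4 or m < 16]
        return max(pairs, key=min) if pairs else None

    total = n
    while best_pair(total) is None:
        total += 1
    rows, cols = best_pair(total)
    return rows, cols, total - n


def tv_reconstruct_1d(
    x: np.ndarray,
    mask: SamplingMask,
    reshape_cols: int | None = None,
    params: ProxParams | None = None,
) -> np.ndarray:
    """1D recovery through 2D TV minimization.

    The signal is reshaped column-wise into a (near-square) matrix, its
    available samples act as known pixels for the TV solver, the result
    is flattened back and the available samples restored bit-exactly.
    """
    x = np.asarray(x, dtype=float)
    n = mask.n
    if x.size != n:
        raise ValueError("signal length does not match mask")
    if reshape_cols is not None:
        if n % reshape_cols:
            raise ValueError("N must be divisible by reshape_cols")
        rows, cols, pad = n // reshape_cols, reshape_cols, 0
    else:
        rows, cols, pad = reshape_1d_to_2d(n)
    if rows < 2 or cols < 2:
        raise ValueError("degenerate reshape; choose a different column count")
    avail_bool = np.zeros(n + pad, dtype=bool)
    avail_bool[mask.available] = True
    padded = np.zeros(n + pad)
    padded[mask.available] = x[mask.available]
    if pad:  # pad samples are treated as known zeros and discarded afterwards
        avail_bool[n:] = True
    img = padded.reshape((rows, cols), order="F")
    mask2d = ImageMask2D(avail_bool.reshape((rows, cols), order="F"), kind="pixel-random")
    rec = tv_reconstruct(img[mask2d.available], mask2d, domain="2d-dct",
                         params=params, measure_space="pixel")
    out = rec.reshape(-1, order="F")[:n]
    out[mask.available] = x[mask.available]
    return out
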