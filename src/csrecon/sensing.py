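"""Random under-sampling masks, measurement extraction and the CS matrix.

Measurements are time-domain samples kept at random positions:
``y(i) = x(n_i)``.  The compressive-sensing matrix ``A`` is the partial
inverse-transform matrix — the rows of ``inverse`` at the kept positions —
so ``A @ forward(x) == y`` holds exactly for any signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import Signal1D, TransformBasis

__all__ = ["SamplingMask", "Measurements", "random_mask", "full_mask",
           "take_measurements", "cs_matrix", "zero_filled"]


@dataclass
class SamplingMask:
    """Sorted 0-based indices of the available samples of a length-N signal."""

    available: np.ndarray
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.available, dtype=int)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("mask needs at least one available index")
        if idx.size != np.unique(idx).size:
            raise ValueError("mask indices must be unique")
        if idx.min() < 0 or idx.max() >= self.n:
            raise ValueError("mask indices out of range")
        self.available = np.sort(idx)

    @property
    def m(self) -> int:
        return self.available.size

    @property
    def missing(self) -> np.ndarray:
        """The complement index set (samples to be recovered)."""
        out = np.ones(self.n, dtype=bool)
        out[self.available] = False
        return np.flatnonzero(out)

    def boolean(self) -> np.ndarray:
        out = np.zeros(self.n, dtype=bool)
        out[self.available] = True
        return out


@dataclass
class Measurements:
    """Measurement vector with its mask and CS matrix."""

    y: np.ndarray
    mask: SamplingMask
    a: np.ndarray


def random_mask(n: int, fraction_available: float, seed: int) -> SamplingMask:
    """Keep ``round(fraction * n)`` positions drawn uniformly without replacement."""
    if not 0 < fraction_available <= 1:
        raise ValueError("fraction_available must lie in (0, 1]")
    m = int(np.floor(fraction_available * n + 0.5))  # round half away from zero
    if m < 1:
        raise ValueError("fraction keeps no samples")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=m, replace=False)
    return SamplingMask(np.sort(idx), n, seed=seed)


def full_mask(n: int) -> SamplingMask:
    return SamplingMask(np.arange(n), n)


def take_measurements(x: Signal1D | np.ndarray, mask: SamplingMask) -> np.ndarray:
    samples = x.samples if isinstance(x, Signal1D) else np.asarray(x)
    if samples.size != mask.n:
        raise ValueError("signal length does not match mask")
    return samples[mask.available]


def cs_matrix(basis: TransformBasis, mask: SamplingMask) -> np.ndarray:
    """Partial inverse-transform matrix: rows of ``inverse`` at kept positions."""
    if basis.n != mask.n:
        raise ValueError("basis size does not match mask")
    return basis.inverse[mask.available, :]


def zero_filled(y: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Length-N signal with measurements in place and zeros at missing positions."""
    y = np.asarray(y)
    if y.size != mask.m:
        raise ValueError("measurement length does not match mask")
    out = np.zeros(mask.n, dtype=y.dtype if np.iscomplexobj(y) else float)
    out[mask.available] = y
    return out
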