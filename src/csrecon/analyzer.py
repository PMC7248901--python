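"""The statistical analyzer: run configured reconstructions and compare them.

Each run reports concentration measures (l1, Gini) computed twice — on
the transform of the zero-filled available samples ("before") and on the
transform of the reconstruction ("after") — plus the time-domain MSE
against the original and the wall-clock time.  A successful sparse
recovery shows the before/after ordering: l1 drops, Gini rises.  Several
configurations are compared on one shared mask so the numbers are
head-to-head.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import convex, greedy
from .measures import gini_index, l1_measure, mse
from .sensing import SamplingMask, cs_matrix, random_mask, take_measurements, zero_filled
from .transforms import Signal1D, TransformBasis, build_basis, optimize_sigma

__all__ = ["RunConfig", "ComparisonReport", "ALGORITHMS", "evaluate_run", "compare"]

log = logging.getLogger(__name__)

ALGORITHMS = ("omp", "sira", "gdbra", "bp", "dr", "gradient", "tv1d")

#: required parameter keys per algorithm (mirrors each method's inputs)
_REQUIRED_PARAMS = {
    "omp": {"k"},
    "sira": {"p"},
    "gdbra": set(),       # p, c, ell, k all have documented defaults
    "bp": set(),
    "dr": set(),
    "gradient": set(),
    "tv1d": set(),
}


@dataclass
class RunConfig:
    """One reconstruction request: algorithm + basis + sampling."""

    algorithm: str
    basis: str = "dft"
    sigma: float | str | None = None     # HT scale, or "optimal"
    fraction: float = 0.5
    seed: int = 0
    params: dict = field(default_factory=dict)
    mask: SamplingMask | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        missing = _REQUIRED_PARAMS[self.algorithm] - set(self.params)
        if missing:
            raise ValueError(f"{self.algorithm} needs parameter(s): {sorted(missing)}")


@dataclass
class ComparisonReport:
    table: pd.DataFrame
    mask: SamplingMask
    basis_names: list[str]
    best_mse: int | None
    best_l1: int | None
    best_gini: int | None

    def to_json_dict(self) -> dict:
        return {
            "n": int(self.mask.n),
            "m": int(self.mask.m),
            "mask_seed": self.mask.seed,
            "best_mse_row": self.best_mse,
            "best_l1_row": self.best_l1,
            "best_gini_row": self.best_gini,
            "rows": self.table.to_dict(orient="records"),
        }


def _resolve_basis(config: RunConfig, original: Signal1D) -> TransformBasis:
    sigma = config.sigma
    if config.basis == "ht" and sigma == "optimal":
        sigma, _ = optimize_sigma(original)
    return build_basis(config.basis, original.n, sigma=sigma if config.basis == "ht" else None)


def _reconstruct(
    config: RunConfig,
    y: np.ndarray,
    basis: TransformBasis,
    mask: SamplingMask,
) -> np.ndarray:
    """Dispatch one algorithm; returns the reconstructed time signal."""
    p = config.params
    if config.algorithm == "omp":
        a = cs_matrix(basis, mask)
        est = greedy.omp(y, a, int(p["k"]), pair_conjugates=bool(p.get("pair_conjugates", False)))
        return basis.inverse @ est.spectrum()
    if config.algorithm == "sira":
        est = greedy.sira(y, basis, mask, k=int(p.get("k", 0)), p=float(p["p"]))
        return basis.inverse @ est.spectrum()
    if config.algorithm == "gdbra":
        if basis.name != "dft":
            raise ValueError("GDBRA is defined for the DFT domain only")
        est = greedy.gdbra(
            y, mask.available, basis.n,
            ell=int(p.get("ell", 2)), p=float(p.get("p", 1.0)),
            c=p.get("c", "median"), k=p.get("k"),
        )
        return basis.inverse @ est.spectrum()
    if config.algorithm == "bp":
        a = cs_matrix(basis, mask)
        return basis.inverse @ convex.basis_pursuit(y, a)
    if config.algorithm == "dr":
        a = cs_matrix(basis, mask)
        dr_params = convex.ProxParams(**p) if p else None
        return basis.inverse @ convex.douglas_rachford(y, a, dr_params)
    if config.algorithm == "gradient":
        g_params = convex.GradientParams(**p) if p else None
        return convex.gradient_reconstruct(y, mask, basis, g_params)
    if config.algorithm == "tv1d":
        return convex.tv_reconstruct_1d(zero_filled(y, mask), mask,
                                        reshape_cols=p.get("reshape_cols"))
    raise AssertionError("unreachable")


def evaluate_run(
    config: RunConfig,
    original: Signal1D,
    mask: SamplingMask | None = None,
) -> dict:
    """Execute one configured reconstruction and measure it.

    Returns a flat report row; algorithm failures are captured in the
    ``error`` field rather than raised, so batch comparisons survive a
    single bad run.
    """
    mask = mask or config.mask or random_mask(original.n, config.fraction, config.seed)
    basis = _resolve_basis(config, original)
    y = take_measurements(original, mask)
    before_spec = basis.forward @ zero_filled(y, mask)
    row: dict = {
        "algorithm": config.algorithm,
        "basis": basis.name,
        "sigma": basis.sigma,
        "n": original.n,
        "m": mask.m,
        "l1_before": l1_measure(before_spec),
        "gini_before": gini_index(before_spec),
        "l1_after": None,
        "gini_after": None,
        "mse": None,
        "elapsed_s": None,
        "error": None,
    }
    t0 = time.perf_counter()
    try:
        rec = _reconstruct(config, y, basis, mask)
    except Exception as exc:  # keep the comparison alive
        log.warning("run %s failed: %s", config.algorithm, exc)
        row["error"] = f"{type(exc).__name__}: {exc}"
        return row
    row["elapsed_s"] = time.perf_counter() - t0
    after_spec = basis.forward @ rec
    row["l1_after"] = l1_measure(after_spec)
    row["gini_after"] = gini_index(after_spec)
    row["mse"] = mse(rec, original.samples)
    return row


def compare(configs: list[RunConfig], original: Signal1D) -> ComparisonReport:
    """Run several configurations on one shared mask and tabulate the metrics.

    The mask comes from the first configuration (explicit mask, else
    fraction + seed); any conflicting explicit mask is rejected so every
    row answers the same question.  Rows achieving the best MSE, l1 and
    Gini are flagged.
    """
    if not configs:
        raise ValueError("need at least one run configuration")
    first = configs[0]
    shared = first.mask or random_mask(original.n, first.fraction, first.seed)
    for cfg in configs:
        if cfg.mask is not None and not np.array_equal(cfg.mask.available, shared.available):
            raise ValueError("all configurations must share the same mask")
    rows = [evaluate_run(cfg, original, mask=shared) for cfg in configs]
    table = pd.DataFrame(rows)
    ok = table["error"].isna()

    def _best(col: str, smaller: bool) -> int | None:
        sub = table.loc[ok, col].astype(float)
        if sub.empty or sub.isna().all():
            return None
        return int(sub.idxmin() if smaller else sub.idxmax())

    return ComparisonReport(
        table=table,
        mask=shared,
        basis_names=[cfg.basis for cfg in configs],
        best_mse=_best("mse", smaller=True),
        best_l1=_best("l1_after", smaller=True),
        best_gini=_best("gini_after", smaller=False),
    )
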