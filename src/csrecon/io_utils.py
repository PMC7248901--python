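"""Readers/writers, the QRS windowing utility and batch-job execution.

1D signals travel as single-column plain text or CSV; 2D images as 8-bit
grayscale PNG/TIFF; masks as single-column integer text.  A job file is a
JSON document selecting the input, the sampling, and one or more
algorithm configurations; running it produces a delimited report table, a
JSON report and (optionally) plots.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analyzer import ALGORITHMS, RunConfig, compare
from .sensing import SamplingMask
from .transforms import Signal1D

__all__ = [
    "SchemaError",
    "JobSpec",
    "read_signal",
    "write_signal",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "extract_qrs",
    "load_job",
    "run_job",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A job/config document does not match the expected schema."""


def read_signal(path: str | Path) -> Signal1D:
    """One numeric column (or one row) of samples, plain text or CSV."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty signal file: {path}")
    delimiter = "," if "," in text else None
    try:
        data = np.loadtxt(path, delimiter=delimiter, dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric content in {path}: {exc}") from None
    data = np.atleast_1d(data).ravel()
    return Signal1D(data)


def write_signal(path: str | Path, x: Signal1D | np.ndarray) -> None:
    samples = x.samples if isinstance(x, Signal1D) else np.asarray(x)
    np.savetxt(path, np.real_if_close(samples), fmt="%.17g")


def read_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A) to grayscale
        img = img[..., :3].mean(axis=-1)
    return img.astype(float)


def write_image(path: str | Path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    out = np.clip(np.asarray(img), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)


def read_mask(path: str | Path, n: int) -> SamplingMask:
    idx = np.loadtxt(path, dtype=int, ndmin=1)
    return SamplingMask(idx, n)


def write_mask(path: str | Path, mask: SamplingMask) -> None:
    np.savetxt(path, mask.available, fmt="%d")


def extract_qrs(x: Signal1D, center: int, half_width: int) -> Signal1D:
    """Window of length 2*half_width + 1 centred on a user-chosen beat.

    Finding beat centres is left to the user (or an external detector);
    windows running off either edge are clipped with a warning.
    """
    if not 0 <= center < x.n:
        raise ValueError("center out of range")
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    lo = center - half_width
    hi = center + half_width + 1
    if lo < 0 or hi > x.n:
        warnings.warn(f"QRS window clipped to [{max(lo, 0)}, {min(hi, x.n)})", stacklevel=2)
        lo, hi = max(lo, 0), min(hi, x.n)
    win = x.samples[lo:hi]
    if win.size == 1:  # Signal1D requires length >= 2; duplicate degenerate window
        return Signal1D(np.repeat(win, 2), period=x.period)
    return Signal1D(win, period=x.period)


# ---------------------------------------------------------------------------
# Jobs
# ---------------------------------------------------------------------------

@dataclass
class JobSpec:
    """A validated batch job."""

    input_path: Path
    mode: str                      # "1d" or "2d"
    configs: list[RunConfig]
    output_dir: Path
    seed: int = 0
    make_plots: bool = False
    image_params: dict = field(default_factory=dict)


def _require(doc: dict, key: str, kind, where: str):
    if key not in doc:
        raise SchemaError(f"missing key {key!r} in {where}")
    val = doc[key]
    if not isinstance(val, kind):
        raise SchemaError(f"key {key!r} in {where} must be {kind}")
    return val


def load_job(path: str | Path) -> JobSpec:
    """Parse and validate a JSON job file."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON in {path}: {exc}") from None
    if not isinstance(doc, dict):
        raise SchemaError("job document must be a JSON object")
    mode = _require(doc, "mode", str, "job")
    if mode not in ("1d", "2d"):
        raise SchemaError("mode must be '1d' or '2d'")
    input_path = Path(_require(doc, "input", str, "job"))
    seed = int(doc.get("seed", 0))
    configs: list[RunConfig] = []
    if mode == "1d":
        runs = _require(doc, "runs", list, "job")
        if not runs:
            raise SchemaError("job needs at least one run")
        for i, run in enumerate(runs):
            if not isinstance(run, dict):
                raise SchemaError(f"run {i} must be an object")
            algorithm = _require(run, "algorithm", str, f"run {i}")
            if algorithm not in ALGORITHMS:
                raise SchemaError(f"run {i}: unknown algorithm {algorithm!r}")
            try:
                configs.append(
                    RunConfig(
                        algorithm=algorithm,
                        basis=run.get("basis", "dft"),
                        sigma=run.get("sigma"),
                        fraction=float(run.get("fraction", doc.get("fraction", 0.5))),
                        seed=int(run.get("seed", seed)),
                        params=run.get("params", {}),
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"run {i}: {exc}") from None
    return JobSpec(
        input_path=input_path,
        mode=mode,
        configs=configs,
        output_dir=Path(doc.get("output_dir", ".")),
        seed=seed,
        make_plots=bool(doc.get("plots", False)),
        image_params=doc.get("image", {}),
    )


def _plot_run(out_dir: Path, original: Signal1D, report) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        log.warning("matplotlib unavailable; skipping plots")
        return
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(np.real(original.samples), label="original", lw=1)
    ax.plot(report.mask.available, np.real(original.samples[report.mask.available]),
            "r.", ms=3, label="available")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("input signal and available samples")
    fig.tight_layout()
    fig.savefig(out_dir / "signal.png", dpi=120)
    plt.close(fig)


def run_job(spec: JobSpec) -> int:
    """Execute a job; returns a process exit status (0 = success)."""
    try:
        spec.output_dir.mkdir(parents=True, exist_ok=True)
        if spec.mode == "1d":
            original = read_signal(spec.input_path)
            log.info("job: %d samples, %d run(s), seed %d",
                     original.n, len(spec.configs), spec.seed)
            report = compare(spec.configs, original)
            report.table.to_csv(spec.output_dir / "report.csv", index=False)
            (spec.output_dir / "report.json").write_text(
                json.dumps(report.to_json_dict(), indent=2, default=_json_default)
            )
            if spec.make_plots:
                _plot_run(spec.output_dir, original, report)
        else:
            from . import convex
            from .measures import mse as _mse, psnr as _psnr

            img = read_image(spec.input_path)
            n_lines = int(spec.image_params.get("n_lines", 20))
            mask2d = convex.radial_fourier_mask(img.shape, n_lines)
            measured = convex._forward2d(img, "2d-dft")[mask2d.available]
            rec = convex.tv_reconstruct(measured, mask2d, domain="2d-dft")
            write_image(spec.output_dir / "reconstruction.png", rec)
            summary = {
                "n_lines": n_lines,
                "fraction_measured": mask2d.fraction,
                "mse": _mse(rec, img),
                "psnr_db": _psnr(rec, img, peak=255.0),
            }
            (spec.output_dir / "report.json").write_text(json.dumps(summary, indent=2))
        return 0
    except (OSError, ValueError, RuntimeError) as exc:
        log.error("job failed: %s", exc)
        return 1


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
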