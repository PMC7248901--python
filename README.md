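# csrecon

Compressive-sensing (CS) reconstruction and sparsity analysis for 1D
biomedical signals (ECG and extracted QRS complexes, EEG, EOG,
respiration) and 2D grayscale images such as MRI slices.

Biomedical signals are often available only in part: samples are dropped
to speed up acquisition or transmission, lost on noisy channels, or
discarded as corrupted. If the signal is sparse in some transform domain
— only K of its N coefficients are non-negligible — it can still be
recovered from M < N samples. `csrecon` implements the full pipeline
for doing that and, just as importantly, for *judging* the result, so
that the right transform/algorithm combination can be picked for a given
signal class.

## What is inside

**Transforms** (`csrecon.transforms`) — three sparsifying bases behind one
matrix convention `X = Ψx`:

- DFT, unnormalized forward with the 1/N on the inverse;
- orthonormal DCT-II;
- the Hermite transform (HT): expansion in Hermite functions
  ψ_p(t/σ) evaluated at the roots of the order-N Hermite polynomial,
  with Gauss–Hermite weights so the pair inverts exactly.  Hermite
  functions share the morphology of QRS complexes, so a beat is
  HT-sparse when the scale σ is right; `optimize_sigma` finds that scale
  by sinc-resampling the signal onto σ-scaled nodes and minimizing the
  spectrum's ℓ1 norm, σ_opt = argmin_σ ‖HT{x(σn_m)}‖₁.

**Sensing** (`csrecon.sensing`) — random masks keeping M = round(f·N)
sample positions, measurements y(i) = x(n_i), and the CS matrix **A**
(rows of Ψ⁻¹ at the kept positions), so y = A X exactly.

**Reconstruction** — seven algorithm families:

| algorithm | idea | a-priori input |
|---|---|---|
| `basis_pursuit` | min ‖X‖₁ s.t. AX = y, interior-point LP | — |
| `gradient_reconstruct` | treat missing samples as variables, descend the spectral ℓ1 with a shrinking ±Δ probe | — |
| `omp` | greedy: pick the column most correlated with the residual, re-fit, repeat | K |
| `sira` | one pass: threshold the zero-filled spectrum at an analytic missing-sample-noise level, then least squares | P |
| `gdbra` | detect DFT support from generalized deviations of the demodulated available samples | p, c, L, K |
| `douglas_rachford` | proximal splitting: reflect the soft-threshold and the affine projection to a basis-pursuit fixed point | λ, μ |
| `tv_reconstruct` / `tv_reconstruct_1d` | min ‖img‖_TV subject to the data (radial 2D-DFT lines, DCT low/middle bands, or known pixels) | lines / bands |

**Measures** (`csrecon.measures`) — the statistical analyzer's metrics:
ℓ1 concentration, the Gini sparsity index
G(x) = 1 − 2 Σᵢ (|x_s(i)|/‖x‖₁)·((N − i + ½)/N) ∈ [0, 1]
(higher = sparser, scale invariant), time-domain MSE, PSNR, and the
quantization-error bound e² = 3.01 log₂K − 6.02B − 7.78 dB for B-bit
measurements.

**Analyzer** (`csrecon.analyzer`) — run one or many configured
reconstructions on a single shared mask and tabulate ℓ1/Gini before and
after reconstruction, MSE and runtime, flagging the best rows.

**Synthetic data** (`csrecon.synth`) — K-sparse signals in any basis,
QRS-like Hermite mixtures, piecewise-constant phantoms — all with
declared ground truth.

## Worked example

```python
import numpy as np
from csrecon import RunConfig, Signal1D, compare, gen_sparse_signal

gt = gen_sparse_signal(n=128, k=3, basis="dft", seed=7, mode="real")
signal = Signal1D(gt.data)
configs = [
    RunConfig("gradient", basis="dft", fraction=0.5, seed=3),
    RunConfig("omp", basis="dft", fraction=0.5, seed=3,
              params={"k": 3, "pair_conjugates": True}),
    RunConfig("sira", basis="dft", fraction=0.5, seed=3, params={"p": 0.99}),
]
report = compare(configs, signal)
```

Output (formatted):

```
algorithm  l1_before  l1_after  gini_before  gini_after     mse
 gradient   1669.942   678.143        0.377       0.955 2.1e-17
      omp   1669.942   678.143        0.377       0.955 5.6e-28
     sira   1669.942   678.143        0.377       0.955 5.7e-28
```

The signal has three real sinusoidal components and half of its 128
samples were kept. Every algorithm recovers it essentially exactly (MSE
at numerical noise). The before/after columns show what reconstruction
does to the spectrum of the zero-filled signal: the ℓ1 concentration
drops (1669.9 → 678.1, the ℓ1 of the true 3-component spectrum) and the
Gini index rises (0.38 → 0.95), i.e. the missing-sample noise spread
across all frequency bins has been removed and the energy re-concentrated
onto the true support.

The same runs from a shell:

```
csrecon simulate --kind sparse --n 128 --k 3 --mode real --seed 7 --out sig.txt
csrecon reconstruct sig.txt --algorithm omp --param k=3 \
        --param pair_conjugates=true --fraction 0.5 --seed 3 --out rec.txt
csrecon compare job.json        # several algorithms, one shared mask
csrecon image phantom.png --n-lines 20 --out rec.png
```

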