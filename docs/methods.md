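# Methods

This note records the models behind `csrecon`, the conventions that all
thresholds depend on, the calibration derivations, the numerical choices
made where the design was genuinely open, and what the synthetic-data
batteries do and do not demonstrate.

## Signal model and transform conventions

A length-N signal x(n) is K-sparse in a basis if its spectrum
X = Ψx has only K non-negligible entries. Measurements are time-domain
samples kept at M random positions, y(i) = x(n_i); the CS matrix A
consists of the corresponding M rows of Ψ⁻¹, so y = AX holds exactly.

Conventions (every detection threshold below assumes them):

- **DFT**: forward unnormalized, Ψ[k,n] = e^{−j2πkn/N}; the 1/N factor
  rides on the inverse. Spectrum coefficients of a unit-amplitude
  complex exponential therefore have magnitude N.
- **DCT**: orthonormal DCT-II, c(0) = √(1/N), c(k>0) = √(2/N).
- **HT**: signals live on the roots n_m of the order-N Hermite
  polynomial (computed by the Golub–Welsch eigenvalue method). Row p of
  the forward matrix is ψ_p(σn_m; σ) / (N·ψ_{N−1}(σn_m; σ)²); the
  squared top-order Hermite function in the denominator is exactly the
  Gauss–Hermite quadrature weight, which is why the pair inverts to
  machine precision and why the rows are orthonormal under that
  quadrature. Hermite functions are evaluated by the stable three-term
  recurrence on the *normalized* functions (the Gaussian folded in from
  φ₀), never by the derivative formula, which overflows beyond small
  orders.

Uniformly sampled signals are indexed on a centred grid, sample i at
time (i − ⌊N/2⌋)·T, because Hermite nodes are symmetric about zero.
Resampling onto σ-scaled nodes uses the truncated sinc (band-limited)
interpolation over all N samples. Truncation is the dominant error:
for a pure sine of period 8 the interpolation error at an off-grid node
is ≈ 4·10⁻³ at N = 64 and halves with each doubling of N.

**Scale search.** σ_opt = argmin over a grid of ‖HT{x(σn_m)}‖₁ (default
grid: 50 log-spaced points in [0.1, 10]; first minimum wins on ties).
The ℓ1 curve is exactly proportional under signal scaling, so σ_opt is
scale invariant. Caveat: the matched scale is the *global* ℓ1 minimum
only when the mixture's ℓ1 at match (Σ|a_p|) is not far above its ℓ2;
mixtures over consecutive low orders (the QRS-like regime) behave well,
while sparse mixtures over widely spaced same-parity orders with mixed
signs can have a lower ℓ1 at a mismatched scale.

## Missing-sample noise and the SIRA threshold

Zero-filling the missing samples perturbs every off-support coefficient
of the spectrum. For a uniformly random mask keeping M of N samples,
one coefficient X₀(k) = Σ_{n kept} x(n)Ψ[k,n] is a without-replacement
sum from a population whose full sum is zero (off support), so

    Var X₀(k) = M(N−M)/(N−1) · popvar(x(n)Ψ[k,n]).

Estimating the population sum from the kept samples (scale by N/M)
gives the working forms:

- DFT (|Ψ| = 1):  σ²_MS = M(N−M)/(N−1) · (Σᵢ|y(i)|²)/M;
- DCT (Ψ² ≈ 1/N): σ²_MS = M(N−M)/(N²(N−1)) · ΣA_i², with
  ΣA_i² = (N/M)·Σ y² (Parseval from the kept samples);
- HT: rows are far from constant-magnitude, so the per-coefficient
  population variance is computed from the basis matrix itself and
  averaged over k. The single-mask estimate is noisy (±40% at N = 64)
  but unbiased; tests verify the mask-averaged estimate against Monte
  Carlo.

The detection threshold T is the level below which all noise-only
coefficients stay with probability P. DFT noise coefficients are
complex Gaussian, their squared magnitudes exponential, hence

    T_DFT = sqrt(−σ²_MS · ln(1 − P^{1/(N−K)}))    (natural log; N−K ≈ N).

DCT and HT noise coefficients are real Gaussian, so T is the half-normal
max-quantile, T = σ_MS·√2·erfinv(P^{1/N}), computed exactly via
`scipy.special.erfinv` rather than through the a = 0.147 rational
approximation of erfinv that this formula is usually carried with.

Monte-Carlo calibration at N = 128, M = 64, P = 0.99 (10,000 masks):
the closed-form T_DFT sits 4% above the empirical 0.99-quantile of the
maximum noise magnitude, and SIRA's full-support detection rate on
3-component unit-amplitude signals is 100% over 500 trials. SIRA
detection compares |X₀(k)| directly against T — the variance derivation
and the threshold share the unnormalized-forward convention, so no extra
1/N rescaling appears.

A false alarm (a noise coefficient above T) is harmless in the noiseless
setting: the least-squares re-fit on an enlarged support still solves
the consistent system exactly. A missed component is what breaks
recovery; that is why thresholds are calibrated against the maximum
noise quantile.

## GDBRA

Demodulating the kept samples at a frequency actually present in the
signal turns that component into a constant, lowering the generalized
deviation GD(k) = mean|demod − mean(demod)|^L by the component's power.
Defaults: L = 2, threshold p·median(GD) with p = 1; when the sparsity K
is supplied the support is the K smallest deviations. The deviations are
derived for complex exponentials; for real sinusoids each conjugate pair
contributes half-amplitude components and the GD gap shrinks
accordingly.

## Convex solvers

**Basis pursuit** is recast as the LP min Σt s.t. −t ≤ X ≤ t, AX = y and
solved by HiGHS's interior-point method; complex systems are stacked
into real/imaginary blocks. The stacked objective (Σ|Re| + Σ|Im|) is a
surrogate for the complex-modulus ℓ1; in the exact-recovery regime both
share the sparse minimizer, which the cross-validation below confirms.
The returned solution must satisfy ‖AX − y‖_∞ < 10⁻⁶ or the call fails.

**Douglas–Rachford** iterates
z ← (1 − μ/2)z + (μ/2)·rprox_g(rprox_f(z)) with f the indicator of
{AX = y}, g = λ‖·‖₁, rprox_h = 2prox_h − I, and returns prox_f of the
fixed point so the output is always feasible. prox_g is the complex-safe
soft threshold; prox_f the affine projection x + A^H(AA^H)⁻¹(y − Ax)
with a cached Cholesky factor. Defaults λ = 1 (applied relative to
max|y| with a 0.1 factor, making the iteration scale free), μ = 1,
stop when the fixed-point increment falls below 10⁻¹⁰·max|y| (cap 4000
iterations, flagged if hit). Cross-validation: on 50 random sparse
instances (N ≤ 32) BP and DR agree in support on all instances with a
worst ℓ1 gap ≈ 3·10⁻⁹.

**Gradient algorithm.** Missing samples start at zero and move against
the two-sided probe g(n_i) = (‖F(x+Δe_i)‖₁ − ‖F(x−Δe_i)‖₁)/N (plus an
imaginary probe for complex signals). Because the transform is linear,
F(x ± Δe_i) = F(x) ± ΔF[:,i], so one sweep costs a single transform and
rank-1 updates. The inner loop stops when the largest update falls
below Δ·10⁻³, when the spectral ℓ1 stops decreasing, or at 150 sweeps;
then Δ shrinks by 3 (from Δ₀ = max|x⁰|) until Δ < 10⁻⁷. The spectral ℓ1
recorded at the end of each Δ-stage is non-increasing — asserted in
tests on every instance.

## Total variation

TV is the isotropic form: Σ over pixels of the gradient-vector magnitude
with forward differences and zero contribution beyond the boundary.
Reconstruction minimizes TV subject to exact data consistency via the
same Douglas–Rachford loop; the data projection is exact (orthonormal
2D-DFT/DCT coefficient replacement, or pixel replacement), and prox of
λ·TV, which has no closed form, uses a fixed budget of 30 iterations of
the projected-dual (Chambolle) scheme with step 0.249. λ is set to
0.05·max|zero-filled| — it affects the convergence path, not the
constrained fixed point. The TV objective is monitored every 25
iterations and the best feasible iterate is kept.

Sampling patterns:

- **Radial Fourier**: equiangular diameters through the centred DC bin,
  rasterized by 0.25-pixel stepping in both directions; every marked
  point's point reflection modulo the grid is marked too, so the mask is
  exactly centro-symmetric (compatible with conjugate symmetry of real
  images, whose measurements are complex coefficient samples). A 64×64
  two-region phantom reconstructs from 20 lines (≈ 35% of coefficients)
  to PSNR ≈ 100 dB — numerically exact recovery.
- **DCT low+middle band**: the full block i + j < r_low plus a random
  fraction of r_low ≤ i + j < 2r_low, mirroring the "number of low and
  middle frequency components" inputs of the DCT-based TV route.

**1D signals through 2D TV**: the signal is reshaped column-wise into
the most-square factorization of N (padded to the next factorable length
when N is prime, pads treated as known zeros and discarded), the kept
samples act as known pixels, and the available samples are restored
bit-exactly afterwards. Limitation: with pixel constraints a staircase
is recovered only up to boundary ambiguity — missing pixels at a region
boundary admit feasible images of equal or lower TV — so relative MSE is
typically 10⁻⁴–10⁻³ and can reach ~10⁻² for high-contrast staircases.
The DCT-band measurement route recovers such images exactly.

## Synthetic data and what the batteries show

Generators produce K-sparse spectra (component amplitudes in [1, 2] by
default, bounded away from zero so support recovery is well posed; DFT
components get random phases, real mode plants conjugate pairs),
QRS-like Hermite mixtures of low consecutive orders at scale λ, and
nested-ellipse phantoms with 8-bit gray levels. Each generator declares
its exact support and coefficients, and the declared spectrum matches
the forward transform of the generated data to 10⁻¹⁰.

The standing battery runs all six 1D solvers on 3-sparse unit-amplitude
random-phase complex exponentials, N = 128, 50% of samples kept, 200
trials, success = time-domain MSE < 10⁻⁶. Unit amplitude matches the
regime for which the SIRA threshold calibration is quoted; complex
exponentials are the signal class for which GDBRA's deviations are
derived. On this battery every algorithm succeeds in 100% of trials,
and on every successful run the reconstructed spectrum has lower ℓ1 and
higher Gini index than the zero-filled one.

These synthetic conditions exercise every code path but idealize real
data in known ways: no measurement noise, exactly sparse spectra,
components bounded away from zero, and uniformly random masks. Passing
the battery therefore demonstrates correctness of the machinery, not
clinical-grade performance on recorded ECG/EEG, where spectra are only
approximately sparse and the greedy methods' a-priori inputs (K, P)
must be chosen with care.

## Problem sizes and determinism

The default experiment sizes — N = 128 batteries of 200 trials, 10,000
Monte-Carlo masks for the threshold calibration, 500 detection trials,
64×64 phantoms with 20 radial lines — were chosen as the smallest sizes
at which the asymptotic arguments above (finite-population variance,
max-quantile calibration, TV exact recovery) visibly hold; everything
completes in about a minute on one CPU. All randomness flows through
`numpy.random.default_rng` seeded per run; batteries derive per-trial
seeds from a single master seed, so every reported number is exactly
reproducible. Wall-clock times are reported but never asserted.
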