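# Methods

## Model

Given n samples x_i ∈ R^d, the (uncentered) second-moment matrix is
S = (1/n) Σ_i x_i x_iᵀ. The leading sparse principal component is computed
as the minimizer of the strongly convex composite objective

    P(z) = F(z) + R(z),
    F(z) = ½ zᵀ(λI − S)z − wᵀz,     R(z) = γ‖z‖₁,

with λ > λ₁(S) (so that λI − S ≻ 0 and F is strongly convex with modulus
λ − λ₁(S)), a fixed direction vector w ∈ R^d, and a sparsity weight γ ≥ 0.
At γ = 0 the minimizer is z* = (λI − S)⁻¹w, which amplifies the component
of w along the leading eigenspace by 1/(λ − λ₁); as λ ↓ λ₁ the direction of
z* converges to the leading eigenvector. The ℓ1 term produces exact zeros
through soft-thresholding, so support sizes are well defined without any
epsilon cut-offs.

F decomposes as the average of n per-sample losses
f_i(z) = ½ zᵀ(λI − x_i x_iᵀ)z − wᵀz, which is what the stochastic solvers
exploit. S is never materialized: every S z product is computed as
(1/n) Xᵀ(X z), with sparse-aware per-row products for count data.

**Centering.** S is the uncentered second moment by convention. An explicit
`center_data` helper subtracts feature means when a caller wants a true
covariance; nothing centers implicitly.

## Solvers

**Prox-SVRG** (the main algorithm). Epoch s computes the full gradient at a
reference point z̃ and then performs m inner steps

    v_k = (λI − x_i x_iᵀ)(z_{k−1} − z̃) + ∇F(z̃),
    z_k = prox_{ηγ‖·‖₁}(z_{k−1} − η v_k),

sampling i uniformly with replacement (a without-replacement option
exists). v_k is an exact unbiased estimate of ∇F(z_{k−1}) — averaging it
over all n samples reproduces the full gradient to machine precision — and
its deviation from ∇F(z_{k−1}) vanishes as both z_{k−1} and z̃ approach the
optimum, which is what allows a constant step size and a geometric rate.
The new reference point is the average of the inner iterates by default
("last" is available, see the stopping discussion).

For 0 < η < 1/(4 L_Q), with L_Q = max_i L_i the worst per-sample gradient
Lipschitz constant, the expected suboptimality contracts per epoch by

    ρ = 1/(ℓ(1 − 4L_Qη)mη) + 4L_Qη(m+1)/((1 − 4L_Qη)m),

valid whenever ρ < 1. ℓ is the optimal-strong-convexity constant; it is not
computable in general, so the package defaults to the conservative valid
choice ℓ = λ − λ̂₁(S) and lets callers override it. `theoretical_rate`
warns (not errors) when ρ ≥ 1.

**Prox-SGD baseline.** The same loop with v_k = ∇f_i(z_{k−1}) and no
correction, with an optional 1/k step-size decay. Its gradient deviation
does not vanish at the optimum, which is visible in the per-epoch
`vk_variance` diagnostic: the mean of ‖v_k − ∇F(z_{k−1})‖² over a small
number of instrumented inner iterations (each probe costs one full data
pass, so 4 probes per epoch by default).

**Deterministic oracles.** An ISTA reference solver (proximal full-gradient
iteration with η = 1/L, L = ‖λI − S‖₂) and a closed-form γ = 0 solve
(Cholesky for d ≤ 2000, conjugate gradients on the implicit operator above
that) provide independent routes against which every stochastic result is
validated; the suite requires agreement in objective to 1e−6 and the
closed-form residual to 1e−8.

## Hyperparameter heuristics

`auto_hyperparams` derives, from the power-iteration estimate λ̂₁:

* λ = (1 + margin)·λ̂₁, margin default 0.05 — large enough for strict
  convexity under estimation error, small enough that z* stays aligned with
  the leading eigenvector and m = Θ(L_Q/(λ − λ̂₁)) stays moderate;
* η = θ_η/(4 L_Q), θ_η ∈ (0,1) default 0.4, so the rate condition holds by
  construction;
* m = ceil(c_m·L_Q/(λ − λ̂₁)), default c_m = 2, clamped to [1, 10n].

The defaults give fast practical convergence; they do **not** make the
theoretical ρ < 1 (the second rate term alone is ≈ θ_η/(1−θ_η)). Where a
certified contraction is wanted the validation suite uses θ_η = 0.2 and
c_m = 50, which yields ρ ≈ 0.7–0.8 on its fixtures.

**Two L_Q modes, and when the spectral heuristic fails.** `mode="paper"`
takes L_Q = λ̂₁(S), the common practice for step-size selection.
`mode="exact"` computes L_i = ‖λI − x_i x_iᵀ‖₂ = max(λ, |‖x_i‖² − λ|) and
L_Q = max_i L_i. The spectral heuristic can under-estimate the per-sample
curvature by orders of magnitude: for i.i.d. N(0,1) data, ‖x_i‖² ≈ d while
λ₁(S) ≈ (1+√(d/n))², so at n = 2000, d = 100 the heuristic step size is
~100× too large and the inner loop diverges (the solvers detect the
overflow and raise a numeric error naming the epoch). The validation suite
therefore uses exact mode for its d ≥ 100 Gaussian fixtures; the spectral
heuristic is fine when d is small or rows are normalized.

## Choosing w, and support recovery

w breaks the symmetry of the quadratic surrogate; γ is only meaningful on
[0, ‖w‖∞], since for γ ≥ ‖w‖∞ the zero vector satisfies 0 ∈ ∂P(0) and the
solution is exactly z = 0 (verified as an exact fixed point in the suite).
The default is w ~ N(0, I) from a dedicated, logged seed, and w can always
be supplied explicitly.

A random w is **not** suitable when the recovered support matters. The
stationarity condition at a coordinate with z_j = 0 is |(Sz)_j + w_j| ≤ γ:
wherever the data are uninformative, (Sz)_j is negligible and coordinates
deactivate in order of |w_j| — the path reflects w, not the data.
Meanwhile the planted signal deactivates near γ ≈ (vᵀw)/Σ_{j∈supp}|v_j|,
so exact recovery would need an atypically aligned draw. Measured on the
spiked fixture below, the best-on-path support F1 with random w is ≈ 0.09.
The package's recommended practice (`spectral_w`) is to set w to the
power-iteration eigenvector estimate of S. This is the same alignment that
a warm-started reconstruct-and-recover path experiment has — when the
"known" component is itself the output of a previous fit with the same w,
w and the component are correlated by construction — and it makes recovery
exact on both recovery fixtures (F1 = 1.0 across seeds). The CLI keeps the
random-w default; the recovery pipelines in the test suite and acceptance
script use `spectral_w`.

## Regularization path and components

The path solves an ascending γ grid (default: 30 log-spaced points from
1e−3·‖w‖∞ to ‖w‖∞), warm-starting each solve from the previous solution.
Grid points with γ ≥ ‖w‖∞ are solved from the zero start instead, where 0
is an exact fixed point; a warm start would only approach the (provably
zero) solution asymptotically and leave ~1e−8 residuals.

Components beyond the first use Hotelling deflation: after a unit loading
v is found, S ← S − (vᵀSv)vvᵀ, applied matvec-only and threaded through the
per-sample gradients so SVRG's unbiasedness is preserved. On exact
eigenvectors Hotelling deflation annihilates the found direction and leaves
the rest of the spectrum untouched (projection deflation is available as a
labeled alternative for spectral analysis). For each component λ̂₁, λ, η, m
are re-derived on the deflated operator. Loadings are normalized to unit
ℓ2 norm with the sign fixed so the largest-magnitude entry is positive.
The first component always uses the caller's w (so p = 1 reproduces a
direct fit); later components default to the spectral w of the deflated
operator (`w_mode="spectral"`), with `w_mode="random"` drawing from a
seeded stream.

## Stopping rules

Default: a fixed number of epochs T. The alternative `support_stable` rule
stops once the nonzero pattern of the epoch point is unchanged for
`patience` (default 5) consecutive epochs. For pattern-stabilization
comparisons the epoch point should be the **last** inner iterate
(`tilde_update="last"`): the average of inner iterates is zero only where
every iterate is zero, so for any stochastic method it is almost surely
dense and a dense pattern would look spuriously "stable". With last-iterate
points the rule discriminates as intended: near the optimum SVRG's probe
gradients satisfy |v_j| ≤ γ on inactive coordinates, so its exact zeros
persist, while prox-SGD's per-sample gradient noise keeps flipping
coordinates at its variance floor and the pattern never settles at a
constant step size.

## Synthetic generators

* `gen_gaussian_matrix` — i.i.d. N(0,1) entries; the convergence and
  timing-style benchmarks.
* `gen_spiked_data` — population covariance I + (strength−1)vvᵀ with a
  planted k-sparse unit v of equal-magnitude entries (random support and
  signs). Equal magnitudes make support recovery crisply defined.
* `gen_pc_reconstructed_cov` — Σ = λ₁vvᵀ + noise·E (E symmetric Gaussian),
  eigenvalue-clipped to PSD, sampled as Gaussian rows; `v` may be supplied
  explicitly to express the reconstruct-and-recover experiment.
* `gen_emr_counts` — sparse non-negative integer matrix emulating
  per-patient diagnosis-code counts: log-series per-row record counts
  (right-skewed, median < mean), power-law code popularity, geometric
  entry values, CSR storage.

What the generators do **not** emulate: demographic or diagnostic
structure of real medical-record cohorts (code co-occurrence, age/sex
strata), heavy-tailed feature scales, missingness, or temporal structure.
Passing tests show the optimization and recovery machinery behaves as
specified under these idealized conditions; they are not evidence about
clinical interpretability on real cohorts.

## Numerical choices

* Power iteration declares convergence when successive Rayleigh estimates
  differ by < tol·max(1, estimate) (tol 1e−10); all-zero data returns
  λ̂₁ = 0 with an arbitrary unit vector. With a degenerate leading
  eigenvalue (multiplicity > 1) any vector in the dominant eigenspace is a
  valid fixed point; this is documented, not an error.
* nnz counts exact zeros only — soft-thresholding produces them.
* z₀ defaults to zeros (deterministic, and makes the γ ≥ ‖w‖∞ fixed point
  exact); any start can be given.
* All randomness flows from two seeds (sampling/data and w); fixed seeds
  give bitwise-identical traces.
* m's ceil uses a 1e−9 slack so roundoff in λ − λ̂₁ cannot bump an exact
  integer ratio up by one.
* ISTA stops at ‖z⁺ − z‖ ≤ tol·max(1, ‖z‖); CG for the large-d γ = 0 solve
  runs at rtol 1e−12.

## Validation problem sizes

The suite validates oracle agreement and geometric convergence on 200×20
Gaussian instances (10 seeds), variance reduction on 2000×100, support
recovery on 2000×200 spiked data (k = 5, strength 10, 10 seeds) and a
2000×10 reconstructed covariance, and the SVRG/SGD stabilization race on
5000×500 (10 seeds, epoch cap 40). These sizes keep every claim checkable
on a single desk-scale run while preserving the regimes that matter
(n ≫ d for the stochastic advantage, d ≫ k for sparsity).

## Known limitations

* The theoretical rate certificate uses ℓ = λ − λ̂₁, which can be very
  conservative; the measured per-epoch contraction is typically far below ρ.
* The "paper" L_Q mode (spectral heuristic) is unsafe for unnormalized
  wide data (see above); exact
  mode costs one pass over row norms plus a d×d eigendecomposition (or a
  bound) for L.
* Hotelling deflation on inexact loadings can leave the operator slightly
  indefinite; this is warned about and tolerated, not corrected.
* prox-SGD with a constant step does not converge to the minimizer, only to
  a neighborhood; its trace is a baseline, not an estimator.
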