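"""Problem data types and per-evaluation mathematics for convex sparse PCA.

The leading sparse principal component of an n-by-d data matrix X (rows are
samples x_i) is obtained here as the minimizer of the composite objective

    P(z) = F(z) + R(z),
    F(z) = 1/2 z^T (lam*I - S) z - w^T z,      R(z) = gamma * ||z||_1,

where S = (1/n) sum_i x_i x_i^T is the (uncentered) second-moment matrix,
lam > lambda_1(S) makes F strongly convex, w is a fixed random direction and
gamma controls sparsity.  F decomposes as the average of n per-sample losses
f_i(z) = 1/2 z^T (lam*I - x_i x_i^T) z - w^T z, which is what the stochastic
solvers exploit.

Everything in this module is matrix-free: S is never materialized; S z is
always computed as (1/n) X^T (X z).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse


class InputError(ValueError):
    """Bad argument values or shapes supplied by the caller."""


class ConfigurationError(ValueError):
    """A solve-time condition (e.g. lam > lambda_1(S)) is violated."""


class NumericError(RuntimeError):
    """A non-finite iterate or other numerical breakdown during a solve."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DataMatrix:
    """An n-by-d samples-by-features matrix, dense or sparse.

    The sole carrier of the samples x_i and, implicitly, of the second-moment
    matrix S = (1/n) sum_i x_i x_i^T.  Sparse storage (CSR) is the natural
    choice for count data such as per-patient diagnosis-code frequencies,
    where each row has very few nonzeros.
    """

    values: np.ndarray | sparse.sparray | sparse.spmatrix
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if sparse.issparse(v):
            self.values = sparse.csr_array(v, dtype=np.float64)
            if not np.all(np.isfinite(self.values.data)):
                raise InputError("data matrix contains non-finite entries")
        else:
            v = np.asarray(v, dtype=np.float64)
            if v.ndim != 2:
                raise InputError(f"data matrix must be 2-D, got ndim={v.ndim}")
            if not np.all(np.isfinite(v)):
                raise InputError("data matrix contains non-finite entries")
            self.values = v
        if self.n < 1 or self.d < 1:
            raise InputError("data matrix must have n >= 1 and d >= 1")
        if self.feature_names is not None and len(self.feature_names) != self.d:
            raise InputError(
                f"feature_names has length {len(self.feature_names)}, expected d={self.d}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def is_sparse(self) -> bool:
        return sparse.issparse(self.values)

    def row(self, i: int) -> np.ndarray:
        """Sample x_i as a dense 1-D array."""
        if self.is_sparse:
            return self.values[[i], :].toarray().ravel()
        return np.asarray(self.values[i])

    def row_squared_norms(self) -> np.ndarray:
        """||x_i||^2 for every sample (sparse-aware)."""
        if self.is_sparse:
            sq = self.values.multiply(self.values)
            return np.asarray(sq.sum(axis=1)).ravel()
        return np.einsum("ij,ij->i", self.values, self.values)


@dataclass
class ProblemSpec:
    """Parameters (lam, w, gamma) of the composite objective P(z).

    lam is on the scale of the eigenvalues of S and must exceed lambda_1(S)
    at solve time; w is a fixed d-vector (by convention standard normal,
    drawn from a dedicated seed); gamma >= 0 weights the l1 penalty.
    """

    lam: float
    w: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        self.lam = float(self.lam)
        self.gamma = float(self.gamma)
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        if self.w.size == 0:
            raise InputError("w must be a nonempty vector")
        if not np.all(np.isfinite(self.w)):
            raise InputError("w contains non-finite entries")
        if self.gamma < 0:
            raise InputError(f"gamma must be >= 0, got {self.gamma}")
        if not np.isfinite(self.lam):
            raise InputError("lam must be finite")

    @property
    def d(self) -> int:
        return self.w.size


@dataclass
class SpectralEstimate:
    """Power-iteration estimate of lambda_1(S) and its eigenvector."""

    lambda1: float
    vector: np.ndarray
    iterations: int
    converged: bool


@dataclass
class LipschitzInfo:
    """Gradient Lipschitz constants of the per-sample losses.

    L_Q = max_i L_i bounds every component gradient; L bounds the gradient of
    the average F.  mode="exact" computes L_i = ||lam*I - x_i x_i^T||_2 =
    max(lam, | ||x_i||^2 - lam |); mode="paper" uses the common heuristic
    L_Q = lambda_1(S), which matches practice but can under-estimate max_i L_i.
    """

    L_Q: float
    L: float
    mode: str


# ---------------------------------------------------------------------------
# Second-moment operator (supports deflation without materializing S)
# ---------------------------------------------------------------------------


def second_moment_matvec(data: DataMatrix, z: np.ndarray) -> np.ndarray:
    """Compute S z = (1/n) X^T (X z) without forming the d-by-d matrix S."""
    z = _check_vector(z, data.d, "z")
    return np.asarray(data.values.T @ (data.values @ z)) / data.n


def _check_vector(z: np.ndarray, d: int, name: str) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.size != d:
        raise InputError(f"{name} has length {z.size}, expected {d}")
    if not np.all(np.isfinite(z)):
        raise InputError(f"{name} contains non-finite entries")
    return z


class SecondMomentOperator:
    """Matrix-free view of S (optionally with rank-one Hotelling corrections).

    ``deflations`` is a sequence of (v, alpha) pairs; the operator computes
    S u - sum_t alpha_t (v_t @ u) v_t.  Used both by power iteration and by
    the solvers when extracting components beyond the first.
    """

    def __init__(
        self,
        base: "DataMatrix | np.ndarray | SecondMomentOperator",
        deflations: Sequence[tuple[np.ndarray, float]] = (),
    ) -> None:
        self.base = base
        self.deflations = [
            (np.asarray(v, dtype=np.float64).ravel(), float(a)) for v, a in deflations
        ]
        if isinstance(base, DataMatrix):
            self._dim = base.d
        elif isinstance(base, SecondMomentOperator):
            self._dim = base.dim
        else:
            a = np.asarray(base, dtype=np.float64)
            if a.ndim != 2 or a.shape[0] != a.shape[1]:
                raise InputError("explicit covariance must be a square matrix")
            self.base = a
            self._dim = a.shape[0]

    @property
    def dim(self) -> int:
        return self._dim

    def matvec(self, u: np.ndarray) -> np.ndarray:
        u = _check_vector(u, self.dim, "u")
        if isinstance(self.base, DataMatrix):
            y = second_moment_matvec(self.base, u)
        elif isinstance(self.base, SecondMomentOperator):
            y = self.base.matvec(u)
        else:
            y = self.base @ u
        for v, alpha in self.deflations:
            y = y - alpha * (v @ u) * v
        return y


def _as_operator(data) -> SecondMomentOperator:
    if isinstance(data, SecondMomentOperator):
        return data
    return SecondMomentOperator(data)


# ---------------------------------------------------------------------------
# Spectral estimate
# ---------------------------------------------------------------------------


def estimate_lambda1(
    data,
    tol: float = 1e-10,
    max_iter: int = 1000,
    seed: int = 0,
) -> SpectralEstimate:
    """Largest eigenvalue of S by power iteration on the implicit operator.

    Accepts a :class:`DataMatrix`, an explicit square matrix, or a
    :class:`SecondMomentOperator` (e.g. a deflated one).  Convergence is
    declared when successive Rayleigh-quotient estimates differ by less than
    ``tol * max(1, estimate)``.  All-zero data yields lambda1 = 0.

    When lambda_1 has multiplicity > 1 the iteration still returns a valid
    vector in the dominant eigenspace (any such vector is a fixed point);
    this is documented behaviour, not an error.
    """
    if max_iter < 1:
        raise InputError("max_iter must be >= 1")
    if tol <= 0:
        raise InputError("tol must be > 0")
    op = _as_operator(data)
    d = op.dim
    rng = np.random.default_rng(seed)
    b = rng.standard_normal(d)
    b /= np.linalg.norm(b)
    est_prev = np.inf
    est = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        y = op.matvec(b)
        ny = np.linalg.norm(y)
        est = float(b @ y)
        if ny < 1e-300:
            # operator annihilates b: zero (or fully deflated) spectrum
            return SpectralEstimate(lambda1=0.0, vector=b, iterations=it, converged=True)
        b = y / ny
        if abs(est - est_prev) < tol * max(1.0, abs(est)):
            converged = True
            break
        est_prev = est
    return SpectralEstimate(lambda1=est, vector=b, iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# Objective, gradients, prox
# ---------------------------------------------------------------------------


def objective_value(problem: ProblemSpec, data, z: np.ndarray) -> float:
    """P(z) = 1/2 z^T (lam*I - S) z - w^T z + gamma ||z||_1."""
    op = _as_operator(data)
    z = _check_vector(z, op.dim, "z")
    Sz = op.matvec(z)
    quad = 0.5 * (problem.lam * float(z @ z) - float(z @ Sz))
    return quad - float(problem.w @ z) + problem.gamma * float(np.abs(z).sum())


def full_gradient(problem: ProblemSpec, data, z: np.ndarray) -> np.ndarray:
    """grad F(z) = (lam*I - S) z - w, via the matrix-free S z product."""
    op = _as_operator(data)
    z = _check_vector(z, op.dim, "z")
    return problem.lam * z - op.matvec(z) - problem.w


def vr_stochastic_gradient(
    problem: ProblemSpec,
    x_i: np.ndarray,
    z_prev: np.ndarray,
    z_tilde: np.ndarray,
    g_full: np.ndarray,
) -> np.ndarray:
    """Variance-reduced stochastic gradient

        v_k = (lam*I - x_i x_i^T)(z_prev - z_tilde) + grad F(z_tilde),

    with ``g_full`` the caller-supplied full gradient at z_tilde.  The
    correction uses one inner product and vector operations only; the
    rank-one matrix is never formed.  Averaging v_k over all samples i
    recovers grad F(z_prev) exactly (unbiasedness).
    """
    d = z_prev.shape[0] if hasattr(z_prev, "shape") else len(z_prev)
    x_i = _check_vector(x_i, d, "x_i")
    z_prev = _check_vector(z_prev, d, "z_prev")
    z_tilde = _check_vector(z_tilde, d, "z_tilde")
    g_full = _check_vector(g_full, d, "g_full")
    diff = z_prev - z_tilde
    return problem.lam * diff - x_i * (x_i @ diff) + g_full


def prox_l1(v: np.ndarray, threshold: float) -> np.ndarray:
    """Soft-thresholding: sign(v) * max(0, |v| - threshold), componentwise.

    This is the proximal operator of threshold * ||.||_1 and produces exact
    zeros, which is what makes the reported support sizes meaningful.
    """
    if threshold < 0:
        raise InputError(f"threshold must be >= 0, got {threshold}")
    v = np.asarray(v, dtype=np.float64)
    return np.sign(v) * np.maximum(0.0, np.abs(v) - threshold)


# ---------------------------------------------------------------------------
# Lipschitz constants and the trivial-solution bound
# ---------------------------------------------------------------------------


def lipschitz_constant(data: DataMatrix, lam: float, mode: str = "paper") -> LipschitzInfo:
    """Gradient Lipschitz constants of the per-sample losses f_i.

    mode="exact": L_i = ||lam*I - x_i x_i^T||_2 = max(lam, | ||x_i||^2 - lam |),
    L_Q = max_i L_i, and L = ||lam*I - S||_2 (dense eigendecomposition for
    moderate d, else the valid upper bound max(lam, lambda1_hat - lam)).

    mode="paper": L_Q = lambda1_hat(S), the heuristic used in practice for
    step-size selection; L is reported as the same exact/bounded value.
    """
    if lam <= 0:
        raise InputError(f"lam must be > 0, got {lam}")
    if data.n < 1:
        raise InputError("empty data")
    if mode not in ("exact", "paper"):
        raise InputError(f"mode must be 'exact' or 'paper', got {mode!r}")
    rn2 = data.row_squared_norms()
    L_exact = float(np.max(np.maximum(lam, np.abs(rn2 - lam))))
    # spectral norm of lam*I - S
    if data.d <= 1500:
        X = data.values.toarray() if data.is_sparse else data.values
        evals = np.linalg.eigvalsh((X.T @ X) / data.n)
        L_avg = float(np.max(np.abs(lam - evals)))
    else:
        lam1 = estimate_lambda1(data).lambda1
        L_avg = float(max(lam, abs(lam1 - lam)))
    if mode == "exact":
        return LipschitzInfo(L_Q=L_exact, L=L_avg, mode="exact")
    lam1 = estimate_lambda1(data).lambda1
    return LipschitzInfo(L_Q=float(lam1), L=L_avg, mode="paper")


def center_data(data: DataMatrix) -> DataMatrix:
    """Subtract per-feature means (opt-in; the default pipeline leaves the
    second moment uncentered, matching the S = (1/n) sum x_i x_i^T convention).

    Centering densifies sparse storage, so it is refused for large sparse
    matrices rather than silently exhausting memory.
    """
    if data.is_sparse:
        if data.n * data.d > 50_000_000:
            raise InputError("refusing to densify a large sparse matrix for centering")
        X = data.values.toarray()
    else:
        X = data.values.copy()
    X -= X.mean(axis=0)
    return DataMatrix(X, feature_names=data.feature_names)


def gamma_max(w: np.ndarray) -> float:
    """||w||_inf: the smallest gamma at which z = 0 becomes optimal.

    For gamma >= ||w||_inf the zero vector satisfies 0 in dP(0) (subgradient
    optimality: |w_j| <= gamma for all j), so the solution is trivially
    all-zero; useful gamma values lie in [0, ||w||_inf).
    """
    w = np.asarray(w, dtype=np.float64).ravel()
    if w.size == 0:
        raise InputError("w must be nonempty")
    if not np.all(np.isfinite(w)):
        raise InputError("w contains non-finite entries")
    return float(np.max(np.abs(w)))
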