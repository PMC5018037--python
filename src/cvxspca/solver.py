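"""Solvers for the convex sparse-PCA objective P(z) = F(z) + gamma ||z||_1.

The workhorse is proximal SVRG: epochs s = 1..T each compute the full
gradient at a reference point z_tilde and then take m cheap stochastic
proximal steps whose gradients

    v_k = (lam*I - x_i x_i^T)(z_{k-1} - z_tilde) + grad F(z_tilde)

are unbiased for grad F(z_{k-1}) with variance that vanishes as both points
approach the optimum, giving a geometric (linear) convergence rate with a
constant step size.  A plain proximal SGD baseline, a deterministic ISTA
reference solver, and a closed-form gamma = 0 solve are provided so every
stochastic result can be checked against an independent route.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy.sparse import linalg as spla

from .core import (
    ConfigurationError,
    DataMatrix,
    InputError,
    LipschitzInfo,
    NumericError,
    ProblemSpec,
    SecondMomentOperator,
    estimate_lambda1,
    full_gradient,
    lipschitz_constant,
    objective_value,
    prox_l1,
)

__all__ = [
    "SolverConfig",
    "Trace",
    "TraceRecord",
    "SolveResult",
    "RateParams",
    "fit_prox_svrg",
    "fit_prox_sgd",
    "fit_ista_reference",
    "solve_gamma0_closed_form",
    "theoretical_rate",
    "auto_hyperparams",
]


# ---------------------------------------------------------------------------
# Configuration and result types
# ---------------------------------------------------------------------------


@dataclass
class SolverConfig:
    """Stochastic-solver configuration.

    eta is the constant step size, m the number of inner iterations per
    epoch, T the maximum number of epochs.  ``tilde_update`` selects whether
    the epoch reference point is the average of the inner iterates (the
    analysed variant, default) or the last iterate.  ``stop`` is either
    "fixed_epochs" (run all T epochs) or "support_stable" (stop once the
    nonzero pattern of z_tilde is unchanged for ``patience`` consecutive
    epochs).  ``lq_for_bound``, when set, enforces the step-size condition
    eta < 1/(4 L_Q) required by the geometric-rate guarantee; together with
    ``ell`` it also makes the solver report the theoretical contraction
    factor rho.

    ``variance_probes`` inner iterations per epoch are instrumented with the
    exact deviation ||v_k - grad F(z_{k-1})||^2 (each probe costs one full
    data pass, so the count is kept small); their mean is the per-epoch
    ``vk_variance`` diagnostic.

    ``eta_decay`` applies to prox-SGD only: "constant" keeps eta fixed,
    "inv_k" uses eta_t = eta / (1 + t/m) with t the global inner-step count,
    i.e. roughly eta/s during epoch s.
    """

    eta: float
    m: int
    T: int
    seed: int = 0
    init: str = "zeros"  # "zeros" | "given"
    z0: np.ndarray | None = None
    tilde_update: str = "average"  # "average" | "last"
    stop: str = "fixed_epochs"  # "fixed_epochs" | "support_stable"
    patience: int = 5
    sample_with_replacement: bool = True
    eta_decay: str = "constant"  # "constant" | "inv_k" (prox-SGD only)
    variance_probes: int = 4
    lq_for_bound: float | None = None
    ell: float | None = None

    def validate(self, d: int) -> None:
        if self.eta <= 0:
            raise InputError(f"eta must be > 0, got {self.eta}")
        if self.m < 1:
            raise InputError(f"m must be >= 1, got {self.m}")
        if self.T < 1:
            raise InputError(f"T must be >= 1, got {self.T}")
        if self.init not in ("zeros", "given"):
            raise InputError(f"init must be 'zeros' or 'given', got {self.init!r}")
        if self.init == "given":
            if self.z0 is None:
                raise InputError("init='given' requires z0")
            if np.asarray(self.z0).ravel().size != d:
                raise InputError("z0 has the wrong length")
        if self.tilde_update not in ("average", "last"):
            raise InputError(f"unknown tilde_update {self.tilde_update!r}")
        if self.stop not in ("fixed_epochs", "support_stable"):
            raise InputError(f"unknown stop rule {self.stop!r}")
        if self.stop == "support_stable" and self.patience < 1:
            raise InputError("patience must be >= 1")
        if self.eta_decay not in ("constant", "inv_k"):
            raise InputError(f"unknown eta_decay {self.eta_decay!r}")
        if self.lq_for_bound is not None and not self.eta < 1.0 / (4.0 * self.lq_for_bound):
            raise ConfigurationError(
                f"step size eta={self.eta} violates the geometric-rate condition "
                f"0 < eta < 1/(4*L_Q) = {1.0 / (4.0 * self.lq_for_bound):.6g}"
            )

    def initial_point(self, d: int) -> np.ndarray:
        if self.init == "zeros":
            return np.zeros(d)
        return np.asarray(self.z0, dtype=np.float64).ravel().copy()


@dataclass
class TraceRecord:
    epoch: int
    objective: float
    grad_norm: float
    nnz: int
    vk_variance: float
    inner_iterations: int


@dataclass
class Trace:
    """Per-epoch diagnostics of a stochastic solve."""

    records: list[TraceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def objectives(self) -> np.ndarray:
        return np.array([r.objective for r in self.records])

    def variances(self) -> np.ndarray:
        return np.array([r.vk_variance for r in self.records])

    def supports(self) -> np.ndarray:
        return np.array([r.nnz for r in self.records])


@dataclass
class SolveResult:
    z: np.ndarray
    objective: float
    nnz: int
    epochs_run: int
    converged: bool
    rho_theoretical: float | None = None


@dataclass
class RateParams:
    """Inputs of the geometric contraction factor rho (see theoretical_rate)."""

    ell: float
    L_Q: float
    eta: float
    m: int


# ---------------------------------------------------------------------------
# Inner-loop machinery shared by SVRG and SGD
# ---------------------------------------------------------------------------


class _Sampler:
    def __init__(self, n: int, rng: np.random.Generator, with_replacement: bool):
        self.n = n
        self.rng = rng
        self.with_replacement = with_replacement

    def draw(self, m: int) -> np.ndarray:
        if self.with_replacement:
            return self.rng.integers(0, self.n, size=m)
        reps = math.ceil(m / self.n)
        idx = np.concatenate([self.rng.permutation(self.n) for _ in range(reps)])
        return idx[:m]


def _row_accessor(data: DataMatrix):
    """Return f(i, u) -> x_i * (x_i @ u) computed sparse-aware, and the data."""
    if data.is_sparse:
        csr = data.values
        indptr, indices, vals = csr.indptr, csr.indices, csr.data

        def apply(i: int, u: np.ndarray, out: np.ndarray) -> None:
            lo, hi = indptr[i], indptr[i + 1]
            cols = indices[lo:hi]
            xv = vals[lo:hi]
            t = xv @ u[cols]
            out[cols] -= xv * t

        return apply
    X = data.values

    def apply(i: int, u: np.ndarray, out: np.ndarray) -> None:
        xi = X[i]
        out -= xi * (xi @ u)

    return apply


def _probe_positions(m: int, count: int) -> frozenset[int]:
    if count <= 0:
        return frozenset()
    ks = np.unique(np.round(np.linspace(1, m, num=min(count, m))).astype(int))
    return frozenset(int(k) for k in ks)


def _check_lambda(problem: ProblemSpec, op: SecondMomentOperator, seed: int) -> float:
    est = estimate_lambda1(op, seed=seed)
    if problem.lam <= est.lambda1:
        raise ConfigurationError(
            f"convexity condition violated: lam={problem.lam:.6g} must exceed "
            f"lambda_1(S) ~= {est.lambda1:.6g}"
        )
    return est.lambda1


def _maybe_rho(config: SolverConfig) -> float | None:
    if config.lq_for_bound is None or config.ell is None:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return theoretical_rate(
                RateParams(ell=config.ell, L_Q=config.lq_for_bound, eta=config.eta, m=config.m)
            )
    except InputError:
        return None


def _epoch_point(iterate_sum: np.ndarray, last: np.ndarray, m: int, mode: str) -> np.ndarray:
    return iterate_sum / m if mode == "average" else last.copy()


# ---------------------------------------------------------------------------
# Proximal SVRG (the main algorithm)
# ---------------------------------------------------------------------------


def fit_prox_svrg(
    problem: ProblemSpec,
    data: DataMatrix,
    config: SolverConfig,
    deflations: Sequence[tuple[np.ndarray, float]] = (),
) -> tuple[SolveResult, Trace]:
    """Minimize P(z) with proximal stochastic variance-reduced gradients.

    Each epoch computes grad F at the reference point z_tilde, then performs
    m inner steps z_k = prox_l1(z_{k-1} - eta v_k, eta*gamma) with the
    variance-reduced gradient v_k, and finally resets z_tilde to the average
    (or last) inner iterate.  ``deflations`` carries Hotelling rank-one
    corrections (v, alpha) subtracted from S, used when extracting components
    beyond the first; they enter both the full gradient and each per-sample
    gradient so unbiasedness is preserved.
    """
    op = SecondMomentOperator(data, deflations)
    config.validate(data.d)
    _check_lambda(problem, op, config.seed)
    if problem.d != data.d:
        raise InputError(f"w has length {problem.d}, expected d={data.d}")

    lam, gamma, eta = problem.lam, problem.gamma, config.eta
    thr = eta * gamma
    m, n = config.m, data.n
    rng = np.random.default_rng(config.seed)
    sampler = _Sampler(n, rng, config.sample_with_replacement)
    row_apply = _row_accessor(data)
    defl = op.deflations
    probes = _probe_positions(m, config.variance_probes)

    z_tilde = config.initial_point(data.d)
    trace = Trace()
    support_prev: bytes | None = None
    stable = 0
    converged = False
    epochs_run = 0

    for s in range(1, config.T + 1):
        g_full = full_gradient(problem, op, z_tilde)
        idx = sampler.draw(m)
        z = z_tilde.copy()
        z_sum = np.zeros_like(z)
        var_acc = 0.0
        var_cnt = 0
        for k in range(1, m + 1):
            i = idx[k - 1]
            diff = z - z_tilde
            vk = lam * diff + g_full
            row_apply(i, diff, vk)
            for v, a in defl:
                vk += a * (v @ diff) * v
            if k in probes:
                dev = vk - full_gradient(problem, op, z)
                var_acc += float(dev @ dev)
                var_cnt += 1
            u = z - eta * vk
            z = np.sign(u) * np.maximum(0.0, np.abs(u) - thr)
            z_sum += z
        z_tilde = _epoch_point(z_sum, z, m, config.tilde_update)
        if not np.all(np.isfinite(z_tilde)):
            raise NumericError(f"non-finite iterate at epoch {s}")
        epochs_run = s
        obj = objective_value(problem, op, z_tilde)
        if not np.isfinite(obj):
            raise NumericError(
                f"objective overflowed at epoch {s}; the step size is likely "
                "unstable (try lq_mode='exact' for eta selection)"
            )
        gnorm = float(np.linalg.norm(full_gradient(problem, op, z_tilde)))
        nnz = int(np.count_nonzero(z_tilde))
        trace.records.append(
            TraceRecord(
                epoch=s,
                objective=obj,
                grad_norm=gnorm,
                nnz=nnz,
                vk_variance=var_acc / max(var_cnt, 1),
                inner_iterations=m,
            )
        )
        if config.stop == "support_stable":
            support = (z_tilde != 0).tobytes()
            stable = stable + 1 if support == support_prev else 0
            support_prev = support
            if stable >= config.patience:
                converged = True
                break
    if config.stop == "fixed_epochs":
        converged = True

    result = SolveResult(
        z=z_tilde,
        objective=objective_value(problem, op, z_tilde),
        nnz=int(np.count_nonzero(z_tilde)),
        epochs_run=epochs_run,
        converged=converged,
        rho_theoretical=_maybe_rho(config),
    )
    return result, trace


# ---------------------------------------------------------------------------
# Plain proximal SGD baseline
# ---------------------------------------------------------------------------


def fit_prox_sgd(
    problem: ProblemSpec,
    data: DataMatrix,
    config: SolverConfig,
    deflations: Sequence[tuple[np.ndarray, float]] = (),
) -> tuple[SolveResult, Trace]:
    """Proximal stochastic gradient baseline, without variance reduction.

    Uses v_k = grad f_i(z_{k-1}) = (lam*I - x_i x_i^T) z_{k-1} - w directly.
    The loop keeps the same epoch structure as SVRG (m inner steps per epoch,
    same diagnostics and stopping rules) so paired comparisons of the traces
    are meaningful; no full gradient enters the updates.
    """
    op = SecondMomentOperator(data, deflations)
    config.validate(data.d)
    _check_lambda(problem, op, config.seed)
    if problem.d != data.d:
        raise InputError(f"w has length {problem.d}, expected d={data.d}")

    lam, gamma, w = problem.lam, problem.gamma, problem.w
    eta0, m, n = config.eta, config.m, data.n
    rng = np.random.default_rng(config.seed)
    sampler = _Sampler(n, rng, config.sample_with_replacement)
    row_apply = _row_accessor(data)
    defl = op.deflations
    probes = _probe_positions(m, config.variance_probes)

    z = config.initial_point(data.d)
    point = z.copy()
    trace = Trace()
    support_prev: bytes | None = None
    stable = 0
    converged = False
    epochs_run = 0
    t_global = 0

    for s in range(1, config.T + 1):
        idx = sampler.draw(m)
        z_sum = np.zeros_like(z)
        var_acc = 0.0
        var_cnt = 0
        for k in range(1, m + 1):
            i = idx[k - 1]
            vk = lam * z - w
            row_apply(i, z, vk)
            for v, a in defl:
                vk += a * (v @ z) * v
            if k in probes:
                dev = vk - full_gradient(problem, op, z)
                var_acc += float(dev @ dev)
                var_cnt += 1
            eta = eta0 if config.eta_decay == "constant" else eta0 / (1.0 + t_global / m)
            u = z - eta * vk
            z = np.sign(u) * np.maximum(0.0, np.abs(u) - eta * gamma)
            z_sum += z
            t_global += 1
        point = _epoch_point(z_sum, z, m, config.tilde_update)
        if not np.all(np.isfinite(z)):
            raise NumericError(f"non-finite iterate at epoch {s}")
        epochs_run = s
        obj = objective_value(problem, op, point)
        if not np.isfinite(obj):
            raise NumericError(
                f"objective overflowed at epoch {s}; the step size is likely "
                "unstable (try lq_mode='exact' for eta selection)"
            )
        trace.records.append(
            TraceRecord(
                epoch=s,
                objective=obj,
                grad_norm=float(np.linalg.norm(full_gradient(problem, op, point))),
                nnz=int(np.count_nonzero(point)),
                vk_variance=var_acc / max(var_cnt, 1),
                inner_iterations=m,
            )
        )
        if config.stop == "support_stable":
            support = (point != 0).tobytes()
            stable = stable + 1 if support == support_prev else 0
            support_prev = support
            if stable >= config.patience:
                converged = True
                break
    if config.stop == "fixed_epochs":
        converged = True

    result = SolveResult(
        z=point,
        objective=objective_value(problem, op, point),
        nnz=int(np.count_nonzero(point)),
        epochs_run=epochs_run,
        converged=converged,
        rho_theoretical=None,
    )
    return result, trace


# ---------------------------------------------------------------------------
# Deterministic reference solvers
# ---------------------------------------------------------------------------


def fit_ista_reference(
    problem: ProblemSpec,
    data: DataMatrix,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    deflations: Sequence[tuple[np.ndarray, float]] = (),
) -> SolveResult:
    """Deterministic proximal full-gradient (ISTA) solve, used as an oracle.

    Iterates z <- prox_l1(z - eta grad F(z), eta*gamma) with eta = 1/L until
    ||z_new - z|| <= tol * max(1, ||z||).  Because lam > lambda_1(S) makes F
    strongly convex, ISTA converges linearly to the unique minimizer; the
    stochastic solvers are validated against its objective.
    """
    if tol <= 0:
        raise InputError("tol must be > 0")
    op = SecondMomentOperator(data, deflations)
    _check_lambda(problem, op, seed=0)
    if deflations:
        # ||lam*I - S'||: S' is PSD up to deflation error and bounded by lam
        L = problem.lam
    else:
        L = lipschitz_constant(data, problem.lam, mode="exact").L
    eta = 1.0 / L
    z = np.zeros(op.dim)
    converged = False
    for _ in range(max_iter):
        g = full_gradient(problem, op, z)
        z_new = prox_l1(z - eta * g, eta * problem.gamma)
        if np.linalg.norm(z_new - z) <= tol * max(1.0, float(np.linalg.norm(z))):
            z = z_new
            converged = True
            break
        z = z_new
    return SolveResult(
        z=z,
        objective=objective_value(problem, op, z),
        nnz=int(np.count_nonzero(z)),
        epochs_run=0,
        converged=converged,
        rho_theoretical=None,
    )


def solve_gamma0_closed_form(problem: ProblemSpec, data) -> np.ndarray:
    """Exact minimizer of F alone (gamma = 0): the solution of (lam*I - S) z = w.

    Direct Cholesky solve on the materialized system for small d; conjugate
    gradients on the implicit operator otherwise.  Raises ConfigurationError
    when lam*I - S is not positive definite.
    """
    op = SecondMomentOperator(data) if isinstance(data, DataMatrix) else data
    _check_lambda(problem, op, seed=0)
    d = op.dim
    if isinstance(op.base, DataMatrix) and not op.deflations and d <= 2000:
        dm = op.base
        X = dm.values.toarray() if dm.is_sparse else dm.values
        A = problem.lam * np.eye(d) - (X.T @ X) / dm.n
        try:
            c, low = sla.cho_factor(A)
        except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
            raise ConfigurationError("lam*I - S is not positive definite") from exc
        return sla.cho_solve((c, low), problem.w)
    linop = spla.LinearOperator(
        (d, d), matvec=lambda u: problem.lam * u - op.matvec(u), dtype=np.float64
    )
    z, info = spla.cg(linop, problem.w, rtol=1e-12, atol=0.0, maxiter=50 * d)
    if info != 0:
        raise NumericError(f"conjugate gradients did not converge (info={info})")
    return z


# ---------------------------------------------------------------------------
# Theoretical rate and hyperparameter heuristics
# ---------------------------------------------------------------------------


def theoretical_rate(params: RateParams) -> float:
    """Per-epoch contraction factor of the geometric convergence guarantee:

        rho = 1 / (ell * (1 - 4 L_Q eta) * m * eta)
              + 4 L_Q eta (m + 1) / ((1 - 4 L_Q eta) * m),

    valid for 0 < eta < 1/(4 L_Q).  ell is the optimal-strong-convexity
    constant; for this objective the strong-convexity modulus lam -
    lambda_1(S) of F is a valid (conservative) choice.  A warning is emitted
    when rho >= 1, where the geometric guarantee is vacuous.
    """
    ell, L_Q, eta, m = params.ell, params.L_Q, params.eta, params.m
    if ell <= 0:
        raise InputError(f"ell must be > 0, got {ell}")
    if m < 1:
        raise InputError(f"m must be >= 1, got {m}")
    if not 0 < eta < 1.0 / (4.0 * L_Q):
        raise InputError(
            f"eta={eta} violates the rate condition 0 < eta < 1/(4*L_Q) = "
            f"{1.0 / (4.0 * L_Q):.6g}"
        )
    denom = 1.0 - 4.0 * L_Q * eta
    rho = 1.0 / (ell * denom * m * eta) + 4.0 * L_Q * eta * (m + 1) / (denom * m)
    if rho >= 1.0:
        warnings.warn(
            f"theoretical contraction factor rho={rho:.4g} >= 1: the geometric "
            "guarantee does not apply with these (eta, m, ell, L_Q)",
            RuntimeWarning,
            stacklevel=2,
        )
    return rho


def auto_hyperparams(
    data,
    margin: float = 0.05,
    c_m: float = 2.0,
    theta_eta: float = 0.4,
    lq_mode: str = "paper",
    seed: int = 0,
) -> tuple[float, float, int, LipschitzInfo]:
    """Derive (lam, eta, m) from the data spectrum.

    lam = (1 + margin) * lambda1_hat keeps F strongly convex with a moderate
    modulus; eta = theta_eta / (4 L_Q) satisfies the rate condition by
    construction (theta_eta < 1); m = ceil(c_m * L_Q / (lam - lambda1_hat)),
    clamped to [1, 10n], follows the standard Theta(L_Q / modulus) sizing of
    the inner loop.  L_Q comes from :func:`lipschitz_constant` in the
    requested mode ("paper": lambda1_hat itself).
    """
    if margin <= 0:
        raise InputError(f"margin must be > 0, got {margin}")
    if not 0 < theta_eta < 1:
        raise InputError(f"theta_eta must lie in (0, 1), got {theta_eta}")
    if c_m <= 0:
        raise InputError(f"c_m must be > 0, got {c_m}")
    est = estimate_lambda1(data, seed=seed)
    if est.lambda1 <= 0:
        raise ConfigurationError("cannot derive hyperparameters from all-zero data")
    lam = (1.0 + margin) * est.lambda1
    if isinstance(data, DataMatrix):
        lip = lipschitz_constant(data, lam, mode=lq_mode)
    else:
        if lq_mode != "paper":
            raise InputError("exact Lipschitz mode requires a DataMatrix, not an operator")
        lip = LipschitzInfo(L_Q=est.lambda1, L=lam, mode="paper")
    eta = theta_eta / (4.0 * lip.L_Q)
    if isinstance(data, DataMatrix):
        n = data.n
    elif isinstance(data, SecondMomentOperator) and isinstance(data.base, DataMatrix):
        n = data.base.n
    else:
        n = data.dim
    # tolerance guards against ceil(40 + 3e-10) = 41 from roundoff in lam - lambda1
    m = int(math.ceil(c_m * lip.L_Q / (lam - est.lambda1) - 1e-9))
    m = max(1, min(m, 10 * n))
    return lam, eta, m, lip
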