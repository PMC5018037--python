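"""Synthetic data generators.

Four generators cover the inputs the method is exercised on:

* plain i.i.d. standard-normal matrices (the convergence benchmarks),
* spiked-covariance data with a planted sparse leading eigenvector (the
  support-recovery test bed),
* data sampled from a covariance reconstructed from one sparse principal
  component plus a small symmetric noise perturbation (the
  regularization-path demonstration), and
* sparse non-negative integer count matrices emulating per-patient
  diagnosis-code frequencies, where most rows have very few nonzeros and
  code popularity is heavy-tailed.

Every generator is a pure function of its arguments, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .core import DataMatrix, InputError

__all__ = [
    "SpikeSpec",
    "gen_gaussian_matrix",
    "gen_spiked_data",
    "gen_pc_reconstructed_cov",
    "gen_emr_counts",
]


@dataclass
class SpikeSpec:
    """Parameters of the planted sparse-spike model.

    The population covariance is I + (strength - 1) v v^T with v a unit
    vector supported on k coordinates; strength is therefore the leading
    population eigenvalue (the remaining d-1 eigenvalues are 1).
    """

    n: int
    d: int
    k: int
    strength: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.d < 1:
            raise InputError("n and d must be >= 1")
        if not 1 <= self.k <= self.d:
            raise InputError(f"k must lie in [1, d={self.d}], got {self.k}")
        if self.strength <= 1:
            raise InputError(f"strength must be > 1, got {self.strength}")


def gen_gaussian_matrix(n: int, d: int, seed: int = 0) -> DataMatrix:
    """n-by-d matrix of i.i.d. N(0, 1) entries."""
    if n < 1 or d < 1:
        raise InputError(f"dimensions must be positive, got n={n}, d={d}")
    rng = np.random.default_rng(seed)
    return DataMatrix(rng.standard_normal((n, d)))


def _sparse_unit_vector(d: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Unit vector with k equal-magnitude entries (random support and signs).

    Equal magnitudes keep support recovery crisply defined: every planted
    coordinate carries the same weight 1/sqrt(k).
    """
    v = np.zeros(d)
    support = rng.choice(d, size=k, replace=False)
    v[support] = rng.choice([-1.0, 1.0], size=k) / np.sqrt(k)
    return v


def gen_spiked_data(spec: SpikeSpec) -> tuple[DataMatrix, np.ndarray]:
    """Sample from the spiked model: x = sqrt(strength - 1) * g0 * v + g.

    g0 is standard-normal scalar and g a standard-normal d-vector, so the
    population covariance is I + (strength - 1) v v^T.  Returns the data
    and the planted unit vector v (exactly k nonzeros).
    """
    rng = np.random.default_rng(spec.seed)
    v = _sparse_unit_vector(spec.d, spec.k, rng)
    g0 = rng.standard_normal(spec.n)
    g = rng.standard_normal((spec.n, spec.d))
    X = np.sqrt(spec.strength - 1.0) * np.outer(g0, v) + g
    return DataMatrix(X), v


def gen_pc_reconstructed_cov(
    d: int,
    k: int,
    noise: float,
    n: int,
    seed: int = 0,
    lam1: float = 5.0,
    v: np.ndarray | None = None,
) -> tuple[DataMatrix, np.ndarray]:
    """Data whose covariance is rebuilt from one sparse principal component.

    Sigma = lam1 * v v^T + noise * E with E symmetric standard-normal, then
    projected to the nearest positive semi-definite matrix (eigenvalue
    clipping); n rows are sampled from N(0, Sigma).  With noise = 0 the
    covariance is exactly rank one with top eigenvector v.

    By default v is a random k-sparse equal-magnitude unit vector; a caller
    may instead plant an explicit unit vector ``v`` — e.g. a sparse loading
    learned from a previous fit, mirroring the reconstruct-and-recover
    regularization-path experiment.
    """
    if noise < 0:
        raise InputError(f"noise must be >= 0, got {noise}")
    if not 1 <= k <= d:
        raise InputError(f"k must lie in [1, d={d}], got {k}")
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if v is None:
        v = _sparse_unit_vector(d, k, rng)
    else:
        v = np.asarray(v, dtype=np.float64).ravel()
        if v.size != d or abs(np.linalg.norm(v) - 1.0) > 1e-8:
            raise InputError("explicit v must be a unit d-vector")
    sigma = lam1 * np.outer(v, v)
    if noise > 0:
        G = rng.standard_normal((d, d))
        sigma = sigma + noise * (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(sigma)
    evals = np.clip(evals, 0.0, None)
    if not np.all(evals >= 0):  # pragma: no cover - clip guarantees this
        raise RuntimeError("covariance still indefinite after projection")
    root = evecs * np.sqrt(evals)
    X = rng.standard_normal((n, d)) @ root.T
    return DataMatrix(X), v


def gen_emr_counts(
    n_patients: int,
    n_codes: int,
    density: float,
    seed: int = 0,
) -> DataMatrix:
    """Sparse non-negative integer count matrix emulating per-patient code counts.

    Per-patient record counts follow a scaled log-series distribution, so
    most rows have very few nonzeros while a minority have many
    (right-skewed, median < mean); which codes appear follows a power-law
    popularity over code rank; nonzero entries are small positive counts
    (geometric).  ``density`` sets the target overall nonzero fraction.
    """
    if not 0 < density < 1:
        raise InputError(f"density must lie in (0, 1), got {density}")
    if n_patients < 1 or n_codes < 1:
        raise InputError("dimensions must be positive")
    target_row_nnz = density * n_codes
    if target_row_nnz < 0.5:
        raise InputError(
            f"density {density} implies fewer than 0.5 expected records per patient "
            f"at d={n_codes}; increase density or n_codes"
        )
    rng = np.random.default_rng(seed)
    # log-series with p=0.8: mean = -p / ((1-p) ln(1-p))
    p = 0.8
    mean_ls = -p / ((1.0 - p) * np.log(1.0 - p))
    raw = rng.logseries(p, size=n_patients).astype(float)
    scale = target_row_nnz / mean_ls
    row_nnz = np.clip(np.round(raw * scale), 1, n_codes).astype(int)

    popularity = 1.0 / np.arange(1, n_codes + 1) ** 1.2
    popularity /= popularity.sum()

    rows, cols, vals = [], [], []
    for i in range(n_patients):
        kk = row_nnz[i]
        chosen = rng.choice(n_codes, size=kk, replace=False, p=popularity)
        counts = rng.geometric(0.6, size=kk)
        rows.append(np.full(kk, i))
        cols.append(chosen)
        vals.append(counts)
    mat = sparse.coo_array(
        (np.concatenate(vals).astype(np.float64),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_patients, n_codes),
    ).tocsr()
    names = [f"code{j:04d}" for j in range(n_codes)]
    return DataMatrix(mat, feature_names=names)
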