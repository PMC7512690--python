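"""First-order vector autoregressive models and their stationary Gaussians.

The generative model throughout the package is the AR(1) process

    X' = A X + E,        E ~ N(0, Sigma_E),

with X the past state and X' the present state of an N-element system.
When the spectral radius of A is below one, the process has a stationary
law whose past covariance solves the discrete Lyapunov equation
``Sigma_X = A Sigma_X A^T + Sigma_E`` and whose lag-one cross-covariance
is ``Sigma_X A^T``.  The 2N-dimensional joint Gaussian over (X, X') is
the sole input to every integrated-information computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import StationarityError, ValidationError

# refuse models this close to the unit circle instead of regularizing
_STATIONARITY_MARGIN = 1e-9


def _as_matrix(m, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim == 0:
        m = m.reshape(1, 1)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {m.shape}")
    return m


def _check_symmetric_pd(m: np.ndarray, name: str, sym_tol: float = 1e-8) -> None:
    if not np.allclose(m, m.T, atol=sym_tol * (1 + np.abs(m).max())):
        raise ValidationError(f"{name} is not symmetric")
    try:
        linalg.cholesky(m, lower=True)
    except linalg.LinAlgError as exc:
        raise ValidationError(f"{name} is not positive definite") from exc


@dataclass(frozen=True)
class ARModel:
    """AR(1) model ``X' = A X + E`` with Gaussian innovations.

    Parameters
    ----------
    A : (N, N) array
        Connectivity matrix (dimensionless gains); spectral radius < 1.
    sigma_e : (N, N) array
        Innovation covariance, symmetric positive definite.
    """

    A: np.ndarray
    sigma_e: np.ndarray

    def __post_init__(self) -> None:
        A = _as_matrix(self.A, "A")
        S = _as_matrix(self.sigma_e, "Sigma_E")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "sigma_e", S)
        if A.shape != S.shape:
            raise ValidationError(
                f"A {A.shape} and Sigma_E {S.shape} shapes disagree"
            )
        rho = spectral_radius(A)
        if rho >= 1.0 - _STATIONARITY_MARGIN:
            raise StationarityError(
                f"spectral radius {rho:.6g} >= 1: AR model has no stationary law"
            )
        _check_symmetric_pd(S, "Sigma_E")

    @property
    def n(self) -> int:
        return self.A.shape[0]


def spectral_radius(A: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(np.asarray(A, dtype=float))).max())


@dataclass(frozen=True)
class JointGaussian:
    """Stationary 2N-dimensional Gaussian over (past X, present X').

    Index convention: rows/columns ``0..N-1`` are the past, ``N..2N-1``
    the present.  All block access goes through the named accessors;
    nothing else in the package touches raw offsets.
    """

    sigma: np.ndarray

    def __post_init__(self) -> None:
        S = _as_matrix(self.sigma, "joint covariance")
        if S.shape[0] % 2:
            raise ValidationError("joint covariance must be 2N x 2N")
        object.__setattr__(self, "sigma", S)
        _check_symmetric_pd(S, "joint covariance")

    @property
    def n(self) -> int:
        return self.sigma.shape[0] // 2

    @property
    def cov_past(self) -> np.ndarray:
        """Sigma(X)."""
        n = self.n
        return self.sigma[:n, :n]

    @property
    def cov_present(self) -> np.ndarray:
        """Sigma(X')."""
        n = self.n
        return self.sigma[n:, n:]

    @property
    def cross(self) -> np.ndarray:
        """Sigma(X, X'): entry (i, j) is cov(X_i, X'_j)."""
        n = self.n
        return self.sigma[:n, n:]

    def joint_indices(self, elements) -> np.ndarray:
        """Row indices of (M, M') for a subset of elements (past then present)."""
        el = np.asarray(list(elements), dtype=int)
        return np.concatenate([el, el + self.n])

    def sub_joint(self, elements) -> np.ndarray:
        """Covariance of (M, M') for the given element subset."""
        idx = self.joint_indices(elements)
        return self.sigma[np.ix_(idx, idx)]

    @classmethod
    def from_blocks(
        cls, cov_past: np.ndarray, cross: np.ndarray, cov_present: np.ndarray | None = None
    ) -> "JointGaussian":
        cov_past = _as_matrix(cov_past, "Sigma(X)")
        if cov_present is None:
            cov_present = cov_past
        top = np.hstack([cov_past, cross])
        bottom = np.hstack([cross.T, cov_present])
        sigma = np.vstack([top, bottom])
        return cls(0.5 * (sigma + sigma.T))


def stationary_covariance(model: ARModel) -> np.ndarray:
    """Solve ``Sigma_X = A Sigma_X A^T + Sigma_E`` for the stationary covariance."""
    sig = linalg.solve_discrete_lyapunov(model.A, model.sigma_e)
    return 0.5 * (sig + sig.T)


def cross_covariance(sigma_x: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Lag-one cross-covariance ``Sigma(X, X') = Sigma_X A^T``."""
    sigma_x = np.asarray(sigma_x, dtype=float)
    A = np.asarray(A, dtype=float)
    if sigma_x.shape != A.shape:
        raise ValidationError(
            f"Sigma_X {sigma_x.shape} and A {A.shape} shapes disagree"
        )
    return sigma_x @ A.T


def joint_gaussian(model: ARModel) -> JointGaussian:
    """Analytic stationary joint Gaussian of an AR(1) model."""
    sigma_x = stationary_covariance(model)
    return JointGaussian.from_blocks(sigma_x, cross_covariance(sigma_x, model.A))


def simulate(model: ARModel, T: int, seed=None) -> np.ndarray:
    """Simulate T samples of the stationary AR(1) process.

    The initial state is drawn from the stationary distribution, so every
    sample is marginally stationary.  Returns a (T, N) array.
    """
    if T < 1:
        raise ValidationError("T must be >= 1")
    rng = np.random.default_rng(seed)
    sigma_x = stationary_covariance(model)
    n = model.n
    out = np.empty((T, n))
    chol_x = linalg.cholesky(sigma_x, lower=True)
    chol_e = linalg.cholesky(model.sigma_e, lower=True)
    x = chol_x @ rng.standard_normal(n)
    out[0] = x
    noise = rng.standard_normal((T - 1, n)) @ chol_e.T
    for t in range(1, T):
        x = model.A @ x + noise[t - 1]
        out[t] = x
    return out


def estimate_joint_gaussian(series: np.ndarray, lag: int = 1, jitter: bool = True) -> JointGaussian:
    """Estimate the lagged joint Gaussian from a multichannel time series.

    Parameters
    ----------
    series : (T, N) array
        Rows are samples, columns are channels.
    lag : int
        Lag in samples between the "past" and "present" segments.  With
        100 Hz signals and a 10 ms step, one sample.
    jitter : bool
        If the estimated 2N x 2N covariance is not positive definite, add
        a small diagonal ``eps * I`` with ``eps = 1e-10 * trace / (2N)``
        and warn, rather than failing outright.

    Covariances use the biased 1/T normalization and are symmetrized.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValidationError("series must be a 2-D (T, N) array")
    T, n = series.shape
    if lag < 0:
        raise ValidationError("lag must be >= 0")
    if T <= lag + n:
        raise ValidationError(
            f"need more than lag + N = {lag + n} samples for a full-rank estimate, got {T}"
        )
    variances = series.var(axis=0)
    if np.any(variances <= 0):
        dead = np.flatnonzero(variances <= 0) + 1
        raise ValidationError(f"zero-variance channel(s): {dead.tolist()} (1-based)")

    past = series[: T - lag]
    present = series[lag:]
    m = past.shape[0]
    past_c = past - past.mean(axis=0)
    pres_c = present - present.mean(axis=0)
    cov_past = past_c.T @ past_c / m
    cov_present = pres_c.T @ pres_c / m
    cross = past_c.T @ pres_c / m
    cov_past = 0.5 * (cov_past + cov_past.T)
    cov_present = 0.5 * (cov_present + cov_present.T)

    top = np.hstack([cov_past, cross])
    sigma = np.vstack([top, np.hstack([cross.T, cov_present])])
    sigma = 0.5 * (sigma + sigma.T)
    try:
        linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        if not jitter:
            raise ValidationError("estimated joint covariance is rank deficient")
        eps = 1e-10 * np.trace(sigma) / sigma.shape[0]
        warnings.warn(
            f"estimated joint covariance is rank deficient; adding diagonal jitter {eps:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma = sigma + eps * np.eye(sigma.shape[0])
    return JointGaussian(sigma)
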