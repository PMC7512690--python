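"""Integrated-information measures for stationary Gaussian systems.

All three measures quantify the Kullback-Leibler divergence between the
joint past/present law p(X, X') and the closest "disconnected" law q in
which cross-partition interactions have been removed; they differ in
which interactions are removed:

``phi_mi``
    Mutual information between the two parts' past+present blocks — all
    interactions removed (q = product of the parts' marginals).
``phi_si``
    Stochastic interaction — causal and equal-time cross-partition
    influences on the present removed (q factorizes the transition law).
``phi_g``
    Geometric integrated information — only causal cross-partition
    influences removed: q keeps a free equal-time noise covariance but
    each part's present may regress only on its own past.  There is no
    closed form; the Gaussian minimization is solved by exact
    block-coordinate descent (see :func:`phi_g`).

Values are in nats.  The measures obey phi_g <= phi_si <= phi_mi and are
symmetric under swapping a part with its complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .ar_gaussian import JointGaussian
from .exceptions import ConvergenceError, ValidationError
from .partitions import Bipartition

LOG_2PI_E = math.log(2.0 * math.pi * math.e)

#: values in (-CLAMP_TOL, 0) are rounded up to zero; anything more
#: negative is treated as an implementation bug, not float noise
CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class PhiValue:
    """An integrated-information value with solver metadata.

    ``iterations``/``residual``/``converged`` are populated only for the
    geometric measure, which is computed iteratively.
    """

    measure: str
    value: float
    iterations: int | None = None
    residual: float | None = None
    converged: bool | None = None

    def __float__(self) -> float:
        return self.value


def _logdet(cov: np.ndarray, name: str = "covariance") -> float:
    """log det via Cholesky; raises naming the offending block."""
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValidationError(f"{name} block is not positive definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy (nats) of N(mu, cov): 0.5 log((2*pi*e)^k det cov)."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    k = cov.shape[0]
    return 0.5 * (k * LOG_2PI_E + _logdet(cov))


def conditional_entropy(cov_joint: np.ndarray, n_given: int) -> float:
    """H(Y | X) for a joint Gaussian over (X, Y), X the first n_given coords.

    Computed as H(X, Y) - H(X); the Schur complement never needs forming
    explicitly.
    """
    cov_joint = np.asarray(cov_joint, dtype=float)
    k = cov_joint.shape[0] - n_given
    ld_joint = _logdet(cov_joint, "joint")
    ld_given = _logdet(cov_joint[:n_given, :n_given], "conditioning")
    return 0.5 * (k * LOG_2PI_E + ld_joint - ld_given)


def _clamp(value: float, measure: str, tol: float = CLAMP_TOL) -> float:
    if value < -tol:
        raise ValidationError(
            f"phi_{measure} evaluated to {value:.3e} < -{tol:g}: "
            "input is numerically inconsistent or an implementation bug"
        )
    return max(value, 0.0)


def _sides(part: Bipartition) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(part.members, dtype=int)
    b = np.asarray(part.complement, dtype=int)
    return a, b


def phi_mi(joint: JointGaussian, part: Bipartition) -> PhiValue:
    """Mutual information between the two parts' (past, present) blocks.

    Equals H(M1, M1') + H(M2, M2') - H(X, X'); the dimension terms cancel
    so only log-determinants remain.
    """
    _check_part(joint, part)
    a, b = _sides(part)
    val = 0.5 * (
        _logdet(joint.sub_joint(a), "part-1 joint")
        + _logdet(joint.sub_joint(b), "part-2 joint")
        - _logdet(joint.sigma, "full joint")
    )
    return PhiValue("mi", _clamp(val, "mi"))


def phi_si(joint: JointGaussian, part: Bipartition) -> PhiValue:
    """Stochastic interaction: sum_i H(M_i'|M_i) - H(X'|X)."""
    _check_part(joint, part)
    a, b = _sides(part)
    cov_past = joint.cov_past
    val = 0.0
    for side, label in ((a, "part-1"), (b, "part-2")):
        val += 0.5 * (
            _logdet(joint.sub_joint(side), f"{label} joint")
            - _logdet(cov_past[np.ix_(side, side)], f"{label} past")
        )
    val -= 0.5 * (_logdet(joint.sigma, "full joint") - _logdet(cov_past, "past"))
    return PhiValue("si", _clamp(val, "si"))


def _check_part(joint: JointGaussian, part: Bipartition) -> None:
    if part.n != joint.n:
        raise ValidationError(
            f"partition is over {part.n} elements but the system has {joint.n}"
        )


def _residual_cov(
    syy: np.ndarray, syx: np.ndarray, sxx: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """Covariance of X' - B X under p."""
    BS = B @ syx.T  # B Sigma(X, X')
    R = syy - BS - BS.T + B @ sxx @ B.T
    return 0.5 * (R + R.T)


def phi_g(
    joint: JointGaussian,
    part: Bipartition,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> PhiValue:
    """Geometric integrated information across a bipartition.

    The disconnected model is the Gaussian q with q(X) = p(X) and
    transition law X' = B X + E', where B is constrained so each part's
    present depends only on its own past (block-diagonal with respect to
    the partition) and the innovation covariance D is unconstrained —
    exactly the Markov condition that each M_i' is independent of the
    rest of the past given M_i.  Minimizing KL(p || q) over (B, D) is
    done by exact block-coordinate descent:

    * given D, the optimal within-part regression blocks solve a pair of
      coupled linear equations (normal equations preconditioned by
      D^{-1});
    * given B, the optimal D is the residual covariance of X' - B X
      under p.

    Each step minimizes the KL exactly in one coordinate block, so the
    objective is monotone non-increasing.  At a fixed point the value is
    0.5 * (log det D - log det Sigma(X'|X)).

    Raises
    ------
    ConvergenceError
        If the parameter change has not dropped below ``tol`` within
        ``max_iter`` iterations; no partial value is returned.
    """
    _check_part(joint, part)
    a, b = _sides(part)
    sxx = joint.cov_past
    syy = joint.cov_present
    syx = joint.cross.T  # cov(X', X)

    # full regression X' = A_hat X + eps and its residual covariance
    a_hat = np.linalg.solve(sxx, syx.T).T
    cond_cov = syy - a_hat @ joint.cross
    ld_cond = _logdet(0.5 * (cond_cov + cond_cov.T), "present-given-past")

    n = joint.n
    B = np.zeros((n, n))
    B[np.ix_(a, a)] = a_hat[np.ix_(a, a)]
    B[np.ix_(b, b)] = a_hat[np.ix_(b, b)]
    D = _residual_cov(syy, syx, sxx, B)

    sxx_aa = sxx[np.ix_(a, a)]
    sxx_bb = sxx[np.ix_(b, b)]
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        P = np.linalg.inv(D)
        B_prev = B.copy()
        D_prev = D

        # part-1 block, holding the part-2 block fixed
        rhs = P[np.ix_(a, a)] @ syx[np.ix_(a, a)] + P[np.ix_(a, b)] @ (
            syx[np.ix_(b, a)] - B[np.ix_(b, b)] @ sxx[np.ix_(b, a)]
        )
        tmp = np.linalg.solve(P[np.ix_(a, a)], rhs)
        B[np.ix_(a, a)] = np.linalg.solve(sxx_aa, tmp.T).T

        # part-2 block, using the refreshed part-1 block
        rhs = P[np.ix_(b, b)] @ syx[np.ix_(b, b)] + P[np.ix_(b, a)] @ (
            syx[np.ix_(a, b)] - B[np.ix_(a, a)] @ sxx[np.ix_(a, b)]
        )
        tmp = np.linalg.solve(P[np.ix_(b, b)], rhs)
        B[np.ix_(b, b)] = np.linalg.solve(sxx_bb, tmp.T).T

        D = _residual_cov(syy, syx, sxx, B)
        residual = max(
            float(np.abs(B - B_prev).max()), float(np.abs(D - D_prev).max())
        )
        if residual < tol:
            val = 0.5 * (_logdet(D, "optimized innovation") - ld_cond)
            return PhiValue(
                "g",
                _clamp(val, "g", tol=max(CLAMP_TOL, 10 * tol)),
                iterations=iteration,
                residual=residual,
                converged=True,
            )
    raise ConvergenceError(
        f"phi_g did not converge in {max_iter} iterations "
        f"(last parameter change {residual:.3e})",
        iterations=max_iter,
        residual=residual,
    )


_MEASURES = {"mi": phi_mi, "si": phi_si, "g": phi_g}


def phi(measure: str, joint: JointGaussian, part: Bipartition, **kwargs) -> PhiValue:
    """Dispatch to phi_mi / phi_si / phi_g by measure tag."""
    try:
        fn = _MEASURES[measure.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown measure {measure!r}; expected one of {sorted(_MEASURES)}"
        ) from None
    return fn(joint, part, **kwargs)


def _fast_logdet(cov: np.ndarray, name: str = "covariance") -> float:
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"{name} block is not positive definite") from exc
    return 2.0 * float(np.log(np.diagonal(chol)).sum())


def make_phi_function(joint: JointGaussian, measure: str, **kwargs):
    """Subset-valued view of a measure: ``f(S) -> float`` on 0-based subsets.

    The empty set and the full set are boundary cases of the symmetric
    set function and evaluate to 0.  Whole-system log-determinants are
    precomputed once, so the closures are cheap enough to serve as
    search oracles; values agree with phi_mi/phi_si/phi_g exactly.
    """
    measure = measure.lower()
    if measure not in _MEASURES:
        raise ValidationError(
            f"unknown measure {measure!r}; expected one of {sorted(_MEASURES)}"
        )
    n = joint.n
    sigma = joint.sigma
    past = joint.cov_past

    def _split(subset):
        # canonical side (containing element 0) first, so that f(S) and
        # f(complement) run the identical float computation
        s = frozenset(subset)
        if not s or len(s) == n:
            return None
        mask = np.zeros(n, dtype=bool)
        mask[list(s)] = True
        if not mask[0]:
            mask = ~mask
        return np.flatnonzero(mask), np.flatnonzero(~mask)

    def _sub_joint(idx: np.ndarray) -> np.ndarray:
        idx2 = np.concatenate([idx, idx + n])
        return sigma[np.ix_(idx2, idx2)]

    if measure == "mi":
        ld_full = _logdet(sigma, "full joint")

        def f(subset) -> float:
            sides = _split(subset)
            if sides is None:
                return 0.0
            a, b = sides
            val = 0.5 * (
                _fast_logdet(_sub_joint(a), "part-1 joint")
                + _fast_logdet(_sub_joint(b), "part-2 joint")
                - ld_full
            )
            return _clamp(val, "mi")

    elif measure == "si":
        ld_cond_full = _logdet(sigma, "full joint") - _logdet(past, "past")

        def f(subset) -> float:
            sides = _split(subset)
            if sides is None:
                return 0.0
            val = -0.5 * ld_cond_full
            for side, label in zip(sides, ("part-1", "part-2")):
                val += 0.5 * (
                    _fast_logdet(_sub_joint(side), f"{label} joint")
                    - _fast_logdet(past[np.ix_(side, side)], f"{label} past")
                )
            return _clamp(val, "si")

    else:  # geometric: the iterative solver dominates, no fast path needed

        def f(subset) -> float:
            sides = _split(subset)
            if sides is None:
                return 0.0
            part = Bipartition.from_members(subset, n)
            return float(phi_g(joint, part, **kwargs))

    f.measure = measure
    f.joint = joint
    return f
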