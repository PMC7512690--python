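import numpy as np
import pytest
from scipy import optimize, stats

from phimip import (
    ARModel,
    Bipartition,
    ConvergenceError,
    JointGaussian,
    ValidationError,
    gaussian_entropy,
    joint_gaussian,
    make_phi_function,
    phi_g,
    phi_mi,
    phi_si,
)
from phimip.measures import LOG_2PI_E, _clamp

from conftest import random_model


def direct_gaussian_kl(sigma_p, sigma_q):
    """KL(N(0, sigma_p) || N(0, sigma_q)) by the closed form (oracle)."""
    k = sigma_p.shape[0]
    inv_q = np.linalg.inv(sigma_q)
    return 0.5 * (
        np.trace(inv_q @ sigma_p)
        - k
        + np.linalg.slogdet(sigma_q)[1]
        - np.linalg.slogdet(sigma_p)[1]
    )


class TestGaussianEntropy:
    def test_univariate_closed_form(self):
        assert gaussian_entropy([[1.0]]) == pytest.approx(0.5 * LOG_2PI_E)

    def test_additivity_for_identity(self):
        assert gaussian_entropy(np.eye(2)) == pytest.approx(2 * gaussian_entropy([[1.0]]))

    def test_against_monte_carlo(self, rng):
        a = rng.normal(size=(4, 4))
        cov = a @ a.T + 4 * np.eye(4)
        x = rng.multivariate_normal(np.zeros(4), cov, size=1_000_000)
        mc = -np.mean(stats.multivariate_normal.logpdf(x, mean=np.zeros(4), cov=cov))
        assert gaussian_entropy(cov) == pytest.approx(mc, abs=0.01)

    def test_non_pd_rejected(self):
        with pytest.raises(ValidationError, match="positive definite"):
            gaussian_entropy(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestPhiMI:
    def test_independent_subsystems_give_zero(self):
        # joint covariance block diagonal in (M1, M1') vs (M2, M2')
        j1 = joint_gaussian(random_model(2, seed=0))
        j2 = joint_gaussian(random_model(2, seed=1))
        sigma = np.zeros((8, 8))
        idx1 = [0, 1, 4, 5]  # elements {1,2}: past 0,1 and present 4,5
        idx2 = [2, 3, 6, 7]
        sigma[np.ix_(idx1, idx1)] = j1.sigma
        sigma[np.ix_(idx2, idx2)] = j2.sigma
        joint = JointGaussian(sigma)
        part = Bipartition.from_members([0, 1], 4)
        assert float(phi_mi(joint, part)) == pytest.approx(0.0, abs=1e-12)

    def test_equals_direct_kl_to_product_of_marginals(self, small_joint):
        part = Bipartition.from_members([0], small_joint.n)
        a = list(part.members)
        b = list(part.complement)
        sigma_q = np.zeros_like(small_joint.sigma)
        for side in (a, b):
            idx = small_joint.joint_indices(side)
            sigma_q[np.ix_(idx, idx)] = small_joint.sub_joint(side)
        expected = direct_gaussian_kl(small_joint.sigma, sigma_q)
        assert float(phi_mi(small_joint, part)) == pytest.approx(expected, abs=1e-10)


class TestPhiSI:
    def test_zero_for_decoupled_white_system(self):
        # A = 0 with diagonal noise: present independent of past and across parts
        model = ARModel(np.zeros((4, 4)), np.diag([1.0, 2.0, 0.5, 3.0]))
        joint = joint_gaussian(model)
        part = Bipartition.from_members([0, 2], 4)
        assert float(phi_si(joint, part)) == pytest.approx(0.0, abs=1e-9)

    def test_zero_for_block_model_half_split(self, block_model_8):
        # transition law factorizes exactly over the two blocks when the
        # noise is also block diagonal
        h = block_model_8.n // 2
        sigma_e = np.array(block_model_8.sigma_e)
        sigma_e[:h, h:] = 0.0
        sigma_e[h:, :h] = 0.0
        model = ARModel(block_model_8.A, sigma_e)
        joint = joint_gaussian(model)
        part = Bipartition.from_members(range(h), model.n)
        assert float(phi_si(joint, part)) == pytest.approx(0.0, abs=1e-9)

    def test_against_monte_carlo_kl(self, rng):
        # q(X, X') = p(X) * prod_i p(M_i'|M_i): estimate KL(p || q) by sampling
        model = random_model(4, seed=21)
        joint = joint_gaussian(model)
        part = Bipartition.from_members([0, 3], 4)
        n = 4
        x = rng.multivariate_normal(np.zeros(2 * n), joint.sigma, size=1_000_000)
        log_p = stats.multivariate_normal.logpdf(x, cov=joint.sigma)
        log_q = stats.multivariate_normal.logpdf(x[:, :n], cov=joint.cov_past)
        for side in (list(part.members), list(part.complement)):
            idx = joint.joint_indices(side)
            sub = joint.sub_joint(side)  # covariance of (M, M')
            k = len(side)
            # conditional law M'|M from the sub-joint
            w = np.linalg.solve(sub[:k, :k], sub[:k, k:]).T
            cond_cov = sub[k:, k:] - w @ sub[:k, k:]
            resid = x[:, idx[k:]] - x[:, idx[:k]] @ w.T
            log_q += stats.multivariate_normal.logpdf(resid, cov=cond_cov)
        mc_kl = np.mean(log_p - log_q)
        assert float(phi_si(joint, part)) == pytest.approx(mc_kl, abs=0.01)


def phi_g_numeric_oracle(joint, part, tol=1e-13):
    """Black-box minimization of the Gaussian KL over the free parameters of q."""
    a = np.array(part.members)
    b = np.array(part.complement)
    n = joint.n
    sxx, syy, sxy = joint.cov_past, joint.cov_present, joint.cross
    syx = sxy.T
    a_hat = np.linalg.solve(sxx, syx.T).T
    ld_cond = np.linalg.slogdet(syy - a_hat @ sxy)[1]
    na, nb = len(a), len(b)
    nb_theta = na * na + nb * nb
    tril = np.tril_indices(n)

    def kl(theta):
        B = np.zeros((n, n))
        B[np.ix_(a, a)] = theta[: na * na].reshape(na, na)
        B[np.ix_(b, b)] = theta[na * na:nb_theta].reshape(nb, nb)
        L = np.zeros((n, n))
        L[tril] = theta[nb_theta:]
        if np.any(np.diag(L) <= 1e-8):
            return np.inf
        D = L @ L.T
        BS = B @ syx.T
        R = syy - BS - BS.T + B @ sxx @ B.T
        return 0.5 * (np.trace(np.linalg.solve(D, R)) - n + np.linalg.slogdet(D)[1] - ld_cond)

    B0 = np.zeros((n, n))
    B0[np.ix_(a, a)] = a_hat[np.ix_(a, a)]
    B0[np.ix_(b, b)] = a_hat[np.ix_(b, b)]
    BS0 = B0 @ syx.T
    L0 = np.linalg.cholesky(syy - BS0 - BS0.T + B0 @ sxx @ B0.T)
    theta0 = np.concatenate([B0[np.ix_(a, a)].ravel(), B0[np.ix_(b, b)].ravel(), L0[tril]])
    res = optimize.minimize(kl, theta0, method="Nelder-Mead",
                            options=dict(maxiter=200_000, maxfev=200_000, xatol=tol, fatol=tol))
    return res.fun


class TestPhiG:
    def test_zero_on_block_model_half_partition(self, block_model_8):
        joint = joint_gaussian(block_model_8)
        part = Bipartition.from_members(range(block_model_8.n // 2), block_model_8.n)
        val = phi_g(joint, part)
        assert val.value == pytest.approx(0.0, abs=1e-6)
        assert val.converged

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_generic_numeric_minimizer(self, seed):
        joint = joint_gaussian(random_model(4, seed=seed))
        part = Bipartition.from_members([0, 2], 4)
        mine = float(phi_g(joint, part))
        oracle = phi_g_numeric_oracle(joint, part)
        assert mine == pytest.approx(oracle, abs=1e-5)

    def test_never_exceeds_phi_si(self):
        for seed in range(10):
            joint = joint_gaussian(random_model(5, seed=seed))
            part = Bipartition.from_members([0, 1], 5)
            assert float(phi_g(joint, part)) <= float(phi_si(joint, part)) + 1e-7

    def test_nonconvergence_is_an_error(self, small_joint):
        part = Bipartition.from_members([0], small_joint.n)
        with pytest.raises(ConvergenceError) as err:
            phi_g(small_joint, part, tol=1e-16, max_iter=2)
        assert err.value.residual > 0

    def test_metadata_present(self, small_joint):
        part = Bipartition.from_members([0, 1], small_joint.n)
        val = phi_g(small_joint, part)
        assert val.iterations >= 1 and val.residual < 1e-8 and val.converged


class TestInvariants:
    @pytest.mark.parametrize("measure", ["mi", "si", "g"])
    def test_symmetry_and_nonnegativity(self, small_joint, measure):
        f = make_phi_function(small_joint, measure)
        n = small_joint.n
        for mask in range(1, 2**n - 1):
            s = {i for i in range(n) if mask >> i & 1}
            comp = set(range(n)) - s
            assert f(s) == f(comp)  # exact, required by the searchers
            assert f(s) >= 0.0
            if mask > 40:  # full sweep only for the cheap masks
                break

    def test_ordering_on_random_instances(self, rng):
        for seed in range(30):
            joint = joint_gaussian(random_model(4, seed=seed))
            mask = int(rng.integers(1, 2**4 - 1))
            part = Bipartition.from_members({i for i in range(4) if mask >> i & 1}, 4)
            g, si, mi = float(phi_g(joint, part)), float(phi_si(joint, part)), float(phi_mi(joint, part))
            assert g <= si + 1e-7 <= mi + 2e-7


def test_clamp_distinguishes_noise_from_bugs():
    assert _clamp(-1e-12, "mi") == 0.0
    with pytest.raises(ValidationError):
        _clamp(-1e-6, "mi")
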