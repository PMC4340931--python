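import numpy as np
import pytest
from scipy import integrate
from scipy.special import erfcinv
from scipy.stats import norm

from spinet.vbsr import (
    VbsrConvergenceError,
    _coordinate_posterior,
    _fit_one_restart,
    compute_penalty,
    pvalue_from_z,
    vbsr_fit,
)


def chi2_1_quantile(prob_upper):
    """Independent chi-squared(1) upper quantile via the error function:
    F^{-1}(1 - a) = (Phi^{-1}(1 - a/2))^2 = 2 * erfcinv(a)^2."""
    return 2.0 * erfcinv(prob_upper) ** 2


class TestPenalty:
    def test_log_odds_terms_cancel_at_half(self):
        pc = compute_penalty(m=50, n=30, p=0.5)
        expected = -chi2_1_quantile(0.05 / 50) - np.log(30)
        assert pc.l0 == pytest.approx(expected, rel=1e-10)

    def test_matches_independent_quantile_oracle(self):
        pc = compute_penalty(m=141, n=47, p=0.95)
        expected = (
            -chi2_1_quantile(0.05 / 141)
            - np.log(47)
            + 2 * np.log(0.05)
            - 2 * np.log(0.95)
        )
        assert pc.l0 == pytest.approx(expected, rel=1e-10)

    def test_strictly_decreasing_in_m(self):
        l0s = [compute_penalty(m, 47).l0 for m in (10, 100, 1000)]
        assert l0s[0] > l0s[1] > l0s[2]

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_p_rejected(self, p):
        with pytest.raises(ValueError):
            compute_penalty(m=10, n=10, p=p)


class TestPvalue:
    def test_center_and_reference_quantile(self):
        assert pvalue_from_z(0.0) == 1.0
        assert pvalue_from_z(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_decreasing_in_magnitude(self):
        zs = np.linspace(0, 8, 50)
        ps = pvalue_from_z(zs)
        assert np.all(np.diff(ps) < 0)
        np.testing.assert_allclose(pvalue_from_z(-zs), ps)


def quadrature_spike_posterior(y, x, sigma2, l0):
    """Single-coordinate spike posterior by numerical integration.

    Slab branch: improper flat prior of unit density with weight exp(l0/2)
    relative to the point mass at zero; alpha = slab mass / total mass.
    """
    d, c = x @ x, x @ y

    def relative_slab_like(beta):
        # likelihood ratio against beta = 0, avoiding tiny absolute scales
        return np.exp(-(beta * beta * d - 2 * beta * c) / (2 * sigma2))

    width = 50 * np.sqrt(sigma2 / d)
    center = c / d
    slab_mass, _ = integrate.quad(
        relative_slab_like, center - width, center + width,
        limit=400, epsabs=0, epsrel=1e-12,
    )
    num = np.exp(0.5 * l0) * slab_mass
    return num / (num + 1.0)


class TestCoordinateUpdate:
    def test_matches_quadrature_oracle(self, rng):
        """On a single coordinate the variational update is the exact posterior."""
        n = 40
        for effect in (0.0, 0.3, 1.0):
            x = rng.standard_normal(n)
            y = effect * x + rng.standard_normal(n)
            sigma2, l0 = 0.9, -12.0
            alpha, mu, s2 = _coordinate_posterior(x @ y, x @ x, sigma2, l0)
            alpha_oracle = quadrature_spike_posterior(y, x, sigma2, l0)
            assert alpha == pytest.approx(alpha_oracle, abs=1e-8)
            assert mu == pytest.approx((x @ y) / (x @ x), rel=1e-12)
            assert s2 == pytest.approx(sigma2 / (x @ x), rel=1e-12)


class TestFit:
    def test_single_predictor_matches_ols(self, rng):
        n = 100
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 2 * x + 0.3 * rng.standard_normal(n)
        y -= y.mean()
        fit = vbsr_fit(y, x[:, None], n_restarts=5, seed=0)
        d = x @ x
        bhat = (x @ y) / d
        rss = np.sum((y - bhat * x) ** 2)
        ols_z = bhat / np.sqrt(rss / (n - 1) / d)
        assert fit.z_stat[0] == pytest.approx(ols_z, rel=0.05)
        assert fit.inclusion_prob[0] > 0.999

    def test_null_design_controls_family_wise_error(self):
        """Pure-noise responses: no |z| exceeds the study's Bonferroni Z_crit
        in at least 95% of replicates at n = 47, q = 20."""
        z_crit = norm.ppf(1 - 0.025 / 14200)
        hits = 0
        n_reps = 200
        for rep in range(n_reps):
            r = np.random.default_rng([99, rep])
            X = r.standard_normal((47, 20))
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            y = r.standard_normal(47)
            y = (y - y.mean()) / y.std(ddof=1)
            fit = vbsr_fit(y, X, n_restarts=3, seed=rep)
            hits += np.any(np.abs(fit.z_stat) > z_crit)
        assert hits / n_reps <= 0.05

    def test_penalty_limits(self, rng):
        n, q = 50, 5
        X = rng.standard_normal((n, q))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X @ np.array([2.0, -1.5, 0.0, 0.0, 1.0]) + 0.5 * rng.standard_normal(n)
        y -= y.mean()
        hard = compute_penalty(m=q, n=n)
        empty = vbsr_fit(y, X, penalty=type(hard)(p=hard.p, m=q, n=n, l0=-1e6),
                         n_restarts=3, seed=0)
        assert empty.support.sum() == 0
        # orthogonalized design so the everything-in limit is well defined
        Q, _ = np.linalg.qr(X - X.mean(0))
        Xo = Q * np.sqrt(n - 1)
        full = vbsr_fit(y, Xo, penalty=type(hard)(p=hard.p, m=q, n=n, l0=1e6),
                        n_restarts=3, seed=0)
        assert full.support.all()

    def test_lower_bound_monotone_over_sweeps(self, rng):
        n, q = 60, 10
        X = rng.standard_normal((n, q))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X[:, 0] - 0.8 * X[:, 3] + rng.standard_normal(n)
        y -= y.mean()
        pen = compute_penalty(m=q, n=n)
        *_, trace = _fit_one_restart(
            X.T @ y, X.T @ X, np.einsum("ij,ij->j", X, X), float(y @ y),
            n, pen.l0, np.arange(q), 1000, 1e-8,
        )
        assert np.all(np.diff(trace) >= -1e-6)

    def test_predictor_permutation_equivariance(self, rng):
        n, q = 80, 6
        X = rng.standard_normal((n, q))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = 1.5 * X[:, 1] - X[:, 4] + rng.standard_normal(n)
        y -= y.mean()
        fit = vbsr_fit(y, X, n_restarts=20, seed=5)
        perm = np.array([3, 0, 5, 1, 4, 2])
        fit_p = vbsr_fit(y, X[:, perm], n_restarts=20, seed=5)
        np.testing.assert_allclose(fit_p.z_stat, fit.z_stat[perm], atol=1e-8)
        np.testing.assert_allclose(
            fit_p.inclusion_prob, fit.inclusion_prob[perm], atol=1e-8
        )

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((40, 8))
        y = rng.standard_normal(40)
        a = vbsr_fit(y, X, n_restarts=10, seed=7)
        b = vbsr_fit(y, X, n_restarts=10, seed=7)
        np.testing.assert_array_equal(a.z_stat, b.z_stat)
        assert a.lower_bound == b.lower_bound

    def test_non_convergence_carries_best_partial_fit(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        with pytest.raises(VbsrConvergenceError) as exc:
            vbsr_fit(y, X, n_restarts=2, seed=0, max_iter=1)
        assert exc.value.best_fit is not None
        assert exc.value.best_fit.z_stat.shape == (4,)
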