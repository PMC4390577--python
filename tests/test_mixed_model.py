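import numpy as np
import pytest

from tsblup import mixed_model as mm
from tsblup.errors import NonIdentifiableError, ValidationError
from tsblup.kinship import build_D, build_G, build_S, build_T, center_genotypes
from .conftest import random_genotypes


def solve_mme(y, X, Z, K, lam):
    """Independent oracle: Henderson's mixed model equations solved directly."""
    Kinv = np.linalg.inv(K)
    p = X.shape[1]
    lhs = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Kinv]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:p], sol[p:]


def random_instance(rng, n, m, frac_phenotyped=1.0, ridge=1e-6, kinship="G"):
    g = random_genotypes(rng, n, m)
    G = build_G(g)
    if kinship == "G":
        K = G.values + ridge * np.eye(n)
    else:
        chosen = list(g.marker_ids[: max(2, m // 5)])
        D = build_D(chosen, rng.uniform(0.2, 2.0, size=len(chosen)))
        T = build_T(build_S(g, D), G, omega=0.3)
        K = T.values + ridge * np.eye(n)
    n_ph = max(3, int(round(frac_phenotyped * n)))
    ph_idx = np.sort(rng.choice(n, size=n_ph, replace=False))
    X, Z = mm.design_matrices(g.individual_ids, g.individual_ids[ph_idx])
    y = rng.standard_normal(n_ph) + 1.0
    lam = float(rng.uniform(0.3, 3.0))
    return y, X, Z, K, lam


class TestGlsFixedEffects:
    def test_identity_covariance_gives_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        Z = np.eye(3)
        b = mm.gls_fixed_effects(y, X, Z, np.eye(3), 1.0)
        assert b[0] == pytest.approx(2.0, abs=1e-12)

    def test_constant_y(self, rng):
        y = np.full(5, 7.5)
        g = random_genotypes(rng, 5, 20)
        K = build_G(g).values + 1e-6 * np.eye(5)
        X, Z = mm.design_matrices(g.individual_ids, g.individual_ids)
        b = mm.gls_fixed_effects(y, X, Z, K, 0.8)
        assert b[0] == pytest.approx(7.5, abs=1e-10)

    def test_matches_mme_oracle(self, rng):
        y, X, Z, K, lam = random_instance(rng, 12, 30)
        b = mm.gls_fixed_effects(y, X, Z, K, lam)
        b_mme, _ = solve_mme(y, X, Z, K, lam)
        np.testing.assert_allclose(b, b_mme, atol=1e-10)


class TestSolveShat:
    def test_identity_case(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        Z = np.eye(3)
        s = mm.solve_shat(y, X, Z, np.eye(3), 1.0, np.array([2.0]))
        np.testing.assert_allclose(s, [-0.5, 0.0, 0.5], atol=1e-12)

    def test_perfect_fixed_fit_gives_zero(self, rng):
        y = np.full(4, 3.0)
        g = random_genotypes(rng, 4, 12)
        K = build_G(g).values + 1e-6 * np.eye(4)
        X, Z = mm.design_matrices(g.individual_ids, g.individual_ids)
        s = mm.solve_shat(y, X, Z, K, 1.2, np.array([3.0]))
        np.testing.assert_allclose(s, np.zeros(4), atol=1e-10)

    def test_kzt_shat_equals_mme_u(self, rng):
        y, X, Z, K, lam = random_instance(rng, 10, 25)
        b = mm.gls_fixed_effects(y, X, Z, K, lam)
        s = mm.solve_shat(y, X, Z, K, lam, b)
        _, u_mme = solve_mme(y, X, Z, K, lam)
        np.testing.assert_allclose(K @ Z.T @ s, u_mme, atol=1e-10)


class TestGebvFromShat:
    def test_identity(self):
        s = np.array([-0.5, 0.0, 0.5])
        np.testing.assert_array_equal(mm.gebv_from_shat(np.eye(3), np.eye(3), s), s)

    def test_unrelated_candidate_gets_zero(self):
        K = np.eye(4)
        K[3, :3] = K[:3, 3] = 0.0
        X, Z = mm.design_matrices(["a", "b", "c", "d"], ["a", "b", "c"])
        gebv = mm.gebv_from_shat(K, Z, np.array([0.3, -0.1, 0.9]))
        assert gebv[3] == 0.0

    def test_with_unphenotyped_matches_mme(self, rng):
        y, X, Z, K, lam = random_instance(rng, 20, 50, frac_phenotyped=0.8)
        b = mm.gls_fixed_effects(y, X, Z, K, lam)
        s = mm.solve_shat(y, X, Z, K, lam, b)
        gebv = mm.gebv_from_shat(K, Z, s)
        _, u_mme = solve_mme(y, X, Z, K, lam)
        np.testing.assert_allclose(gebv, u_mme, atol=1e-10)


class TestEquivalenceProperty:
    @pytest.mark.parametrize("seed", range(10))
    def test_mme_equivalence_G_and_T(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        m = int(rng.integers(2 * n, 3 * n))
        kinship = "G" if seed % 2 == 0 else "T"
        y, X, Z, K, lam = random_instance(
            rng, n, m, frac_phenotyped=float(rng.uniform(0.7, 1.0)), kinship=kinship
        )
        fit = mm.solve_blup(y, X, Z, K, lam)
        b_mme, u_mme = solve_mme(y, X, Z, K, lam)
        np.testing.assert_allclose(fit.b_hat, b_mme, atol=1e-10)
        np.testing.assert_allclose(fit.gebv, u_mme, atol=1e-10)


class TestMarkerEffects:
    def test_tiny_example(self):
        from tsblup.kinship import CenteredGenotypes

        M = CenteredGenotypes(
            marker_ids=np.array(["m1", "m2"], dtype=object),
            values=np.array([[-1.0, 1.0], [1.0, -1.0]]),
            scale_constant=1.0,
        )
        g = mm.marker_effects_rrblup(M, np.eye(2), np.array([0.5, -0.5]))
        np.testing.assert_allclose(g, [-1.0, 1.0])

    def test_zero_shat_gives_zero_effects(self, rng):
        g = random_genotypes(rng, 5, 12)
        cg = center_genotypes(g)
        eff = mm.marker_effects_rrblup(cg, np.eye(5), np.zeros(5))
        np.testing.assert_array_equal(eff, np.zeros(12))

    def test_scale_mismatch_error(self, rng):
        g = random_genotypes(rng, 5, 12)
        cg = center_genotypes(g)
        with pytest.raises(ValidationError):
            mm.marker_effects_rrblup(cg, np.eye(5), np.zeros(5), scale_constant=3.0)

    def test_stranden_garrick_identity(self, rng):
        n, m = 15, 40
        g = random_genotypes(rng, n, m)
        G = build_G(g)
        cg = center_genotypes(g)
        X, Z = mm.design_matrices(g.individual_ids, g.individual_ids)
        y = rng.standard_normal(n)
        fit = mm.solve_blup(y, X, Z, G, 1.5)
        eff = mm.marker_effects_rrblup(cg, Z, fit.s_hat)
        np.testing.assert_allclose(cg.values @ eff, fit.gebv, atol=1e-10)


class TestReml:
    def _simulate_under_model(self, rng, n, m, h2):
        g = random_genotypes(rng, n, m)
        K = build_G(g).values + 1e-8 * np.eye(n)
        L = np.linalg.cholesky(K)
        sigma_u2, sigma_e2 = h2, 1.0 - h2
        u = np.sqrt(sigma_u2) * (L @ rng.standard_normal(n))
        y = 2.0 + u + np.sqrt(sigma_e2) * rng.standard_normal(n)
        X, Z = mm.design_matrices(g.individual_ids, g.individual_ids)
        return y, X, Z, K

    def test_grid_oracle(self, rng):
        y, X, Z, K = self._simulate_under_model(rng, 60, 150, 0.5)
        vc = mm.estimate_variance_components(y, X, Z, K)
        xi, eta, df = mm._projected_spectrum(y, X, Z, K)
        eta2 = eta**2

        def negll(h2):
            delta = (1 - h2) / h2
            v = xi + delta
            return 0.5 * (df * np.log(eta2 @ (1 / v)) + np.log(v).sum())

        grid = np.linspace(1e-3, 1 - 1e-3, 1000)
        values = np.array([negll(h) for h in grid])
        assert negll(vc.h2) <= values.min() + 1e-9
        assert abs(vc.h2 - grid[values.argmin()]) <= grid[1] - grid[0]

    def test_lambda_consistency(self, rng):
        y, X, Z, K = self._simulate_under_model(rng, 50, 120, 0.4)
        vc = mm.estimate_variance_components(y, X, Z, K)
        assert vc.lam == pytest.approx(vc.sigma_e2 / vc.sigma_u2, abs=1e-10)
        assert np.isfinite(vc.log_restricted_likelihood)

    def test_recovery_h2_half(self):
        # scaled-down parameter recovery; the full-size check lives in the
        # acceptance suite
        estimates = []
        for seed in range(15):
            rng = np.random.default_rng(1000 + seed)
            y, X, Z, K = self._simulate_under_model(rng, 300, 700, 0.5)
            estimates.append(mm.estimate_variance_components(y, X, Z, K).h2)
        assert abs(np.mean(estimates) - 0.5) <= 0.08

    def test_pure_noise_shrinks_to_zero(self):
        # REML sampling error for h2 at n=500 is ~0.08, so individual
        # estimates regularly land just above 0.1; assert the boundary
        # behavior at thresholds the sampling distribution supports
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            g = random_genotypes(rng, 500, 1000)
            K = build_G(g).values
            X, Z = mm.design_matrices(g.individual_ids, g.individual_ids)
            y = rng.standard_normal(500)
            estimates.append(mm.estimate_variance_components(y, X, Z, K).h2)
        estimates = np.array(estimates)
        assert np.mean(estimates < 0.2) >= 0.9
        assert np.mean(estimates < 0.02) >= 0.5  # boundary mass at zero
        assert estimates.mean() < 0.08

    def test_identity_kinship_not_identifiable(self, rng):
        y = rng.standard_normal(20)
        X = np.ones((20, 1))
        Z = np.eye(20)
        with pytest.raises(NonIdentifiableError):
            mm.estimate_variance_components(y, X, Z, np.eye(20))


class TestShrinkage:
    def test_large_lambda_kills_gebv(self, rng):
        y, X, Z, K, _ = random_instance(rng, 15, 40)
        norms = []
        for lam in (0.1, 10.0, 1e4, 1e8):
            fit = mm.solve_blup(y, X, Z, K, lam)
            norms.append(np.linalg.norm(fit.gebv))
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3

    def test_small_lambda_interpolates(self, rng):
        n = 12
        g = random_genotypes(rng, n, 3 * n)
        K = build_G(g).values + 1e-4 * np.eye(n)
        X, Z = mm.design_matrices(g.individual_ids, g.individual_ids)
        y = rng.standard_normal(n)
        fit = mm.solve_blup(y, X, Z, K, 1e-10)
        fitted = X @ fit.b_hat + Z @ fit.gebv
        np.testing.assert_allclose(fitted, y, atol=1e-5)


class TestMetrics:
    def test_accuracy_perfect(self):
        assert mm.accuracy([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_accuracy_reversed(self):
        assert mm.accuracy([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_accuracy_loop_oracle(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        am, bm = a.mean(), b.mean()
        num = sum((x - am) * (y - bm) for x, y in zip(a, b))
        den = np.sqrt(sum((x - am) ** 2 for x in a) * sum((y - bm) ** 2 for y in b))
        assert mm.accuracy(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_accuracy_zero_variance_raises(self):
        with pytest.raises(ValidationError):
            mm.accuracy([1, 1, 1], [1, 2, 3])

    def test_unbiasedness_scale(self):
        assert mm.unbiasedness([1, 2, 3], [2, 4, 6]) == pytest.approx(2.0)

    def test_unbiasedness_identity(self):
        assert mm.unbiasedness([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_unbiasedness_closed_form(self, rng):
        gebv = rng.standard_normal(25)
        ref = rng.standard_normal(25)
        cov = np.cov(gebv, ref, ddof=1)[0, 1]
        assert mm.unbiasedness(gebv, ref) == pytest.approx(
            cov / np.var(gebv, ddof=1), abs=1e-12
        )
        fwd, rev = mm.regression_slopes(gebv, ref)
        assert rev == pytest.approx(cov / np.var(ref, ddof=1), abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            mm.accuracy([1, 2], [1, 2])
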