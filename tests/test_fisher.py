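"""Fisher density, resultant summaries, ML fitting and the exact sampler."""

import numpy as np
import pytest
from scipy import integrate, stats

from spherout import (
    FisherParams,
    fisher_pdf,
    fit_fisher,
    from_cartesian,
    mean_resultant_a,
    resultant,
    rotate_to_mean,
    sample_fisher,
    to_cartesian,
)
from spherout.fisher import kappa_approx, kappa_mle, sample_pole

from conftest import random_unit_vectors


class TestDensity:
    @pytest.mark.parametrize("kappa", [0.1, 1.0, 5.0, 20.0, 100.0])
    def test_normalization(self, kappa):
        params = FisherParams(alpha=0.7, beta=1.2, kappa=kappa)
        total, _ = integrate.dblquad(
            lambda p, t: fisher_pdf(t, p, params), 0.0, np.pi, 0.0, 2 * np.pi,
            epsabs=1e-8,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_vanishes_at_pole_and_symmetric_about_it(self):
        params = FisherParams(alpha=0.0, beta=0.0, kappa=3.0)
        assert fisher_pdf(0.0, 1.0, params) == 0.0
        phis = np.linspace(0, 2 * np.pi, 7, endpoint=False)
        vals = fisher_pdf(np.full_like(phis, 0.8), phis, params)
        assert np.allclose(vals, vals[0], atol=1e-14)

    def test_huge_kappa_does_not_overflow(self):
        params = FisherParams(alpha=0.0, beta=0.0, kappa=2000.0)
        v = fisher_pdf(1e-2, 0.0, params)
        assert np.isfinite(v) and v > 0

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            FisherParams(alpha=0.0, beta=0.0, kappa=0.0)
        with pytest.raises(ValueError):
            FisherParams(alpha=0.0, beta=0.0, kappa=-1.0)


class TestResultant:
    def test_single_point(self):
        v = to_cartesian(0.4, 1.1)
        s = resultant(v[None, :])
        assert s.R == pytest.approx(1.0, abs=1e-12)
        assert s.mean_direction == pytest.approx((0.4, 1.1), abs=1e-12)

    def test_antipodal_pair_is_degenerate(self):
        v = to_cartesian(0.4, 1.1)
        s = resultant(np.stack([v, -v]))
        assert s.degenerate
        assert s.mean_direction is None

    def test_eye_data_mean_direction(self, eye_vectors):
        s = resultant(eye_vectors)
        theta, phi = s.mean_direction
        assert theta == pytest.approx(0.6833, abs=2e-3)
        assert phi == pytest.approx(1.5744, abs=2e-3)

    def test_permutation_invariant_and_rotation_equivariant(self, rng):
        V = random_unit_vectors(15, rng)
        s = resultant(V)
        s_perm = resultant(V[rng.permutation(15)])
        assert s_perm.R == pytest.approx(s.R, abs=1e-12)
        alpha, beta = 0.9, 2.5
        s_rot = resultant(rotate_to_mean(V, alpha, beta))
        expected = rotate_to_mean(to_cartesian(*s.mean_direction), alpha, beta)
        assert np.allclose(to_cartesian(*s_rot.mean_direction), expected, atol=1e-10)


class TestFit:
    def test_eye_data_kappa(self, eye_vectors):
        params = fit_fisher(eye_vectors)
        assert params.kappa == pytest.approx(17.9100, abs=5e-2)

    def test_modified_eye_data_kappa(self, eye_vectors_modified):
        params = fit_fisher(eye_vectors_modified)
        assert params.kappa == pytest.approx(16.5789, abs=5e-2)

    def test_exact_mle_closer_to_reported_value_than_approximation(self, eye_vectors):
        """Of the candidate estimators, the exact ML equation solved at Rbar
        is the one that reproduces the reported eye-data concentration; the
        (n-1)/(n-R) approximation is off by ~0.8."""
        s = resultant(eye_vectors)
        exact = kappa_mle(s.Rbar)
        approx = kappa_approx(s.n, s.R)
        assert abs(exact - 17.9100) < 0.05
        assert abs(approx - 17.9100) > 0.5

    def test_mle_solves_the_score_equation(self, rng):
        for rbar in [0.05, 0.4, 0.9, 0.999]:
            k = kappa_mle(rbar)
            assert mean_resultant_a(k) == pytest.approx(rbar, abs=1e-10)

    def test_identical_points_rejected(self):
        V = np.tile(to_cartesian(0.3, 0.3), (5, 1))
        with pytest.raises(ValueError):
            fit_fisher(V)

    def test_parameter_recovery(self, rng):
        true = FisherParams(alpha=0.8, beta=2.0, kappa=5.0)
        V = sample_fisher(true, 10_000, rng)
        est = fit_fisher(V)
        assert est.kappa == pytest.approx(5.0, rel=0.05)
        assert est.alpha == pytest.approx(true.alpha, abs=0.03)
        assert est.beta == pytest.approx(true.beta, abs=0.05)


class TestSampler:
    def test_reproducible_per_seed(self):
        p = FisherParams(alpha=0.5, beta=1.0, kappa=8.0)
        a = sample_fisher(p, 100, np.random.default_rng(7))
        b = sample_fisher(p, 100, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_concentration_limit(self, rng):
        p = FisherParams(alpha=0.7, beta=1.9, kappa=1e6)
        V = sample_fisher(p, 1000, rng)
        mu = to_cartesian(0.7, 1.9)
        assert np.all(np.arccos(np.clip(V @ mu, -1, 1)) < 0.01)

    def test_mean_cosine_matches_closed_form(self, rng):
        # E[cos theta'] about the mean is A(kappa) = coth(kappa) - 1/kappa
        w = sample_pole(2.0, 100_000, rng)[:, 2]
        assert w.mean() == pytest.approx(mean_resultant_a(2.0), abs=0.01)

    def test_longitude_uniform_about_pole(self, rng):
        V = sample_pole(5.0, 20_000, rng)
        _, phi = from_cartesian(V)
        # KS test against Uniform[0, 2 pi); 1% critical value
        ks = stats.kstest(phi, stats.uniform(loc=0, scale=2 * np.pi).cdf)
        assert ks.statistic < 1.63 / np.sqrt(len(phi))

    def test_invalid_arguments(self, rng):
        p = FisherParams(alpha=0.0, beta=0.0, kappa=2.0)
        with pytest.raises(ValueError):
            sample_fisher(p, 0, rng)
        with pytest.raises(ValueError):
            sample_pole(-1.0, 10, rng)
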