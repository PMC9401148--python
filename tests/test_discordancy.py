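"""The Q^k, C^k and E^k statistics against brute-force oracles and the
published worked-example values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spherout import (
    ck_statistic,
    ek_statistic,
    qk_statistic,
    qk_statistics,
    rotate_to_mean,
    sphere_distance,
    to_cartesian,
)

from conftest import random_unit_vectors


def brute_force_qk(V, k):
    """All-pairs distances with a full ascending sort, k-th entry per row."""
    n = len(V)
    out = np.empty(n)
    for i in range(n):
        d = sorted(sphere_distance(V[i], V[j]) for j in range(n) if j != i)
        out[i] = d[k - 1]
    return out


def loo_resultants_from_scratch(V):
    n = len(V)
    return np.array([np.linalg.norm(np.delete(V, i, axis=0).sum(axis=0)) for i in range(n)])


class TestQk:
    # printed worked-example values; tolerance reflects the 3-decimal
    # rounding of the published input angles
    @pytest.mark.parametrize("k,expected", [(1, 0.0366), (2, 0.1702), (3, 0.1930)])
    def test_eye_data_observation_17(self, eye_vectors, k, expected):
        stat = qk_statistic(eye_vectors, k)
        assert stat.per_obs[16] == pytest.approx(expected, abs=2e-3)

    @pytest.mark.parametrize(
        "obs,values",
        [(9, (0.0022, 0.1844, 0.1871)), (16, (0.0022, 0.1702, 0.1928))],
    )
    def test_modified_eye_data_patch(self, eye_vectors_modified, obs, values):
        for k, expected in zip((1, 2, 3), values):
            stat = qk_statistic(eye_vectors_modified, k)
            assert stat.per_obs[obs] == pytest.approx(expected, abs=2e-3)

    def test_identical_points_give_zero(self):
        V = np.tile(to_cartesian(0.3, 1.0), (6, 1))
        for k in (1, 2, 5):
            assert np.allclose(qk_statistic(V, k).per_obs, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1), st.integers(4, 8))
    def test_matches_brute_force(self, seed, n):
        V = random_unit_vectors(n, np.random.default_rng(seed))
        for k in range(1, n):
            assert np.allclose(qk_statistic(V, k).per_obs, brute_force_qk(V, k), atol=1e-12)

    def test_nondecreasing_in_k(self, rng):
        V = random_unit_vectors(12, rng)
        stats = qk_statistics(V, range(1, 12))
        per = np.stack([stats[k].per_obs for k in range(1, 12)])
        assert np.all(np.diff(per, axis=0) >= -1e-15)

    def test_invalid_k(self, rng):
        V = random_unit_vectors(5, rng)
        with pytest.raises(ValueError):
            qk_statistic(V, 0)
        with pytest.raises(ValueError):
            qk_statistic(V, 5)

    def test_multi_k_consistent_with_single_k(self, rng):
        V = random_unit_vectors(9, rng)
        multi = qk_statistics(V, [1, 3, 5])
        for k in (1, 3, 5):
            assert np.allclose(multi[k].per_obs, qk_statistic(V, k).per_obs)


class TestCk:
    def test_eye_data_observation_17(self, eye_vectors):
        assert ck_statistic(eye_vectors).per_obs[16] == pytest.approx(0.0104, abs=2e-3)

    def test_modified_eye_data(self, eye_vectors_modified):
        stat = ck_statistic(eye_vectors_modified)
        assert stat.per_obs[9] == pytest.approx(0.0099, abs=2e-3)
        assert stat.per_obs[16] == pytest.approx(0.0100, abs=2e-3)

    def test_matches_from_scratch_recomputation(self, rng):
        V = random_unit_vectors(20, rng)
        n = len(V)
        R_loo = loo_resultants_from_scratch(V)
        rbar = np.linalg.norm(V.sum(axis=0)) / n
        expected = (R_loo / (n - 1) - rbar) / rbar
        assert np.allclose(ck_statistic(V).per_obs, expected, atol=1e-10)

    def test_deleting_central_point_never_looks_discordant(self, rng):
        # removing a point that sits exactly at the mean direction of the
        # others cannot raise the mean resultant length, so its C value is
        # nonpositive
        others = random_unit_vectors(10, rng)
        S = others.sum(axis=0)
        centre = S / np.linalg.norm(S)
        V = np.vstack([others, centre])
        assert ck_statistic(V).per_obs[-1] <= 1e-12


class TestEk:
    def test_eye_data_observation_17(self, eye_vectors):
        assert ek_statistic(eye_vectors).per_obs[16] == pytest.approx(5.6622, abs=2e-2)

    def test_modified_eye_data(self, eye_vectors_modified):
        stat = ek_statistic(eye_vectors_modified)
        assert stat.per_obs[9] == pytest.approx(4.9557, abs=2e-2)
        assert stat.per_obs[16] == pytest.approx(5.0162, abs=2e-2)

    def test_matches_from_scratch_recomputation(self, rng):
        V = random_unit_vectors(15, rng)
        n = len(V)
        R_loo = loo_resultants_from_scratch(V)
        R_n = np.linalg.norm(V.sum(axis=0))
        expected = (n - 2) * (1 + R_loo - R_n) / (n - 1 - R_loo)
        assert np.allclose(ek_statistic(V).per_obs, expected, atol=1e-10)

    def test_grows_as_lone_point_moves_away(self):
        rng = np.random.default_rng(3)
        cluster = rotate_to_mean(
            np.stack([to_cartesian(t, p) for t, p in rng.random((9, 2)) * [0.05, 6.28]]),
            0.0, 0.0,
        )
        values = []
        for theta in np.linspace(0.2, 2.8, 14):
            V = np.vstack([cluster, to_cartesian(theta, 0.0)])
            values.append(ek_statistic(V).per_obs[-1])
        assert np.all(np.diff(values) > 0)


def test_all_statistics_rotation_invariant(rng):
    V = random_unit_vectors(18, rng)
    W = rotate_to_mean(V, 1.1, 4.0)
    for k in (1, 2, 3):
        assert np.allclose(qk_statistic(V, k).per_obs, qk_statistic(W, k).per_obs, atol=1e-10)
    assert np.allclose(ck_statistic(V).per_obs, ck_statistic(W).per_obs, atol=1e-10)
    assert np.allclose(ek_statistic(V).per_obs, ek_statistic(W).per_obs, atol=1e-10)
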