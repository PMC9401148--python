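"""Discordancy statistics for spherical samples: Q^k, C^k and E^k.

Q^k is the k-nearest-neighbour distance statistic: for each observation i,
the k-th smallest ``1 - cos`` distance to the other observations.  Isolated
points — single outliers for k = 1, patches of k outliers for larger k —
produce large values.

C^k and E^k are the classical leave-one-out competitors.  With ``R_n`` the
full-sample resultant length and ``R_{n-1}^(-i)`` the resultant after
deleting observation i,

    C_i = (Rbar_{n-1}^(-i) - Rbar_n) / Rbar_n
    E_i = (n - 2) (1 + R_{n-1}^(-i) - R_n) / (n - 1 - R_{n-1}^(-i)),

large values again indicating that deleting i makes the rest more
concentrated.  All three statistics are invariant under a common rotation of
the sample; per-observation indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere import pairwise_distances

__all__ = ["StatisticValues", "qk_statistic", "qk_statistics", "ck_statistic", "ek_statistic"]

STATISTIC_NAMES = ("Q", "C", "E")


@dataclass(frozen=True)
class StatisticValues:
    """Per-observation values of one discordancy statistic.

    ``k`` is the neighbour order for Q and ``None`` for C/E.  ``argmax`` is
    the 0-based index of the observation attaining ``max_value``.
    """

    name: str
    k: int | None
    per_obs: np.ndarray
    max_value: float
    argmax: int

    @classmethod
    def _from_values(cls, name, k, per_obs):
        per_obs = np.asarray(per_obs, dtype=float)
        i = int(np.argmax(per_obs))
        return cls(name=name, k=k, per_obs=per_obs, max_value=float(per_obs[i]), argmax=i)


def _check_sample(V, min_n: int) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of unit vectors")
    if len(V) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return V


def _kth_neighbour_distances(D: np.ndarray, k: int) -> np.ndarray:
    # The self-distance (diagonal) is exactly 0 and occupies one of the lowest
    # ranks, so the k-th smallest distance to the *other* points is the
    # element of rank k (0-based) of each row including the diagonal.
    return np.partition(D, k, axis=-1)[..., k]


def qk_statistic(V, k: int) -> StatisticValues:
    """k-nearest-neighbour distance Q_i^k for every observation.

    Distances are sorted ascending; tied distances occupy consecutive ranks.
    Requires ``1 <= k <= n - 1``.
    """
    V = _check_sample(V, 2)
    n = len(V)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n - 1, got k={k}, n={n}")
    per_obs = _kth_neighbour_distances(pairwise_distances(V), k)
    return StatisticValues._from_values("Q", k, per_obs)


def qk_statistics(V, ks) -> dict[int, StatisticValues]:
    """Q^k for several neighbour orders from one distance matrix."""
    V = _check_sample(V, 2)
    n = len(V)
    ks = sorted(set(int(k) for k in ks))
    if not ks or ks[0] < 1 or ks[-1] > n - 1:
        raise ValueError("neighbour orders must satisfy 1 <= k <= n - 1")
    D = np.partition(pairwise_distances(V), ks, axis=-1)
    return {k: StatisticValues._from_values("Q", k, D[:, k]) for k in ks}


def _loo_resultant_lengths(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Leave-one-out resultant lengths ``R_{n-1}^(-i)`` and full-sample ``R_n``.

    Uses the algebraic update ``S - x_i``; equivalent to recomputing the
    resultant on each (n-1)-subset.
    """
    S = V.sum(axis=0)
    R_n = float(np.linalg.norm(S))
    R_loo = np.linalg.norm(S[None, :] - V, axis=1)
    return R_loo, R_n


def ck_statistic(V) -> StatisticValues:
    """Relative increase of the mean resultant length upon deleting each point."""
    V = _check_sample(V, 3)
    n = len(V)
    R_loo, R_n = _loo_resultant_lengths(V)
    if R_n < 1e-12 * n:
        raise ValueError("degenerate sample: resultant length is zero")
    rbar = R_n / n
    per_obs = (R_loo / (n - 1) - rbar) / rbar
    return StatisticValues._from_values("C", None, per_obs)


def ek_statistic(V) -> StatisticValues:
    """Likelihood-ratio-type statistic from the leave-one-out resultants."""
    V = _check_sample(V, 4)
    n = len(V)
    R_loo, R_n = _loo_resultant_lengths(V)
    denom = (n - 1) - R_loo
    if np.any(denom <= 1e-12):
        raise ValueError("degenerate sample: n - 1 points are coincident")
    per_obs = (n - 2) * (1.0 + R_loo - R_n) / denom
    return StatisticValues._from_values("E", None, per_obs)


# --- batched kernels over stacks of samples (used by the Monte-Carlo code) ---


def batch_qk_per_obs(W: np.ndarray, ks) -> dict[int, np.ndarray]:
    """Q_i^k for a ``(reps, n, 3)`` stack; returns ``(reps, n)`` per k."""
    reps, n, _ = W.shape
    D = 1.0 - np.einsum("rik,rjk->rij", W, W)
    np.clip(D, 0.0, 2.0, out=D)
    D[:, np.arange(n), np.arange(n)] = 0.0
    ks = sorted(set(int(k) for k in ks))
    D = np.partition(D, ks, axis=-1)
    return {k: D[:, :, k] for k in ks}


def batch_ce_per_obs(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """C_i and E_i for a ``(reps, n, 3)`` stack; each ``(reps, n)``."""
    reps, n, _ = W.shape
    S = W.sum(axis=1)
    R_n = np.linalg.norm(S, axis=-1)
    R_loo = np.linalg.norm(S[:, None, :] - W, axis=-1)
    rbar = (R_n / n)[:, None]
    C = (R_loo / (n - 1) - rbar) / rbar
    E = (n - 2) * (1.0 + R_loo - R_n[:, None]) / ((n - 1) - R_loo)
    return C, E
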