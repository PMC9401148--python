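"""Sequential outlier detection with the Q^k statistic.

The procedure starts at k = 1 and tests the first-nearest-neighbour
distances against a Monte-Carlo cut-off calibrated at the sample's
``(n, kappa)``.  If any observation exceeds the cut-off, those observations
are declared a patch of k outliers and the procedure stops; otherwise k is
increased by one, up to ``max_k``.  A single outlier is the k = 1 case.

``kappa`` for the calibration defaults to the maximum-likelihood estimate
from the *full* sample, suspected outliers included — the plug-in choice is
susceptible to masking when contamination is heavy, but it is the standard
practice for these tests and the package default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import DEFAULT_REPS, simulate_cutoff, simulate_qk_cutoffs
from .discordancy import StatisticValues, ck_statistic, ek_statistic, qk_statistics
from .fisher import fit_fisher

__all__ = ["DetectionResult", "apply_test", "detect_sequential"]


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of a discordancy test or of the sequential procedure.

    ``flagged`` lists the 0-based indices whose statistic value strictly
    exceeds the cut-off.  For the sequential procedure ``stopped_at_k`` is
    the smallest k with a non-empty flag set (or ``max_k`` if none) and
    ``declared_patch_size`` equals that k when anything was flagged.
    ``all_values`` keeps the per-k statistic values examined along the way.
    """

    statistic: str
    k_used: int | None
    per_obs: np.ndarray
    cutoff: float
    level: float | None
    flagged: tuple[int, ...]
    stopped_at_k: int | None = None
    declared_patch_size: int | None = None
    kappa: float | None = None
    all_values: dict = field(default_factory=dict, repr=False)
    cutoffs: dict = field(default_factory=dict, repr=False)

    @property
    def detected(self) -> bool:
        return len(self.flagged) > 0


def apply_test(values: StatisticValues, cutoff: float, level: float | None = None) -> DetectionResult:
    """Flag every observation whose statistic value strictly exceeds ``cutoff``."""
    if not np.isfinite(cutoff) and not cutoff == np.inf:
        raise ValueError("cutoff must be a number or +inf")
    if cutoff < 0 and values.name == "Q":
        raise ValueError("a Q cutoff must be nonnegative")
    flagged = tuple(int(i) for i in np.nonzero(values.per_obs > cutoff)[0])
    return DetectionResult(
        statistic=values.name, k_used=values.k, per_obs=values.per_obs,
        cutoff=float(cutoff), level=level, flagged=flagged,
    )


def detect_sequential(
    V,
    level: float = 0.10,
    max_k: int = 3,
    kappa: float | None = None,
    reps: int = DEFAULT_REPS,
    seed=None,
    rng=None,
    include_neighbours: bool = False,
) -> DetectionResult:
    """Run the sequential Q^k procedure on a sample of unit vectors.

    Parameters
    ----------
    V : (n, 3) array
        The sample as direction cosines.
    level : float
        Upper-tail significance level of each cut-off (0.10, 0.05 or 0.01).
    max_k : int
        Largest neighbour order tried before giving up (capped at n - 2).
    kappa : float, optional
        Concentration used to calibrate the cut-offs; fitted from the full
        sample when omitted.
    reps, seed, rng
        Monte-Carlo calibration control; cut-offs for all k are simulated
        from one shared set of null samples.
    include_neighbours : bool
        Alternative patch-membership rule: flag each exceeding observation
        together with its k - 1 nearest neighbours.  Off by default; the
        default rule flags exactly the observations whose Q_i^k exceeds the
        cut-off.
    """
    V = np.asarray(V, dtype=float)
    n = len(V)
    if n < 5:
        raise ValueError("need at least 5 observations")
    max_k = min(int(max_k), n - 2)
    if max_k < 1:
        raise ValueError("max_k must be at least 1")
    if kappa is None:
        kappa = fit_fisher(V).kappa
    ks = list(range(1, max_k + 1))
    tables = simulate_qk_cutoffs(n, kappa, ks, levels=(level,), reps=reps, seed=seed, rng=rng)
    values = qk_statistics(V, ks)

    all_values = {k: values[k].per_obs for k in ks}
    cutoffs = {k: tables[k].values[0] for k in ks}
    for k in ks:
        cq = cutoffs[k]
        exceed = np.nonzero(values[k].per_obs > cq)[0]
        if exceed.size:
            flagged = set(int(i) for i in exceed)
            if include_neighbours and k > 1:
                from .sphere import pairwise_distances

                D = pairwise_distances(V)
                for i in list(flagged):
                    order = np.argsort(D[i], kind="stable")
                    flagged.update(int(j) for j in order[1:k] )
            return DetectionResult(
                statistic="Q", k_used=k, per_obs=values[k].per_obs, cutoff=cq,
                level=level, flagged=tuple(sorted(flagged)), stopped_at_k=k,
                declared_patch_size=k, kappa=kappa, all_values=all_values,
                cutoffs=cutoffs,
            )
    return DetectionResult(
        statistic="Q", k_used=max_k, per_obs=values[max_k].per_obs,
        cutoff=cutoffs[max_k], level=level, flagged=(), stopped_at_k=max_k,
        declared_patch_size=None, kappa=kappa, all_values=all_values,
        cutoffs=cutoffs,
    )


def detect_with_statistic(
    V,
    statistic: str,
    level: float = 0.10,
    k: int = 1,
    kappa: float | None = None,
    reps: int = DEFAULT_REPS,
    seed=None,
    rng=None,
) -> DetectionResult:
    """One-shot test with C, E or a single-k Q, calibrating its own cut-off."""
    V = np.asarray(V, dtype=float)
    statistic = statistic.upper()
    if kappa is None:
        kappa = fit_fisher(V).kappa
    table = simulate_cutoff(statistic, len(V), kappa,
                            k=k if statistic == "Q" else None,
                            levels=(level,), reps=reps, seed=seed, rng=rng)
    if statistic == "Q":
        values = qk_statistics(V, [k])[k]
    elif statistic == "C":
        values = ck_statistic(V)
    else:
        values = ek_statistic(V)
    res = apply_test(values, table.values[0], level=level)
    return DetectionResult(
        statistic=res.statistic, k_used=res.k_used, per_obs=res.per_obs,
        cutoff=res.cutoff, level=level, flagged=res.flagged, kappa=kappa,
    )
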