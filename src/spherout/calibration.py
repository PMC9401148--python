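"""Monte-Carlo calibration of null-distribution cut-off points.

Under the null hypothesis of no outliers the sample is i.i.d. Fisher.  For a
given statistic the calibrated cut-off C_Q at upper level ``l`` is the
empirical ``(1 - l)`` quantile of the per-sample *maximum* of the statistic
over ``reps`` simulated null samples — using the maximum controls the
family-wise exceedance rate and matches the detection rule, which flags any
observation whose value exceeds the cut-off.

The null distribution of the distances depends on ``(n, kappa)`` only, not on
the mean direction, so all null samples are drawn about the north pole.

The empirical quantile convention is fixed so tables are reproducible per
seed: with the maxima sorted ascending, the cut-off at level ``l`` is the
``ceil(reps * (1 - l))``-th order statistic (1-based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discordancy import batch_ce_per_obs, batch_qk_per_obs
from .fisher import sample_pole

__all__ = [
    "CutoffTable",
    "empirical_upper_quantile",
    "simulate_null_maxima",
    "simulate_cutoff",
    "simulate_qk_cutoffs",
    "cutoff_grid",
    "cutoffs_to_frame",
    "write_cutoffs",
    "read_cutoffs",
]

DEFAULT_LEVELS = (0.10, 0.05, 0.01)
DEFAULT_REPS = 3000

# cap on the reps*n*n distance-tensor size per chunk (~160 MB of float64)
_CHUNK_BUDGET = 20_000_000


@dataclass(frozen=True)
class CutoffTable:
    """Calibrated upper cut-offs for one (statistic, k, n, kappa) design point."""

    statistic: str
    k: int | None
    n: int
    kappa: float
    levels: tuple[float, ...]
    values: tuple[float, ...]
    reps: int
    seed: int | None = None
    maxima: np.ndarray | None = field(default=None, repr=False, compare=False)

    def cutoff(self, level: float) -> float:
        for lv, val in zip(self.levels, self.values):
            if math.isclose(lv, level):
                return val
        raise KeyError(f"level {level} not calibrated (have {self.levels})")


def empirical_upper_quantile(x, level: float) -> float:
    """Upper-``level`` empirical quantile: the ``ceil(m (1 - level))``-th order statistic."""
    x = np.sort(np.asarray(x, dtype=float))
    m = len(x)
    if m == 0:
        raise ValueError("empty sample")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    idx = int(math.ceil(m * (1.0 - level)))
    return float(x[max(idx, 1) - 1])


def _chunks(reps: int, n: int):
    per = max(1, _CHUNK_BUDGET // (n * n))
    done = 0
    while done < reps:
        take = min(per, reps - done)
        yield take
        done += take


def simulate_null_maxima(
    statistic: str,
    n: int,
    kappa: float,
    ks=None,
    reps: int = DEFAULT_REPS,
    rng=None,
) -> dict:
    """Per-replicate maxima of a statistic over ``reps`` null Fisher samples.

    For ``statistic='Q'``, ``ks`` is an iterable of neighbour orders and the
    result maps each k to its ``(reps,)`` maxima (all orders share the same
    simulated samples).  For ``'C'``/``'E'`` the result maps the statistic
    name to its maxima.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if kappa <= 0.0:
        raise ValueError("kappa must be positive")
    if reps < 1:
        raise ValueError("reps must be positive")
    statistic = statistic.upper()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    if statistic == "Q":
        ks = [1] if ks is None else sorted(set(int(k) for k in np.atleast_1d(ks)))
        if ks[0] < 1 or ks[-1] > n - 1:
            raise ValueError("neighbour orders must satisfy 1 <= k <= n - 1")
        out = {k: np.empty(reps) for k in ks}
        pos = 0
        for take in _chunks(reps, n):
            W = sample_pole(kappa, (take, n), rng)
            per = batch_qk_per_obs(W, ks)
            for k in ks:
                out[k][pos : pos + take] = per[k].max(axis=1)
            pos += take
        return out
    if statistic in ("C", "E"):
        out = np.empty(reps)
        pos = 0
        for take in _chunks(reps, n):
            W = sample_pole(kappa, (take, n), rng)
            C, E = batch_ce_per_obs(W)
            vals = C if statistic == "C" else E
            out[pos : pos + take] = vals.max(axis=1)
            pos += take
        return {statistic: out}
    raise ValueError(f"unknown statistic {statistic!r}")


def simulate_cutoff(
    statistic: str,
    n: int,
    kappa: float,
    k: int | None = None,
    levels=DEFAULT_LEVELS,
    reps: int = DEFAULT_REPS,
    seed=None,
    rng=None,
    keep_maxima: bool = False,
) -> CutoffTable:
    """Calibrate cut-offs for one statistic at one ``(n, kappa)`` design point.

    ``k`` is required for the Q statistic and ignored otherwise.  Either a
    ``seed`` (stored in the table for provenance) or an existing ``rng`` may
    be supplied.
    """
    statistic = statistic.upper()
    if statistic == "Q" and k is None:
        raise ValueError("the Q statistic requires a neighbour order k")
    if rng is None:
        rng = np.random.default_rng(seed)
    maxima = simulate_null_maxima(statistic, n, kappa, ks=None if k is None else [k], reps=reps, rng=rng)
    (key,) = maxima.keys()
    vals = tuple(empirical_upper_quantile(maxima[key], lv) for lv in levels)
    return CutoffTable(
        statistic=statistic, k=k if statistic == "Q" else None, n=n, kappa=kappa,
        levels=tuple(levels), values=vals, reps=reps, seed=seed,
        maxima=maxima[key] if keep_maxima else None,
    )


def simulate_qk_cutoffs(
    n: int,
    kappa: float,
    ks,
    levels=DEFAULT_LEVELS,
    reps: int = DEFAULT_REPS,
    seed=None,
    rng=None,
) -> dict[int, CutoffTable]:
    """Cut-offs for several Q^k orders from one shared set of null samples."""
    if rng is None:
        rng = np.random.default_rng(seed)
    maxima = simulate_null_maxima("Q", n, kappa, ks=ks, reps=reps, rng=rng)
    return {
        k: CutoffTable(
            statistic="Q", k=k, n=n, kappa=kappa, levels=tuple(levels),
            values=tuple(empirical_upper_quantile(mx, lv) for lv in levels),
            reps=reps, seed=seed,
        )
        for k, mx in maxima.items()
    }


def cutoff_grid(
    statistic: str,
    n_grid,
    kappa_grid,
    k: int | None = None,
    levels=DEFAULT_LEVELS,
    reps: int = DEFAULT_REPS,
    seed=None,
) -> list[CutoffTable]:
    """Cross-product calibration over sample sizes and concentrations.

    Each ``(n, kappa)`` cell uses an independent child stream spawned from
    ``seed``, so the grid is reproducible and insensitive to cell order.
    """
    n_grid = list(n_grid)
    kappa_grid = list(kappa_grid)
    if not n_grid or not kappa_grid:
        raise ValueError("grids must be non-empty")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(n_grid) * len(kappa_grid))
    out = []
    i = 0
    for n in n_grid:
        for kappa in kappa_grid:
            rng = np.random.default_rng(streams[i])
            i += 1
            out.append(
                simulate_cutoff(statistic, n, kappa, k=k, levels=levels, reps=reps, seed=seed, rng=rng)
            )
    return out


def cutoffs_to_frame(tables) -> pd.DataFrame:
    """Tidy frame with one row per (design point, level)."""
    rows = [
        {
            "statistic": t.statistic, "k": t.k, "n": t.n, "kappa": t.kappa,
            "level": lv, "cutoff": val, "reps": t.reps, "seed": t.seed,
        }
        for t in tables
        for lv, val in zip(t.levels, t.values)
    ]
    return pd.DataFrame(rows)


def write_cutoffs(tables, path) -> None:
    cutoffs_to_frame(tables).to_csv(path, index=False)


def read_cutoffs(path) -> pd.DataFrame:
    return pd.read_csv(path)
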