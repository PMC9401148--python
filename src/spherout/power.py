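"""Power study of the discordancy statistics under slippage contamination.

The contamination model draws ``n - m`` observations from the null Fisher
distribution F(0, 0, kappa_null) and ``m`` contaminants i.i.d. from
F(lambda * pi, 0, kappa_out): the contaminants keep a concentrated shape but
their mean direction slips away from the null pole as lambda grows from 0
(no displacement) to 1 (antipodal).  Contaminants are placed at random
positions in the sample and their indices tracked.

The performance measure is P5, the probability of *correct* detection: the
proportion of replicates in which the contaminant observation(s) are the
ones flagged.  By default a replicate counts as correct when every
contaminant index exceeds the cut-off at k = patch size ("all"); stricter
("exact": the flag set equals the contaminant set) and looser ("any") rules
are available.  Cut-offs are Monte-Carlo calibrated at (n, kappa_null).

All three statistics are evaluated on the same simulated samples (common
random numbers), so their curves are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DEFAULT_REPS, _chunks, empirical_upper_quantile, simulate_null_maxima
from .discordancy import batch_ce_per_obs, batch_qk_per_obs
from .fisher import sample_pole
from .sphere import rotation_to_mean

__all__ = ["ContaminationDesign", "P5Curve", "run_p5", "compare_statistics", "plot_curves"]

_CRITERIA = ("all", "exact", "any")


@dataclass(frozen=True)
class ContaminationDesign:
    """Design of one slippage-contamination experiment."""

    n: int
    kappa_null: float
    lambda_grid: tuple[float, ...]
    n_outliers: int = 1
    kappa_out: float = 30.0
    level: float = 0.10
    reps: int = DEFAULT_REPS
    calibration_reps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_outliers < self.n:
            raise ValueError("need 1 <= n_outliers < n")
        lam = np.asarray(self.lambda_grid, dtype=float)
        if lam.size == 0 or np.any(lam < 0.0) or np.any(lam > 1.0):
            raise ValueError("lambda grid values must lie in [0, 1]")
        if self.kappa_null <= 0.0 or self.kappa_out <= 0.0:
            raise ValueError("concentrations must be positive")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be positive")


@dataclass(frozen=True)
class P5Curve:
    """Correct-detection probability of one statistic along the lambda grid."""

    statistic: str
    k: int | None
    lambdas: np.ndarray
    p5: np.ndarray
    reps: int
    seed: int | None = None
    cutoff: float | None = None


def _calibrate_cutoffs(design: ContaminationDesign, k: int, rng) -> dict[str, float]:
    reps = design.calibration_reps or design.reps
    qmax = simulate_null_maxima("Q", design.n, design.kappa_null, ks=[k], reps=reps, rng=rng)
    cmax = simulate_null_maxima("C", design.n, design.kappa_null, reps=reps, rng=rng)
    emax = simulate_null_maxima("E", design.n, design.kappa_null, reps=reps, rng=rng)
    lv = design.level
    return {
        "Q": empirical_upper_quantile(qmax[k], lv),
        "C": empirical_upper_quantile(cmax["C"], lv),
        "E": empirical_upper_quantile(emax["E"], lv),
    }


def _correct(flags: np.ndarray, mask: np.ndarray, criterion: str) -> np.ndarray:
    if criterion == "all":
        return np.all(flags | ~mask, axis=1)
    if criterion == "exact":
        return np.all(flags == mask, axis=1)
    if criterion == "any":
        return np.any(flags & mask, axis=1)
    raise ValueError(f"criterion must be one of {_CRITERIA}")


def _p5_all_statistics(design: ContaminationDesign, k: int, criterion: str) -> dict[str, P5Curve]:
    """P5 curves for Q^k, C and E from shared simulated samples."""
    if not 1 <= k <= design.n - 1:
        raise ValueError("invalid neighbour order for this design")
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    ss = np.random.SeedSequence(design.seed)
    calib_rng, sim_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    cut = _calibrate_cutoffs(design, k, calib_rng)

    n, m = design.n, design.n_outliers
    lambdas = np.asarray(design.lambda_grid, dtype=float)
    hits = {s: np.zeros(lambdas.size) for s in ("Q", "C", "E")}
    for take in _chunks(design.reps, n):
        # the same null draws, pole-centred contaminant draws and placement
        # permutations serve every lambda (common random numbers), so the
        # curves vary smoothly in the displacement
        null_part = sample_pole(design.kappa_null, (take, n - m), sim_rng)
        contam_pole = sample_pole(design.kappa_out, (take, m), sim_rng)
        perm = np.argsort(sim_rng.random((take, n)), axis=1)
        mask = perm >= n - m
        for li, lam in enumerate(lambdas):
            W = np.empty((take, n, 3))
            W[:, : n - m] = null_part
            W[:, n - m :] = contam_pole @ rotation_to_mean(lam * np.pi, 0.0).T
            W = np.take_along_axis(W, perm[:, :, None], axis=1)
            q = batch_qk_per_obs(W, [k])[k]
            C, E = batch_ce_per_obs(W)
            hits["Q"][li] += _correct(q > cut["Q"], mask, criterion).sum()
            hits["C"][li] += _correct(C > cut["C"], mask, criterion).sum()
            hits["E"][li] += _correct(E > cut["E"], mask, criterion).sum()
    return {
        s: P5Curve(statistic=s, k=k if s == "Q" else None, lambdas=lambdas,
                   p5=hits[s] / design.reps, reps=design.reps, seed=design.seed,
                   cutoff=cut[s])
        for s in ("Q", "C", "E")
    }


def run_p5(design: ContaminationDesign, statistic: str, k: int | None = None,
           criterion: str = "all") -> P5Curve:
    """P5 curve of one statistic; ``k`` defaults to the patch size for Q.

    The simulated samples depend only on the design (not on which statistic
    is requested), so curves from separate calls with the same seed are
    mutually comparable.
    """
    statistic = statistic.upper()
    if statistic not in ("Q", "C", "E"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if k is None:
        k = design.n_outliers
    return _p5_all_statistics(design, k, criterion)[statistic]


def compare_statistics(design: ContaminationDesign, k: int | None = None,
                       criterion: str = "all") -> pd.DataFrame:
    """Tidy table of P5 for Q^k, C and E computed on shared random draws."""
    if k is None:
        k = design.n_outliers
    curves = _p5_all_statistics(design, k, criterion)
    rows = [
        {"statistic": s, "k": c.k, "lambda": lam, "p5": p,
         "reps": design.reps, "seed": design.seed}
        for s, c in curves.items()
        for lam, p in zip(c.lambdas, c.p5)
    ]
    return pd.DataFrame(rows)


def plot_curves(table: pd.DataFrame, ax=None):
    """Plot P5 against lambda for each statistic in a tidy comparison table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for stat, grp in table.groupby("statistic"):
        ax.plot(grp["lambda"], grp["p5"], marker="o", label=stat)
    ax.set_xlabel(r"$\lambda$ (contaminant displacement / $\pi$)")
    ax.set_ylabel("P5 (probability of correct detection)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax
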