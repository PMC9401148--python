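"""The Fisher distribution on S²: density, sampling and ML estimation.

The Fisher (von Mises–Fisher with p = 3) density for angles ``(theta, phi)``
with mean direction ``(alpha, beta)`` and concentration ``kappa > 0`` is

    f(theta, phi) = kappa / (4 pi sinh kappa)
                    * exp{kappa [cos a cos t + sin a sin t cos(phi - beta)]}
                    * sin t,

which integrates to one over ``0 <= theta < pi``, ``0 <= phi < 2 pi``.  The
mean resultant length of the model is ``A(kappa) = coth(kappa) - 1/kappa``,
and the maximum-likelihood estimate of ``kappa`` solves ``A(kappa) = Rbar``
with ``Rbar`` the sample mean resultant length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .sphere import TWO_PI, from_cartesian, rotate_to_mean

__all__ = [
    "FisherParams",
    "ResultantSummary",
    "fisher_pdf",
    "mean_resultant_a",
    "resultant",
    "fit_fisher",
    "kappa_mle",
    "kappa_approx",
    "sample_fisher",
]


@dataclass(frozen=True)
class FisherParams:
    """Mean direction ``(alpha, beta)`` in radians and concentration ``kappa``."""

    alpha: float
    beta: float
    kappa: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.alpha, self.beta, self.kappa]).all():
            raise ValueError("Fisher parameters must be finite")
        if not 0.0 <= self.alpha < np.pi:
            raise ValueError("alpha must lie in [0, pi)")
        if not 0.0 <= self.beta < TWO_PI:
            raise ValueError("beta must lie in [0, 2*pi)")
        if self.kappa <= 0.0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class ResultantSummary:
    """Component sums, resultant length and mean direction of a sample.

    ``degenerate`` is set when ``R == 0`` (perfectly balanced sample), in
    which case the mean direction is undefined and stored as ``None``.
    """

    Sx: float
    Sy: float
    Sz: float
    R: float
    Rbar: float
    n: int
    mean_direction: tuple[float, float] | None
    degenerate: bool


def _log_norm_const(kappa: float) -> float:
    # log[kappa / (4 pi sinh kappa)] computed without overflowing sinh:
    # log sinh(k) = k + log(1 - e^{-2k}) - log 2
    log_sinh = kappa + np.log1p(-np.exp(-2.0 * kappa)) - np.log(2.0)
    return np.log(kappa) - np.log(4.0 * np.pi) - log_sinh


def fisher_pdf(theta, phi, params: FisherParams):
    """Fisher density of the angle pair ``(theta, phi)``, per (d theta, d phi).

    Includes the ``sin(theta)`` area element, so the density vanishes at the
    poles and integrates to 1 over the angle rectangle.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    a, b, k = params.alpha, params.beta, params.kappa
    cos_angle = np.cos(a) * np.cos(theta) + np.sin(a) * np.sin(theta) * np.cos(phi - b)
    out = np.exp(_log_norm_const(k) + k * cos_angle) * np.sin(theta)
    return out if out.ndim else float(out)


def mean_resultant_a(kappa):
    """``A(kappa) = coth(kappa) - 1/kappa``: model mean resultant length."""
    kappa = np.asarray(kappa, dtype=float)
    out = 1.0 / np.tanh(kappa) - 1.0 / kappa
    return out if out.ndim else float(out)


def resultant(V) -> ResultantSummary:
    """Resultant summary (S, R, Rbar, mean direction) of unit vectors ``V``."""
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] != 3 or len(V) < 1:
        raise ValueError("expected a non-empty (n, 3) array of unit vectors")
    n = len(V)
    S = V.sum(axis=0)
    R = float(np.linalg.norm(S))
    degenerate = R < 1e-12 * n
    mean_dir = None if degenerate else from_cartesian(S / R)
    return ResultantSummary(
        Sx=float(S[0]), Sy=float(S[1]), Sz=float(S[2]),
        R=R, Rbar=R / n, n=n, mean_direction=mean_dir, degenerate=degenerate,
    )


def kappa_mle(rbar: float) -> float:
    """Solve the exact ML equation ``coth(kappa) - 1/kappa = rbar``."""
    if not 0.0 < rbar < 1.0:
        raise ValueError("mean resultant length must lie strictly in (0, 1)")
    if rbar > 1.0 - 1e-12:
        raise ValueError("Rbar too close to 1: kappa estimate diverges")
    hi = max(10.0, 4.0 / (1.0 - rbar))
    return brentq(lambda k: mean_resultant_a(k) - rbar, 1e-12, hi, xtol=1e-13)


def kappa_approx(n: int, R: float) -> float:
    """Large-``kappa`` approximation ``(n - 1) / (n - R)``."""
    return (n - 1) / (n - R)


def fit_fisher(V, method: str = "mle") -> FisherParams:
    """Fit ``(alpha, beta, kappa)`` to a sample of unit vectors.

    The mean direction is the direction of the resultant vector; ``kappa``
    comes either from the exact ML equation (``method='mle'``, default) or
    from the ``(n-1)/(n-R)`` large-concentration approximation
    (``method='approx'``).
    """
    V = np.asarray(V, dtype=float)
    if len(V) < 2:
        raise ValueError("need at least two observations to fit")
    summ = resultant(V)
    if summ.degenerate:
        raise ValueError("degenerate sample: resultant length is zero")
    alpha, beta = summ.mean_direction
    if method == "mle":
        kappa = kappa_mle(summ.Rbar)
    elif method == "approx":
        kappa = kappa_approx(summ.n, summ.R)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FisherParams(alpha=alpha, beta=beta, kappa=kappa)


def _sample_colatitude_cos(kappa: float, shape, rng: np.random.Generator):
    """Draw ``cos(theta')`` about the pole by exact inversion.

    The colatitude cosine w has density proportional to exp(kappa * w) on
    [-1, 1]; inverting its CDF gives
    ``w = 1 + log(u + (1 - u) e^{-2 kappa}) / kappa`` for uniform u.
    """
    u = rng.random(shape)
    e2k = np.exp(-2.0 * kappa)  # underflows to 0 for kappa > ~350, harmlessly
    w = 1.0 + np.log(e2k + u * (1.0 - e2k)) / kappa
    return np.clip(w, -1.0, 1.0)


def sample_pole(kappa: float, shape, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. Fisher draws about the north pole, as unit vectors.

    ``shape`` may be an int or tuple; the result has shape ``shape + (3,)``.
    """
    if kappa <= 0.0:
        raise ValueError("kappa must be positive")
    w = _sample_colatitude_cos(kappa, shape, rng)
    phi = rng.random(np.shape(w)) * TWO_PI
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    return np.stack([s * np.cos(phi), s * np.sin(phi), w], axis=-1)


def sample_fisher(params: FisherParams, n: int, rng) -> np.ndarray:
    """Draw ``n`` i.i.d. observations from ``params`` as ``(n, 3)`` unit vectors.

    Sampling is by exact inversion of the colatitude cosine about the pole
    (no rejection), a uniform longitude, and a rotation taking the pole to
    the mean direction.  ``rng`` is a :class:`numpy.random.Generator` or a
    seed acceptable to :func:`numpy.random.default_rng`.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    V = sample_pole(params.kappa, n, rng)
    if params.alpha == 0.0 and params.beta == 0.0:
        return V
    return rotate_to_mean(V, params.alpha, params.beta)


def sample_fisher_angles(params: FisherParams, n: int, rng):
    """As :func:`sample_fisher` but returning ``(theta, phi)`` angle arrays."""
    return from_cartesian(sample_fisher(params, n, rng))
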