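"""Coordinate conversions and the chord-type distance on the unit sphere.

Observations on S² are handled in two equivalent forms:

* angle pairs ``(theta, phi)`` — colatitude ``theta`` in ``[0, pi]`` measured
  from the north pole and longitude ``phi`` in ``[0, 2*pi)``, both in radians;
* direction cosines — unit vectors ``(x, y, z)`` with
  ``x = sin(theta) cos(phi)``, ``y = sin(theta) sin(phi)``, ``z = cos(theta)``.

All functions are vectorised over leading axes, so a sample of *n* points is
an ``(n,)`` pair of angle arrays or an ``(n, 3)`` array of unit vectors.

The distance used throughout the package is ``d = 1 - cos(theta_12)`` where
``theta_12`` is the angle between the two directions, i.e. half the squared
chord length ``|u - v|^2 / 2``.  It ranges over ``[0, 2]``, is zero only for
identical directions and equals 2 for antipodal ones.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "wrap_longitude",
    "to_cartesian",
    "from_cartesian",
    "sphere_distance",
    "pairwise_distances",
    "rotation_to_mean",
    "rotate_to_mean",
]


def wrap_longitude(phi):
    """Wrap longitude(s) into ``[0, 2*pi)``."""
    return np.mod(phi, TWO_PI)


def _validate_angles(theta, phi):
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(phi))):
        raise ValueError("angles must be finite")
    if np.any(theta < 0.0) or np.any(theta > np.pi):
        raise ValueError("colatitude must lie in [0, pi]")
    return theta, wrap_longitude(phi)


def to_cartesian(theta, phi):
    """Convert colatitude/longitude to direction cosines.

    Parameters
    ----------
    theta, phi : array_like
        Colatitude in ``[0, pi]`` and longitude in radians (wrapped modulo
        ``2*pi``).  Broadcast against each other.

    Returns
    -------
    ndarray, shape ``(..., 3)``
        Unit vectors ``(sin t cos p, sin t sin p, cos t)``.
    """
    theta, phi = _validate_angles(theta, phi)
    st = np.sin(theta)
    return np.stack(
        np.broadcast_arrays(st * np.cos(phi), st * np.sin(phi), np.cos(theta)),
        axis=-1,
    )


def from_cartesian(v, *, atol: float = 1e-8):
    """Convert unit vectors back to ``(theta, phi)`` angles.

    Longitude is wrapped to ``[0, 2*pi)`` and defined as 0 at the poles,
    where it is geometrically degenerate.

    Raises
    ------
    ValueError
        If any vector is not of unit length within ``atol`` (in particular
        the zero vector).
    """
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    if not np.all(np.isfinite(norms)):
        raise ValueError("vector components must be finite")
    if np.any(np.abs(norms - 1.0) > atol):
        raise ValueError("input is not a unit vector")
    # arctan2(hypot, z) rather than arccos(z): identical mathematically but
    # well-conditioned for directions near the poles
    sin_t = np.hypot(v[..., 0], v[..., 1])
    theta = np.arctan2(sin_t, v[..., 2])
    phi = wrap_longitude(np.arctan2(v[..., 1], v[..., 0]))
    # at the poles (sin theta == 0) longitude is a gauge choice; fix it to 0
    at_pole = sin_t == 0.0
    phi = np.where(at_pole, 0.0, phi)
    if phi.ndim == 0:
        return float(theta), float(phi)
    return theta, phi


def sphere_distance(u, v):
    """Distance ``1 - cos(theta_12)`` between unit vectors ``u`` and ``v``.

    Symmetric, zero iff the directions coincide, maximal (= 2) for antipodal
    pairs, and invariant under any common rotation.  Broadcasts over leading
    axes.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d = 1.0 - np.sum(u * v, axis=-1)
    return np.clip(d, 0.0, 2.0)


def pairwise_distances(V):
    """All-pairs ``1 - cos`` distance matrix of an ``(n, 3)`` sample.

    The diagonal is exactly zero; small negative values from round-off are
    clipped to zero.
    """
    V = np.asarray(V, dtype=float)
    D = 1.0 - V @ V.T
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


def rotation_to_mean(alpha: float, beta: float) -> np.ndarray:
    """Rotation matrix taking the north pole ``(0, 0, 1)`` to ``(alpha, beta)``.

    Composed as a rotation by ``alpha`` about the y-axis followed by ``beta``
    about the z-axis.  Any rotation with the same image of the pole would do:
    the Fisher model is rotationally symmetric about its mean direction, so
    the azimuthal gauge is immaterial.
    """
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    ry = np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])
    rz = np.array([[cb, -sb, 0.0], [sb, cb, 0.0], [0.0, 0.0, 1.0]])
    return rz @ ry


def rotate_to_mean(v, alpha: float, beta: float):
    """Rotate vector(s) ``v`` by the rotation taking the pole to ``(alpha, beta)``.

    Used to re-centre samples drawn about the north pole onto an arbitrary
    mean direction; inner products between vectors are preserved.
    """
    v = np.asarray(v, dtype=float)
    return v @ rotation_to_mean(alpha, beta).T
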