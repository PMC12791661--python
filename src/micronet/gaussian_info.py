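"""Closed-form Gaussian mutual information and conditional mutual information.

Under a joint Gaussian assumption, MI and CMI have closed forms in terms of
covariance determinants:

    MI(X, Y)      = 1/2 log( sx^2 sy^2 / |C(X,Y)| )   =  -1/2 log(1 - rho^2)
    CMI(X, Y | Z) = 1/2 log( |C(X,Z)| |C(Y,Z)| / ( |C(Z)| |C(X,Y,Z)| ) )

with sample covariances (n-1 denominator) and natural logs (units: nats).
MI is zero iff X and Y are uncorrelated; CMI is zero iff they are partially
uncorrelated given Z, which under Gaussianity is conditional independence.
With a single conditioning variable, CMI equals -1/2 log(1 - r^2) for the
partial correlation r of X and Y given Z.

Numerical policy: tiny negative values in (-1e-9, 0) arising from floating
point are clamped to 0; anything below -1e-9 raises, since it signals a bug
in the covariance computation rather than roundoff.  Degenerate inputs with
a singular covariance get a small ridge (1e-10 * trace/dim); if the
determinant ratio still diverges the value is capped (default 10 nats) with
a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["InfoEstimate", "mi_gaussian", "cmi_gaussian", "DEFAULT_CAP_NATS"]

DEFAULT_CAP_NATS = 10.0
_CLAMP_TOL = 1e-9


@dataclass
class InfoEstimate:
    """A nonnegative (C)MI value in nats, with the pair it belongs to."""

    value: float
    pair: tuple[str, str] = ("X", "Y")
    conditioned_on: list[str] = field(default_factory=list)


def _det(m: np.ndarray) -> float:
    m = np.atleast_2d(np.asarray(m, dtype=float))
    return float(np.linalg.det(m))


def _ridged(m: np.ndarray) -> np.ndarray:
    m = np.atleast_2d(np.asarray(m, dtype=float))
    eps = 1e-10 * np.trace(m) / m.shape[0]
    return m + eps * np.eye(m.shape[0])


def _finalize(value: float, cap: float, context: str) -> float:
    if not np.isfinite(value) or value > cap:
        warnings.warn(
            f"{context}: value diverges (near-singular covariance); "
            f"capped at {cap} nats",
            stacklevel=3,
        )
        return cap
    if value < 0:
        if value > -_CLAMP_TOL:
            return 0.0
        raise FloatingPointError(
            f"{context}: value {value} is below -{_CLAMP_TOL}; "
            "this indicates a covariance-computation bug"
        )
    return value


def mi_from_cov(cov: np.ndarray, i: int, j: int, cap: float = DEFAULT_CAP_NATS) -> float:
    """Gaussian MI of variables i, j from a precomputed covariance matrix."""
    sub = cov[np.ix_([i, j], [i, j])]
    d = _det(sub)
    if d <= 0:
        d = _det(_ridged(sub))
    if d <= 0:
        return _finalize(np.inf, cap, "MI")
    return _finalize(0.5 * np.log(cov[i, i] * cov[j, j] / d), cap, "MI")


def cmi_from_cov(
    cov: np.ndarray, i: int, j: int, ks: list[int], cap: float = DEFAULT_CAP_NATS
) -> float:
    """Gaussian CMI of variables i, j given variables ks, from a covariance."""
    if not ks:
        return mi_from_cov(cov, i, j, cap)
    idx = [i, j, *ks]
    joint = cov[np.ix_(idx, idx)]

    def dets(m: np.ndarray) -> tuple[float, float, float, float]:
        # within m: x at 0, y at 1, z at 2..
        z = list(range(2, m.shape[0]))
        return (
            _det(m[np.ix_([0, *z], [0, *z])]),
            _det(m[np.ix_([1, *z], [1, *z])]),
            _det(m[np.ix_(z, z)]),
            _det(m),
        )

    d_xz, d_yz, d_z, d_xyz = dets(joint)
    if min(d_xz, d_yz, d_z) <= 0 or d_xyz <= 0:
        d_xz, d_yz, d_z, d_xyz = dets(_ridged(joint))
        if min(d_xz, d_yz, d_z) <= 0:
            raise np.linalg.LinAlgError(
                "singular conditioned covariance after regularization"
            )
        if d_xyz <= 0:
            return _finalize(np.inf, cap, "CMI")
    return _finalize(
        0.5 * (np.log(d_xz) + np.log(d_yz) - np.log(d_z) - np.log(d_xyz)),
        cap,
        "CMI",
    )


def _validate_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 3:
        raise ValueError(f"{name}: need at least 3 observations, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError(f"{name} is constant; (C)MI undefined")
    return v


def mi_gaussian(
    x: np.ndarray,
    y: np.ndarray,
    names: tuple[str, str] = ("X", "Y"),
    cap: float = DEFAULT_CAP_NATS,
) -> InfoEstimate:
    """Gaussian MI between two abundance vectors, in nats."""
    x = _validate_vector(x, names[0])
    y = _validate_vector(y, names[1])
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    cov = np.cov(np.column_stack([x, y]), rowvar=False, ddof=1)
    return InfoEstimate(mi_from_cov(cov, 0, 1, cap), pair=names)


def cmi_gaussian(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None,
    names: tuple[str, str] = ("X", "Y"),
    z_names: list[str] | None = None,
    cap: float = DEFAULT_CAP_NATS,
) -> InfoEstimate:
    """Gaussian CMI of x, y given the columns of z, in nats.

    Empty/None ``z`` delegates to :func:`mi_gaussian`.
    """
    if z is None or np.size(z) == 0:
        return mi_gaussian(x, y, names, cap)
    x = _validate_vector(x, names[0])
    y = _validate_vector(y, names[1])
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != x.size or y.size != x.size:
        raise ValueError("x, y and z must have the same number of observations")
    z_names = z_names or [f"Z{k}" for k in range(z.shape[1])]
    for k in range(z.shape[1]):
        if np.ptp(z[:, k]) == 0:
            raise ValueError(f"conditioning column {z_names[k]!r} is constant")
    cov = np.cov(np.column_stack([x, y, z]), rowvar=False, ddof=1)
    ks = list(range(2, 2 + z.shape[1]))
    return InfoEstimate(
        cmi_from_cov(cov, 0, 1, ks, cap), pair=names, conditioned_on=list(z_names)
    )
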