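"""Pointwise analytic maps from visual-field coordinates to cortical mm.

The family is built on the complex-log transform of the visual hemifield.
Writing a visual location as ``z = E * exp(i*theta)`` (eccentricity ``E``
in degrees, polar angle ``theta`` in radians, 0 on the horizontal
meridian, positive for the upper field), the variants are

``monopole``
    ``w = k * log(z + a)`` -- conformal, tapers only at the fovea.
``dipole``
    ``w = k * log((z + a) / (z + b))`` -- conformal, tapers at the fovea
    and towards the periphery.
``sheared_monopole`` / ``sheared_dipole``
    the same log maps evaluated at an angularly sheared position
    ``z_hat = E * exp(i * shear(theta, E))``.  The shear is constructed so
    that areal magnification is invariant with polar angle at fixed
    eccentricity -- the defining property of the sheared ("double-sech")
    family.  This breaks conformality, most strongly at the vertical
    meridian near eccentricities ``a`` and ``b``, and makes the map
    outline narrower and more elongated than the conformal one.

The shear solves, for each eccentricity, the ordinary differential
equation ``d(theta_hat)/d(theta) = |f'(E)|^2 / |f'(E*exp(i*theta_hat))|^2``
(with ``f`` the relevant complex-log map), whose quadrature reduces to
Poisson-kernel integrals with a closed form.  For the monopole the
inverse is explicit; for the dipole the quadrature is inverted with a
vectorized Newton iteration.  No extra free parameters are introduced.

Cortical outputs are planar mm; the right hemifield maps to a left
hemisphere flat map with x growing from fovea to periphery.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import ModelParams

__all__ = [
    "VisualPoint", "CorticalPoint", "Jacobian2x2",
    "shear_polar_angle", "map_complex",
    "monopole_map", "dipole_map", "double_sech_map",
    "local_jacobian", "SINGULARITY_TOL",
]

#: distance (deg) from a log-map pole below which evaluation is flagged
SINGULARITY_TOL = 1e-6


@dataclass(frozen=True)
class VisualPoint:
    """A location in the visual hemifield."""
    eccentricity: float  # degrees of visual angle, >= 0
    polar_angle: float   # radians, 0 = horizontal meridian, + = upper field

    def __post_init__(self):
        if not np.isfinite(self.eccentricity) or not np.isfinite(self.polar_angle):
            raise ValueError("visual coordinates must be finite")
        if self.eccentricity < 0:
            raise ValueError(f"eccentricity must be >= 0, got {self.eccentricity}")


@dataclass(frozen=True)
class CorticalPoint:
    """Planar cortical coordinates in mm."""
    x: float
    y: float

    @classmethod
    def from_complex(cls, w: complex) -> "CorticalPoint":
        return cls(float(np.real(w)), float(np.imag(w)))


@dataclass(frozen=True)
class Jacobian2x2:
    """Local derivative of cortical position w.r.t. visual displacements.

    Columns are the cortical images (mm/deg) of unit visual-field steps
    along the iso-polar (radial) and iso-eccentricity (tangential)
    directions respectively.
    """
    dx_dr: float
    dx_dt: float
    dy_dr: float
    dy_dt: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.dx_dr, self.dx_dt], [self.dy_dr, self.dy_dt]])

    @property
    def det(self) -> float:
        return self.dx_dr * self.dy_dt - self.dx_dt * self.dy_dr

    @property
    def M_p(self) -> float:
        """Linear magnification along iso-polar (radial) lines, mm/deg."""
        return float(np.hypot(self.dx_dr, self.dy_dr))

    @property
    def M_e(self) -> float:
        """Linear magnification along iso-eccentricity lines, mm/deg."""
        return float(np.hypot(self.dx_dt, self.dy_dt))

    @property
    def singular_values(self) -> tuple[float, float]:
        s = np.linalg.svd(self.matrix, compute_uv=False)
        return (float(s[0]), float(s[1]))

    @property
    def areal(self) -> float:
        """Areal magnification |det|, mm^2/deg^2."""
        return abs(self.det)


# ----------------------------------------------------------------------
# shear machinery
# ----------------------------------------------------------------------

def _poisson_integral(A, B, th):
    """``int_0^th du / (A + B cos u)`` for A >= B >= 0, |th| <= pi.

    Continuous through A == B (pole eccentricity), where the integral
    degenerates to ``tan(th/2) / A``.
    """
    with np.errstate(over="ignore"):  # tan(pi/2) overflow is benign
        t = np.tan(0.5 * th)
    c = np.sqrt(np.maximum(A - B, 0.0) / (A + B))
    x = c * t
    small = c < 1e-8
    with np.errstate(invalid="ignore"):
        series = t * (1.0 - x * x / 3.0)
        exact = np.arctan(x) / np.where(small, 1.0, c)
    return 2.0 / (A + B) * np.where(small, series, exact)


def _shear_single_pole(theta, E, p):
    """Exact constant-areal-magnification shear for ``k*log(z + p)``.

    Closed form: ``tan(th_hat/2) = tan(c*theta/2) / c`` with
    ``c = |E - p| / (E + p)``.
    """
    theta = np.asarray(theta, dtype=float)
    E = np.asarray(E, dtype=float)
    c = np.abs(E - p) / (E + p)
    x = c * theta / 2.0
    small = c < 1e-7
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(
            small,
            (theta / 2.0) * (1.0 + x * x / 3.0),   # c -> 0 limit (E == p)
            np.tan(x) / np.where(small, 1.0, c),
        )
    return 2.0 * np.arctan(t)


def _dipole_theta_of_sheared(th_hat, E, a, b):
    """Unsheared angle as a function of the sheared angle, dipole map.

    Quadrature of the constancy ODE:
    ``theta = int_0^th_hat |f'(E e^{iu})|^2 du / |f'(E)|^2`` with
    ``f = log((z+a)/(z+b))``.  The integrand is a product of two Poisson
    kernels; partial fractions give the closed form, with a separate
    branch where the kernels become proportional (``E^2 = a*b``).
    """
    th_hat = np.asarray(th_hat, dtype=float)
    E = np.asarray(E, dtype=float)
    A1, B1 = E * E + a * a, 2.0 * a * E
    A2, B2 = E * E + b * b, 2.0 * b * E
    D = A1 * B2 - A2 * B1  # = 2 E (b-a)(E^2 - ab)
    degen = np.abs(D) <= 1e-9 * (A1 * B2 + A2 * B1)
    Dsafe = np.where(degen, 1.0, D)

    i1 = _poisson_integral(A1, B1, th_hat)
    i2 = _poisson_integral(A2, B2, th_hat)
    generic = -B1 / Dsafe * i1 + B2 / Dsafe * i2

    # E^2 ~ ab: integrand ~ (B1/B2) / (A1 + B1 cos u)^2
    with np.errstate(divide="ignore", invalid="ignore"):
        kap = np.where(B1 > 0, B2 / np.where(B1 > 0, B1, 1.0), np.inf)
        s2 = (A1 - B1) * (A1 + B1)
        sq = (A1 * i1 - B1 * np.sin(th_hat) / (A1 + B1 * np.cos(th_hat))) / s2
        degenerate = sq / kap

    integral = np.where(degen, degenerate, generic)
    h0 = 1.0 / ((E + a) ** 2 * (E + b) ** 2)  # |f'(E)|^2 / (b-a)^2
    theta = integral / h0
    # E == 0: no shear
    return np.where(E == 0, th_hat, theta)


def _shear_dipole(theta, E, a, b, tol=1e-12, maxiter=60):
    """Invert the dipole quadrature: sheared angle for target ``theta``."""
    theta = np.asarray(theta, dtype=float)
    E = np.asarray(E, dtype=float)
    theta, E = np.broadcast_arrays(theta, E)
    th = np.clip(_shear_single_pole(theta, E, a), -np.pi + 1e-12, np.pi - 1e-12)
    h0 = 1.0 / ((E + a) ** 2 * (E + b) ** 2)
    for _ in range(maxiter):
        resid = _dipole_theta_of_sheared(th, E, a, b) - theta
        za2 = E * E + a * a + 2.0 * a * E * np.cos(th)
        zb2 = E * E + b * b + 2.0 * b * E * np.cos(th)
        h = 1.0 / (za2 * zb2)
        step = resid * h0 / h
        th = np.clip(th - step, -np.pi + 1e-12, np.pi - 1e-12)
        if np.max(np.abs(step)) < tol:
            break
    return np.where(E == 0, theta, th)


def shear_polar_angle(theta, E, params: ModelParams):
    """Sheared polar angle used inside the sheared (double-sech) maps.

    Odd-symmetric in ``theta``, zero on the horizontal meridian, and
    strongest near the vertical meridian at eccentricities around the
    poles ``a`` (and ``b`` for the dipole).  For conformal variants the
    angle is returned unchanged.

    Accepts angles over the full intermediate-space span (|theta| up to
    pi), not just the hemifield.
    """
    theta = np.asarray(theta, dtype=float)
    E = np.asarray(E, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(E))):
        raise ValueError("non-finite inputs to shear_polar_angle")
    if not params.is_sheared:
        return theta + np.zeros_like(E)
    if params.variant == "sheared_monopole":
        return _shear_single_pole(theta, E, params.a)
    return _shear_dipole(theta, E, params.a, params.b)


# ----------------------------------------------------------------------
# pointwise maps
# ----------------------------------------------------------------------

def map_complex(E, theta, params: ModelParams):
    """Vectorized map to cortical position as complex mm (untranslated).

    Evaluations closer than ``SINGULARITY_TOL`` deg to a log-map pole
    return NaN rather than raising, so gridded evaluation can proceed.
    """
    E = np.asarray(E, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(theta))):
        raise ValueError("non-finite visual coordinates")
    th_hat = shear_polar_angle(theta, E, params)
    z = E * np.exp(1j * th_hat)
    za = z + params.a
    bad = np.abs(za) < SINGULARITY_TOL
    if params.is_dipole:
        zb = z + params.b
        bad = bad | (np.abs(zb) < SINGULARITY_TOL)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = params.k * (np.log(za) - np.log(zb))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            w = params.k * np.log(za)
    if np.any(bad):
        w = np.where(bad, np.nan + 1j * np.nan, w)
    return w


def _as_point(E, theta) -> VisualPoint:
    return E if isinstance(E, VisualPoint) else VisualPoint(E, theta)


def monopole_map(p: VisualPoint, params: ModelParams) -> CorticalPoint:
    """``w = k*log(z + a)``: conformal map with a foveal pole only."""
    w = map_complex(p.eccentricity, p.polar_angle,
                    params.with_(variant="monopole"))
    return CorticalPoint.from_complex(complex(w))


def dipole_map(p: VisualPoint, params: ModelParams) -> CorticalPoint:
    """``w = k*log((z + a)/(z + b))``: conformal, tapers at both poles."""
    if params.a >= params.b:
        raise ValueError("dipole map requires a < b (a == b collapses the map)")
    w = map_complex(p.eccentricity, p.polar_angle,
                    params.with_(variant="dipole"))
    return CorticalPoint.from_complex(complex(w))


def double_sech_map(p: VisualPoint, params: ModelParams) -> CorticalPoint:
    """Sheared complex-log projection (monopole or dipole by variant).

    On the horizontal meridian the shear vanishes and the result equals
    the conformal map of the same point; at fixed eccentricity the areal
    magnification is invariant with polar angle.
    """
    variant = ("sheared_dipole" if params.is_dipole else "sheared_monopole"
               ) if not params.is_sheared else params.variant
    w = map_complex(p.eccentricity, p.polar_angle, params.with_(variant=variant))
    return CorticalPoint.from_complex(complex(w))


# ----------------------------------------------------------------------
# local Jacobian
# ----------------------------------------------------------------------

def default_step(E: float, params: ModelParams, rel: float = 1e-5) -> float:
    """Finite-difference step in deg: relative, floored near the fovea."""
    return rel * max(abs(E), params.a / 10.0)


def local_jacobian(
    map_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None,
    p: VisualPoint,
    params: ModelParams,
    step: float | None = None,
) -> Jacobian2x2:
    """Central finite-difference Jacobian in (radial, tangential) deg.

    ``map_fn(E, theta) -> complex mm`` defaults to the variant map in
    ``params``.  Both columns are scaled per degree of visual field; the
    tangential step is taken along the iso-eccentricity arc (arc length
    in deg), so the column norms are the linear magnifications
    ``M_p`` and ``M_e``.
    """
    if map_fn is None:
        map_fn = lambda E, th: map_complex(E, th, params)  # noqa: E731
    E, th = p.eccentricity, p.polar_angle
    if E <= 0:
        raise ValueError("local_jacobian requires E > 0 (fovea is a map anchor)")
    h = default_step(E, params) if step is None else float(step)
    if h <= 0 or E + h == E:
        raise ValueError("finite-difference step underflow")
    h = min(h, 0.5 * E)
    w_r = (map_fn(E + h, th) - map_fn(E - h, th)) / (2 * h)
    # tangential displacement of h deg of arc corresponds to dtheta = h/E
    w_t = (map_fn(E, th + h / E) - map_fn(E, th - h / E)) / (2 * h)
    if not (np.isfinite(w_r) and np.isfinite(w_t)):
        raise ValueError(
            f"non-finite derivative at E={E}, theta={th} (near a map singularity?)"
        )
    return Jacobian2x2(
        dx_dr=float(np.real(w_r)), dx_dt=float(np.real(w_t)),
        dy_dr=float(np.imag(w_r)), dy_dt=float(np.imag(w_t)),
    )


def conformal_derivative_abs(E, theta, params: ModelParams):
    """|dw/dz| of the conformal variants -- closed-form oracle, mm/deg."""
    z = np.asarray(E, dtype=float) * np.exp(1j * np.asarray(theta, dtype=float))
    if params.is_dipole:
        return params.k * np.abs(1.0 / (z + params.a) - 1.0 / (z + params.b))
    return params.k / np.abs(z + params.a)
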