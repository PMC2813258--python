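"""The V1-V2-V3 complex: mirrored intermediate space and foveal banding.

The visual hemifield is mapped three times, once per area.  In a first
step the hemifield quadrants are reflected into an intermediate "pacman"
space: V1 occupies the central wedge (angular width ``alpha1 * pi``),
V2v/V2d are appended by mirroring each quadrant about the shared
vertical-meridian border with angular compression ``alpha2``, and V3v/V3d
by mirroring once more (compression ``alpha3``), so the V2/V3 border
carries the horizontal meridian and the outer rim of the pacman is again
a vertical-meridian representation.  In a second step the pacman is
projected to cortex through one of the complex-log maps.

The banding modification displaces the pacman by ``lam`` degrees along
the Cartesian x axis before the log projection: V1 shifts uniformly
toward the origin, while for ``|theta'| > pi/2`` (V2 and V3) the shift
magnitude grows with angle, which turns the shared foveal apex into a
line and the V2/V3 wedges into trapezoids -- on cortex, V2 and V3 then
form bands around the foveal tip of V1 instead of converging to a point.

Angle conventions: upper-field (ventral) areas occupy
positive intermediate angles, mirroring the sign of the visual polar
angle in V1.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import numpy as np

from .mapping import CorticalPoint, VisualPoint, map_complex
from .params import ModelParams

__all__ = [
    "AreaLabel", "PacmanPoint", "hemifield_to_pacman", "banding_shift",
    "classify_area", "project_complex", "project_batch", "project_with_flags",
    "pacman_angle", "graded_shift", "VisualAreaMap", "AREA_GROUPS",
]


class AreaLabel(str, Enum):
    """Early visual areas; v/d halves represent upper/lower quadrants."""
    V1 = "V1"
    V2v = "V2v"
    V2d = "V2d"
    V3v = "V3v"
    V3d = "V3d"

    def __str__(self) -> str:  # tidy CSV output
        return self.value


#: area groups used for curves and surface-area ratios
AREA_GROUPS: dict[str, tuple[AreaLabel, ...]] = {
    "V1": (AreaLabel.V1,),
    "V2": (AreaLabel.V2v, AreaLabel.V2d),
    "V3": (AreaLabel.V3v, AreaLabel.V3d),
}

_VENTRAL = (AreaLabel.V2v, AreaLabel.V3v)
_DORSAL = (AreaLabel.V2d, AreaLabel.V3d)


@dataclass(frozen=True)
class PacmanPoint:
    """A location in the mirrored/shifted intermediate space."""
    r: float           # degrees; equals E before the banding shift
    theta_p: float     # radians, intermediate angle
    label: AreaLabel
    source: VisualPoint | None = None
    folded: bool = False  # banding displaced the point through x = 0


def _borders(params: ModelParams) -> tuple[float, float, float]:
    """Cumulative positive angular borders V1|V2, V2|V3, V3|rim (rad)."""
    h = np.pi / 2
    a1, a2, a3 = params.alphas
    return (h * a1, h * (a1 + a2), h * (a1 + a2 + a3))


def pacman_angle(theta, area: AreaLabel, params: ModelParams, strict: bool = True):
    """Intermediate-space angle of visual polar angle ``theta`` in ``area``.

    Vectorized over ``theta``.  With ``strict`` (the default) the input
    must lie in the hemifield quadrant the area represents (ventral =
    upper field); with ``strict=False`` the area's own reflection formula
    is continued analytically slightly past its borders, which the
    finite-square estimators need.
    """
    theta = np.asarray(theta, dtype=float)
    if strict:
        if np.any(np.abs(theta) > np.pi / 2 + 1e-12):
            raise ValueError("hemifield polar angle must satisfy |theta| <= pi/2")
        if area in _VENTRAL and np.any(theta < -1e-12):
            raise ValueError(f"{area} represents the upper field; got theta < 0")
        if area in _DORSAL and np.any(theta > 1e-12):
            raise ValueError(f"{area} represents the lower field; got theta > 0")
    b1, b2, _ = _borders(params)
    a1, a2, a3 = params.alphas
    # signed forms agree with the reflection construction on each area's
    # quadrant and continue it smoothly beyond the borders
    if area == AreaLabel.V1:
        return a1 * theta
    if area == AreaLabel.V2v:
        return b1 + a2 * (np.pi / 2 - theta)
    if area == AreaLabel.V2d:
        return -b1 - a2 * (np.pi / 2 + theta)
    if area == AreaLabel.V3v:
        return b2 + a3 * theta
    return -b2 + a3 * theta


def hemifield_to_pacman(
    p: VisualPoint, target: AreaLabel, params: ModelParams
) -> PacmanPoint:
    """Reflect a hemifield point into the intermediate space of ``target``."""
    th_p = float(pacman_angle(p.polar_angle, target, params))
    return PacmanPoint(r=p.eccentricity, theta_p=th_p, label=target, source=p)


def classify_area(theta_p, params: ModelParams) -> AreaLabel:
    """Area label from an intermediate angle; borders go to the more
    foveal (lower-index) area."""
    t = float(theta_p)
    b1, b2, b3 = _borders(params)
    if abs(t) > b3 + 1e-12:
        raise ValueError(f"angle {t} outside the pacman span +-{b3}")
    if abs(t) <= b1:
        return AreaLabel.V1
    if abs(t) <= b2:
        return AreaLabel.V2v if t > 0 else AreaLabel.V2d
    return AreaLabel.V3v if t > 0 else AreaLabel.V3d


# ----------------------------------------------------------------------
# banding
# ----------------------------------------------------------------------

#: grading slope of the banding shift beyond |theta'| = pi/2, per radian
GRADING_SLOPE = 1.0


def graded_shift(theta_p, params: ModelParams):
    """Shift magnitude s(theta') of the banding, degrees.

    Constant ``lam`` over the V1 half-plane (|theta'| <= pi/2) and
    growing linearly at ``GRADING_SLOPE * lam`` per radian beyond it, so
    the shared apex of V2/V3 opens into a line while V1 translates
    rigidly.  The slope balances two foveal effects of the banding: the
    areal-magnification boost of V2/V3 (from the tangential stretch of
    the apex neighbourhood) against the distance of the foveal bands
    from the magnified pole.
    """
    t = np.abs(np.asarray(theta_p, dtype=float))
    return params.lam * np.where(
        t <= np.pi / 2, 1.0, 1.0 + GRADING_SLOPE * (t - np.pi / 2))


def _shift_arrays(r, theta_p, params: ModelParams):
    """Vectorized banding shift; returns (r', theta'', folded mask).

    The shift is a pure Cartesian x-displacement per intermediate angle,
    re-expressed in polar coordinates.  Points of the V1 half-plane whose
    displaced position crosses x = 0 (eccentricities below roughly
    ``lam``) fold into the pacman mouth beyond the foveal anchor; they
    stay on the map (the displaced frame is still injective per area)
    but are flagged for auditability.  For ``lam < a`` the folded region
    stays clear of the log-map pole.
    """
    r = np.asarray(r, dtype=float)
    theta_p = np.asarray(theta_p, dtype=float)
    r, theta_p = np.broadcast_arrays(r, theta_p)
    if params.lam == 0:
        return r.copy(), theta_p.copy(), np.zeros(r.shape, dtype=bool)
    s = graded_shift(theta_p, params)
    x = r * np.cos(theta_p) - s
    y = r * np.sin(theta_p)
    folded = (np.abs(theta_p) < np.pi / 2) & (x < 0)
    r2 = np.hypot(x, y)
    th2 = np.arctan2(y, x)
    # canonicalize the negative-x axis to +pi so the apex of V1 (y = +-0)
    # is one point rather than straddling the angular seam
    th2 = np.where((y == 0.0) & (x < 0), np.pi, th2)
    # keep a defined angle where the radius vanishes (apex at lam = r)
    th2 = np.where(r2 == 0, theta_p, th2)
    return r2, th2, folded


def banding_shift(q: PacmanPoint, params: ModelParams) -> PacmanPoint:
    """Apply the lam displacement to one intermediate point."""
    r2, th2, folded = _shift_arrays(q.r, q.theta_p, params)
    return PacmanPoint(r=float(r2), theta_p=float(th2), label=q.label,
                       source=q.source, folded=bool(folded))


# ----------------------------------------------------------------------
# full-complex projection
# ----------------------------------------------------------------------

def _foveal_offset(params: ModelParams) -> complex:
    """Cortical image of the pacman origin; subtracted so the V1 foveal
    point sits at the cortical origin."""
    return complex(map_complex(0.0, 0.0, params))


def project_with_flags(E, theta, area: AreaLabel, params: ModelParams,
                       banded: bool = False, strict: bool = True):
    """As :func:`project_batch`, also returning the banding fold mask."""
    E = np.asarray(E, dtype=float)
    th_p = pacman_angle(theta, area, params, strict=strict)
    E, th_p = np.broadcast_arrays(E, th_p)
    if banded:
        r, t, clamp = _shift_arrays(E, th_p, params)
    else:
        r, t, clamp = E, th_p, np.zeros(np.shape(E), dtype=bool)
    return map_complex(r, t, params) - _foveal_offset(params), clamp


def project_batch(E, theta, area: AreaLabel, params: ModelParams,
                  banded: bool = False, strict: bool = True):
    """Project arrays of hemifield points into ``area``; complex mm.

    Pipeline: mirror into the pacman, optional banding shift, complex-log
    projection (variant from ``params``), foveal translation.
    """
    w, _ = project_with_flags(E, theta, area, params, banded, strict)
    return w


def project_complex(p: VisualPoint, target: AreaLabel, params: ModelParams,
                    banded: bool = False) -> CorticalPoint:
    """Project one visual point into the cortical map of ``target``."""
    w = project_batch(p.eccentricity, p.polar_angle, target, params, banded)
    return CorticalPoint.from_complex(complex(w))


class VisualAreaMap:
    """A configured retino-cortical map of the V1-V2-V3 complex.

    Bundles a parameter set, map variant and banding flag, and exposes
    projection plus the cartography estimators as methods.

    Parameters
    ----------
    params
        Model parameters (variant selects the pointwise map family).
    banded
        Apply the lam banding shift before the log projection.
    """

    def __init__(self, params: ModelParams | None = None, banded: bool = False):
        self.params = params if params is not None else ModelParams()
        self.banded = bool(banded)

    def __repr__(self) -> str:
        p = self.params
        return (f"VisualAreaMap(variant={p.variant!r}, banded={self.banded}, "
                f"k={p.k}, a={p.a}, b={p.b}, lam={p.lam}, "
                f"alphas={p.alphas})")

    # -- projection ------------------------------------------------------
    def project(self, E, theta, area: AreaLabel | str, strict: bool = True):
        """Complex cortical positions (mm) of hemifield points in ``area``."""
        area = AreaLabel(area)
        return project_batch(E, theta, area, self.params, self.banded,
                             strict=strict)

    def project_flagged(self, E, theta, area: AreaLabel | str,
                        strict: bool = True):
        area = AreaLabel(area)
        return project_with_flags(E, theta, area, self.params, self.banded,
                                  strict=strict)

    def project_point(self, p: VisualPoint, area: AreaLabel | str) -> CorticalPoint:
        return CorticalPoint.from_complex(complex(self.project(
            p.eccentricity, p.polar_angle, area)))

    def areas_for(self, theta: float) -> tuple[AreaLabel, ...]:
        """The three areas containing the image of a point at ``theta``."""
        if theta >= 0:
            return (AreaLabel.V1, AreaLabel.V2v, AreaLabel.V3v)
        return (AreaLabel.V1, AreaLabel.V2d, AreaLabel.V3d)

    def with_(self, *, banded: bool | None = None, **updates) -> "VisualAreaMap":
        return VisualAreaMap(self.params.with_(**updates),
                             self.banded if banded is None else banded)

    # -- cartography (delegated; see foveamap.cartography) ---------------
    def local_anisotropy_field(self, grid=None):
        from .cartography import local_anisotropy_field
        return local_anisotropy_field(self, grid)

    def meridional_anisotropy_field(self, grid=None):
        from .cartography import meridional_anisotropy_field
        return meridional_anisotropy_field(self, grid)

    def areal_magnification_curve(self, area="V1", eccs=None):
        from .cartography import areal_magnification_curve
        return areal_magnification_curve(self, area, eccs)

    def area_ratio(self, area_i="V3", area_j="V1", ecc_range=(0.5, 12.0)):
        from .cartography import area_ratio
        return area_ratio(self, area_i, area_j, ecc_range)

    def extract_isolines(self, levels=None, n_pts=181):
        from .cartography import extract_isolines
        return extract_isolines(self, levels, n_pts=n_pts)

    def numeric_inverse(self, c: CorticalPoint | complex):
        from .cartography import numeric_inverse
        return numeric_inverse(self, c)
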