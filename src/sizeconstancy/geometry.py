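"""Stereo viewing geometry.

Maps horizontal disparity and vergence to egocentric distance for an object
on the cyclopean line of sight (directly in front of the observer).  With
interocular distance ``I`` (metres), vergence ``v`` and disparity ``delta``
(both in degrees; crossed/near disparities are negative, uncrossed/far
positive), the object subtends the binocular angle ``theta = v - delta`` and
its geometric distance is

    D_geom = I / (2 * tan((v - delta) / 2))

Human observers do not report ``D_geom`` veridically: close distances are
overestimated and far distances underestimated.  The module therefore also
exposes a *perceived* distance, obtained by evaluating the same formula with
a corrected disparity ``delta' = f(delta)`` where ``f`` is a compressive odd
function.  The correction is pluggable; the default is
``f(delta) = k1 * k2 * tanh(delta / k2)``.

All public interfaces use degrees; conversion to radians happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_INTEROCULAR_DISTANCE",
    "MIN_OBJECT_ANGLE_DEG",
    "GeometryError",
    "ViewingGeometry",
    "TanhDisparityCorrection",
    "identity_correction",
    "geometric_distance",
    "perceived_distance",
    "vergence_for_distance",
    "distance_grid",
]

#: Human interocular distance in metres (typical adult value).
DEFAULT_INTEROCULAR_DISTANCE = 0.065

#: Object angles (vergence - disparity) below this many degrees are rejected
#: rather than mapped to astronomically large distances.
MIN_OBJECT_ANGLE_DEG = 1e-6


class GeometryError(ValueError):
    """Raised when a viewing geometry violates its domain bounds."""


@dataclass(frozen=True)
class ViewingGeometry:
    """Binocular viewing configuration for a midline object.

    Parameters
    ----------
    vergence : float
        Vergence angle in degrees; must be positive (eyes converged).
    disparity : float
        Horizontal disparity in degrees.  Negative (crossed) for objects
        nearer than fixation, positive (uncrossed) for farther objects.
    interocular_distance : float
        Interocular separation in metres.
    """

    vergence: float
    disparity: float = 0.0
    interocular_distance: float = DEFAULT_INTEROCULAR_DISTANCE

    def __post_init__(self) -> None:
        if self.interocular_distance <= 0:
            raise GeometryError(
                f"interocular_distance must be > 0, got {self.interocular_distance}"
            )
        if self.vergence <= 0:
            raise GeometryError(f"vergence must be > 0 deg, got {self.vergence}")
        if self.vergence - self.disparity <= 0:
            raise GeometryError(
                "object angle (vergence - disparity) must be > 0 deg, got "
                f"{self.vergence - self.disparity}"
            )

    @property
    def object_angle(self) -> float:
        """Binocular subtense of the object, ``v - delta``, in degrees."""
        return self.vergence - self.disparity


# -- disparity corrections ---------------------------------------------------

#: A disparity correction maps a disparity (degrees) to a corrected disparity
#: (degrees).  It must be odd (f(0) = 0) to leave the fixation point fixed.
DisparityCorrection = Callable[[float], float]


def identity_correction(delta_deg: float) -> float:
    """Leave the disparity unchanged (perceived distance == geometric)."""
    return delta_deg


@dataclass(frozen=True)
class TanhDisparityCorrection:
    """Compressive odd disparity correction ``k1 * k2 * tanh(delta / k2)``.

    For ``gain <= 1`` the correction shrinks ``|delta|``, which overestimates
    near (crossed-disparity) distances and underestimates far (uncrossed)
    ones relative to the geometric solution — the pattern reported for human
    observers.  ``scale_deg`` (k2) sets the disparity range over which the
    compression saturates.
    """

    gain: float = 1.0
    scale_deg: float = 2.0

    def __call__(self, delta_deg: float) -> float:
        return self.gain * self.scale_deg * math.tanh(delta_deg / self.scale_deg)


DEFAULT_CORRECTION = TanhDisparityCorrection()


# -- distance computations ---------------------------------------------------


def _distance_from_angle(theta_deg: float, interocular: float) -> float:
    if not theta_deg > MIN_OBJECT_ANGLE_DEG:
        raise GeometryError(
            f"object angle {theta_deg} deg is below the minimum "
            f"{MIN_OBJECT_ANGLE_DEG} deg (distance would be unbounded)"
        )
    if theta_deg >= 180.0:
        raise GeometryError(f"object angle {theta_deg} deg must be < 180 deg")
    return interocular / (2.0 * math.tan(math.radians(theta_deg) / 2.0))


def geometric_distance(g: ViewingGeometry) -> float:
    """Geometric egocentric distance in metres, ``I / (2 tan((v - d)/2))``.

    Strictly decreasing in the object angle ``v - delta``.

    Raises
    ------
    GeometryError
        If the object angle is non-positive, below ``MIN_OBJECT_ANGLE_DEG``
        or at/above 180 degrees.
    """
    return _distance_from_angle(g.object_angle, g.interocular_distance)


def perceived_distance(
    g: ViewingGeometry,
    correction: DisparityCorrection = DEFAULT_CORRECTION,
) -> float:
    """Perceived egocentric distance in metres.

    Evaluates the geometric formula with the corrected disparity
    ``delta' = correction(delta)``.  With the identity correction this equals
    :func:`geometric_distance` exactly; with the default compressive
    correction near distances come out larger and far distances smaller than
    geometric.
    """
    delta_corr = correction(g.disparity)
    return _distance_from_angle(g.vergence - delta_corr, g.interocular_distance)


def vergence_for_distance(
    distance_m: float, interocular: float = DEFAULT_INTEROCULAR_DISTANCE
) -> float:
    """Vergence angle (degrees) that fixates a midline point at ``distance_m``.

    Inverts the geometric-distance formula at zero disparity:
    ``v = 2 * atan(I / (2 D))``.
    """
    if distance_m <= 0:
        raise GeometryError(f"distance must be > 0 m, got {distance_m}")
    return math.degrees(2.0 * math.atan(interocular / (2.0 * distance_m)))


def distance_grid(
    vergence_deg: np.ndarray,
    disparity_deg: np.ndarray,
    interocular: float = DEFAULT_INTEROCULAR_DISTANCE,
    correction: DisparityCorrection = DEFAULT_CORRECTION,
) -> pd.DataFrame:
    """Evaluate geometric and perceived distance over a (v, delta) product grid.

    Grid points with an invalid object angle are dropped.  Returns a tidy
    frame with columns ``vergence_deg, disparity_deg, d_geom_m, d_perc_m``.
    """
    rows = []
    for v in np.asarray(vergence_deg, dtype=float):
        for d in np.asarray(disparity_deg, dtype=float):
            if v - d <= MIN_OBJECT_ANGLE_DEG or v <= 0:
                continue
            g = ViewingGeometry(vergence=v, disparity=d, interocular_distance=interocular)
            rows.append(
                {
                    "vergence_deg": v,
                    "disparity_deg": d,
                    "d_geom_m": geometric_distance(g),
                    "d_perc_m": perceived_distance(g, correction),
                }
            )
    return pd.DataFrame(rows, columns=["vergence_deg", "disparity_deg", "d_geom_m", "d_perc_m"])
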