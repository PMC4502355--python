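"""10-20 / 10-10 EEG scalp positions by the proportional-arc construction.

Positions are unit direction vectors on the idealized spherical head
(world origin at the sphere center, +z vertex, +y nasion, +x right
preauricular).  Three families of landmarks anchor the construction:

* the midline nasion-inion arc through Cz, subdivided in 10% steps
  (Fpz at 10%, Fz 30%, Cz 50%, Pz 70%, Oz 90%, ...);
* the ear-to-ear arc through Cz (T7 at 10%, C5 20%, C3 30%, C1 40%, ...);
* the 10% "ring" — the circle of polar angle 72 degrees from the vertex
  through Fpz, T7/T8 and Oz — subdivided in equal azimuthal steps of 18
  degrees (Fpz, Fp2, AF8, F8, FT8, T8, ... going rightward).

Interior labels (F3, FC5, P3, CP1, ...) lie on the circle through their
row's two ring anchors and midline anchor (e.g. FC3 on the FT7-FCz-FT8
circle), subdivided proportionally: label 5 a quarter of the way in from
the ring, 3 halfway, 1 three quarters.  This is the standard spherical
idealization of the 10-10 system; by construction left/right pairs are
exact mirror images across the x = 0 plane.
"""

from __future__ import annotations

import re

import numpy as np

from .errors import UnknownNameError

__all__ = ["standard_position", "angular_distance_deg", "SUPPORTED_HINT"]

_MIDLINE = {
    "Nz": 0.0, "Fpz": 0.10, "AFz": 0.20, "Fz": 0.30, "FCz": 0.40,
    "Cz": 0.50, "CPz": 0.60, "Pz": 0.70, "POz": 0.80, "Oz": 0.90, "Iz": 1.0,
}

_EAR_ARC = {  # fractions from the LEFT preauricular point through Cz
    "T7": 0.10, "C5": 0.20, "C3": 0.30, "C1": 0.40, "Cz": 0.50,
    "C2": 0.60, "C4": 0.70, "C6": 0.80, "T8": 0.90,
}

# ring labels: azimuth (degrees) measured from +y (nasion) toward +x (right)
_RING_RIGHT = ["Fpz", "Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2", "Oz"]
_RING_LEFT = ["Fpz", "Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1", "Oz"]
_RING_POLAR_DEG = 72.0

_ROW_ANCHORS = {  # interior row -> (left ring anchor, midline anchor)
    "F": ("F7", "Fz"), "FC": ("FT7", "FCz"), "CP": ("TP7", "CPz"), "P": ("P7", "Pz"),
}

SUPPORTED_HINT = (
    "midline labels (Fpz..Oz), the C row (T7, C5..C6, T8), 10% ring labels "
    "(Fp1/2, AF7/8, F7/8, FT7/8, TP7/8, P7/8, PO7/8, O1/2) and interior "
    "rows F/FC/CP/P with numbers 1-6"
)


def _midline(frac: float) -> np.ndarray:
    theta = np.pi * frac  # angle from nasion, through Cz, to inion
    return np.array([0.0, np.cos(theta), np.sin(theta)])


def _ear_arc(frac: float) -> np.ndarray:
    phi = np.pi * frac  # angle from the left ear, through Cz, to the right ear
    return np.array([-np.cos(phi), 0.0, np.sin(phi)])


def _ring(azimuth_deg: float) -> np.ndarray:
    pol = np.deg2rad(_RING_POLAR_DEG)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(pol) * np.sin(az), np.sin(pol) * np.cos(az), np.cos(pol)])


def _ring_azimuth(label: str) -> float | None:
    if label in _RING_RIGHT:
        return 18.0 * _RING_RIGHT.index(label)
    if label in _RING_LEFT:
        return -18.0 * _RING_LEFT.index(label)
    return None


def _circle_point(a: np.ndarray, m: np.ndarray, frac: float, mirror: bool) -> np.ndarray:
    """Point a fraction ``frac`` along the circle arc from ``a`` to ``m``.

    The circle is the intersection of the sphere with the plane through
    ``a``, ``m`` and the mirror image of ``a`` (the row's far anchor).
    ``mirror`` reflects the result across x = 0 for right-sided labels.
    """
    b = a * np.array([-1.0, 1.0, 1.0])  # right anchor = mirrored left anchor
    normal = np.cross(m - a, b - a)
    normal = normal / np.linalg.norm(normal)
    center = np.dot(normal, a) * normal  # closest point of the plane to origin
    rho = np.linalg.norm(a - center)
    e1 = (a - center) / rho
    e2 = np.cross(normal, e1)
    beta = np.arctan2(np.dot(m - center, e2), np.dot(m - center, e1))
    ang = frac * beta
    p = center + rho * (np.cos(ang) * e1 + np.sin(ang) * e2)
    if mirror:
        p = p * np.array([-1.0, 1.0, 1.0])
    return p / np.linalg.norm(p)


def standard_position(label: str) -> np.ndarray:
    """Unit direction of a 10-10 scalp position in head coordinates.

    Supports midline, C-row, 10% ring, and interior F/FC/CP/P row labels;
    raises :class:`~fieldlab.errors.UnknownNameError` otherwise.
    """
    if label in _MIDLINE:
        return _midline(_MIDLINE[label])
    if label in _EAR_ARC:
        return _ear_arc(_EAR_ARC[label])
    az = _ring_azimuth(label)
    if az is not None:
        return _ring(az)
    m = re.fullmatch(r"(F|FC|C|CP|P)([1-6])", label)
    if m:
        row, num = m.group(1), int(m.group(2))
        if row == "C":  # C2/C4/C6 (odd handled by the ear-arc table)
            return _ear_arc(_EAR_ARC[f"C{num}"])
        left_anchor, mid_anchor = _ROW_ANCHORS[row]
        # odd numbers are left-sided, even mirror the corresponding odd one;
        # 5 sits a quarter of the way in from the ring anchor, 3 halfway, 1
        # three quarters (10-10 half-row has four equal arc intervals)
        n_eff = num if num % 2 == 1 else num - 1
        frac = {5: 0.25, 3: 0.5, 1: 0.75}[n_eff]
        a = standard_position(left_anchor)
        mid = standard_position(mid_anchor)
        return _circle_point(a, mid, frac, mirror=(num % 2 == 0))
    raise UnknownNameError(f"unknown 10-10 label {label!r}; supported: {SUPPORTED_HINT}")


def angular_distance_deg(label_a: str, label_b: str) -> float:
    """Great-circle angle (degrees) between two 10-10 positions."""
    a, b = standard_position(label_a), standard_position(label_b)
    return float(np.rad2deg(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))
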