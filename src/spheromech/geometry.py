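"""Analytic geometry of a two-sphere (doublet) silhouette.

A fusing spheroid pair projects to the union of two disks.  The neck
radius r0 is the half-length of the common chord of the two circles;
these helpers convert between (radius_a, radius_b, center distance)
and the neck radius, and give the exact union area used to validate
segmentation.
"""

from __future__ import annotations

import math

__all__ = [
    "neck_half_chord",
    "center_distance_for_neck",
    "union_area",
]


def neck_half_chord(radius_a: float, radius_b: float, distance: float) -> float:
    """Half-length of the common chord of two circles.

    Returns 0 for separated or externally tangent circles and the smaller
    radius when one circle is entirely contained in the other (the neck
    saturates at full engulfment).
    """
    if radius_a <= 0 or radius_b <= 0:
        raise ValueError("radii must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance >= radius_a + radius_b:
        return 0.0
    if distance <= abs(radius_a - radius_b):
        return min(radius_a, radius_b)
    # distance from center A to the radical line
    x = (distance * distance + radius_a * radius_a - radius_b * radius_b) / (2.0 * distance)
    h2 = radius_a * radius_a - x * x
    return math.sqrt(max(h2, 0.0))


def center_distance_for_neck(radius_a: float, radius_b: float, neck_radius: float) -> float:
    """Center distance at which two circles share a chord of half-length ``neck_radius``.

    Valid for the partial-overlap (fusion) regime where both centers lie on
    opposite sides of the chord: d = sqrt(Ra^2 - r0^2) + sqrt(Rb^2 - r0^2).
    ``neck_radius = 0`` gives external tangency, ``neck_radius = min(Ra, Rb)``
    the engulfment boundary.
    """
    if radius_a <= 0 or radius_b <= 0:
        raise ValueError("radii must be positive")
    if neck_radius < 0:
        raise ValueError("neck_radius must be non-negative")
    rmin = min(radius_a, radius_b)
    if neck_radius > rmin * (1.0 + 1e-12):
        raise ValueError(
            f"neck_radius {neck_radius} exceeds the smaller radius {rmin}: "
            "no two-circle silhouette exists"
        )
    r0 = min(neck_radius, rmin)
    xa = math.sqrt(max(radius_a * radius_a - r0 * r0, 0.0))
    xb = math.sqrt(max(radius_b * radius_b - r0 * r0, 0.0))
    return xa + xb


def union_area(radius_a: float, radius_b: float, distance: float) -> float:
    """Exact area of the union of two disks at center distance ``distance``."""
    if radius_a <= 0 or radius_b <= 0:
        raise ValueError("radii must be positive")
    a_a = math.pi * radius_a * radius_a
    a_b = math.pi * radius_b * radius_b
    if distance >= radius_a + radius_b:
        return a_a + a_b
    if distance <= abs(radius_a - radius_b):
        return max(a_a, a_b)
    d2 = distance * distance
    ra2 = radius_a * radius_a
    rb2 = radius_b * radius_b
    alpha = math.acos((d2 + ra2 - rb2) / (2.0 * distance * radius_a))
    beta = math.acos((d2 + rb2 - ra2) / (2.0 * distance * radius_b))
    lens = (
        ra2 * alpha
        + rb2 * beta
        - 0.5
        * math.sqrt(
            (-distance + radius_a + radius_b)
            * (distance + radius_a - radius_b)
            * (distance - radius_a + radius_b)
            * (distance + radius_a + radius_b)
        )
    )
    return a_a + a_b - lens


def lobe_radius_from_cap_area(side_area: float, half_chord: float) -> float:
    """Radius of a circle whose area minus the cap beyond a chord equals ``side_area``.

    Used to recover a lobe radius from the pixel area of one side of a
    segmented doublet: the visible lobe is the full disk minus the circular
    cap that lies beyond the neck plane (chord of half-length ``half_chord``).
    Monotone in r, solved by bisection.
    """
    if side_area <= 0:
        raise ValueError("side_area must be positive")
    if half_chord < 0:
        raise ValueError("half_chord must be non-negative")
    c = half_chord

    def area(r: float) -> float:
        if r <= c:
            return 0.5 * math.pi * r * r
        h = math.sqrt(r * r - c * c)
        cap = r * r * math.acos(h / r) - h * c
        return math.pi * r * r - cap

    # degenerate: measured area smaller than the half-disk of the chord
    if side_area <= area(c):
        return max(c, math.sqrt(2.0 * side_area / math.pi))
    lo = c
    hi = max(2.0 * c, math.sqrt(side_area / math.pi)) + 1.0
    while area(hi) < side_area:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if area(mid) < side_area:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
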