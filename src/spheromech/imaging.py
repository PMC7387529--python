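"""Geometry extraction from doublet time-lapse images.

Replaces manual measurement of fusing spheroid pairs: each frame is
segmented (global Otsu threshold, dark objects on a light field), the
doublet axis is taken as the principal axis of the foreground, and a
width profile perpendicular to that axis yields the neck radius (half the
minimal width between the two lobe maxima) and the lobe radii (area-based
equivalent circles corrected for the cap hidden beyond the neck plane).

Lengths are converted to µm through the pixel size; raster coordinates are
row/column, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .fusion import NeckSeries
from .geometry import lobe_radius_from_cap_area, neck_half_chord

__all__ = [
    "SegmentationMask",
    "FrameGeometry",
    "NeckUndefinedError",
    "segment_doublet",
    "measure_pair_geometry",
    "track_series",
]


class NeckUndefinedError(ValueError):
    """The width profile is unimodal: the pair has fully fused."""


@dataclass
class SegmentationMask:
    mask: np.ndarray  # bool raster
    pixel_size: float  # µm/px
    frame_time: float = float("nan")  # h

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class FrameGeometry:
    """Per-frame doublet geometry, lengths in µm, angle in radians."""

    centroid_a: tuple[float, float]  # (row, col) µm
    centroid_b: tuple[float, float]
    radius_a: float
    radius_b: float
    neck_radius: float
    axis_angle: float
    separated: bool = False
    meta: dict = field(default_factory=dict)


def segment_doublet(
    image: np.ndarray,
    pixel_size: float,
    min_area_px: int = 100,
    frame_time: float = float("nan"),
) -> SegmentationMask:
    """Threshold a frame and keep the (up to two) largest foreground objects.

    Otsu's global threshold is applied to the intensity image; the minority
    class is taken as foreground, holes are filled, and components below
    64 px are discarded as debris.  Raises ``ValueError('no object found')``
    when the total foreground is below ``min_area_px``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    try:
        th = threshold_otsu(img)
    except ValueError:  # constant image
        raise ValueError("no object found") from None
    fg = img < th
    if fg.mean() > 0.5:
        fg = ~fg
    if fg.sum() == 0 or fg.all():
        raise ValueError("no object found")
    # genuine objects separate from background by far more than the
    # within-class spread; a thresholded noise floor does not
    contrast = abs(img[fg].mean() - img[~fg].mean())
    spread = max(img[fg].std(), img[~fg].std(), 1e-12)
    if contrast < 4.0 * spread:
        raise ValueError("no object found")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no object found")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(areas)[::-1]
    keep_labels = [order[i] + 1 for i in range(min(2, n)) if areas[order[i]] >= 64]
    if not keep_labels:
        keep_labels = [order[0] + 1]
    mask = np.isin(labels, keep_labels)
    if mask.sum() < min_area_px:
        raise ValueError("no object found")
    return SegmentationMask(mask=mask, pixel_size=pixel_size, frame_time=frame_time)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit vector of the largest-variance direction of pixel coordinates."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(c)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    # deterministic sign: positive row (or column) component
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis


def _width_profile(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-1-px-bin perpendicular extent of the foreground along the axis.

    Floor binning keeps exactly one pixel column per bin when the doublet
    axis is raster-aligned (rounding would alternate empty/double bins).
    """
    ub = np.floor(u).astype(int)
    lo, hi = ub.min(), ub.max()
    nbin = hi - lo + 1
    width = np.zeros(nbin)
    vmax = np.full(nbin, -np.inf)
    vmin = np.full(nbin, np.inf)
    np.maximum.at(vmax, ub - lo, v)
    np.minimum.at(vmin, ub - lo, v)
    filled = np.isfinite(vmax)
    width[filled] = vmax[filled] - vmin[filled] + 1.0  # +1: pixel footprint
    centers = np.arange(lo, hi + 1, dtype=float) + 0.5
    return centers, width


def _neck_vertex(
    x: np.ndarray, y: np.ndarray, imin: int, p1: int, p2: int
) -> tuple[float, float]:
    """Sub-pixel neck position/width from the V-shaped profile minimum.

    The union width near the neck is the larger of the two lobe chords, a
    function with a downward kink at the crossing, so the raw bin minimum
    overshoots the true width.  Each arm is locally a smooth circle arc:
    fit a line to 2–4 bins per side (abscissa shifted half a bin toward the
    arm's lobe, where the bin extent is actually attained) and intersect.
    Falls back to the raw minimum for degenerate arms.
    """
    xm, ym = float(x[imin]), float(y[imin])
    li = np.arange(max(p1, imin - 4), imin)
    ri = np.arange(imin + 1, min(p2, imin + 4) + 1)
    if li.size < 2 or ri.size < 2:
        return xm, ym
    ml, bl = np.polyfit(x[li] - 0.5, y[li], 1)
    mr, br = np.polyfit(x[ri] + 0.5, y[ri], 1)
    if ml >= 0 or mr <= 0 or abs(ml - mr) < 1e-9:
        return xm, ym
    xv = (br - bl) / (ml - mr)
    if not (xm - 1.5 <= xv <= xm + 1.5):
        return xm, ym
    yv = ml * xv + bl
    return float(xv), float(min(max(yv, 0.0), ym))


def _fit_circle_boundary(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Sub-pixel circle through outer-boundary pixel centers.

    Kasa algebraic fit, then Gauss–Newton refinement with a +0.5 px outward
    correction (an outermost mask pixel center lies on average half a pixel
    inside the true edge).
    """
    x, y = pts[:, 1], pts[:, 0]
    A = np.c_[2 * x, 2 * y, np.ones(len(x))]
    sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    c = np.array([sol[1], sol[0]])
    r = math.sqrt(max(sol[2] + sol[0] ** 2 + sol[1] ** 2, 1e-12))
    for _ in range(3):
        dvec = pts - c
        dist = np.linalg.norm(dvec, axis=1)
        r = float(dist.mean()) + 0.5
        unit = dvec / np.maximum(dist[:, None], 1e-9)
        resid = dist + 0.5 - r
        dc, *_ = np.linalg.lstsq(-unit, -resid, rcond=None)
        c = c + dc
    return c, r


def measure_pair_geometry(mask: SegmentationMask) -> FrameGeometry:
    """Neck radius and lobe radii of a segmented doublet.

    Two separate components → separated pair, neck radius 0, plain
    equivalent-circle radii.  One component → the width profile
    perpendicular to the principal axis must show two lobe maxima (else
    :class:`NeckUndefinedError`: fully fused); the neck plane initializes a
    two-circle refinement in which each lobe's circle is fit sub-pixel to
    its side of the union boundary (away from the neck that boundary *is*
    the lobe circle), and the neck radius is the half-chord of the fitted
    circles.  If the refinement is degenerate, the profile-based minimum
    width and cap-corrected split areas are used directly.
    """
    ps = mask.pixel_size
    labels, n = ndimage.label(mask.mask)
    if n == 0:
        raise ValueError("empty mask")
    if n >= 2:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        order = np.argsort(areas)[::-1][:2]
        cents = ndimage.center_of_mass(mask.mask, labels, index=[o + 1 for o in order])
        radii = [math.sqrt(areas[o] / math.pi) * ps for o in order]
        (ca, cb) = [(c[0] * ps, c[1] * ps) for c in cents]
        ang = math.atan2(cb[0] - ca[0], cb[1] - ca[1])
        return FrameGeometry(
            centroid_a=ca,
            centroid_b=cb,
            radius_a=radii[0],
            radius_b=radii[1],
            neck_radius=0.0,
            axis_angle=ang,
            separated=True,
        )

    coords = np.argwhere(mask.mask).astype(float)
    axis = _principal_axis(coords)
    perp = np.array([-axis[1], axis[0]])
    center = coords.mean(axis=0)
    u = (coords - center) @ axis
    v = (coords - center) @ perp
    centers, width = _width_profile(u, v)
    # light smoothing for peak finding only; raw profile keeps the metrology
    if width.size >= 5:
        kernel = np.ones(3) / 3.0
        smooth = np.convolve(width, kernel, mode="same")
        smooth[0], smooth[-1] = width[0], width[-1]
    else:
        smooth = width
    # prominence threshold scaled to the object (rasterization jitter is a
    # few px, a genuine second lobe rises well above the neck); a minimum
    # peak distance stops a jittery lobe plateau from counting twice
    prom = max(2.0, 0.04 * float(width.max()))
    peaks, props = find_peaks(smooth, prominence=prom, distance=max(len(smooth) // 5, 2))
    if peaks.size < 2:
        raise NeckUndefinedError("neck undefined: width profile is unimodal (fully fused)")
    top2 = peaks[np.argsort(props["prominences"])[::-1][:2]]
    p1, p2 = sorted(top2)
    imin = p1 + int(np.argmin(width[p1 : p2 + 1]))
    u_neck, w_neck = _neck_vertex(centers, width, imin, p1, p2)
    neck_radius_px = max(w_neck / 2.0, 0.0)
    ang = math.atan2(axis[0], axis[1])
    method = "two_circle_fit"

    # two-circle sub-pixel refinement on the union boundary
    boundary = np.argwhere(mask.mask & ~ndimage.binary_erosion(mask.mask)).astype(float)
    ub = (boundary - center) @ axis
    pts_a = boundary[ub < u_neck - 2.0]
    pts_b = boundary[ub > u_neck + 2.0]
    ca_px = cb_px = None
    if len(pts_a) >= 10 and len(pts_b) >= 10:
        try:
            ca_px, ra_px = _fit_circle_boundary(pts_a)
            cb_px, rb_px = _fit_circle_boundary(pts_b)
            d = float(np.linalg.norm(ca_px - cb_px))
            neck_radius_px = neck_half_chord(ra_px, rb_px, d)
        except (np.linalg.LinAlgError, ValueError):
            ca_px = None
    if ca_px is None:
        # profile fallback: minimal width + cap-corrected split areas
        method = "width_profile"
        side_a = u < u_neck
        ra_px = lobe_radius_from_cap_area(float(side_a.sum()), neck_radius_px)
        rb_px = lobe_radius_from_cap_area(float((~side_a).sum()), neck_radius_px)
        ha = math.sqrt(max(ra_px**2 - neck_radius_px**2, 0.0))
        hb = math.sqrt(max(rb_px**2 - neck_radius_px**2, 0.0))
        ca_px = center + (u_neck - ha) * axis
        cb_px = center + (u_neck + hb) * axis
    return FrameGeometry(
        centroid_a=(ca_px[0] * ps, ca_px[1] * ps),
        centroid_b=(cb_px[0] * ps, cb_px[1] * ps),
        radius_a=ra_px * ps,
        radius_b=rb_px * ps,
        neck_radius=neck_radius_px * ps,
        axis_angle=ang,
        meta={"method": method, "profile_neck_px": max(w_neck / 2.0, 0.0)},
    )


def track_series(
    stack: np.ndarray,
    times: np.ndarray,
    pixel_size: float,
    pair_type: str = "measured",
    age_days: float = 7.0,
) -> NeckSeries:
    """Measure a whole time-lapse stack into a :class:`NeckSeries`.

    Per-frame failures (no object, fully fused) become flagged missing
    points, not aborts.  R0 is frozen from the first measurable frame as the
    mean of the two lobe radii; for a separated first frame the components'
    equivalent radii are used.
    """
    stack = np.asarray(stack)
    times = np.asarray(times, dtype=float)
    if stack.shape[0] != times.size:
        raise ValueError("stack length must equal times length")
    neck = np.full(times.size, np.nan)
    rad_a = np.full(times.size, np.nan)
    rad_b = np.full(times.size, np.nan)
    errors: dict[int, str] = {}
    for k in range(times.size):
        try:
            m = segment_doublet(stack[k], pixel_size, frame_time=times[k])
            geo = measure_pair_geometry(m)
        except (ValueError, NeckUndefinedError) as exc:  # noqa: PERF203
            errors[k] = str(exc)
            continue
        neck[k] = geo.neck_radius
        rad_a[k] = geo.radius_a
        rad_b[k] = geo.radius_b
    valid = ~np.isnan(rad_a)
    if not valid.any():
        raise ValueError("no frame could be measured")
    first = int(np.nonzero(valid)[0][0])
    R0 = 0.5 * (rad_a[first] + rad_b[first])
    return NeckSeries(
        times=times,
        neck_radius=neck,
        R0=R0,
        radius_a=rad_a,
        radius_b=rad_b,
        pair_type=pair_type,
        age_days=age_days,
        meta={"pixel_size_um": pixel_size, "frame_errors": errors, "R0_frame": first},
    )
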