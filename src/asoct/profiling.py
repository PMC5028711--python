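"""Spur-referenced thickness profiling.

Measurement locations are defined at fixed distances from the scleral
spur, measured either along the arc of the curved posterior scleral
boundary (the primary scheme: 0, 1, 2, 3 and 4 mm) or as straight-line
lateral distances (a sensitivity variant).  At each location the
conjunctival thickness is the ACB-to-ASB distance and the scleral
thickness the ASB-to-PSB distance, using either the axial (vertical)
metric or the distance along the local normal of a reference boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .core import (
    BoundaryTrace,
    cumulative_arc_length,
    line_polyline_intersections,
)

DEFAULT_DISTANCES_UM = (0.0, 1000.0, 2000.0, 3000.0, 4000.0)


@dataclass(frozen=True)
class MeasurementScheme:
    """Where and how thickness is measured."""

    distances_um: Tuple[float, ...] = DEFAULT_DISTANCES_UM
    location_mode: str = "arc_psb"   # or "straight_line"
    metric: str = "axial"            # or "normal"
    normal_reference: str = "ASB"    # boundary anchoring the normal metric

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_um, dtype=float)
        if d.size == 0 or np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("distances must be non-negative and strictly increasing")
        if self.location_mode not in ("arc_psb", "straight_line"):
            raise ValueError(f"unknown location_mode {self.location_mode!r}")
        if self.metric not in ("axial", "normal"):
            raise ValueError(f"unknown metric {self.metric!r}")
        object.__setattr__(self, "distances_um", tuple(float(v) for v in d))


@dataclass
class ThicknessProfile:
    """Conjunctival and scleral thickness at the scheme's locations for
    one eye and meridian."""

    eye_id: str
    meridian: str
    scheme: MeasurementScheme
    conjunctival_um: np.ndarray
    scleral_um: np.ndarray
    n_repeats_averaged: int = 1

    def __post_init__(self) -> None:
        self.conjunctival_um = np.asarray(self.conjunctival_um, dtype=float)
        self.scleral_um = np.asarray(self.scleral_um, dtype=float)
        k = len(self.scheme.distances_um)
        if self.conjunctival_um.shape != (k,) or self.scleral_um.shape != (k,):
            raise ValueError("one thickness value per location is required")
        if np.any(self.conjunctival_um <= 0) or np.any(self.scleral_um <= 0):
            raise ValueError("thickness values must be positive")


def project_to_polyline(point: Sequence[float], xs: np.ndarray, zs: np.ndarray):
    """Nearest point on the polyline (xs, zs) to ``point``.

    Returns (projected_point, vertex_index, segment_fraction).
    """
    p = np.asarray(point, dtype=float)
    ax, az = xs[:-1], zs[:-1]
    ex, ez = np.diff(xs), np.diff(zs)
    seg_len_sq = ex**2 + ez**2
    u = ((p[0] - ax) * ex + (p[1] - az) * ez) / seg_len_sq
    u = np.clip(u, 0.0, 1.0)
    px = ax + u * ex
    pz = az + u * ez
    d_sq = (px - p[0]) ** 2 + (pz - p[1]) ** 2
    i = int(np.argmin(d_sq))
    return np.array([px[i], pz[i]]), i, float(u[i])


def locate_points(
    psb: BoundaryTrace,
    spur: Sequence[float],
    scheme: MeasurementScheme,
) -> np.ndarray:
    """(x, depth) measurement points on the PSB for each scheme distance.

    The spur annotation is projected onto the PSB polyline; distances
    then run away from the limbus (increasing x), either along the
    cumulative arc of the PSB or as straight-line lateral offsets.
    """
    xs, zs = psb.x, psb.depth
    spur_pt, i, u = project_to_polyline(spur, xs, zs)
    dist = np.asarray(scheme.distances_um, dtype=float)

    if scheme.location_mode == "straight_line":
        x_targets = spur_pt[0] + dist
        if x_targets[-1] > xs[-1] + 1e-9:
            raise ValueError(
                f"distance {dist[-1]:.0f} um exceeds trace extent; "
                f"maximum reachable is {xs[-1] - spur_pt[0]:.1f} um"
            )
        return np.column_stack([x_targets, np.interp(x_targets, xs, zs)])

    # arc mode: cumulative chord length from the spur projection
    arc = cumulative_arc_length(xs, zs)
    s_spur = arc[i] + u * (arc[i + 1] - arc[i])
    s_targets = s_spur + dist
    if s_targets[-1] > arc[-1] + 1e-9:
        raise ValueError(
            f"arc distance {dist[-1]:.0f} um exceeds trace extent; "
            f"maximum reachable is {arc[-1] - s_spur:.1f} um"
        )
    x_pts = np.interp(s_targets, arc, xs)
    z_pts = np.interp(s_targets, arc, zs)
    return np.column_stack([x_pts, z_pts])


def axial_thickness(
    upper: BoundaryTrace, lower: BoundaryTrace, points: np.ndarray
) -> np.ndarray:
    """Vertical (along A-scan) distance lower - upper at each point's x."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x = points[:, 0]
    return lower(x) - upper(x)


def normal_thickness(
    reference: BoundaryTrace,
    upper: BoundaryTrace,
    lower: BoundaryTrace,
    points: np.ndarray,
    slope_window: int = 5,
) -> np.ndarray:
    """Thickness along the local normal of ``reference`` at each point.

    The normal line is anchored on the reference boundary at the
    point's lateral position; thickness is the distance between its
    intersections with the upper and lower traces.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    slopes = reference.slope(window=slope_window)
    out = np.empty(points.shape[0])
    for k, (x_p, _) in enumerate(points):
        m = np.interp(x_p, reference.x, slopes)
        anchor = np.array([x_p, float(reference(x_p))])
        # downward-pointing unit normal of a surface with slope m
        n_hat = np.array([-m, 1.0]) / np.hypot(m, 1.0)
        t_up = _nearest_intersection(anchor, n_hat, upper)
        t_lo = _nearest_intersection(anchor, n_hat, lower)
        out[k] = t_lo - t_up
    return out


def _nearest_intersection(p0, d, trace: BoundaryTrace) -> float:
    ts = line_polyline_intersections(p0, d, trace.x, trace.depth)
    if ts.size == 0:
        raise ValueError(
            f"normal through x={p0[0]:.1f} um does not intersect {trace.name}"
        )
    return float(ts[np.argmin(np.abs(ts))])


def average_repeats(profiles: List[ThicknessProfile]) -> ThicknessProfile:
    """Per-location arithmetic mean of repeated scans of one eye/meridian."""
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.scheme != first.scheme:
            raise ValueError("profiles have mismatched measurement schemes")
        if (p.eye_id, p.meridian) != (first.eye_id, first.meridian):
            raise ValueError("profiles belong to different eyes/meridians")
    conj = np.mean([p.conjunctival_um for p in profiles], axis=0)
    scl = np.mean([p.scleral_um for p in profiles], axis=0)
    return ThicknessProfile(
        eye_id=first.eye_id,
        meridian=first.meridian,
        scheme=first.scheme,
        conjunctival_um=conj,
        scleral_um=scl,
        n_repeats_averaged=sum(p.n_repeats_averaged for p in profiles),
    )


def profile_from_boundaries(
    acb: BoundaryTrace,
    asb: BoundaryTrace,
    psb: BoundaryTrace,
    spur: Sequence[float],
    scheme: MeasurementScheme,
    eye_id: str = "",
    meridian: str = "nasal",
) -> ThicknessProfile:
    """Full thickness profile from three physical-space traces."""
    points = locate_points(psb, spur, scheme)
    if scheme.metric == "axial":
        conj = axial_thickness(acb, asb, points)
        scl = axial_thickness(asb, psb, points)
    else:
        ref = {"ACB": acb, "ASB": asb, "PSB": psb}[scheme.normal_reference]
        conj = normal_thickness(ref, acb, asb, points)
        scl = normal_thickness(ref, asb, psb, points)
    return ThicknessProfile(
        eye_id=eye_id,
        meridian=meridian,
        scheme=scheme,
        conjunctival_um=conj,
        scleral_um=scl,
    )
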