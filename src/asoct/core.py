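"""Shared domain types and geometry helpers.

Coordinate conventions used throughout the package:

* Lateral position ``x`` is in micrometres, increasing *away* from the
  limbus, so arc distance from the scleral spur is non-negative in both
  the nasal and temporal meridians.
* Depth increases downward (row 0 is the top of the B-scan).
* Boundary traces carry their coordinate *space*:

  - ``image``    -- as exported by the device: depths are device-scaled
    micrometres (rows times the axial pixel pitch, which assumes a
    uniform tissue refractive index), lateral positions are column
    positions times the lateral pixel pitch.
  - ``optical``  -- depths below the anterior conjunctival boundary are
    cumulative optical path length (geometric distance times group
    index); the ACB itself is geometric (air).
  - ``physical`` -- true geometric micrometres after refraction
    correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

BOUNDARY_NAMES = ("ACB", "ASB", "PSB")
SPACES = ("image", "optical", "physical")
PROVENANCES = ("auto", "auto+corrected", "manual")


class RefractionError(ValueError):
    """Raised when a ray cannot be traced (total internal reflection,
    ray fold-over, or a normal that misses a boundary)."""


@dataclass(frozen=True)
class RefractiveModel:
    """Group refractive indices of the media traversed by the OCT beam.

    The device exports images scaled with a single uniform tissue index
    (``n_device``); the correction re-propagates each A-scan with
    separate conjunctival and scleral indices.
    """

    n_air: float = 1.000
    n_conjunctiva: float = 1.38
    n_sclera: float = 1.41
    n_device: float = 1.40

    def __post_init__(self) -> None:
        for name in ("n_air", "n_conjunctiva", "n_sclera", "n_device"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"refractive index {name} must be >= 1")


@dataclass(frozen=True)
class DeviceModel:
    """Scan geometry of the spectral-domain anterior-segment OCT.

    ``axial_scale`` is the axial pixel pitch in tissue under the
    device's uniform-index assumption; it is configurable because the
    manufacturer publishes the axial *resolution* (3.9 um) but not the
    sampling pitch.
    """

    width_px: int = 1536
    height_px: int = 678
    lateral_scale: float = 16000.0 / 1536.0  # um per pixel
    axial_scale: float = 3.87                # um per pixel in tissue at n_device
    axial_resolution: float = 3.9            # um (metadata)
    wavelength_nm: float = 870.0             # metadata

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ValueError("pixel scales must be positive")

    @property
    def width_um(self) -> float:
        return self.width_px * self.lateral_scale

    @property
    def depth_um(self) -> float:
        return self.height_px * self.axial_scale


@dataclass
class BoundaryTrace:
    """One tissue boundary as a per-column sub-pixel polyline.

    ``x`` and ``depth`` are parallel 1-D arrays in micrometres (see
    module docstring for the meaning of ``space``).
    """

    name: str
    space: str
    x: np.ndarray
    depth: np.ndarray
    provenance: str = "auto"

    def __post_init__(self) -> None:
        if self.name not in BOUNDARY_NAMES:
            raise ValueError(f"unknown boundary name {self.name!r}")
        if self.space not in SPACES:
            raise ValueError(f"unknown coordinate space {self.space!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.depth.shape:
            raise ValueError("x and depth must be matching 1-D arrays")
        if self.x.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")

    def __call__(self, x) -> np.ndarray:
        """Depth at lateral position(s) ``x`` by linear interpolation."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x[0] - 1e-9) or np.any(x > self.x[-1] + 1e-9):
            raise ValueError(
                f"x outside traced extent [{self.x[0]:.1f}, {self.x[-1]:.1f}] um"
            )
        return np.interp(x, self.x, self.depth)

    def slope(self, window: int = 5) -> np.ndarray:
        """Smoothed d(depth)/dx along the trace (central differences
        followed by a ``window``-sample moving average)."""
        return smoothed_slope(self.x, self.depth, window=window)

    def with_depth(self, depth: np.ndarray, **changes) -> "BoundaryTrace":
        out = replace(self, depth=np.asarray(depth, dtype=float), **changes)
        return out


@dataclass
class BScanImage:
    """A rendered or loaded cross-sectional scan.

    ``pixels`` is a (height, width) float array in arbitrary intensity
    units (uint16 data is divided by its nominal white level on load).
    ``spur_annotation`` is an image-space (column_px, row_px) pair.
    """

    pixels: np.ndarray
    device: DeviceModel
    meridian: str
    quality_index: Optional[float] = None
    spur_annotation: Optional[Tuple[float, float]] = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.meridian not in ("nasal", "temporal"):
            raise ValueError(f"unknown meridian {self.meridian!r}")

    @property
    def spur_x_um(self) -> Optional[float]:
        if self.spur_annotation is None:
            return None
        return self.spur_annotation[0] * self.device.lateral_scale


def smoothed_slope(x: np.ndarray, z: np.ndarray, window: int = 5) -> np.ndarray:
    """dz/dx via central differences with a moving-average smooth.

    Handles non-uniform ``x``. The smoothing window is small relative
    to anatomical curvature so it suppresses per-column noise without
    biasing the local surface tangent.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    slope = np.gradient(z, x)
    if window > 1 and slope.size >= window:
        slope = uniform_filter1d(slope, size=window, mode="nearest")
    return slope


def refract(d: np.ndarray, normal: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Snell's-law refraction of unit direction(s) ``d`` at surface
    normal(s) ``normal`` going from index ``n1`` into ``n2``.

    Both arguments are (..., 2) arrays of (x, z) components.  Raises
    :class:`RefractionError` on total internal reflection rather than
    clamping, because for the scleral indices (1.00/1.38/1.41) TIR is
    impossible at physiologic surface slopes and indicates bad input.
    """
    d = np.asarray(d, dtype=float)
    n = np.asarray(normal, dtype=float)
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    # orient normals against the incident ray
    dot = np.sum(d * n, axis=-1, keepdims=True)
    n = np.where(dot > 0, -n, n)
    cos_i = -np.sum(d * n, axis=-1, keepdims=True)
    eta = n1 / n2
    sin_t_sq = eta**2 * (1.0 - cos_i**2)
    if np.any(sin_t_sq > 1.0):
        raise RefractionError(
            f"total internal reflection (n1={n1}, n2={n2}); check surface slopes"
        )
    cos_t = np.sqrt(1.0 - sin_t_sq)
    t = eta * d + (eta * cos_i - cos_t) * n
    return t / np.linalg.norm(t, axis=-1, keepdims=True)


def normal_from_slope(slope) -> np.ndarray:
    """Upward-pointing unit surface normal(s) for depth slope dz/dx."""
    slope = np.atleast_1d(np.asarray(slope, dtype=float))
    n = np.stack([slope, -np.ones_like(slope)], axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def line_polyline_intersections(
    p0: np.ndarray, d: np.ndarray, xs: np.ndarray, zs: np.ndarray
) -> np.ndarray:
    """Signed parameters ``t`` where the line ``p0 + t*d`` crosses the
    piecewise-linear curve (xs, zs).  Returns a sorted 1-D array (may be
    empty)."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(d, dtype=float)
    xs = np.asarray(xs, dtype=float)
    zs = np.asarray(zs, dtype=float)
    ex = np.diff(xs)
    ez = np.diff(zs)
    wx = xs[:-1] - p0[0]
    wz = zs[:-1] - p0[1]
    det = ex * d[1] - ez * d[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ex * wz - ez * wx) / det
        u = (d[0] * wz - d[1] * wx) / det
    ok = np.isfinite(t) & (u >= 0.0) & (u < 1.0)
    # include the very last vertex
    ok[-1] = np.isfinite(t[-1]) and (0.0 <= u[-1] <= 1.0)
    return np.sort(t[ok])


def cumulative_arc_length(xs: np.ndarray, zs: np.ndarray) -> np.ndarray:
    """Cumulative chord length along a polyline, starting at 0."""
    xs = np.asarray(xs, dtype=float)
    zs = np.asarray(zs, dtype=float)
    seg = np.hypot(np.diff(xs), np.diff(zs))
    return np.concatenate([[0.0], np.cumsum(seg)])
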