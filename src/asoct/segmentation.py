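"""Graph-based boundary segmentation.

Each boundary is found as the minimum-cost left-to-right path through a
node-per-pixel graph.  Edge weights favour strong vertical intensity
gradients of the requested polarity:

    w(a -> b) = 2 - (g_a + g_b) + eps,   eps = 1e-5

with ``g`` the polarity-signed vertical gradient normalized to [0, 1],
so low-cost paths ride along bright-to-dark or dark-to-bright edges.
Vertical moves are limited to +/- ``max_step`` rows per column, ties are
broken toward the smaller row index, and the winning row is refined to
sub-pixel precision by a parabolic fit of the gradient.  The search is
exact: the path graph is a DAG, so a column-by-column dynamic program
returns the global minimum-cost monotone path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter, minimum_filter1d, uniform_filter1d
from scipy.signal import savgol_filter

from .core import BoundaryTrace, BScanImage

EDGE_EPS = 1e-5


class SegmentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the boundary search protocol."""

    max_step: int = 2                      # rows per column
    smooth_sigma: Tuple[float, float] = (1.0, 4.0)   # (axial, lateral) px
    top_margin_px: int = 5                 # excluded from the ACB search
    acb_psb_min_sep_um: float = 100.0      # PSB searched below ACB + this
    band_dip_ratio: float = 0.75           # hypo-band depth criterion
    band_window_px: int = 30               # ASB search depth below band min
    band_max_bad_frac: float = 0.2         # tolerated columns without a band
    band_clearance_px: int = 8             # skip the ACB/PSB edge-blur tails
    # quadratic Savitzky-Golay polish of the final traces; boundaries
    # are anatomically smooth at the scan's lateral pitch, and slope
    # estimates for ray tracing need the per-column jitter removed
    trace_smooth_columns: int = 21         # 0 disables


def gate_quality(image: BScanImage, threshold_db: float = 25.0) -> bool:
    """Inclusion gate: strictly greater than the dB threshold."""
    if image.quality_index is None:
        raise ValueError("image has no recorded quality index")
    return image.quality_index > threshold_db


def _polarity_gradient(pixels: np.ndarray, polarity: str) -> np.ndarray:
    if polarity not in ("dark_to_light", "light_to_dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    grad = np.gradient(pixels, axis=0)
    if polarity == "light_to_dark":
        grad = -grad
    lo, hi = grad.min(), grad.max()
    if hi - lo <= 0:
        return np.zeros_like(grad)
    return (grad - lo) / (hi - lo)


def _normalize_roi(roi, n_cols: int, n_rows: int):
    """Accepts (lo, hi) scalars or (columns, lo, hi) arrays; returns
    (columns, lo, hi) arrays with inclusive row bounds."""
    if len(roi) == 2:
        columns = np.arange(n_cols)
        lo = np.full(n_cols, int(roi[0]))
        hi = np.full(n_cols, int(roi[1]))
    else:
        columns, lo, hi = (np.asarray(a) for a in roi)
        lo = np.round(lo).astype(int)
        hi = np.round(hi).astype(int)
    lo = np.clip(lo, 0, n_rows - 1)
    hi = np.clip(hi, 0, n_rows - 1)
    for c, l, h in zip(columns, lo, hi):
        if l > h:
            raise SegmentationError(f"empty ROI in column {int(c)}")
    return columns.astype(int), lo, hi


def minimum_cost_path(
    g: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_step: int = 2,
) -> np.ndarray:
    """Exact minimum-cost monotone path over gradient image ``g``.

    ``g`` is (rows, cols) normalized polarity gradient restricted to the
    traced columns; ``lo``/``hi`` are inclusive per-column row bounds.
    Returns integer row indices, ties resolved toward smaller rows.
    """
    n_rows, n_cols = g.shape
    size = 2 * max_step + 1
    cost = np.full((n_rows, n_cols), np.inf)
    cost[lo[0]: hi[0] + 1, 0] = 0.0
    for c in range(1, n_cols):
        a = cost[:, c - 1] - g[:, c - 1]
        win = minimum_filter1d(a, size=size, mode="constant", cval=np.inf)
        col = np.full(n_rows, np.inf)
        sl = slice(lo[c], hi[c] + 1)
        col[sl] = win[sl] + (2.0 + EDGE_EPS - g[sl, c])
        if not np.any(np.isfinite(col)):
            raise SegmentationError(f"path graph disconnected at column {c}")
        cost[:, c] = col

    path = np.empty(n_cols, dtype=int)
    path[-1] = int(np.argmin(cost[:, -1]))  # argmin -> smallest row on ties
    for c in range(n_cols - 1, 0, -1):
        r = path[c]
        r0 = max(r - max_step, 0)
        r1 = min(r + max_step, n_rows - 1)
        a = cost[r0: r1 + 1, c - 1] - g[r0: r1 + 1, c - 1]
        path[c - 1] = r0 + int(np.argmin(a))
    return path


def _subpixel_refine(g_col: np.ndarray, r: int) -> float:
    """Parabolic peak interpolation of the gradient across row r."""
    if r <= 0 or r >= g_col.size - 1:
        return float(r)
    denom = g_col[r - 1] - 2.0 * g_col[r] + g_col[r + 1]
    if denom >= 0:
        return float(r)
    delta = 0.5 * (g_col[r - 1] - g_col[r + 1]) / denom
    return float(r + np.clip(delta, -0.5, 0.5))


def segment_boundary(
    image: BScanImage,
    polarity: str,
    roi,
    max_step: int = 2,
    name: str = "ACB",
) -> BoundaryTrace:
    """Trace one boundary as the minimum-cost path through the scan.

    ``roi`` is either a (lo_row, hi_row) pair applied to all columns or
    a (columns, lo, hi) triple of per-column inclusive row bands.
    The returned trace is in image space (micrometres).
    """
    pixels = image.pixels
    columns, lo, hi = _normalize_roi(roi, pixels.shape[1], pixels.shape[0])
    g = _polarity_gradient(pixels, polarity)
    g_cols = g[:, columns]
    path = minimum_cost_path(g_cols, lo, hi, max_step=max_step)
    rows = np.array([
        _subpixel_refine(g_cols[:, j], r) for j, r in enumerate(path)
    ])
    return BoundaryTrace(
        name=name,
        space="image",
        x=columns * image.device.lateral_scale,
        depth=rows * image.device.axial_scale,
        provenance="auto",
    )


def detect_asb(
    image: BScanImage,
    acb: BoundaryTrace,
    psb: BoundaryTrace,
    params: SegmentationParams = SegmentationParams(),
) -> BoundaryTrace:
    """Locate the anterior scleral boundary: the posterior (deeper)
    dark-to-light edge of the hypo-reflective episcleral vessel band.

    Within each column's ACB-PSB band the band is found as the minimum
    of a smoothed intensity profile; the ASB is then traced by the
    minimum-cost path restricted to a window below that minimum, which
    keeps the trace on the outer sclera even when an extraocular-muscle
    wedge intrudes into the conjunctival compartment above the band.
    """
    dev = image.device
    if np.any(acb(acb.x) >= psb(acb.x)):
        raise ValueError("ACB must lie above the PSB everywhere")

    columns = np.round(acb.x / dev.lateral_scale).astype(int)
    r_acb = acb.depth / dev.axial_scale
    r_psb = psb(acb.x) / dev.axial_scale

    smoothed = gaussian_filter(image.pixels, sigma=params.smooth_sigma)
    m_rows = np.empty(columns.size)
    good = np.zeros(columns.size, dtype=bool)
    for j, c in enumerate(columns):
        top = int(np.ceil(r_acb[j])) + params.band_clearance_px
        bot = int(np.floor(r_psb[j])) - params.band_clearance_px
        if bot <= top:
            raise SegmentationError(f"empty ACB-PSB band in column {int(c)}")
        prof = smoothed[top:bot, c]
        m = int(np.argmin(prof))
        m_rows[j] = top + m
        good[j] = prof[m] < params.band_dip_ratio * np.median(prof)

    bad_frac = 1.0 - good.mean()
    if bad_frac > params.band_max_bad_frac:
        raise SegmentationError(
            f"no hypo-reflective band found in {100 * bad_frac:.0f}% of columns; "
            "manual ASB trace recommended"
        )
    if not good.all():
        m_rows[~good] = np.interp(columns[~good], columns[good], m_rows[good])
    m_rows = uniform_filter1d(m_rows, size=15, mode="nearest")

    lo = np.maximum(m_rows.astype(int), 0)
    hi = np.minimum(m_rows.astype(int) + params.band_window_px,
                    np.floor(r_psb).astype(int) - 2)
    trace = segment_boundary(
        image, "dark_to_light", (columns, lo, hi),
        max_step=params.max_step, name="ASB",
    )
    return trace


def apply_corrections(
    trace: BoundaryTrace,
    control_points: Sequence[Tuple[float, float]],
    blend_columns: int = 10,
) -> BoundaryTrace:
    """Manual correction: monotone-cubic interpolation through operator
    control points replaces the trace inside the corrected span, blended
    linearly over ``blend_columns`` columns at each end.

    Corrections are applied as depth *offsets* interpolated between the
    control points, so control points equal to the existing trace leave
    it unchanged.
    """
    pts = list(control_points)
    if not pts:
        return trace
    xs = np.array([p[0] for p in pts], dtype=float)
    zs = np.array([p[1] for p in pts], dtype=float)
    if np.unique(xs).size != xs.size:
        raise ValueError("duplicate x in control points")
    order = np.argsort(xs)
    xs, zs = xs[order], zs[order]
    if xs[0] < trace.x[0] - 1e-9 or xs[-1] > trace.x[-1] + 1e-9:
        raise ValueError("control points outside the traced extent")

    deltas = zs - trace(xs)
    if xs.size >= 2:
        delta_f = PchipInterpolator(xs, deltas)
    else:
        delta_f = lambda x: np.full(np.shape(x), deltas[0])

    spacing = float(np.median(np.diff(trace.x)))
    blend = blend_columns * spacing
    x = trace.x
    # weight: 1 inside the control span, linear ramp to 0 over the blend
    w = np.clip(np.minimum(x - (xs[0] - blend), (xs[-1] + blend) - x) / blend,
                0.0, 1.0) if blend > 0 else ((x >= xs[0]) & (x <= xs[-1])).astype(float)
    new_depth = trace.depth + w * np.asarray(delta_f(np.clip(x, xs[0], xs[-1])))
    return trace.with_depth(new_depth, provenance="auto+corrected")


def assert_boundary_order(traces: Dict[str, BoundaryTrace], tol_um: float = 1e-6):
    """ACB <= ASB <= PSB at every common lateral position."""
    x = traces["ASB"].x
    acb, asb, psb = traces["ACB"](x), traces["ASB"].depth, traces["PSB"](x)
    if np.any(acb > asb + tol_um) or np.any(asb > psb + tol_um):
        raise SegmentationError("boundary ordering ACB <= ASB <= PSB violated")


def segment_scan(
    image: BScanImage,
    params: SegmentationParams = SegmentationParams(),
    column_range: Optional[Tuple[int, int]] = None,
) -> Dict[str, BoundaryTrace]:
    """Full segmentation protocol for one scan.

    The ACB is the strongest dark-to-light path over the full depth
    (minus a small top margin), the PSB the strongest light-to-dark
    path strictly below the ACB, and the ASB follows from the
    hypo-reflective band between them.
    """
    dev = image.device

    def as_scan(pixels):
        return BScanImage(
            pixels=pixels, device=dev, meridian=image.meridian,
            quality_index=image.quality_index,
            spur_annotation=image.spur_annotation, scan_id=image.scan_id,
        )

    smoothed = as_scan(gaussian_filter(image.pixels, sigma=params.smooth_sigma))
    # ACB/PSB ride on log-intensity gradients: speckle is multiplicative,
    # so the log makes the noise additive and the air-tissue edge dominant
    log_scan = as_scan(gaussian_filter(
        np.log(np.maximum(image.pixels, 1e-4)), sigma=params.smooth_sigma))

    c0, c1 = column_range if column_range is not None else (0, dev.width_px)
    columns = np.arange(max(c0, 0), min(c1, dev.width_px))

    full = (columns,
            np.full(columns.size, params.top_margin_px),
            np.full(columns.size, dev.height_px - 2))
    acb = segment_boundary(log_scan, "dark_to_light", full,
                           max_step=params.max_step, name="ACB")

    sep_px = int(np.ceil(params.acb_psb_min_sep_um / dev.axial_scale))
    lo = np.round(acb.depth / dev.axial_scale).astype(int) + sep_px
    hi = np.full(columns.size, dev.height_px - 2)
    psb = segment_boundary(log_scan, "light_to_dark", (columns, lo, hi),
                           max_step=params.max_step, name="PSB")

    asb = detect_asb(smoothed, acb, psb, params=params)
    traces = {"ACB": acb, "ASB": asb, "PSB": psb}
    w = params.trace_smooth_columns
    if w and columns.size > w:
        traces = {
            name: t.with_depth(savgol_filter(t.depth, w, polyorder=2))
            for name, t in traces.items()
        }
    assert_boundary_order(traces, tol_um=2.0 * dev.axial_scale)
    return traces
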