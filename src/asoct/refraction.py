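"""Refractive-distortion correction of boundary traces.

The device exports scans scaled with a single uniform tissue index
(n = 1.40) and no correction for ray bending at tissue interfaces.
This module undoes that: image-space separations below the ACB are
first converted back to optical path length (x 1.40), then each A-scan
is re-propagated with Snell's law -- refracting at the ACB into
conjunctival tissue (n = 1.38) and at the ASB into scleral tissue
(n = 1.41) -- to give true geometric boundary positions.  The
uncorrected uniform-index mode (keep the device's 1.40 scaling, no
bending) is also provided for sensitivity re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .core import (
    BoundaryTrace,
    RefractionError,
    RefractiveModel,
    normal_from_slope,
    refract,
    smoothed_slope,
)

#: lateral grid pitch (um) of corrected traces; bent rays land at
#: irregular x, downstream arc math wants a uniform grid
RESAMPLE_GRID_UM = 10.0

SLOPE_WINDOW = 5


@dataclass
class CorrectedBoundarySet:
    """Physical-space ACB/ASB/PSB traces plus the correction mode."""

    acb: BoundaryTrace
    asb: BoundaryTrace
    psb: BoundaryTrace
    refractive_model: RefractiveModel
    mode: str  # "snell_corrected" | "uniform_1p40"
    # image-space lateral position of each source A-scan and where its
    # PSB intersection landed physically (for spur mapping)
    _img_x: Optional[np.ndarray] = field(default=None, repr=False)
    _psb_land_x: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("snell_corrected", "uniform_1p40"):
            raise ValueError(f"unknown mode {self.mode!r}")
        x = self.asb.x
        if np.any(self.acb(x) >= self.asb.depth) or np.any(
            self.asb.depth >= self.psb(x)
        ):
            raise RefractionError("corrected boundaries are not ordered ACB<ASB<PSB")

    def spur_physical(self, spur_img: Sequence[float]) -> np.ndarray:
        """Physical (x, depth) of an image-space spur annotation (um).

        The spur is carried through the correction by following the
        A-scan it was marked on to its corrected PSB intersection.
        """
        x_img = float(spur_img[0])
        if self.mode == "snell_corrected" and self._img_x is not None:
            x_phys = float(np.interp(x_img, self._img_x, self._psb_land_x))
        else:
            x_phys = x_img
        x_phys = float(np.clip(x_phys, self.psb.x[0], self.psb.x[-1]))
        return np.array([x_phys, float(self.psb(x_phys))])

    def traces(self) -> Dict[str, BoundaryTrace]:
        return {"ACB": self.acb, "ASB": self.asb, "PSB": self.psb}


def _require_space(traces: Dict[str, BoundaryTrace], space: str) -> None:
    for t in traces.values():
        if t.space != space:
            raise ValueError(f"expected {space}-space traces, got {t.space!r}")


def to_optical_path(
    traces: Dict[str, BoundaryTrace],
    model: RefractiveModel = RefractiveModel(),
) -> Dict[str, BoundaryTrace]:
    """Undo the device's uniform-index axial scaling.

    Below the ACB, optical path = image-space separation x n_device;
    the ACB itself is geometric (the beam above it travels in air).
    """
    _require_space(traces, "image")
    acb = traces["ACB"]
    out = {"ACB": acb.with_depth(acb.depth, space="optical")}
    for name in ("ASB", "PSB"):
        t = traces[name]
        depth = acb(t.x) + (t.depth - acb(t.x)) * model.n_device
        out[name] = t.with_depth(depth, space="optical")
    return out


def optical_to_image(
    traces: Dict[str, BoundaryTrace],
    model: RefractiveModel = RefractiveModel(),
) -> Dict[str, BoundaryTrace]:
    """Inverse of :func:`to_optical_path` (round-trips to ~1e-12)."""
    _require_space(traces, "optical")
    acb = traces["ACB"]
    out = {"ACB": acb.with_depth(acb.depth, space="image")}
    for name in ("ASB", "PSB"):
        t = traces[name]
        depth = acb(t.x) + (t.depth - acb(t.x)) / model.n_device
        out[name] = t.with_depth(depth, space="image")
    return out


def correct_refraction(
    traces: Dict[str, BoundaryTrace],
    model: RefractiveModel = RefractiveModel(),
    grid_um: float = RESAMPLE_GRID_UM,
) -> CorrectedBoundarySet:
    """Snell's-law ray trace of every A-scan back to physical space.

    Per column: the incident ray is vertical; at the ACB the local
    surface normal (5-column smoothed central differences of the trace)
    refracts it from air into conjunctiva, it propagates
    (optical segment)/n_conjunctiva to the ASB, refracts into sclera,
    and propagates (optical segment)/n_sclera to the PSB.  The
    resulting polylines are resampled onto a uniform lateral grid.
    """
    _require_space(traces, "optical")
    acb, asb, psb = traces["ACB"], traces["ASB"], traces["PSB"]
    x0 = acb.x
    acb_z = acb.depth
    if np.any(asb(x0) < acb_z) or np.any(psb(x0) < asb(x0)):
        raise RefractionError("input traces are not ordered ACB<=ASB<=PSB")

    d_in = np.tile([0.0, 1.0], (x0.size, 1))
    t1 = refract(d_in, normal_from_slope(acb.slope(SLOPE_WINDOW)),
                 model.n_air, model.n_conjunctiva)
    s1 = (asb(x0) - acb_z) / model.n_conjunctiva
    asb_x = x0 + s1 * t1[:, 0]
    asb_z = acb_z + s1 * t1[:, 1]
    _check_monotone(asb_x, "ASB")

    m_asb = smoothed_slope(asb_x, asb_z, window=SLOPE_WINDOW)
    t2 = refract(t1, normal_from_slope(m_asb), model.n_conjunctiva, model.n_sclera)
    s2 = (psb(x0) - asb(x0)) / model.n_sclera
    psb_x = asb_x + s2 * t2[:, 0]
    psb_z = asb_z + s2 * t2[:, 1]
    _check_monotone(psb_x, "PSB")

    x_lo = max(x0[0], asb_x[0], psb_x[0])
    x_hi = min(x0[-1], asb_x[-1], psb_x[-1])
    grid = np.arange(np.ceil(x_lo / grid_um) * grid_um, x_hi, grid_um)

    def trace(name, xs, zs):
        return BoundaryTrace(name=name, space="physical", x=grid,
                             depth=np.interp(grid, xs, zs),
                             provenance=traces[name].provenance)

    return CorrectedBoundarySet(
        acb=trace("ACB", x0, acb_z),
        asb=trace("ASB", asb_x, asb_z),
        psb=trace("PSB", psb_x, psb_z),
        refractive_model=model,
        mode="snell_corrected",
        _img_x=x0.copy(),
        _psb_land_x=psb_x,
    )


def _check_monotone(x: np.ndarray, name: str) -> None:
    bad = np.nonzero(np.diff(x) <= 0)[0]
    if bad.size:
        raise RefractionError(
            f"refracted rays cross (fold-over) at {name} near column {int(bad[0])}"
        )


def uniform_scale(
    traces: Dict[str, BoundaryTrace],
    n_uniform: float = 1.40,
    grid_um: float = RESAMPLE_GRID_UM,
) -> CorrectedBoundarySet:
    """Uncorrected mode: keep the device's uniform-index scaling.

    Depths below the ACB stay as exported (the device already scaled
    them at ``n_uniform``); no ray bending, lateral positions unchanged.
    """
    _require_space(traces, "image")
    acb = traces["ACB"]
    grid = np.arange(np.ceil(acb.x[0] / grid_um) * grid_um, acb.x[-1], grid_um)

    def trace(name):
        t = traces[name]
        return BoundaryTrace(name=name, space="physical", x=grid,
                             depth=np.interp(grid, t.x, t.depth),
                             provenance=t.provenance)

    model = RefractiveModel(n_conjunctiva=n_uniform, n_sclera=n_uniform,
                            n_device=n_uniform)
    return CorrectedBoundarySet(
        acb=trace("ACB"), asb=trace("ASB"), psb=trace("PSB"),
        refractive_model=model, mode="uniform_1p40",
    )
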