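"""Synthetic anterior-eye B-scan phantoms with exactly known geometry.

A phantom is an analytic cross-section of the limbal region: three
smooth boundaries (anterior conjunctival, anterior scleral and
posterior scleral -- ACB, ASB, PSB) over a 16 mm lateral extent, a
hypo-reflective episcleral vessel band whose posterior edge defines
the ASB, an optional extraocular-muscle (EOM) wedge inside the
conjunctival compartment, and an OCT forward model: per-A-scan Snell's
law refraction at the tissue interfaces followed by the device's
uniform-index (n = 1.40) axial scaling, piecewise-constant layer
reflectivities with resolution-limited edges, and frame-averaged
multiplicative speckle.

Because every boundary is analytic, the phantom provides exact ground
truth for segmentation, refraction correction and thickness profiling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.special import erf

from .core import (
    BoundaryTrace,
    BScanImage,
    DeviceModel,
    RefractionError,
    RefractiveModel,
    normal_from_slope,
    refract,
    smoothed_slope,
)
from .normative import LOCATIONS_UM, location_means, location_sds
from .profiling import MeasurementScheme, ThicknessProfile

LATERAL_EXTENT_UM = 16000.0

DEFAULT_REFLECTIVITIES = {
    "background": 0.03,
    "conjunctiva": 0.60,
    "band": 0.30,
    "sclera": 0.80,
    "deep": 0.30,
    "eom": 0.65,
}


@dataclass
class PhantomSpec:
    """Analytic ground truth for one synthetic scan.

    Boundary curves are monotone-cubic (PCHIP) interpolants through the
    stored knots; depth increases downward and the curves are
    single-valued in x.
    """

    seed: int
    meridian: str
    knots_x: np.ndarray
    acb_knots: np.ndarray
    asb_knots: np.ndarray
    psb_knots: np.ndarray
    spur_x: float
    refractive_model: RefractiveModel = field(default_factory=RefractiveModel)
    layer_reflectivities: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIVITIES)
    )
    band_thickness: float = 60.0
    eom: Optional[Tuple[float, float]] = None  # (insertion from spur um, thickness um)
    speckle_sigma: float = 1.0
    n_frame_averages: int = 50

    def __post_init__(self) -> None:
        self.knots_x = np.asarray(self.knots_x, dtype=float)
        self.acb_knots = np.asarray(self.acb_knots, dtype=float)
        self.asb_knots = np.asarray(self.asb_knots, dtype=float)
        self.psb_knots = np.asarray(self.psb_knots, dtype=float)
        if self.meridian not in ("nasal", "temporal"):
            raise ValueError(f"unknown meridian {self.meridian!r}")
        if not (0.0 <= self.spur_x <= LATERAL_EXTENT_UM):
            raise ValueError("spur_x outside the lateral extent")
        if not (np.all(self.acb_knots < self.asb_knots)
                and np.all(self.asb_knots < self.psb_knots)):
            raise ValueError("boundary ordering ACB < ASB < PSB violated")
        if np.any(self.psb_knots - self.asb_knots > 1500) or np.any(
            self.asb_knots - self.acb_knots > 1500
        ):
            raise ValueError("implied tissue thickness exceeds 1500 um")
        if self.band_thickness < 0:
            raise ValueError("band_thickness must be non-negative")
        self._build_curves()

    def _build_curves(self) -> None:
        self.acb_curve = PchipInterpolator(self.knots_x, self.acb_knots)
        self.asb_curve = PchipInterpolator(self.knots_x, self.asb_knots)
        self.psb_curve = PchipInterpolator(self.knots_x, self.psb_knots)

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        d = {
            "seed": int(self.seed),
            "meridian": self.meridian,
            "knots_x": self.knots_x.tolist(),
            "acb_knots": self.acb_knots.tolist(),
            "asb_knots": self.asb_knots.tolist(),
            "psb_knots": self.psb_knots.tolist(),
            "spur_x": self.spur_x,
            "refractive_model": {
                "n_air": self.refractive_model.n_air,
                "n_conjunctiva": self.refractive_model.n_conjunctiva,
                "n_sclera": self.refractive_model.n_sclera,
                "n_device": self.refractive_model.n_device,
            },
            "layer_reflectivities": self.layer_reflectivities,
            "band_thickness": self.band_thickness,
            "eom": list(self.eom) if self.eom is not None else None,
            "speckle_sigma": self.speckle_sigma,
            "n_frame_averages": self.n_frame_averages,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["refractive_model"] = RefractiveModel(**d["refractive_model"])
        if d["eom"] is not None:
            d["eom"] = tuple(d["eom"])
        return cls(**d)


def _sample_profile(rng: np.random.Generator, means: np.ndarray, sds: np.ndarray,
                    floor: float) -> np.ndarray:
    """Draw one eye's thickness values at the five arc locations.

    A shared eye-level deviation plus small per-location jitter keeps
    the characteristic profile shape while producing realistic
    between-eye spread; values are clipped to +/- 3 SD of each cell and
    to a positive floor.
    """
    z_eye = rng.normal(0.0, 0.8)
    jitter = rng.normal(0.0, 0.35, size=means.size)
    vals = means + z_eye * sds + jitter * sds
    vals = np.clip(vals, means - 3 * sds, means + 3 * sds)
    return np.maximum(vals, floor)


def make_phantom_spec(seed: int, meridian: str, overrides: Optional[dict] = None
                      ) -> PhantomSpec:
    """Randomized but deterministic phantom geometry for one eye.

    The posterior scleral boundary is a gently curved arc with a smooth
    random perturbation; conjunctival and scleral thickness are drawn
    within +/- 3 SD of the normative table at the five spur-referenced
    arc locations and interpolated monotonically between them, giving a
    scleral maximum near the spur and a conjunctival minimum at the
    spur as seen in vivo.
    """
    if meridian not in ("nasal", "temporal"):
        raise ValueError(f"unknown meridian {meridian!r}")
    overrides = dict(overrides or {})
    known = {f.name for f in dc_fields(PhantomSpec)}
    for key in overrides:
        if key not in known:
            raise ValueError(f"unknown PhantomSpec field in overrides: {key!r}")

    rng = np.random.default_rng([int(seed), 0 if meridian == "nasal" else 1])

    # posterior scleral boundary: shallow arc + smooth perturbation
    xc = 8000.0
    radius = rng.uniform(40000.0, 70000.0)
    d0 = rng.normal(1450.0, 60.0)
    coarse_x = np.linspace(0.0, LATERAL_EXTENT_UM, 9)
    coarse_v = rng.normal(0.0, 25.0, size=coarse_x.size)
    perturb = PchipInterpolator(coarse_x, coarse_v)

    def psb_formula(x):
        return d0 + (x - xc) ** 2 / (2.0 * radius) + perturb(x)

    grid = np.arange(0.0, LATERAL_EXTENT_UM + 1.0, 250.0)
    psb0 = PchipInterpolator(grid, psb_formula(grid))

    spur_x = rng.uniform(2200.0, 2800.0)

    # lateral positions of the five arc locations on the PSB
    xx = np.arange(spur_x, LATERAL_EXTENT_UM, 2.0)
    ds = np.hypot(1.0, psb0.derivative()(xx))
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(xx))])
    x_loc = np.interp(LOCATIONS_UM, s, xx)

    band = float(overrides.get("band_thickness", 60.0))
    scl = _sample_profile(rng, location_means("sclera", meridian),
                          location_sds("sclera", meridian), floor=150.0)
    conj = _sample_profile(rng, location_means("conjunctiva", meridian),
                           location_sds("conjunctiva", meridian),
                           floor=band + 60.0)
    # enforce the in-vivo profile shape: scleral max / conjunctival min at spur
    scl[1:] = np.minimum(scl[1:], scl[0] - 5.0)
    conj[1:] = np.maximum(conj[1:], conj[0] + 2.0)

    anchor_x = np.concatenate([[0.0], x_loc, [min(x_loc[-1] + 2000.0, 15000.0),
                                              LATERAL_EXTENT_UM]])
    t_curve = PchipInterpolator(anchor_x, np.concatenate([[scl[0]], scl,
                                                          [scl[-1], scl[-1]]]))
    c_curve = PchipInterpolator(anchor_x, np.concatenate([[conj[0]], conj,
                                                          [conj[-1], conj[-1]]]))

    knots = np.unique(np.concatenate([grid, anchor_x, [spur_x]]))
    psb_k = psb0(knots)
    asb_k = psb_k - t_curve(knots)
    acb_k = asb_k - c_curve(knots)

    base = dict(
        seed=int(seed),
        meridian=meridian,
        knots_x=knots,
        acb_knots=acb_k,
        asb_knots=asb_k,
        psb_knots=psb_k,
        spur_x=float(spur_x),
    )
    base.update(overrides)
    return PhantomSpec(**base)


# ---------------------------------------------------------------------
# geometry oracle
# ---------------------------------------------------------------------

def true_thickness_profile(
    spec: PhantomSpec,
    distances: Sequence[float] = LOCATIONS_UM,
    metric: str = "axial",
) -> ThicknessProfile:
    """Ground-truth thickness at spur-referenced arc locations, computed
    directly from the analytic curves by dense arc-length integration.

    ``metric='axial'`` is the vertical ACB->ASB / ASB->PSB distance at
    each location; ``metric='normal'`` casts the local normal of the ASB
    through the tissue.
    """
    scheme = MeasurementScheme(distances_um=tuple(distances), metric=metric)
    xx = np.arange(spec.spur_x, LATERAL_EXTENT_UM, 1.0)
    dpsb = spec.psb_curve.derivative()(xx)
    ds = np.hypot(1.0, dpsb)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(xx))])
    d = np.asarray(distances, dtype=float)
    if d[-1] > s[-1]:
        raise ValueError(
            f"distance {d[-1]:.0f} um beyond available arc (max {s[-1]:.0f} um)"
        )
    x_loc = np.interp(d, s, xx)

    if metric == "axial":
        conj = spec.asb_curve(x_loc) - spec.acb_curve(x_loc)
        scl = spec.psb_curve(x_loc) - spec.asb_curve(x_loc)
    elif metric == "normal":
        conj = np.empty_like(x_loc)
        scl = np.empty_like(x_loc)
        dasb = spec.asb_curve.derivative()
        for i, x_p in enumerate(x_loc):
            m = float(dasb(x_p))
            nx, nz = -m / np.hypot(m, 1.0), 1.0 / np.hypot(m, 1.0)
            z_a = float(spec.asb_curve(x_p))

            def g(t, curve):
                return (z_a + t * nz) - curve(x_p + t * nx)

            scl[i] = brentq(g, 0.0, 2000.0, args=(spec.psb_curve,), xtol=1e-8)
            conj[i] = -brentq(g, -2000.0, 0.0, args=(spec.acb_curve,), xtol=1e-8)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    return ThicknessProfile(
        eye_id=f"phantom-{spec.seed}",
        meridian=spec.meridian,
        scheme=scheme,
        conjunctival_um=conj,
        scleral_um=scl,
    )


# ---------------------------------------------------------------------
# OCT forward model
# ---------------------------------------------------------------------

def _ray_to_curve(x0, z0, t_dir, curve):
    """Distance along rays (x0,z0) + s*t_dir to the single-valued curve
    depth(x), solved by fixed-point iteration (the curves' slopes are
    small, so the iteration contracts rapidly)."""
    s = (curve(x0) - z0) / t_dir[:, 1]
    for _ in range(12):
        x_hit = x0 + s * t_dir[:, 0]
        s_new = (curve(x_hit) - z0) / t_dir[:, 1]
        if np.max(np.abs(s_new - s)) < 1e-10:
            s = s_new
            break
        s = s_new
    if np.any(s < 0):
        raise RefractionError("ray-curve intersection behind the ray origin")
    return s


def _forward_all(spec: PhantomSpec, device: DeviceModel, columns=None):
    """Image-space depths (um) of every rendered interface per column.

    Returns (x0_um, dict of image-space depth arrays) with keys
    ACB, eom_top, band_top, ASB, PSB.
    """
    model = spec.refractive_model
    if columns is None:
        columns = np.arange(device.width_px)
    x0 = np.asarray(columns, dtype=float) * device.lateral_scale

    acb_z = spec.acb_curve(x0)
    # surface normals use the same 5-column smoothed discrete slope
    # estimator as the correction, so the forward model and its inverse
    # share one normal convention
    m_acb = smoothed_slope(x0, acb_z)
    d_in = np.tile([0.0, 1.0], (x0.size, 1))
    t1 = refract(d_in, normal_from_slope(m_acb), model.n_air, model.n_conjunctiva)

    # conjunctival-compartment interfaces crossed by the refracted ray
    band_top_curve = lambda x: spec.asb_curve(x) - spec.band_thickness
    s_asb = _ray_to_curve(x0, acb_z, t1, spec.asb_curve)
    s_band = _ray_to_curve(x0, acb_z, t1, band_top_curve) \
        if spec.band_thickness > 0 else s_asb
    if spec.eom is not None:
        eom_top_curve = lambda x: band_top_curve(x) - _eom_width(spec, x)
        s_eom = _ray_to_curve(x0, acb_z, t1, eom_top_curve)
    else:
        s_eom = s_band

    x_asb = x0 + s_asb * t1[:, 0]
    z_asb = acb_z + s_asb * t1[:, 1]
    m_asb = smoothed_slope(x_asb, z_asb)
    t2 = refract(t1, normal_from_slope(m_asb), model.n_conjunctiva, model.n_sclera)
    s_psb = _ray_to_curve(x_asb, z_asb, t2, spec.psb_curve)

    opl_eom = model.n_conjunctiva * s_eom
    opl_band = model.n_conjunctiva * s_band
    opl_asb = model.n_conjunctiva * s_asb
    opl_psb = opl_asb + model.n_sclera * s_psb

    nd = model.n_device
    depths = {
        "ACB": acb_z,
        "eom_top": acb_z + opl_eom / nd,
        "band_top": acb_z + opl_band / nd,
        "ASB": acb_z + opl_asb / nd,
        "PSB": acb_z + opl_psb / nd,
    }
    return x0, depths


def _eom_width(spec: PhantomSpec, x) -> np.ndarray:
    """Axial width (um) of the EOM wedge at lateral position x.

    The wedge ramps in from its insertion point and is capped so it
    always fits inside the conjunctival compartment above the band."""
    insertion, thickness = spec.eom
    ramp = 1500.0
    w = thickness * np.clip((np.asarray(x, float) - (spec.spur_x + insertion)) / ramp,
                            0.0, 1.0)
    conj = spec.asb_curve(x) - spec.acb_curve(x)
    return np.minimum(w, np.maximum(conj - spec.band_thickness - 40.0, 0.0))


def forward_distort(spec: PhantomSpec, device: DeviceModel,
                    columns=None) -> Dict[str, BoundaryTrace]:
    """Exact image-space boundary positions under the OCT forward model.

    Per A-scan column the ACB appears at its geometric depth; deeper
    boundaries appear at (cumulative optical path along the refracted
    ray) / n_device below it, i.e. the renderer's truth.
    """
    x0, depths = _forward_all(spec, device, columns=columns)
    return {
        name: BoundaryTrace(name=name, space="image", x=x0, depth=depths[name],
                            provenance="manual")
        for name in ("ACB", "ASB", "PSB")
    }


def render_bscan(
    spec: PhantomSpec,
    device: DeviceModel = DeviceModel(),
    noise_seed: Optional[int] = None,
) -> Tuple[BScanImage, Dict[str, BoundaryTrace]]:
    """Render the phantom to a B-scan plus its image-space ground truth.

    Layers are piecewise-constant in reflectivity with edges smoothed
    at the axial resolution; multiplicative speckle with per-frame
    scale ``speckle_sigma`` is averaged over ``n_frame_averages``
    frames (drawn exactly as a gamma variate).  The reported quality
    index is the scleral signal power over the background noise
    variance, in dB.
    """
    if device.width_px <= 0 or device.height_px <= 0:
        raise ValueError("image dimensions must be positive")
    refl = spec.layer_reflectivities
    x0, depths = _forward_all(spec, device)

    row_depth = (np.arange(device.height_px, dtype=float) * device.axial_scale)[:, None]
    sigma_um = device.axial_resolution / 2.0

    def step(boundary_um):
        return 0.5 * (1.0 + erf((row_depth - boundary_um[None, :])
                                / (np.sqrt(2.0) * sigma_um)))

    stack = [
        ("ACB", refl["conjunctiva"] - refl["background"]),
        ("eom_top", refl["eom"] - refl["conjunctiva"]),
        ("band_top", refl["band"] - refl["eom"]),
        ("ASB", refl["sclera"] - refl["band"]),
        ("PSB", refl["deep"] - refl["sclera"]),
    ]
    if spec.eom is None:
        # zero-width EOM layer: telescope conjunctiva -> band directly
        stack[1] = ("eom_top", 0.0)
        stack[2] = ("band_top", refl["band"] - refl["conjunctiva"])
    img = np.full((device.height_px, device.width_px), refl["background"])
    for name, dv in stack:
        if dv != 0.0:
            img += dv * step(depths[name])

    if spec.speckle_sigma > 0:
        shape = spec.n_frame_averages / spec.speckle_sigma**2
        rng = np.random.default_rng(
            [int(spec.seed if noise_seed is None else noise_seed), 7]
        )
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)

    white = 45000.0
    u16 = np.clip(np.round(img * white), 0, 65535).astype(np.uint16)
    pixels = u16.astype(float) / white

    qi = _quality_index(pixels, depths, device)
    spur_col = spec.spur_x / device.lateral_scale
    spur_row = np.interp(spec.spur_x, x0, depths["PSB"]) / device.axial_scale
    image = BScanImage(
        pixels=pixels,
        device=device,
        meridian=spec.meridian,
        quality_index=qi,
        spur_annotation=(float(spur_col), float(spur_row)),
        scan_id=f"phantom-{spec.seed}-{spec.meridian}",
    )
    truth = {
        name: BoundaryTrace(name=name, space="image", x=x0, depth=depths[name],
                            provenance="manual")
        for name in ("ACB", "ASB", "PSB")
    }
    return image, truth


def _quality_index(pixels: np.ndarray, depths: Dict[str, np.ndarray],
                   device: DeviceModel) -> float:
    """Signal-to-noise quality index in dB: mean scleral signal power
    over background intensity variance, capped at 99 dB."""
    row_depth = np.arange(pixels.shape[0], dtype=float)[:, None] * device.axial_scale
    scleral = (row_depth > depths["ASB"][None, :] + 20.0) & (
        row_depth < depths["PSB"][None, :] - 20.0
    )
    background = row_depth < depths["ACB"][None, :] - 40.0
    if not scleral.any() or not background.any():
        return 0.0
    signal_power = float(np.mean(pixels[scleral] ** 2))
    noise_var = float(np.var(pixels[background]))
    if noise_var <= 0:
        return 99.0
    return float(min(10.0 * np.log10(signal_power / noise_var), 99.0))
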