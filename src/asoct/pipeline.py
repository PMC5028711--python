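"""End-to-end orchestration.

One run takes a cohort of scans -- synthetic phantoms or exported
TIFF/PNG images with JSON metadata sidecars -- through quality gating,
boundary segmentation (with optional manual corrections), refraction
correction in one or both modes, spur-referenced thickness profiling,
repeat averaging and cohort statistics, writing tidy CSV tables and a
run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .core import BoundaryTrace, BScanImage, DeviceModel, RefractiveModel
from .phantom import PhantomSpec, make_phantom_spec, render_bscan
from .profiling import (
    MeasurementScheme,
    ThicknessProfile,
    average_repeats,
    profile_from_boundaries,
)
from .refraction import correct_refraction, to_optical_path, uniform_scale
from .segmentation import (
    SegmentationParams,
    apply_corrections,
    gate_quality,
    segment_scan,
)
from .stats import repeatability_report, summarize_cohort

log = logging.getLogger("asoct")

CSV_FLOAT_FORMAT = "%.6f"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input source)."""

    seed: int = 0
    n_eyes: int = 5
    n_repeats: int = 2
    meridians: Tuple[str, ...] = ("nasal", "temporal")
    image_dir: Optional[str] = None          # alternative input source
    device: DeviceModel = field(default_factory=DeviceModel)
    refractive_model: RefractiveModel = field(default_factory=RefractiveModel)
    scheme: MeasurementScheme = field(default_factory=MeasurementScheme)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    modes: Tuple[str, ...] = ("snell_corrected",)
    quality_threshold_db: float = 25.0
    out_dir: Optional[str] = None
    # manual corrections: scan_id -> [{"boundary": ..., "points": [[x_um, z_um], ...]}]
    corrections: Dict[str, list] = field(default_factory=dict)
    max_failure_fraction: float = 0.5
    lateral_margin_um: Tuple[float, float] = (500.0, 4800.0)

    def __post_init__(self) -> None:
        if self.image_dir is not None and self.n_eyes:
            # image_dir wins; n_eyes only drives the phantom source
            pass
        if not self.modes:
            raise ValueError("at least one correction mode is required")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_jsonable(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


# ---------------------------------------------------------------------
# scan I/O: 16-bit TIFF + JSON sidecar
# ---------------------------------------------------------------------

WHITE_LEVEL = 45000.0


def save_scan(image: BScanImage, path: str) -> None:
    """Write a scan as 16-bit grayscale TIFF plus a JSON sidecar."""
    p = Path(path)
    u16 = np.clip(np.round(image.pixels * WHITE_LEVEL), 0, 65535).astype(np.uint16)
    tifffile.imwrite(p, u16)
    sidecar = {
        "meridian": image.meridian,
        "lateral_scale_um_px": image.device.lateral_scale,
        "axial_scale_um_px": image.device.axial_scale,
        "quality_index_db": image.quality_index,
        "spur_col_px": None if image.spur_annotation is None
        else image.spur_annotation[0],
        "spur_row_px": None if image.spur_annotation is None
        else image.spur_annotation[1],
        "scan_id": image.scan_id,
    }
    p.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_scan(path: str) -> BScanImage:
    """Load a TIFF scan with its JSON metadata sidecar."""
    p = Path(path)
    u16 = tifffile.imread(p)
    meta = json.loads(p.with_suffix(".json").read_text())
    device = DeviceModel(
        width_px=u16.shape[1], height_px=u16.shape[0],
        lateral_scale=meta["lateral_scale_um_px"],
        axial_scale=meta["axial_scale_um_px"],
    )
    spur = None
    if meta.get("spur_col_px") is not None:
        spur = (meta["spur_col_px"], meta["spur_row_px"])
    return BScanImage(
        pixels=u16.astype(float) / WHITE_LEVEL,
        device=device,
        meridian=meta["meridian"],
        quality_index=meta.get("quality_index_db"),
        spur_annotation=spur,
        scan_id=meta.get("scan_id", p.stem),
    )


def write_boundary_csv(traces: Dict[str, BoundaryTrace], path: str,
                       device: DeviceModel) -> None:
    rows = []
    for name, t in traces.items():
        if t.space == "image":
            col = t.x / device.lateral_scale
            depth = t.depth / device.axial_scale
        else:
            col, depth = t.x, t.depth
        for c, d in zip(col, depth):
            rows.append((name, t.space, c, d))
    df = pd.DataFrame(rows, columns=["boundary", "space", "column_px", "depth"])
    prov = ";".join(f"{n}={t.provenance}" for n, t in traces.items())
    with open(path, "w") as fh:
        fh.write(f"# provenance: {prov}\n")
        df.to_csv(fh, index=False, float_format=CSV_FLOAT_FORMAT)


# ---------------------------------------------------------------------
# single-scan analysis
# ---------------------------------------------------------------------

def analyze_scan(
    image: BScanImage,
    config: RunConfig,
    eye_id: str,
    corrections: Optional[list] = None,
) -> Dict[str, ThicknessProfile]:
    """Quality gate -> segmentation -> correction mode(s) -> profile."""
    if not gate_quality(image, config.quality_threshold_db):
        raise RuntimeError(
            f"quality gate failed: QI={image.quality_index:.1f} dB "
            f"<= {config.quality_threshold_db} dB"
        )
    if image.spur_annotation is None:
        raise RuntimeError("scan has no scleral spur annotation")

    dev = image.device
    spur_col = image.spur_annotation[0]
    back, fwd = config.lateral_margin_um
    c0 = int(max(0, spur_col - back / dev.lateral_scale))
    c1 = int(min(dev.width_px, spur_col + fwd / dev.lateral_scale))
    traces = segment_scan(image, params=config.segmentation, column_range=(c0, c1))

    for corr in corrections or []:
        b = corr["boundary"]
        traces[b] = apply_corrections(traces[b], corr["points"])

    spur_img = (image.spur_annotation[0] * dev.lateral_scale,
                image.spur_annotation[1] * dev.axial_scale)

    profiles: Dict[str, ThicknessProfile] = {}
    for mode in config.modes:
        if mode == "snell_corrected":
            cset = correct_refraction(to_optical_path(traces, config.refractive_model),
                                      config.refractive_model)
            scheme = config.scheme
        elif mode == "uniform_1p40":
            cset = uniform_scale(traces, config.refractive_model.n_device)
            # the uncorrected re-analysis also uses straight-line locations
            scheme = MeasurementScheme(
                distances_um=config.scheme.distances_um,
                location_mode="straight_line",
                metric=config.scheme.metric,
                normal_reference=config.scheme.normal_reference,
            )
        else:
            raise ValueError(f"unknown correction mode {mode!r}")
        spur_phys = cset.spur_physical(spur_img)
        profiles[mode] = profile_from_boundaries(
            cset.acb, cset.asb, cset.psb, spur_phys, scheme,
            eye_id=eye_id, meridian=image.meridian,
        )
    return profiles


# ---------------------------------------------------------------------
# cohort runs
# ---------------------------------------------------------------------

def cohort_specs(config: RunConfig) -> List[Tuple[str, int, PhantomSpec]]:
    """(eye_id, repeat, spec) for every phantom scan of the run.

    Repeats of one eye share geometry (one spec) and differ only in the
    speckle noise realisation, like re-imaging the same eye."""
    out = []
    for i in range(config.n_eyes):
        for meridian in config.meridians:
            spec = make_phantom_spec(config.seed * 1000 + i, meridian)
            for r in range(1, config.n_repeats + 1):
                out.append((f"eye{i:03d}", r, spec))
    return out


@dataclass
class PipelineResult:
    per_scan: pd.DataFrame        # eye, meridian, repeat, mode, tissue, location
    averaged: pd.DataFrame        # repeats averaged
    summary: pd.DataFrame         # cohort mean +/- SD grid (primary mode)
    repeatability: Optional[pd.DataFrame]
    failures: List[str]
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis for a phantom cohort or an image directory."""
    out_dir = _prepare_out_dir(config)

    scans: List[Tuple[str, int, BScanImage]] = []
    if config.image_dir is not None:
        paths = sorted(Path(config.image_dir).glob("*.tif*"))
        for k, p in enumerate(paths):
            img = load_scan(p)
            eye_id = img.scan_id.rsplit("-rep", 1)[0] or f"scan{k:03d}"
            rep = int(img.scan_id.rsplit("-rep", 1)[1]) if "-rep" in img.scan_id else 1
            scans.append((eye_id, rep, img))
    else:
        for eye_id, rep, spec in cohort_specs(config):
            img, _ = render_bscan(spec, config.device,
                                  noise_seed=spec.seed * 10 + rep)
            img.scan_id = f"{eye_id}-{spec.meridian}-rep{rep}"
            scans.append((eye_id, rep, img))

    records = []
    failures: List[str] = []
    profile_index: Dict[tuple, ThicknessProfile] = {}
    for eye_id, rep, img in scans:
        try:
            profs = analyze_scan(img, config, eye_id,
                                 corrections=config.corrections.get(img.scan_id))
            for mode, prof in profs.items():
                profile_index[(eye_id, img.meridian, rep, mode)] = prof
                for loc, c_um, s_um in zip(prof.scheme.distances_um,
                                           prof.conjunctival_um, prof.scleral_um):
                    records.append((eye_id, img.meridian, rep, mode,
                                    loc / 1000.0, c_um, s_um, img.scan_id))
            log.info("scan=%s stage=analyze outcome=ok", img.scan_id)
        except Exception as exc:  # per-scan failures are logged, never dropped
            failures.append(f"{img.scan_id}: {exc}")
            log.warning("scan=%s stage=analyze outcome=fail reason=%s",
                        img.scan_id, exc)

    if scans and len(failures) / len(scans) > config.max_failure_fraction:
        raise RuntimeError(
            f"{len(failures)}/{len(scans)} scans failed: " + "; ".join(failures)
        )

    per_scan = pd.DataFrame(
        records, columns=["eye_id", "meridian", "repeat", "mode", "location_mm",
                          "conjunctiva_um", "sclera_um", "scan_id"],
    )

    # average repeats per eye/meridian/mode
    averaged_profiles: Dict[str, List[ThicknessProfile]] = {}
    for mode in config.modes:
        group: Dict[tuple, List[ThicknessProfile]] = {}
        for (eye_id, meridian, rep, m), prof in profile_index.items():
            if m == mode:
                group.setdefault((eye_id, meridian), []).append(prof)
        averaged_profiles[mode] = [average_repeats(v) for v in group.values()]

    avg_records = []
    for mode, plist in averaged_profiles.items():
        for prof in plist:
            for loc, c_um, s_um in zip(prof.scheme.distances_um,
                                       prof.conjunctival_um, prof.scleral_um):
                avg_records.append((prof.eye_id, prof.meridian, mode,
                                    loc / 1000.0, c_um, s_um,
                                    prof.n_repeats_averaged))
    averaged = pd.DataFrame(
        avg_records, columns=["eye_id", "meridian", "mode", "location_mm",
                              "conjunctiva_um", "sclera_um", "n_repeats"],
    ).sort_values(["mode", "eye_id", "meridian", "location_mm"],
                  kind="stable", ignore_index=True)

    primary = config.modes[0]
    summary = summarize_cohort(averaged_profiles[primary]).cells

    repeat_df = None
    n_distinct_eyes = per_scan["eye_id"].nunique() if not per_scan.empty else 0
    # ICC needs >= 3 subjects per cell
    if config.n_repeats >= 2 and n_distinct_eyes >= 3:
        r1, r2 = [], []
        for (eye_id, meridian, rep, m), prof in sorted(
                profile_index.items(), key=lambda kv: kv[0][:2]):
            if m != primary:
                continue
            (r1 if rep == 1 else r2).append(prof)
        if r1 and len(r1) == len(r2):
            repeat_df = repeatability_report(r1, r2)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "config_hash": config.config_hash(),
        "n_scans": len(scans),
        "n_failed": len(failures),
        "failures": failures,
        "scan_ids": [img.scan_id for _, _, img in scans],
    }

    result = PipelineResult(per_scan=per_scan, averaged=averaged, summary=summary,
                            repeatability=repeat_df, failures=failures,
                            manifest=manifest)
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _prepare_out_dir(config: RunConfig) -> Optional[Path]:
    if config.out_dir is None:
        return None
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != config.config_hash():
            raise RuntimeError(
                f"output directory {out} holds a different run "
                f"({old.get('config_hash')}); refusing to mix runs"
            )
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_outputs(result: PipelineResult, out: Path) -> None:
    result.per_scan.to_csv(out / "per_scan_profiles.csv", index=False,
                           float_format=CSV_FLOAT_FORMAT)
    result.averaged.to_csv(out / "averaged_profiles.csv", index=False,
                           float_format=CSV_FLOAT_FORMAT)
    result.summary.to_csv(out / "cohort_summary.csv", index=False,
                          float_format=CSV_FLOAT_FORMAT)
    if result.repeatability is not None:
        result.repeatability.to_csv(out / "repeatability.csv", index=False,
                                    float_format=CSV_FLOAT_FORMAT)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def compare_modes(result: PipelineResult,
                  mode_a: str = "snell_corrected",
                  mode_b: str = "uniform_1p40") -> pd.DataFrame:
    """Per-eye, per-location, per-tissue differences mode_a - mode_b,
    plus cohort mean +/- SD and percentage error relative to mode_a."""
    df = result.averaged
    for m in (mode_a, mode_b):
        if m not in set(df["mode"]):
            raise ValueError(f"mode {m!r} missing from the run")
    idx = ["eye_id", "meridian", "location_mm"]
    a = df[df["mode"] == mode_a].set_index(idx)
    b = df[df["mode"] == mode_b].set_index(idx)
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("modes cover different eyes/locations")
    b = b.reindex(a.index)
    out = pd.DataFrame(index=a.index)
    for tissue in ("conjunctiva", "sclera"):
        col = f"{tissue}_um"
        out[f"{tissue}_diff_um"] = a[col] - b[col]
        out[f"{tissue}_pct"] = 100.0 * (a[col] - b[col]) / a[col]
    return out.reset_index()
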