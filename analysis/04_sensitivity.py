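#!/usr/bin/env python
"""Sensitivity of thickness to the analysis choices.

Two re-analyses of the simulated cohort, mirroring the study's own
robustness checks:

* correction mode -- Snell-corrected vs the device's uniform-index
  (n = 1.40) output with straight-line measurement locations; reported
  as per-eye differences and cohort mean +/- SD and percent.
* thickness metric -- axial (vertical) vs along the ASB normal,
  compared on the analytic cohort geometry.
"""

import sys
from pathlib import Path

import pandas as pd

from asoct.phantom import make_phantom_spec, true_thickness_profile
from asoct.pipeline import PipelineResult, compare_modes

SEED = 1
N_EYES = 10
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    avg_path = OUT / "02_run" / "averaged_profiles.csv"
    if not avg_path.exists():
        print("run analysis/02_recover_thickness.py first", file=sys.stderr)
        return 1
    averaged = pd.read_csv(avg_path)
    result = PipelineResult(per_scan=pd.DataFrame(), averaged=averaged,
                            summary=pd.DataFrame(), repeatability=None,
                            failures=[], manifest={})
    diff = compare_modes(result)
    diff.to_csv(OUT / "04_mode_differences.csv", index=False,
                float_format="%.4f")
    print("corrected - uncorrected (cohort mean +/- SD):")
    for tissue in ("sclera", "conjunctiva"):
        d = diff[f"{tissue}_diff_um"]
        p = diff[f"{tissue}_pct"]
        print(f"  {tissue}: {d.mean():+.1f} +/- {d.std():.1f} um "
              f"({p.mean():+.2f}%)")

    rows = []
    for i in range(N_EYES):
        for meridian in ("nasal", "temporal"):
            spec = make_phantom_spec(SEED * 1000 + i, meridian)
            ax = true_thickness_profile(spec, metric="axial")
            nm = true_thickness_profile(spec, metric="normal")
            for loc, a_s, n_s, a_c, n_c in zip(
                    ax.scheme.distances_um, ax.scleral_um, nm.scleral_um,
                    ax.conjunctival_um, nm.conjunctival_um):
                rows.append((f"eye{i:03d}", meridian, loc / 1000.0,
                             a_s - n_s, a_c - n_c))
    metric = pd.DataFrame(rows, columns=["eye_id", "meridian", "location_mm",
                                         "sclera_axial_minus_normal_um",
                                         "conjunctiva_axial_minus_normal_um"])
    metric.to_csv(OUT / "04_metric_differences.csv", index=False,
                  float_format="%.4f")
    print("axial - normal metric (cohort mean +/- SD):")
    for col, tissue in (("sclera_axial_minus_normal_um", "sclera"),
                        ("conjunctiva_axial_minus_normal_um", "conjunctiva")):
        print(f"  {tissue}: {metric[col].mean():+.2f} +/- "
              f"{metric[col].std():.2f} um")
    print(f"wrote {OUT / '04_mode_differences.csv'} and "
          f"{OUT / '04_metric_differences.csv'}")


if __name__ == "__main__":
    sys.exit(main())
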