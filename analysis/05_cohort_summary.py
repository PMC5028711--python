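#!/usr/bin/env python
"""Cohort summary table.

Builds the mean +/- SD thickness grid (tissue x meridian x location)
from the recovered cohort profiles of 02, with the per-meridian mean
as the unweighted mean of the five location cells, and checks that the
same arithmetic applied to the published normative location means
reproduces the published whole-meridian averages (506/504 um sclera,
270/249 um conjunctiva, nasal/temporal).
"""

import sys
from pathlib import Path

import pandas as pd

from asoct.normative import location_means
from asoct.profiling import MeasurementScheme, ThicknessProfile
from asoct.stats import summarize_cohort

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    summary_path = OUT / "02_run" / "cohort_summary.csv"
    if not summary_path.exists():
        print("run analysis/02_recover_thickness.py first", file=sys.stderr)
        return 1
    cells = pd.read_csv(summary_path)
    wide = cells.pivot_table(index=["tissue", "meridian"],
                             columns="location_mm", values="mean_um")
    wide.columns = [f"loc_{c:g}mm_um" for c in wide.columns]
    wide["meridian_mean_um"] = wide.mean(axis=1)
    wide.round(1).to_csv(OUT / "05_summary_grid.csv", float_format="%.1f")
    print("simulated-cohort thickness grid (um):")
    print(wide.round(0).to_string())

    profiles = [
        ThicknessProfile(
            eye_id="published-mean", meridian=m, scheme=MeasurementScheme(),
            conjunctival_um=location_means("conjunctiva", m),
            scleral_um=location_means("sclera", m))
        for m in ("nasal", "temporal")
    ]
    mm = summarize_cohort(profiles).meridian_means()
    print("\npublished normative location means -> meridian means (um):")
    print(mm.assign(rounded=mm["meridian_mean_um"].round().astype(int))
          .to_string(index=False))
    print(f"wrote {OUT / '05_summary_grid.csv'}")


if __name__ == "__main__":
    sys.exit(main())
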