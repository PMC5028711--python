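#!/usr/bin/env python
"""Repeatability of the thickness measures.

Two parts, mirroring how test-retest agreement is reported for this
kind of imaging study: (a) ICC(2,1), mean repeat difference and SD of
differences per tissue/meridian/location from the cohort's two
repeated scans (read from the 02 run); (b) a ten-repeat experiment on
a single eye -- ten noise realisations of one phantom pushed through
the full pipeline -- summarised as ICC and pooled within-subject SD.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from asoct.core import DeviceModel
from asoct.phantom import make_phantom_spec, render_bscan
from asoct.pipeline import RunConfig, analyze_scan
from asoct.stats import icc_agreement, within_subject_sd

SEED = 1
N_TEN_REPEATS = 10
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    rep_path = OUT / "02_run" / "repeatability.csv"
    if not rep_path.exists():
        print("run analysis/02_recover_thickness.py first", file=sys.stderr)
        return 1
    rep = pd.read_csv(rep_path)
    print("two-repeat cohort repeatability (per location):")
    print(f"  ICC range {rep['icc'].min():.3f} to {rep['icc'].max():.3f}")
    print(f"  |mean repeat difference| <= {rep['mean_diff_um'].abs().max():.1f} um")
    print(f"  SD of differences {rep['sd_diff_um'].min():.1f}"
          f" to {rep['sd_diff_um'].max():.1f} um")

    # ten-repeat single-subject experiment
    spec = make_phantom_spec(SEED * 1000 + 900, "temporal")
    config = RunConfig(seed=SEED)
    device = DeviceModel()
    conj, scl = [], []
    for k in range(N_TEN_REPEATS):
        image, _ = render_bscan(spec, device, noise_seed=SEED * 100 + k)
        prof = analyze_scan(image, config, "single-eye")["snell_corrected"]
        conj.append(prof.conjunctival_um)
        scl.append(prof.scleral_um)
    conj, scl = np.array(conj), np.array(scl)
    rows = []
    for tissue, mat in (("conjunctiva", conj), ("sclera", scl)):
        wssd = within_subject_sd(mat)
        icc = icc_agreement(mat.T)   # locations as subjects, repeats as raters
        rows.append((tissue, N_TEN_REPEATS, wssd, icc))
        print(f"ten-repeat {tissue}: within-subject SD {wssd:.2f} um, "
              f"ICC {icc:.3f}")
    pd.DataFrame(rows, columns=["tissue", "n_repeats", "within_subject_sd_um",
                                "icc"]
                 ).to_csv(OUT / "03_ten_repeat_repeatability.csv", index=False,
                          float_format="%.4f")
    print(f"wrote {OUT / '03_ten_repeat_repeatability.csv'}")


if __name__ == "__main__":
    sys.exit(main())
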