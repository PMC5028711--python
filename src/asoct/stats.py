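"""Repeatability and cohort-summary statistics.

Test-retest agreement uses the two-way random-effects, absolute-
agreement, single-measure intraclass correlation ICC(2,1), computed
from the mean squares of the subjects x measurements layout:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

together with the mean and SD of the repeat differences, and the
pooled within-subject SD for the many-repeat single-subject
experiment.  Cohort summaries are mean +/- SD thickness grids by
tissue, meridian and spur-referenced location, with per-meridian means
taken as the unweighted mean over the five locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .profiling import ThicknessProfile


def icc_agreement(pairs: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measures, from an (n subjects x k measurements) table."""
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2:
        raise ValueError("pairs must be a 2-D (subjects x measurements) array")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not allowed")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)


def repeat_diff_stats(pairs: np.ndarray) -> Tuple[float, float]:
    """Mean and SD of (measure 2 - measure 1) over subjects."""
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 2:
        raise ValueError("need an (n >= 2) x 2 array of repeated measures")
    d = x[:, 1] - x[:, 0]
    return float(d.mean()), float(d.std(ddof=1))


def within_subject_sd(repeats: np.ndarray) -> float:
    """Pooled within-subject SD of a (k repeats x m locations) matrix:
    sqrt of the mean over locations of the per-location variance."""
    x = np.asarray(repeats, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 repeats")
    return float(np.sqrt(np.mean(np.var(x, axis=0, ddof=1))))


# ---------------------------------------------------------------------
# tidy-table helpers
# ---------------------------------------------------------------------

def profiles_to_tidy(profiles: Iterable[ThicknessProfile]) -> pd.DataFrame:
    """Long-format table: one row per eye/meridian/tissue/location."""
    rows = []
    for p in profiles:
        for loc, c_um, s_um in zip(p.scheme.distances_um,
                                   p.conjunctival_um, p.scleral_um):
            rows.append((p.eye_id, p.meridian, loc / 1000.0, "conjunctiva",
                         c_um, p.n_repeats_averaged))
            rows.append((p.eye_id, p.meridian, loc / 1000.0, "sclera",
                         s_um, p.n_repeats_averaged))
    return pd.DataFrame(
        rows, columns=["eye_id", "meridian", "location_mm", "tissue",
                       "thickness_um", "n_repeats"],
    )


@dataclass
class SummaryTable:
    """Mean +/- SD thickness grid by tissue x meridian x location."""

    cells: pd.DataFrame         # tissue, meridian, location_mm, mean, sd, n
    group_means: Optional[pd.DataFrame] = None

    def meridian_means(self) -> pd.DataFrame:
        """Unweighted mean (and SD) across the five location cells."""
        g = self.cells.groupby(["tissue", "meridian"])["mean_um"]
        return g.mean().rename("meridian_mean_um").reset_index()

    def grid(self) -> pd.DataFrame:
        """Wide layout: one row per tissue x meridian, one column per
        location, plus the meridian mean."""
        wide = self.cells.pivot_table(index=["tissue", "meridian"],
                                      columns="location_mm", values="mean_um")
        wide.columns = [f"loc_{c:g}mm_um" for c in wide.columns]
        wide["meridian_mean_um"] = wide.mean(axis=1)
        return wide.reset_index()


def summarize_cohort(
    profiles: Sequence[ThicknessProfile],
    group_labels: Optional[Dict[str, str]] = None,
) -> SummaryTable:
    """Per-cell mean and SD across eyes; permutation-invariant."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    tidy = profiles_to_tidy(profiles).sort_values(
        ["tissue", "meridian", "location_mm", "eye_id"], kind="stable"
    )
    agg = (
        tidy.groupby(["tissue", "meridian", "location_mm"])["thickness_um"]
        .agg(mean_um="mean",
             sd_um=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
             n="size")
        .reset_index()
    )
    group_means = None
    if group_labels is not None:
        tidy = tidy.assign(group=tidy["eye_id"].map(group_labels))
        group_means = (
            tidy.dropna(subset=["group"])
            .groupby(["group", "tissue"])["thickness_um"]
            .agg(mean_um="mean", sd_um=lambda v: v.std(ddof=1), n="size")
            .reset_index()
        )
    return SummaryTable(cells=agg, group_means=group_means)


def repeatability_report(
    repeat1: Sequence[ThicknessProfile],
    repeat2: Sequence[ThicknessProfile],
) -> pd.DataFrame:
    """ICC, mean repeat difference and SD of differences per
    tissue x meridian x location, from two repeated scans per eye."""
    t1 = profiles_to_tidy(repeat1).set_index(
        ["eye_id", "meridian", "tissue", "location_mm"])["thickness_um"]
    t2 = profiles_to_tidy(repeat2).set_index(
        ["eye_id", "meridian", "tissue", "location_mm"])["thickness_um"]
    if not t1.index.equals(t2.index):
        t2 = t2.reindex(t1.index)
        if t2.isna().any():
            raise ValueError("repeat scans do not cover the same eyes/locations")
    both = pd.DataFrame({"m1": t1, "m2": t2}).reset_index()
    rows = []
    for (tissue, meridian, loc), grp in both.groupby(
            ["tissue", "meridian", "location_mm"]):
        pairs = grp[["m1", "m2"]].to_numpy()
        mean_d, sd_d = repeat_diff_stats(pairs)
        rows.append((tissue, meridian, loc, icc_agreement(pairs),
                     mean_d, sd_d, len(grp)))
    return pd.DataFrame(rows, columns=["tissue", "meridian", "location_mm",
                                       "icc", "mean_diff_um", "sd_diff_um", "n"])
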