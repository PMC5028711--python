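"""Normative anterior-eye thickness table.

Cohort mean +/- SD thickness (micrometres) of the anterior conjunctiva
(ACB to ASB) and anterior sclera (ASB to PSB) in healthy children and
young adults, at the five spur-referenced locations 0-4 mm measured
along the arc of the posterior scleral boundary.  These values
parameterise the synthetic phantom sampler (per-eye geometry is drawn
within +/- 3 SD of each cell) and serve as the reference grid for
cohort summary checks.
"""

from __future__ import annotations

import numpy as np

#: Measurement locations in micrometres of arc from the scleral spur.
LOCATIONS_UM = (0.0, 1000.0, 2000.0, 3000.0, 4000.0)

#: (tissue, meridian) -> list of (mean_um, sd_um) per location.
NORMATIVE_THICKNESS = {
    ("conjunctiva", "temporal"): [(218, 55), (267, 59), (261, 57), (243, 52), (255, 61)],
    ("conjunctiva", "nasal"): [(223, 40), (244, 56), (241, 57), (277, 75), (364, 122)],
    ("sclera", "temporal"): [(653, 54), (463, 49), (442, 52), (473, 56), (489, 56)],
    ("sclera", "nasal"): [(606, 42), (483, 45), (502, 41), (495, 45), (446, 66)],
}


def location_means(tissue: str, meridian: str) -> np.ndarray:
    """Mean thickness (um) at the five arc locations."""
    return np.array([m for m, _ in NORMATIVE_THICKNESS[(tissue, meridian)]], float)


def location_sds(tissue: str, meridian: str) -> np.ndarray:
    """Between-eye SD of thickness (um) at the five arc locations."""
    return np.array([s for _, s in NORMATIVE_THICKNESS[(tissue, meridian)]], float)
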