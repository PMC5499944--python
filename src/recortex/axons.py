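"""Corticospinal axon-count aggregation.

Anterogradely labeled axons exiting the corticospinal tract are counted in
the contralateral gray matter of the spinal hemicord at three levels above
the lesion (T1, T4, T7), in five slices per level spaced ≥250 µm apart,
with a stereological sampling scheme covering 50% of the region of
interest per section.  Densities per slice are treated as independent
samples for the level × therapy factorial analysis.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["axon_density", "level_group_table", "SAMPLING_FRACTION", "LEVELS"]

LEVELS = ("T1", "T4", "T7")
SAMPLING_FRACTION = 0.5


def axon_density(count: float, sampled_area_mm2: float,
                 per_roi: bool = False) -> float:
    """Labeled axons per mm².

    By default the density is per mm² of *sampled* gray matter
    (``count / sampled_area``).  With ``per_roi=True`` the count is
    referred to the full region of interest instead, of which the sampled
    area is a 50% fraction.
    """
    if sampled_area_mm2 <= 0:
        raise ValueError("sampled_area_mm2 must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    dens = count / sampled_area_mm2
    if per_roi:
        dens *= SAMPLING_FRACTION
    return float(dens)


def level_group_table(records: pd.DataFrame, per_roi: bool = False) -> pd.DataFrame:
    """Per-slice density samples arranged for the level × therapy ANOVA.

    ``records`` columns: ``animal_id, therapy, level, slice_index, count,
    sampled_area_mm2``.  Returns a tidy frame with one density row per
    slice (90 rows for the full 3 groups × 2 animals × 3 levels × 5 slices
    design); testing is delegated to :func:`recortex.stats.factorial_anova`.
    """
    if records is None or len(records) == 0:
        raise ValueError("empty axon-count table")
    required = {"animal_id", "therapy", "level", "slice_index", "count",
                "sampled_area_mm2"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"axon table missing columns {sorted(missing)}")
    bad = set(records["level"]) - set(LEVELS)
    if bad:
        raise ValueError(f"unknown spinal levels {sorted(bad)}")
    out = records.copy()
    out["density"] = [
        axon_density(c, a, per_roi=per_roi)
        for c, a in zip(out["count"], out["sampled_area_mm2"])
    ]
    return out[["animal_id", "therapy", "level", "slice_index", "density"]]
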