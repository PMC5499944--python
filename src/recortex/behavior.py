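"""Behavioral recovery metrics from annotated step logs and score tables.

Three measures track hindlimb recovery after a complete thoracic
transection:

* **%WSS** — percentage of weight-supported step cycles among the first 100
  treadmill cycles.  A cycle is supported only if all five criteria (a)–(e)
  (hindquarters elevated, paw placed under the body with muscle contraction,
  knee off the belt, plantar contact at lift-off, plantar contact
  re-established after the swing) hold for each hindpaw.
* **BBB open-field score** — 0–21 locomotor rating, normalized at weeks
  4/8/12 to the group average at week two; a score ≥ 9 marks hindquarter
  plantar weight support.
* **Load-bearing failure point** — the minimal assisted vertical weight
  support sustaining ≥3 consecutive step cycles, expressed per animal as a
  percentage of its week-2 value (which is upper-bounded by the animal's
  weight, so normalized values cannot exceed 100%).
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "WssResult",
    "percent_wss",
    "normalize_bbb",
    "weight_support_proportion",
    "failure_point_normalized",
    "step_category_percentages",
    "performer_split",
    "validate_bbb_scale",
    "CRITERIA",
    "PLACEMENTS",
]

CRITERIA = ("a", "b", "c", "d", "e")
PLACEMENTS = ("no_step", "dorsal", "lateral", "plantar")
WSS_WINDOW = 100
PERFORMER_THRESHOLD = 10.0
WEIGHT_SUPPORT_BBB = 9.0


class WssResult(NamedTuple):
    pct: float
    n_cycles: int


def _supported(log: pd.DataFrame) -> pd.Series:
    cols = [f"{paw}_{c}" for paw in ("left", "right") for c in CRITERIA]
    missing = [c for c in cols if c not in log.columns]
    if missing:
        raise ValueError(f"step log missing flag columns {missing}")
    ok = log[cols].all(axis=1)
    # a dragging paw (no_step placement) voids support even if flags disagree
    for paw in ("left", "right"):
        col = f"{paw}_placement"
        if col in log.columns:
            ok &= log[col] != "no_step"
    return ok


def percent_wss(log: pd.DataFrame) -> WssResult:
    """%WSS over the first 100 step cycles of a treadmill session.

    Falls back, with a warning, to the available number of cycles when
    fewer than 100 were annotated; the count used is reported alongside.
    """
    if log is None or len(log) == 0:
        raise ValueError("empty step log")
    n = min(len(log), WSS_WINDOW)
    if len(log) < WSS_WINDOW:
        warnings.warn(
            f"step log has only {len(log)} cycles; %WSS computed over {n}",
            stacklevel=2,
        )
    head = log.iloc[:n]
    return WssResult(pct=float(100.0 * _supported(head).mean()), n_cycles=n)


def normalize_bbb(records: pd.DataFrame, mode: str = "percent_change",
                  baseline_week: int = 2) -> pd.DataFrame:
    """Normalize open-field scores to the week-2 group average.

    ``mode='percent_change'`` (default) maps the baseline to 0%:
    ``100·(x − m₂)/m₂`` with ``m₂`` the group mean at the baseline week;
    ``mode='percent_of_baseline'`` maps it to 100%: ``100·x/m₂``.
    Baseline-week rows pass through with 0 (resp. 100).
    """
    if mode not in ("percent_change", "percent_of_baseline"):
        raise ValueError(f"unknown mode {mode!r}")
    df = records.copy()
    base = (
        df[df["week"] == baseline_week].groupby("group")["bbb"].mean()
    )
    if base.empty or (base <= 0).any():
        raise ValueError("week-2 group baseline missing or non-positive")
    m2 = df["group"].map(base)
    if m2.isna().any():
        raise ValueError("some groups have no baseline-week records")
    if mode == "percent_change":
        df["bbb_norm"] = 100.0 * (df["bbb"] - m2) / m2
    else:
        df["bbb_norm"] = 100.0 * df["bbb"] / m2
    return df


def weight_support_proportion(records: pd.DataFrame, week: int) -> float:
    """Fraction of animals with hindlimb plantar weight support (BBB ≥ 9)."""
    sub = records[records["week"] == week]
    if sub.empty:
        raise ValueError(f"no records at week {week}")
    return float((sub["bbb"] >= WEIGHT_SUPPORT_BBB).mean())


def failure_point_normalized(records: pd.DataFrame,
                             baseline_week: int = 2) -> pd.DataFrame:
    """Failure point as % of each animal's week-2 assisted weight support.

    The week-2 failure point equals the full assisted support (the device is
    calibrated to the animal's weight), so normalized values above 100%
    are physically impossible and rejected.
    """
    df = records.copy()
    base = df[df["week"] == baseline_week].set_index("animal_id")[
        "failure_point_pct"
    ]
    if (base <= 0).any():
        raise ValueError("non-positive week-2 failure point")
    b = df["animal_id"].map(base)
    if b.isna().any():
        missing = sorted(df.loc[b.isna(), "animal_id"].unique())
        raise ValueError(f"animals without a week-2 failure point: {missing}")
    df["failure_point_norm"] = 100.0 * df["failure_point_pct"] / b
    over = df["failure_point_norm"] > 100.0 + 1e-9
    if over.any():
        raise ValueError(
            "failure point above the week-2 assisted support (>100%) for "
            f"{sorted(df.loc[over, 'animal_id'].unique())}"
        )
    return df


def step_category_percentages(log: pd.DataFrame, paw: str) -> pd.Series:
    """Placement-category percentages for one hindpaw (sum to 100)."""
    col = f"{paw}_placement"
    if col not in log.columns:
        raise ValueError(f"step log has no column {col!r}")
    if len(log) == 0:
        raise ValueError("empty step log")
    counts = log[col].value_counts()
    pct = 100.0 * counts.reindex(PLACEMENTS, fill_value=0) / len(log)
    pct.name = paw
    return pct


def performer_split(records: pd.DataFrame, week: int = 12) -> pd.Series:
    """Label animals performer / non_performer at the %WSS > 10 threshold.

    The threshold is strict: an animal exactly at 10 %WSS is a
    non-performer.
    """
    sub = records[records["week"] == week].set_index("animal_id")
    if sub.empty:
        raise ValueError(f"no week-{week} records")
    return pd.Series(
        np.where(sub["pct_wss"] > PERFORMER_THRESHOLD, "performer", "non_performer"),
        index=sub.index,
        name="performance",
    )


def validate_bbb_scale(values, strict: bool = False) -> None:
    """Check BBB scores against the 0–21 scale (half points when strict)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0) or np.any(v > 21):
        raise ValueError("BBB scores must lie in [0, 21]")
    if strict and np.any(np.abs(v * 2 - np.round(v * 2)) > 1e-9):
        raise ValueError("BBB scores must be integers or half points")
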