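"""Intracortical-microstimulation (ICMS) motor-map quantification.

A motor map is a set of electrode penetrations on a 0.5 mm cortical grid
over the medial post-bregma area (AP −0.5 to 2 mm posterior to bregma — the
negative value meaning 0.5 mm *rostral* — and ML 1 to 3.5 mm lateral).  At
each site the minimum current evoking a movement (threshold, up to 100 µA)
and the movement type are recorded.  The representation area of a movement
type is the number of responsive grid cells evoking it times 0.25 mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "MotorMapGrid",
    "snap_to_grid",
    "map_area",
    "threshold_heatmap",
    "area_behavior_correlation",
    "MOVEMENTS",
]

MOVEMENTS = ("trunk", "hindlimb", "forelimb", "vibrissae", "none")

CELL_AREA_MM2 = 0.25


@dataclass(frozen=True)
class GridSpec:
    """Cortical penetration grid (posterior-positive AP, mm from bregma)."""

    ap_min: float = -0.5
    ap_max: float = 2.0
    ml_min: float = 1.0
    ml_max: float = 3.5
    spacing: float = 0.5
    snap_tolerance: float = 0.25

    @property
    def n_ap(self) -> int:
        return int(round((self.ap_max - self.ap_min) / self.spacing)) + 1

    @property
    def n_ml(self) -> int:
        return int(round((self.ml_max - self.ml_min) / self.spacing)) + 1

    def site_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of the (ap, ml) coordinates of every grid cell."""
        ap = self.ap_min + self.spacing * np.arange(self.n_ap)
        ml = self.ml_min + self.spacing * np.arange(self.n_ml)
        A, M = np.meshgrid(ap, ml, indexing="ij")
        return A.ravel(), M.ravel()


def _snap_axis(x: float, x_min: float, x_max: float, spacing: float,
               tol: float) -> int:
    if x < x_min - tol - 1e-9 or x > x_max + tol + 1e-9:
        raise ValueError("coordinate out of grid bounds beyond tolerance")
    u = (x - x_min) / spacing
    # nearest index; exact midpoints break toward the smaller index
    lo = int(np.floor(u))
    frac = u - lo
    idx = lo if frac <= 0.5 + 1e-9 else lo + 1
    n = int(round((x_max - x_min) / spacing)) + 1
    return int(np.clip(idx, 0, n - 1))


def snap_to_grid(ap_mm: float, ml_mm: float,
                 grid: GridSpec | None = None) -> tuple[int, int]:
    """Assign a penetration to its nearest grid cell.

    Penetrations displaced to avoid surface vasculature are corrected by
    snapping to the nearest 0.5 mm cell center; exact midpoints break toward
    the smaller (AP, then ML) index.  Sites beyond ``snap_tolerance`` of the
    grid raise ``ValueError`` with the coordinate in the message.
    """
    if grid is None:
        grid = GridSpec()
    try:
        i = _snap_axis(ap_mm, grid.ap_min, grid.ap_max, grid.spacing, grid.snap_tolerance)
        j = _snap_axis(ml_mm, grid.ml_min, grid.ml_max, grid.spacing, grid.snap_tolerance)
    except ValueError:
        raise ValueError(
            f"site (AP={ap_mm}, ML={ml_mm}) out of grid bounds beyond "
            f"{grid.snap_tolerance} mm tolerance"
        ) from None
    return i, j


@dataclass
class MotorMapGrid:
    """Penetration table plus its grid geometry.

    ``sites`` columns: ``ap_mm, ml_mm, movement, threshold_uA`` (NaN
    threshold iff movement is ``none`` — non-responsive up to 100 µA).
    """

    sites: pd.DataFrame
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        s = pd.DataFrame(self.sites).copy()
        required = {"ap_mm", "ml_mm", "movement", "threshold_uA"}
        missing = required - set(s.columns)
        if missing:
            raise ValueError(f"sites table missing columns {sorted(missing)}")
        bad = set(s["movement"]) - set(MOVEMENTS)
        if bad:
            raise ValueError(f"unknown movement labels {sorted(bad)}")
        responsive = s["movement"] != "none"
        thr = s["threshold_uA"]
        if responsive.any():
            tr = thr[responsive]
            if tr.isna().any() or (tr <= 0).any() or (tr > 100).any():
                raise ValueError("responsive sites need threshold in (0, 100] µA")
        if (~responsive).any() and thr[~responsive].notna().any():
            raise ValueError("non-responsive sites must not carry a threshold")
        self.sites = s.reset_index(drop=True)

    def snapped(self) -> pd.DataFrame:
        """Sites with grid cell indices and snapped coordinates attached."""
        s = self.sites.copy()
        ij = [snap_to_grid(a, m, self.grid) for a, m in zip(s["ap_mm"], s["ml_mm"])]
        s["ap_idx"] = [i for i, _ in ij]
        s["ml_idx"] = [j for _, j in ij]
        s["ap_snap"] = self.grid.ap_min + self.grid.spacing * s["ap_idx"]
        s["ml_snap"] = self.grid.ml_min + self.grid.spacing * s["ml_idx"]
        return s


def _dominant_per_cell(snapped: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple penetrations in a cell to one dominant label.

    The dominant movement is the responsive one with the lowest threshold;
    a cell is ``none`` only if every penetration in it was non-responsive.
    """
    def pick(g: pd.DataFrame) -> pd.Series:
        resp = g[g["movement"] != "none"]
        if len(resp):
            best = resp.loc[resp["threshold_uA"].idxmin()]
            return best[["movement", "threshold_uA"]]
        return g.iloc[0][["movement", "threshold_uA"]]

    out = (
        snapped.groupby(["ap_idx", "ml_idx"], sort=True)
        .apply(pick, include_groups=False)
        .reset_index()
    )
    return out


def map_area(grid_map: MotorMapGrid, movement: str) -> float:
    """Cortical representation area (mm²) of one movement type.

    Responsive grid cells whose dominant evoked movement matches, times
    0.25 mm² per cell.
    """
    if movement not in MOVEMENTS:
        raise ValueError(f"unknown movement {movement!r}")
    cells = _dominant_per_cell(grid_map.snapped())
    return float((cells["movement"] == movement).sum() * CELL_AREA_MM2)


def threshold_heatmap(grid_map: MotorMapGrid) -> pd.DataFrame:
    """Per-cell mean threshold current (µA), 0–100 scale.

    Returns a matrix indexed by AP cell center (rows) and ML cell center
    (columns); cells in which no penetration evoked any movement are NaN
    (rendered hashed in the study's figures).
    """
    g = grid_map.grid
    snapped = grid_map.snapped()
    resp = snapped[snapped["movement"] != "none"]
    mat = np.full((g.n_ap, g.n_ml), np.nan)
    if len(resp):
        means = resp.groupby(["ap_idx", "ml_idx"])["threshold_uA"].mean()
        for (i, j), v in means.items():
            mat[i, j] = v
    ap = g.ap_min + g.spacing * np.arange(g.n_ap)
    ml = g.ml_min + g.spacing * np.arange(g.n_ml)
    return pd.DataFrame(mat, index=pd.Index(ap, name="ap_mm"),
                        columns=pd.Index(ml, name="ml_mm"))


def area_behavior_correlation(trunk_areas, behavior):
    """Correlate per-animal trunk map area with a behavioral measure.

    Returns the :class:`~recortex.stats.CorrelationResult` from the stats
    layer (Pearson r with two-sided p, plus the robust bisquare fit).
    """
    from . import stats as _stats

    x = np.asarray(trunk_areas, dtype=float)
    y = np.asarray(behavior, dtype=float)
    return _stats.pearson_with_bisquare(x, y)
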