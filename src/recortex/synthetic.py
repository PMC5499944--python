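"""Seeded generators for every input the analysis pipeline consumes.

The study this toolkit quantifies has no deposited raw data, so every
analysis stage is exercised on synthetic inputs that reproduce the
*statistical structure* the detectors and tests assume:

* anesthetized tactile mapping — homogeneous Poisson background spiking with
  a stimulus-locked boxcar rate bump on responsive neurons (100 taps at
  0.5 Hz per skin site);
* awake treadmill recordings — inhomogeneous Poisson spiking whose rate is
  modulated around forepaw footfalls;
* intracortical-microstimulation motor maps on a 0.5 mm cortical grid with
  therapy-dependent trunk representation;
* per-animal behavioral trajectories (%WSS, BBB open-field score,
  load-bearing failure point) drawn from moment-matched bound-censored normals
  calibrated to the printed group means ± SDs;
* annotated treadmill step logs with the five weight-support criteria per
  hindpaw;
* Poisson corticospinal axon counts per spinal slice with a rostro-caudal
  gradient and a therapy effect.

Every generator takes an explicit integer seed and is bit-reproducible.
Ground-truth labels are emitted for everything a downstream detector or
classifier estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .session import SpikeSession
from .motormap import GridSpec, MotorMapGrid

__all__ = [
    "SensoryGenParams",
    "LocomotorGenParams",
    "CohortGenParams",
    "MotorMapGenParams",
    "AxonGenParams",
    "gen_sensory_session",
    "gen_locomotor_session",
    "gen_motor_map",
    "gen_behavior_cohort",
    "gen_step_log",
    "gen_axon_counts",
    "child_rng",
    "DEFAULT_GROUP_WEEK_STATS",
]

GROUPS = ("sham", "partial", "complete")


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent child stream of a master seed (fixed offsets, replayable)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), int(stream))))


# --------------------------------------------------------------------------
# anesthetized tactile-stimulation sessions
# --------------------------------------------------------------------------

@dataclass
class SensoryGenParams:
    """Parameters of the anesthetized tactile-mapping simulator.

    ``evoked_magnitude`` is the *expected number of extra spikes per
    stimulus*; the evoked rate bump is a boxcar starting ``evoked_latency``
    ms after the tap and lasting ``evoked_duration`` ms, whose integral
    equals the magnitude — which makes the spikes/stimulus estimator
    analytically checkable.
    """

    background_rate: float = 5.0          # Hz
    evoked_magnitude: float = 2.0         # spikes per stimulus
    evoked_latency: float = 8.0           # ms after the tap
    evoked_duration: float = 30.0         # ms
    n_trials: int = 100                   # taps per site, at 0.5 Hz
    n_neurons: int = 30
    prop_responsive: float = 0.5
    inter_stimulus_interval: float = 2.0  # s
    location: str = "forepaw_digit2"
    seed: int = 0

    def validate(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.evoked_magnitude < 0:
            raise ValueError("evoked_magnitude must be >= 0")
        if not (0.0 <= self.prop_responsive <= 1.0):
            raise ValueError("prop_responsive must lie in [0, 1]")
        if self.n_trials < 1 or self.n_neurons < 1:
            raise ValueError("n_trials and n_neurons must be >= 1")
        post_window_ms = self.inter_stimulus_interval * 1000.0
        if self.evoked_latency < 0 or self.evoked_duration <= 0:
            raise ValueError("evoked latency/duration must be nonnegative/positive")
        if self.evoked_latency + self.evoked_duration > post_window_ms:
            raise ValueError("evoked bump must fit in the post-stimulus window")


def gen_sensory_session(
    params: SensoryGenParams,
) -> tuple[SpikeSession, dict[str, bool]]:
    """Simulate one tactile-mapping session.

    Returns the session and a ground-truth map ``neuron_id -> responsive``.
    Background spiking is homogeneous Poisson; responsive neurons receive,
    after each stimulus, an extra Poisson(``evoked_magnitude``) spikes
    placed uniformly in the boxcar window.
    """
    params.validate()
    rng = child_rng(params.seed, 1)
    isi = params.inter_stimulus_interval
    # stimuli start after one ISI of silence; one ISI tail after the last tap
    event_times = isi * (1 + np.arange(params.n_trials))
    duration = isi * (params.n_trials + 2)

    n_resp = int(round(params.prop_responsive * params.n_neurons))
    responsive_idx = set(rng.choice(params.n_neurons, size=n_resp, replace=False).tolist())

    lat_s = params.evoked_latency / 1000.0
    dur_s = params.evoked_duration / 1000.0
    spikes: dict[str, np.ndarray] = {}
    truth: dict[str, bool] = {}
    for i in range(params.n_neurons):
        nid = f"n{i:03d}"
        n_bg = rng.poisson(params.background_rate * duration)
        t = rng.uniform(0.0, duration, size=n_bg)
        is_resp = i in responsive_idx and params.evoked_magnitude > 0
        if is_resp:
            n_ev = rng.poisson(params.evoked_magnitude, size=params.n_trials)
            ev_t = np.repeat(event_times + lat_s, n_ev) + rng.uniform(
                0.0, dur_s, size=int(n_ev.sum())
            )
            t = np.concatenate([t, ev_t])
        spikes[nid] = np.sort(t)
        truth[nid] = bool(is_resp)

    events = pd.DataFrame({"label": params.location, "time_s": event_times})
    return SpikeSession(spikes=spikes, events=events, duration=duration), truth


# --------------------------------------------------------------------------
# awake treadmill sessions
# --------------------------------------------------------------------------

@dataclass
class LocomotorGenParams:
    """Parameters of the awake treadmill-locomotion simulator.

    The instantaneous rate is ``background × (1 + depth·k(t))`` where
    ``k`` is a Gaussian bump of FWHM ``modulation_width`` centered
    ``modulation_latency`` ms after each footfall (summed over footfalls and
    capped at 1 so the rate never exceeds ``background × (1 + depth)``).
    """

    background_rate: float = 10.0     # Hz
    modulation_depth: float = 2.0     # peak rate multiplier - 1
    modulation_latency: float = 50.0  # ms relative to footfall
    modulation_width: float = 100.0   # ms FWHM of the bump
    n_footfalls: int = 300
    record_duration: float = 600.0    # s ("the recording lasted 10 mins")
    paw: str = "left_forepaw"
    seed: int = 0

    def validate(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.modulation_depth < 0:
            raise ValueError("modulation_depth must be >= 0 (rate would go negative)")
        if self.modulation_width <= 0:
            raise ValueError("modulation_width must be positive")
        if self.record_duration <= 0:
            raise ValueError("record_duration must be positive")
        if self.n_footfalls < 0:
            raise ValueError("n_footfalls must be >= 0")


def _footfall_kernel(t_s: np.ndarray, footfalls: np.ndarray, latency_s: float,
                     sigma_s: float) -> np.ndarray:
    """Sum of per-footfall Gaussian bumps, capped at 1."""
    if footfalls.size == 0:
        return np.zeros_like(t_s)
    out = np.zeros_like(t_s)
    # only neighbours within 5 sigma contribute
    centers = footfalls + latency_s
    lo = np.searchsorted(centers, t_s - 5 * sigma_s)
    hi = np.searchsorted(centers, t_s + 5 * sigma_s)
    for j, (a, b) in enumerate(zip(lo, hi)):
        if b > a:
            d = t_s[j] - centers[a:b]
            out[j] = np.exp(-0.5 * (d / sigma_s) ** 2).sum()
    return np.minimum(out, 1.0)


def gen_locomotor_session(params: LocomotorGenParams) -> SpikeSession:
    """Simulate one awake recording (inhomogeneous Poisson via thinning).

    Footfalls are quasi-periodic: an even grid over the recording with ±20%
    uniform jitter of the inter-step interval.
    """
    params.validate()
    rng = child_rng(params.seed, 2)
    T = params.record_duration
    if params.n_footfalls > 0:
        isi = T / (params.n_footfalls + 1)
        base = isi * (1 + np.arange(params.n_footfalls))
        footfalls = np.sort(base + rng.uniform(-0.2 * isi, 0.2 * isi, params.n_footfalls))
        footfalls = np.clip(footfalls, 0.0, T)
    else:
        footfalls = np.array([], dtype=float)

    lam_max = params.background_rate * (1.0 + params.modulation_depth)
    sigma_s = params.modulation_width / 2.3548200450309493 / 1000.0  # FWHM -> sd
    lat_s = params.modulation_latency / 1000.0
    n_cand = rng.poisson(lam_max * T) if lam_max > 0 else 0
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    if n_cand:
        k = _footfall_kernel(cand, footfalls, lat_s, sigma_s)
        rate = params.background_rate * (1.0 + params.modulation_depth * k)
        keep = rng.uniform(0.0, 1.0, size=n_cand) < rate / lam_max
        spikes = cand[keep]
    else:
        spikes = np.array([], dtype=float)

    events = pd.DataFrame({"label": params.paw, "time_s": footfalls})
    return SpikeSession(spikes={"n000": spikes}, events=events, duration=T)


# --------------------------------------------------------------------------
# motor maps
# --------------------------------------------------------------------------

@dataclass
class MotorMapGenParams:
    """Movement-label probabilities per grid site for one therapy group.

    Probabilities are per site over {trunk, forelimb, vibrissae, hindlimb};
    the remainder is non-responsive. Lesioned groups have hindlimb
    probability 0 (no movement can be evoked below a complete transection).
    """

    p_trunk: float = 0.12
    p_forelimb: float = 0.20
    p_vibrissae: float = 0.15
    p_hindlimb: float = 0.0
    jitter_mm: float = 0.05   # surface-vasculature avoidance jitter
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0

    def probs(self) -> np.ndarray:
        p = np.array(
            [self.p_trunk, self.p_forelimb, self.p_vibrissae, self.p_hindlimb]
        )
        if np.any(p < 0) or p.sum() > 1.0 + 1e-12:
            raise ValueError("movement probabilities must be >= 0 and sum <= 1")
        return np.append(p, max(0.0, 1.0 - p.sum()))  # last = none


#: group presets: complete therapy expands the trunk representation
MOTOR_MAP_PRESETS = {
    "sham": dict(p_trunk=0.12, p_forelimb=0.20, p_vibrissae=0.15),
    "partial": dict(p_trunk=0.22, p_forelimb=0.20, p_vibrissae=0.15),
    "complete": dict(p_trunk=0.38, p_forelimb=0.20, p_vibrissae=0.15),
    "naive": dict(p_trunk=0.12, p_forelimb=0.20, p_vibrissae=0.15, p_hindlimb=0.30),
}


def gen_motor_map(group: str, params: MotorMapGenParams | None = None,
                  seed: int = 0) -> MotorMapGrid:
    """Simulate one intracortical-microstimulation map for a therapy group.

    Each grid site draws a movement label from the group's categorical
    distribution; responsive sites draw a threshold current uniformly in
    (0, 100] µA; site coordinates are jittered by ±``jitter_mm`` to mimic
    penetrations displaced around vasculature (undone by grid snapping).
    """
    if params is None:
        if group not in MOTOR_MAP_PRESETS:
            raise ValueError(f"unknown group {group!r}; give explicit params")
        params = MotorMapGenParams(**MOTOR_MAP_PRESETS[group], seed=seed)
    rng = child_rng(params.seed, 3)
    labels = ("trunk", "forelimb", "vibrissae", "hindlimb", "none")
    ap, ml = params.grid.site_centers()
    n = len(ap)
    draw = rng.choice(len(labels), size=n, p=params.probs())
    movement = np.array(labels)[draw]
    thr = np.where(
        movement == "none",
        np.nan,
        100.0 * (1.0 - rng.uniform(0.0, 1.0, size=n)),  # uniform in (0, 100]
    )
    jit = params.jitter_mm
    sites = pd.DataFrame(
        {
            "ap_mm": ap + rng.uniform(-jit, jit, n),
            "ml_mm": ml + rng.uniform(-jit, jit, n),
            "movement": movement,
            "threshold_uA": thr,
        }
    )
    return MotorMapGrid(sites=sites, grid=params.grid)


# --------------------------------------------------------------------------
# behavioral cohorts
# --------------------------------------------------------------------------

#: printed group statistics (mean, SD) per measure, group and week.
#: %WSS week-4 "1.6 ± 4.3%" applies to all groups; week-12 values are the
#: printed per-group results; week-8 sits between (the study reports a
#: ten-fold increase from week 4 for both therapy groups).  BBB week-2
#: means/SDs are printed; later weeks rise for therapy groups.  Failure
#: point is in % of the week-2 assisted support.
DEFAULT_GROUP_WEEK_STATS: dict[str, dict[str, dict[int, tuple[float, float]]]] = {
    "pct_wss": {
        "sham": {4: (1.6, 4.3), 8: (1.6, 2.9), 12: (1.6, 2.9)},
        "partial": {4: (1.6, 4.3), 8: (10.0, 13.0), 12: (12.3, 15.4)},
        "complete": {4: (1.6, 4.3), 8: (16.0, 16.0), 12: (19.4, 17.8)},
    },
    "bbb": {
        "sham": {2: (6.5, 1.3), 4: (6.5, 1.6), 8: (6.8, 1.8), 12: (7.0, 2.0)},
        "partial": {2: (5.7, 2.0), 4: (6.5, 2.2), 8: (7.6, 2.6), 12: (7.9, 2.8)},
        "complete": {2: (5.2, 2.4), 4: (6.8, 2.4), 8: (8.2, 2.8), 12: (8.8, 3.0)},
    },
    "failure_point_pct": {
        "sham": {4: (97.0, 4.0), 8: (95.0, 6.0), 12: (94.0, 7.0)},
        "partial": {4: (92.0, 8.0), 8: (78.0, 10.0), 12: (65.0, 12.0)},
        "complete": {4: (90.0, 8.0), 8: (70.0, 10.0), 12: (55.0, 12.0)},
    },
}

MEASURE_BOUNDS = {
    "pct_wss": (0.0, 100.0),
    "bbb": (0.0, 21.0),
    "failure_point_pct": (0.0, 100.0),
}


@dataclass
class CohortGenParams:
    """Cohort generator configuration.

    ``group_week_stats[measure][group][week] = (mean, sd)``; values are
    drawn from a normal censored (clipped) to the measure's hard bounds,
    with parent parameters solved so the *censored* distribution has
    exactly the configured mean and SD (moment matching).

    ``n_per_group`` reflects the study design (one sham animal died before
    week 12); ``n_wss_missing_partial`` partial-therapy animals lack week-8
    treadmill data and are dropped listwise from the %WSS mixed ANOVA;
    failure-point data exist for a 12/12/15 subset.
    """

    group_week_stats: dict = field(
        default_factory=lambda: DEFAULT_GROUP_WEEK_STATS
    )
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"sham": 14, "partial": 15, "complete": 15}
    )
    n_wss_missing_partial: int = 2
    n_failure_missing: dict[str, int] = field(
        default_factory=lambda: {"sham": 2, "partial": 3, "complete": 0}
    )
    corr_map_behavior: float = 0.41   # trunk area vs %WSS, printed Pearson R
    trunk_area_mean: float = 2.0      # mm², across-group average
    trunk_area_sd: float = 1.2
    round_half: bool = False          # snap BBB to the 0.5-point rubric
    seed: int = 0


def _censored_normal_moments(mu: float, sig: float,
                             lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of a normal clipped (censored) to [lo, hi], closed form."""
    a, b = (lo - mu) / sig, (hi - mu) / sig
    Fa, Fb = sps.norm.cdf(a), sps.norm.cdf(b)
    fa, fb = sps.norm.pdf(a), sps.norm.pdf(b)
    mid = Fb - Fa
    m = lo * Fa + hi * (1.0 - Fb) + mu * mid + sig * (fa - fb)
    ex2 = (
        lo**2 * Fa
        + hi**2 * (1.0 - Fb)
        + mu**2 * mid
        + 2.0 * mu * sig * (fa - fb)
        + sig**2 * (mid + a * fa - b * fb)
    )
    var = max(ex2 - m * m, 0.0)
    return m, np.sqrt(var)


def _matched_censored_params(mean: float, sd: float,
                             lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-censored normal has the target moments.

    Censoring (clipping at the bounds, with a point mass there) rather than
    truncation, because printed group statistics near a bound can have
    SD > mean − lo, which no truncated normal supports; clipping also
    mirrors floor effects in the real scores (animals at exactly 0 %WSS).
    """
    if not (lo <= mean <= hi):
        raise ValueError(f"target mean {mean} outside bounds [{lo}, {hi}]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return mean, 0.0
    max_sd = np.sqrt((mean - lo) * (hi - mean))
    if sd >= max_sd:
        raise ValueError(
            f"sd={sd} infeasible for mean={mean} on [{lo}, {hi}] (max {max_sd:.3g})"
        )

    def resid(p):
        m, s = _censored_normal_moments(p[0], np.exp(p[1]), lo, hi)
        return [m - mean, s - sd]

    for x0 in ([mean, np.log(sd)],
               [mean - 2 * sd, np.log(3 * sd)],
               [lo - 2 * sd, np.log(4 * sd)]):
        sol = optimize.root(resid, x0=x0, method="hybr")
        if sol.success and np.max(np.abs(sol.fun)) < 1e-8:
            return float(sol.x[0]), float(np.exp(sol.x[1]))
    raise ValueError(
        f"cannot match censored-normal moments mean={mean}, sd={sd} in [{lo}, {hi}]"
    )


_CENSOR_CACHE: dict[tuple, tuple[float, float]] = {}


def _draw_truncated(rng, mean, sd, lo, hi, size):
    key = (round(mean, 10), round(sd, 10), lo, hi)
    if key not in _CENSOR_CACHE:
        _CENSOR_CACHE[key] = _matched_censored_params(mean, sd, lo, hi)
    mu, sig = _CENSOR_CACHE[key]
    if sig == 0:
        return np.full(size, float(np.clip(mu, lo, hi)))
    return np.clip(rng.normal(mu, sig, size=size), lo, hi)


def gen_behavior_cohort(params: CohortGenParams | None = None) -> pd.DataFrame:
    """Simulate a per-animal, per-week behavioral table.

    Returns a tidy frame with columns ``animal_id, group, week, pct_wss,
    bbb, failure_point_pct, trunk_area_mm2`` (NaN where the study design has
    no observation).  The trunk-area covariate is constant per animal and
    coupled to week-12 %WSS at Pearson ``corr_map_behavior`` (exact in
    expectation: the covariate regresses on the empirically standardized
    behavioral score plus independent noise).
    """
    if params is None:
        params = CohortGenParams()
    rng = child_rng(params.seed, 4)
    rows = []
    for group in GROUPS:
        n = params.n_per_group[group]
        for k in range(n):
            rows.append({"animal_id": f"{group[:2]}{k:02d}", "group": group})
    animals = pd.DataFrame(rows)

    frames = []
    for measure, by_group in params.group_week_stats.items():
        lo, hi = MEASURE_BOUNDS[measure]
        for group, by_week in by_group.items():
            ids = animals.loc[animals["group"] == group, "animal_id"].to_numpy()
            for week, (mean, sd) in sorted(by_week.items()):
                vals = _draw_truncated(rng, mean, sd, lo, hi, size=len(ids))
                frames.append(
                    pd.DataFrame(
                        {
                            "animal_id": ids,
                            "group": group,
                            "week": week,
                            "measure": measure,
                            "value": vals,
                        }
                    )
                )
    long = pd.concat(frames, ignore_index=True)
    wide = (
        long.pivot_table(
            index=["animal_id", "group", "week"], columns="measure", values="value"
        )
        .reset_index()
        .rename_axis(columns=None)
    )
    for m in MEASURE_BOUNDS:
        if m not in wide:
            wide[m] = np.nan

    if params.round_half:
        wide["bbb"] = np.round(wide["bbb"] * 2.0) / 2.0

    # study-design missingness
    partial_ids = animals.loc[animals["group"] == "partial", "animal_id"]
    drop_wss = partial_ids.iloc[: params.n_wss_missing_partial]
    wide.loc[
        wide["animal_id"].isin(drop_wss) & (wide["week"] == 8), "pct_wss"
    ] = np.nan
    for group, n_miss in params.n_failure_missing.items():
        if n_miss:
            ids = animals.loc[animals["group"] == group, "animal_id"].iloc[:n_miss]
            wide.loc[wide["animal_id"].isin(ids), "failure_point_pct"] = np.nan

    # trunk-area covariate coupled to week-12 %WSS
    w12 = wide[wide["week"] == 12].set_index("animal_id")["pct_wss"]
    z = (w12 - w12.mean()) / w12.std(ddof=0)
    r = params.corr_map_behavior
    noise = rng.standard_normal(len(z))
    area = params.trunk_area_mean + params.trunk_area_sd * (
        r * z.to_numpy() + np.sqrt(max(0.0, 1.0 - r**2)) * noise
    )
    area = np.maximum(area, 0.0)
    area_map = dict(zip(z.index, area))
    wide["trunk_area_mm2"] = wide["animal_id"].map(area_map)
    return wide.sort_values(["group", "animal_id", "week"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# treadmill step logs
# --------------------------------------------------------------------------

CRITERIA = ("a", "b", "c", "d", "e")
PLACEMENTS = ("no_step", "dorsal", "lateral", "plantar")


def gen_step_log(
    n_cycles: int = 120,
    p_support: float = 0.2,
    placement_mix: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an annotated treadmill step log.

    One row per step cycle, with the five weight-support criteria flags
    (a)–(e) and a placement category per hindpaw.  A cycle is ground-truth
    supported iff all five flags hold for both hindpaws; supported cycles
    are plantar on both paws.  ``placement_mix`` gives the (no_step, dorsal,
    lateral) proportions among *unsupported* cycles, the remainder being
    non-weight-bearing plantar steps.
    """
    if not (0.0 <= p_support <= 1.0):
        raise ValueError("p_support must lie in [0, 1]")
    if placement_mix is None:
        placement_mix = (0.5, 0.2, 0.2)
    pm = np.asarray(placement_mix, dtype=float)
    if np.any(pm < 0) or pm.sum() > 1.0 + 1e-12:
        raise ValueError("placement_mix must be nonnegative and sum <= 1")
    probs = np.append(pm, max(0.0, 1.0 - pm.sum()))  # + plantar
    rng = child_rng(seed, 5)
    supported = rng.uniform(size=n_cycles) < p_support
    rows = []
    for i in range(n_cycles):
        row: dict = {"cycle": i, "supported_truth": bool(supported[i])}
        for paw in ("left", "right"):
            if supported[i]:
                flags = dict.fromkeys(CRITERIA, True)
                placement = "plantar"
            else:
                placement = PLACEMENTS[rng.choice(4, p=probs)]
                flags = {c: bool(rng.uniform() < 0.5) for c in CRITERIA}
                if placement == "no_step":
                    # a dragging paw cannot satisfy plantar-contact criteria
                    flags["d"] = False
                    flags["e"] = False
                if all(flags.values()):
                    flags[rng.choice(CRITERIA)] = False  # keep ground truth exact
            for c in CRITERIA:
                row[f"{paw}_{c}"] = flags[c]
            row[f"{paw}_placement"] = placement
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# axon counts
# --------------------------------------------------------------------------

@dataclass
class AxonGenParams:
    """Corticospinal axon-count simulator (3 groups × 3 levels × 5 slices).

    ``rates`` are axons per mm² of sampled gray matter per (therapy, level);
    counts are Poisson(rate × sampled area).  The default rates encode the
    rostro-caudal gradient (more label caudally, nearer the trunk motoneuron
    pools: T1 < T4 < T7) and the therapy effect (naive < sham < complete).
    """

    rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "naive": {"T1": 2.0, "T4": 3.0, "T7": 5.0},
            "sham": {"T1": 3.0, "T4": 5.0, "T7": 8.0},
            "complete": {"T1": 6.0, "T4": 10.0, "T7": 16.0},
        }
    )
    n_animals_per_group: int = 2
    n_slices: int = 5
    sampled_area_mm2: float = 0.8  # 50% of a ~1.6 mm² hemicord gray ROI
    seed: int = 0


def gen_axon_counts(params: AxonGenParams | None = None) -> pd.DataFrame:
    """Simulate the axon-count table (one row per slice)."""
    if params is None:
        params = AxonGenParams()
    for g, lv in params.rates.items():
        for level, rate in lv.items():
            if rate < 0:
                raise ValueError(f"negative rate for ({g}, {level})")
    if params.sampled_area_mm2 <= 0:
        raise ValueError("sampled_area_mm2 must be positive")
    rng = child_rng(params.seed, 6)
    rows = []
    for group, by_level in params.rates.items():
        for a in range(params.n_animals_per_group):
            for level, rate in by_level.items():
                lam = rate * params.sampled_area_mm2
                counts = rng.poisson(lam, size=params.n_slices)
                for s, c in enumerate(counts, start=1):
                    rows.append(
                        {
                            "animal_id": f"{group[:2]}{a}",
                            "therapy": group,
                            "level": level,
                            "slice_index": s,
                            "count": int(c),
                            "sampled_area_mm2": params.sampled_area_mm2,
                        }
                    )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# provenance
# --------------------------------------------------------------------------

def write_provenance(path: str | Path, **param_blocks) -> None:
    """Echo generation parameters into a JSON provenance record."""
    rec = {}
    for name, block in param_blocks.items():
        if hasattr(block, "__dataclass_fields__"):
            block = asdict(block)
        rec[name] = block
    Path(path).write_text(json.dumps(rec, indent=1, default=str))
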