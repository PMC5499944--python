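"""End-to-end calibration and recovery measurements for the pipeline.

These routines quantify, by simulation on the synthetic generators, the
operating characteristics the analyses rely on: detector false-positive
rate and power, latency-recovery accuracy, type-I error of the statistical
tests under their nulls, and moment/correlation calibration of the cohort
generator.  They are exercised by the validation suite and by the
reproduction script; each takes an explicit seed and returns plain floats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import locomotor, sensory, stats
from .synthetic import (
    CohortGenParams,
    LocomotorGenParams,
    SensoryGenParams,
    child_rng,
    gen_behavior_cohort,
    gen_locomotor_session,
    gen_sensory_session,
)

__all__ = [
    "sensory_false_positive_rate",
    "sensory_power",
    "locomotor_latency_recovery",
    "type_one_error_one_way",
    "type_one_error_factorial",
    "type_one_error_glm",
    "cohort_mean_recovery",
    "correlation_recovery",
    "printed_df_structure",
]


def sensory_false_positive_rate(n_neurons: int = 1000, background_rate: float = 5.0,
                                seed: int = 0) -> float:
    """Fraction of pure-Poisson neurons the sensory classifier flags."""
    session, _ = gen_sensory_session(
        SensoryGenParams(seed=seed, n_neurons=n_neurons, prop_responsive=0.0,
                         background_rate=background_rate)
    )
    loc = session.events["label"].iloc[0]
    hits = sum(
        sensory.detect_response(session, nid, loc).significant
        for nid in session.neuron_ids
    )
    return hits / n_neurons


def sensory_power(n_neurons: int = 200, magnitude: float = 3.0,
                  background_rate: float = 5.0, seed: int = 0) -> float:
    """Detection fraction for evoked responses of a given magnitude."""
    session, _ = gen_sensory_session(
        SensoryGenParams(seed=seed, n_neurons=n_neurons, prop_responsive=1.0,
                         evoked_magnitude=magnitude,
                         background_rate=background_rate)
    )
    loc = session.events["label"].iloc[0]
    hits = sum(
        sensory.detect_response(session, nid, loc).significant
        for nid in session.neuron_ids
    )
    return hits / n_neurons


def locomotor_latency_recovery(n_neurons: int = 200, latency_ms: float = 50.0,
                               depth: float = 3.0, seed: int = 0
                               ) -> tuple[float, int]:
    """Median detected peak latency and number of significant neurons."""
    lats = []
    for i in range(n_neurons):
        p = LocomotorGenParams(seed=(seed * 100003 + i) % 2**31, modulation_depth=depth,
                               modulation_latency=latency_ms)
        s = gen_locomotor_session(p)
        psth = locomotor.build_footfall_psth(s, "n000")
        bg = locomotor.background_rate(s, "n000")
        r = locomotor.detect_locomotor_response(psth, bg)
        if r.significant:
            lats.append(r.peak_latency_ms)
    if not lats:
        return float("nan"), 0
    return float(np.median(lats)), len(lats)


def type_one_error_one_way(reps: int = 5000, alpha: float = 0.05,
                           seed: int = 0) -> float:
    """Rejection rate of the one-way ANOVA under a Gaussian null."""
    rng = child_rng(seed, 70)
    groups = np.repeat(list("abc"), 12)
    hits = 0
    for _ in range(reps):
        df = pd.DataFrame({"g": groups, "y": rng.normal(size=36)})
        hits += stats.one_way_anova(df, "g", "y").effect("g")["p"] < alpha
    return hits / reps


def type_one_error_factorial(reps: int = 5000, alpha: float = 0.05,
                             seed: int = 0) -> float:
    """Rejection rate of the 2×2 factorial interaction under the null."""
    rng = child_rng(seed, 71)
    a = np.repeat([0, 1], 20)
    b = np.tile(np.repeat([0, 1], 10), 2)
    hits = 0
    for _ in range(reps):
        df = pd.DataFrame({"a": a, "b": b, "y": rng.normal(size=40)})
        hits += stats.factorial_anova(df, ["a", "b"], "y").effect("a*b")["p"] < alpha
    return hits / reps


def type_one_error_glm(reps: int = 5000, alpha: float = 0.05,
                       seed: int = 0) -> float:
    """Rejection rate of the binomial-GLM interaction Wald test (null)."""
    rng = child_rng(seed, 72)
    g = np.repeat([0, 1], 120)
    w = np.tile(np.repeat([0, 4, 8, 12], 30), 2)
    hits = 0
    for _ in range(reps):
        y = (rng.uniform(size=240) < 0.3).astype(int)
        df = pd.DataFrame({"g": g, "w": w, "y": y})
        hits += stats.binomial_glm_interaction(df, "y", "g", "w").p < alpha
    return hits / reps


def cohort_mean_recovery(reps: int = 1000, group: str = "complete",
                         week: int = 12, measure: str = "pct_wss",
                         seed: int = 0) -> tuple[float, float]:
    """Replicate-mean of a cohort cell and its standard error.

    Used to check the generator against its configured group statistic
    (e.g. week-12 complete-therapy %WSS).
    """
    means = []
    for i in range(reps):
        c = gen_behavior_cohort(CohortGenParams(seed=(seed * 9973 + i) % 2**31))
        sel = c[(c["group"] == group) & (c["week"] == week)]
        means.append(float(sel[measure].mean()))
    return float(np.mean(means)), float(np.std(means, ddof=1) / np.sqrt(reps))


def correlation_recovery(reps: int = 500, target_r: float = 0.6,
                         seed: int = 0) -> float:
    """Mean empirical Pearson r between trunk area and week-12 %WSS."""
    rs = []
    for i in range(reps):
        c = gen_behavior_cohort(
            CohortGenParams(seed=(seed * 7919 + i) % 2**31, corr_map_behavior=target_r)
        )
        w12 = c[c["week"] == 12].dropna(subset=["pct_wss", "trunk_area_mm2"])
        rs.append(stats.pearson_with_bisquare(
            w12["trunk_area_mm2"], w12["pct_wss"]).r)
    return float(np.mean(rs))


def printed_df_structure(seed: int = 0) -> dict[str, tuple[int, int] | int]:
    """Degrees-of-freedom pairs of every test run at the study's sample sizes.

    Generates one synthetic cohort with the study's group sizes and
    missingness, runs each analysis, and returns the (df_num, df_den) pair
    per test.
    """
    from . import axons, behavior
    from .synthetic import AxonGenParams, gen_axon_counts

    cohort = gen_behavior_cohort(CohortGenParams(seed=seed))
    out: dict[str, tuple[int, int]] = {}

    wss = stats.mixed_anova(cohort[cohort["week"].isin([4, 8, 12])],
                            dv="pct_wss", between="group", within="week",
                            subject="animal_id")
    out["wss_time_by_therapy"] = wss.df_pair("group*week")

    bbb = behavior.normalize_bbb(cohort)
    bbb_aov = stats.mixed_anova(bbb, dv="bbb_norm", between="group",
                                within="week", subject="animal_id")
    out["bbb_time_by_therapy"] = bbb_aov.df_pair("group*week")

    out["bbb_week2_oneway"] = stats.one_way_anova(
        cohort[cohort["week"] == 2], "group", "bbb"
    ).df_pair("group")

    fp = cohort.dropna(subset=["failure_point_pct"])
    out["failure_point_time_by_therapy"] = stats.mixed_anova(
        fp, dv="failure_point_pct", between="group", within="week",
        subject="animal_id"
    ).df_pair("group*week")

    # motor maps: 10 sham / 12 partial / 14 complete animals, 3 locations
    from .synthetic import gen_motor_map
    from . import motormap

    rows = []
    k = 0
    for grp, n in {"sham": 10, "partial": 12, "complete": 14}.items():
        for _ in range(n):
            m = gen_motor_map(grp, seed=(seed * 4721 + k) % 2**31)
            k += 1
            for mv in ("trunk", "forelimb", "vibrissae"):
                rows.append({"animal": f"m{k}", "group": grp, "movement": mv,
                             "area_mm2": motormap.map_area(m, mv)})
    out["map_location_by_therapy"] = stats.mixed_anova(
        pd.DataFrame(rows), dv="area_mm2", between="group",
        within="movement", subject="animal"
    ).df_pair("group*movement")

    dens = axons.level_group_table(gen_axon_counts(AxonGenParams(seed=seed)))
    aov = stats.factorial_anova(dens, ["level", "therapy"], "density")
    out["axon_level"] = aov.df_pair("level")
    out["axon_therapy"] = aov.df_pair("therapy")

    # responding cells: 2 therapies x 4 weeks, neurons as samples
    rng = child_rng(seed, 73)
    rows = []
    probs = {"sham": [0.10, 0.10, 0.10, 0.12],
             "complete": [0.10, 0.22, 0.38, 0.45]}
    for grp, ps in probs.items():
        for wk, p in zip((0, 4, 8, 12), ps):
            y = (rng.uniform(size=200) < p).astype(int)
            rows += [{"group": grp, "week": wk, "responding": int(v)} for v in y]
    glm = stats.binomial_glm_interaction(pd.DataFrame(rows), "responding",
                                         "group", "week")
    out["responding_glm_wald_df"] = glm.df  # single χ² df
    return out
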