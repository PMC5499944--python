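"""Orchestration of the three experiment analogs on synthetic cohorts.

Experiment 1 — behavioral recovery and motor-map reorganization: %WSS and
open-field trajectories, failure point, performer split, ICMS map areas per
therapy group, trunk-area ↔ behavior correlation.

Experiment 2 — corticospinal sprouting: per-slice axon densities and the
level × therapy factorial analysis with post-hoc contrasts.

Experiment 3 — somatosensory reorganization: percent of hindlimb-cortex
neurons responding to forepaw stimulation per therapy × week with the
binomial-GLM interaction test, quadrant response magnitudes, and the awake
footfall-locked latency distribution.

Every run is fully determined by the master seed and writes its result
tables as CSV plus a JSON provenance record sufficient to replay it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import axons, behavior, locomotor, motormap, sensory, stats
from .synthetic import (
    AxonGenParams,
    CohortGenParams,
    LocomotorGenParams,
    SensoryGenParams,
    child_rng,
    gen_axon_counts,
    gen_behavior_cohort,
    gen_locomotor_session,
    gen_motor_map,
    gen_sensory_session,
)

log = logging.getLogger("recortex")

__all__ = ["RunConfig", "run_experiment1", "run_experiment2",
           "run_experiment3", "run_all"]


@dataclass
class RunConfig:
    """Master configuration of a pipeline run.

    Analysis constants default to the study's values (PSTH windows and
    binsizes, the 3-SD / 3-bin / p<0.001 sensory criteria, the 99% CI
    locomotor threshold, α = 0.05 with Bonferroni over the four quadrants);
    generator blocks default to the printed group statistics.
    """

    seed: int = 0
    outdir: str = "results"
    alpha: float = 0.05
    n_quadrant_tests: int = 4
    # experiment-3 synthetic design: ~33 neurons/day/animal over 6-8
    # animals gives on the order of 200 neurons per therapy x week cell
    n_neurons_per_cell: int = 200
    responding_prob: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "sham": {0: 0.10, 4: 0.10, 8: 0.10, 12: 0.12},
            "complete": {0: 0.10, 4: 0.22, 8: 0.38, 12: 0.45},
        }
    )
    n_locomotor_neurons: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "responding_prob" in raw:
            raw["responding_prob"] = {
                g: {int(w): float(p) for w, p in d.items()}
                for g, d in raw["responding_prob"].items()
            }
        return cls(**raw)

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


def _outdir(config: RunConfig, name: str) -> Path:
    d = Path(config.outdir) / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_provenance(d: Path, config: RunConfig, extra: dict | None = None) -> None:
    rec = {"config": config.provenance()}
    if extra:
        rec.update(extra)
    (d / "provenance.json").write_text(json.dumps(rec, indent=1, default=str))


def run_experiment1(config: RunConfig) -> dict:
    """Behavioral + motor-map analysis (treadmill, open field, ICMS maps)."""
    d = _outdir(config, "experiment1")
    log.info("experiment 1: behavioral cohort + motor maps")
    cohort = gen_behavior_cohort(CohortGenParams(seed=config.seed))
    if cohort.empty:
        raise ValueError("empty cohort")
    cohort.to_csv(d / "cohort.csv", index=False)

    wss = stats.mixed_anova(cohort[cohort["week"].isin([4, 8, 12])],
                            dv="pct_wss", between="group", within="week",
                            subject="animal_id")
    bbb_norm = behavior.normalize_bbb(cohort)
    # all four evaluation weeks enter the open-field model (baseline week
    # included as its own repeated level, normalized to 0% change)
    bbb_aov = stats.mixed_anova(bbb_norm, dv="bbb_norm", between="group",
                                within="week", subject="animal_id")
    bbb_w2 = stats.one_way_anova(cohort[cohort["week"] == 2], "group", "bbb")
    # failure points are generated already normalized to the week-2 support
    fp = cohort.dropna(subset=["failure_point_pct"])
    fp_aov = stats.mixed_anova(fp[fp["week"].isin([4, 8, 12])],
                               dv="failure_point_pct", between="group",
                               within="week", subject="animal_id")
    support = {
        int(w): behavior.weight_support_proportion(cohort, w)
        for w in (2, 12)
    }
    split = behavior.performer_split(cohort, week=12)

    # ICMS maps in the mapped subset (10 sham / 12 partial / 14 complete)
    mapped_n = {"sham": 10, "partial": 12, "complete": 14}
    rows = []
    k = 0
    for group, n in mapped_n.items():
        for _ in range(n):
            m = gen_motor_map(group, seed=(config.seed * 10007 + k) % 2**31)
            k += 1
            for mv in ("trunk", "forelimb", "vibrissae"):
                rows.append({"animal": f"map{k:02d}", "group": group,
                             "movement": mv,
                             "area_mm2": motormap.map_area(m, mv)})
    areas = pd.DataFrame(rows)
    areas.to_csv(d / "map_areas.csv", index=False)
    area_aov = stats.mixed_anova(areas, dv="area_mm2", between="group",
                                 within="movement", subject="animal")
    trunk_tukey = stats.tukey_posthoc(
        areas[areas["movement"] == "trunk"], "group", "area_mm2"
    )

    w12 = cohort[cohort["week"] == 12].dropna(subset=["pct_wss", "trunk_area_mm2"])
    corr = motormap.area_behavior_correlation(w12["trunk_area_mm2"], w12["pct_wss"])

    tables = {
        "wss_mixed_anova": wss.table,
        "bbb_mixed_anova": bbb_aov.table,
        "bbb_week2_anova": bbb_w2.table,
        "failure_point_anova": fp_aov.table,
        "map_area_anova": area_aov.table,
        "trunk_area_tukey": trunk_tukey,
    }
    for name, t in tables.items():
        t.to_csv(d / f"{name}.csv", index=False)
    summary = {
        "wss_interaction_df": wss.df_pair("group*week"),
        "bbb_interaction_df": bbb_aov.df_pair("group*week"),
        "bbb_week2_df": bbb_w2.df_pair("group"),
        "failure_point_df": fp_aov.df_pair("group*week"),
        "map_area_df": area_aov.df_pair("group*movement"),
        "weight_support_proportion": support,
        "n_performers": int((split == "performer").sum()),
        "trunk_behavior_r": corr.r,
        "trunk_behavior_p": corr.p,
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    _write_provenance(d, config)
    return {"anova": tables, "summary": summary, "cohort": cohort}


def run_experiment2(config: RunConfig) -> dict:
    """Axon-density analysis (tract-tracing analog)."""
    d = _outdir(config, "experiment2")
    log.info("experiment 2: axon densities")
    counts = gen_axon_counts(AxonGenParams(seed=config.seed))
    counts.to_csv(d / "axon_counts.csv", index=False)
    dens = axons.level_group_table(counts)
    dens.to_csv(d / "axon_densities.csv", index=False)
    aov = stats.factorial_anova(dens, ["level", "therapy"], "density")
    tukey_level = stats.tukey_posthoc(dens, "level", "density")
    tukey_therapy = stats.tukey_posthoc(dens, "therapy", "density")
    aov.table.to_csv(d / "axon_anova.csv", index=False)
    tukey_level.to_csv(d / "tukey_level.csv", index=False)
    tukey_therapy.to_csv(d / "tukey_therapy.csv", index=False)
    summary = {
        "n_rows": len(dens),
        "level_df": aov.df_pair("level"),
        "therapy_df": aov.df_pair("therapy"),
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    _write_provenance(d, config)
    return {"anova": aov, "densities": dens, "summary": summary}


def run_experiment3(config: RunConfig) -> dict:
    """Sensory/locomotor PSTH analysis (somatosensory-map analog)."""
    d = _outdir(config, "experiment3")
    log.info("experiment 3: PSTH response detection")
    layout = sensory.ArrayLayout()
    rng = child_rng(config.seed, 30)
    neuron_rows = []
    sub = 0
    for group, by_week in config.responding_prob.items():
        for week, p_resp in by_week.items():
            params = SensoryGenParams(
                n_neurons=config.n_neurons_per_cell,
                prop_responsive=p_resp,
                seed=(config.seed * 40009 + sub) % 2**31,
            )
            sub += 1
            session, truth = gen_sensory_session(params)
            for nid in session.neuron_ids:
                res = sensory.detect_response(session, nid, params.location)
                neuron_rows.append(
                    {
                        "group": group, "week": week, "neuron_id": nid,
                        "wire": int(rng.integers(16)),
                        "location": params.location,
                        "significant": res.significant,
                        "magnitude": res.magnitude,
                        "truth": truth[nid],
                    }
                )
    results = pd.DataFrame(neuron_rows)
    results.to_csv(d / "sensory_results.csv", index=False)
    pct = (
        results.groupby(["group", "week"])["significant"].mean().rename("responding")
    ).reset_index()
    pct.to_csv(d / "percent_responding.csv", index=False)
    results["responding"] = results["significant"].astype(int)
    glm = stats.binomial_glm_interaction(results, "responding", "group", "week")
    quad = (
        results[results["week"] == 12]
        .groupby("group")
        .apply(lambda g: sensory.quadrant_magnitudes(g, layout),
               include_groups=False)
    )
    quad.to_csv(d / "quadrant_magnitudes.csv")
    alpha_quad = stats.bonferroni_alpha(config.alpha, config.n_quadrant_tests)

    loco_latencies = []
    for i in range(config.n_locomotor_neurons):
        p = LocomotorGenParams(seed=(config.seed * 50021 + i) % 2**31)
        s = gen_locomotor_session(p)
        psth = locomotor.build_footfall_psth(s, "n000")
        bg = locomotor.background_rate(s, "n000")
        loco_latencies.append(locomotor.detect_locomotor_response(psth, bg))
    latencies = locomotor.peak_latency_distribution(loco_latencies)
    pd.DataFrame({"peak_latency_ms": latencies}).to_csv(
        d / "locomotor_latencies.csv", index=False
    )
    summary = {
        "glm_wald_chi2": glm.wald_chi2,
        "glm_df": glm.df,
        "glm_p": glm.p,
        "bonferroni_alpha": alpha_quad,
        "n_significant_locomotor": int(len(latencies)),
        "median_peak_latency_ms": float(np.median(latencies)) if len(latencies) else None,
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    _write_provenance(d, config)
    return {"results": results, "glm": glm, "quadrants": quad,
            "latencies": latencies, "summary": summary}


def run_all(config: RunConfig) -> dict:
    """All three experiment analogs in the study's order."""
    return {
        "experiment1": run_experiment1(config),
        "experiment2": run_experiment2(config),
        "experiment3": run_experiment3(config),
    }
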