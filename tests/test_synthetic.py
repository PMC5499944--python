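import numpy as np
import pandas as pd
import pytest

from recortex import motormap
from recortex.synthetic import (
    AxonGenParams,
    CohortGenParams,
    DEFAULT_GROUP_WEEK_STATS,
    LocomotorGenParams,
    MotorMapGenParams,
    SensoryGenParams,
    gen_axon_counts,
    gen_behavior_cohort,
    gen_locomotor_session,
    gen_motor_map,
    gen_sensory_session,
    gen_step_log,
)


class TestSensoryGenerator:
    def test_same_seed_identical_spikes(self):
        p = SensoryGenParams(seed=42, n_neurons=5)
        s1, t1 = gen_sensory_session(p)
        s2, t2 = gen_sensory_session(SensoryGenParams(seed=42, n_neurons=5))
        assert t1 == t2
        for nid in s1.neuron_ids:
            np.testing.assert_array_equal(s1.spikes[nid], s2.spikes[nid])

    def test_zero_magnitude_labels_all_nonresponsive(self):
        p = SensoryGenParams(seed=1, evoked_magnitude=0.0, n_neurons=8,
                             prop_responsive=1.0)
        session, truth = gen_sensory_session(p)
        assert not any(truth.values())
        # expected spike count = background_rate * duration within 4 sigma
        for nid in session.neuron_ids:
            lam = p.background_rate * session.duration
            assert abs(len(session.spikes[nid]) - lam) < 4 * np.sqrt(lam)

    def test_evoked_spike_budget_matches_poisson_expectation(self):
        # magnitude 2.0 x 100 trials -> 200 expected evoked spikes
        p0 = SensoryGenParams(background_rate=10.0, evoked_magnitude=2.0,
                              n_neurons=1, prop_responsive=1.0)
        extras = []
        for seed in range(100):
            s_on, _ = gen_sensory_session(
                SensoryGenParams(**{**p0.__dict__, "seed": seed})
            )
            s_off, _ = gen_sensory_session(
                SensoryGenParams(**{**p0.__dict__, "seed": seed,
                                    "evoked_magnitude": 0.0})
            )
            extras.append(len(s_on.spikes["n000"]) - len(s_off.spikes["n000"]))
        mean = np.mean(extras)
        se = np.std(extras, ddof=1) / np.sqrt(len(extras))
        assert abs(mean - 200.0) < 3 * se

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="background_rate"):
            gen_sensory_session(SensoryGenParams(background_rate=-1.0))


class TestLocomotorGenerator:
    def test_unmodulated_counts_are_poisson_in_peri_windows(self):
        p = LocomotorGenParams(seed=9, modulation_depth=0.0,
                               background_rate=20.0)
        s = gen_locomotor_session(p)
        t = s.spikes["n000"]
        counts = [
            np.sum((t >= ev - 0.25) & (t < ev + 0.25))
            for ev in s.event_times()
        ]
        lam = p.background_rate * 0.5
        mean = np.mean(counts)
        assert abs(mean - lam) < 4 * np.sqrt(lam / len(counts))

    def test_peak_of_average_rate_at_injected_latency(self):
        # aggregate many footfalls; peak within one 10 ms bin of +50 ms
        from recortex.session import bin_relative_times

        counts = np.zeros(50)
        n_events = 0
        for seed in range(12):
            p = LocomotorGenParams(seed=seed, modulation_depth=3.0,
                                   modulation_latency=50.0,
                                   n_footfalls=600, record_duration=600.0)
            s = gen_locomotor_session(p)
            psth = bin_relative_times(s.spikes["n000"], s.event_times(),
                                      (-250.0, 250.0), 10.0)
            counts += psth.counts
            n_events += psth.n_trials
        assert n_events >= 7000
        peak_center = (np.arange(50) * 10 - 250 + 5)[np.argmax(counts)]
        assert abs(peak_center - 50.0) <= 10.0

    def test_no_footfalls_is_a_valid_session(self):
        s = gen_locomotor_session(
            LocomotorGenParams(seed=0, n_footfalls=0, record_duration=600.0)
        )
        assert len(s.event_times()) == 0
        assert s.duration == 600.0

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError, match="modulation_depth"):
            gen_locomotor_session(LocomotorGenParams(modulation_depth=-0.5))


class TestMotorMapGenerator:
    def test_zero_trunk_probability_zero_area(self):
        p = MotorMapGenParams(p_trunk=0.0, seed=3)
        m = gen_motor_map("custom", params=p)
        assert motormap.map_area(m, "trunk") == 0.0

    def test_all_trunk_grid_area_is_sites_times_quarter(self):
        # 5x6 grid fully trunk -> 30 x 0.25 = 7.5 mm^2
        grid = motormap.GridSpec(ap_min=0.0, ap_max=2.0, ml_min=1.0, ml_max=3.5)
        p = MotorMapGenParams(p_trunk=1.0, p_forelimb=0, p_vibrissae=0,
                              grid=grid, seed=1)
        m = gen_motor_map("custom", params=p)
        assert grid.n_ap * grid.n_ml == 30
        assert motormap.map_area(m, "trunk") == pytest.approx(7.5)

    def test_complete_therapy_expands_trunk_over_sham(self):
        from scipy import stats as sps

        areas = {g: [] for g in ("sham", "complete")}
        for seed in range(200):
            for g in areas:
                areas[g].append(motormap.map_area(gen_motor_map(g, seed=seed),
                                                  "trunk"))
        t, p = sps.ttest_ind(areas["complete"], areas["sham"])
        assert np.mean(areas["complete"]) > np.mean(areas["sham"])
        assert p / 2 < 0.01  # one-sided


class TestCohortGenerator:
    def test_zero_sd_gives_exact_group_means(self):
        stats_ = {
            "pct_wss": {g: {4: (10.0, 0.0), 12: (20.0, 0.0)}
                        for g in ("sham", "partial", "complete")}
        }
        c = gen_behavior_cohort(CohortGenParams(group_week_stats=stats_, seed=0))
        obs = c.dropna(subset=["pct_wss"])
        assert np.allclose(obs.loc[obs.week == 4, "pct_wss"], 10.0)
        assert np.allclose(obs.loc[obs.week == 12, "pct_wss"], 20.0)

    def test_generator_is_moment_calibrated(self):
        # complete-therapy week-12 %WSS replicate mean vs configured 19.4
        target = DEFAULT_GROUP_WEEK_STATS["pct_wss"]["complete"][12][0]
        means = []
        for seed in range(150):
            c = gen_behavior_cohort(CohortGenParams(seed=seed))
            sel = c[(c.group == "complete") & (c.week == 12)]
            means.append(sel["pct_wss"].mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - target) < 3 * se

    def test_impossible_bounds_rejected(self):
        stats_ = {"bbb": {"sham": {2: (25.0, 1.0)},
                          "partial": {2: (5.0, 1.0)},
                          "complete": {2: (5.0, 1.0)}}}
        with pytest.raises(ValueError, match="outside bounds"):
            gen_behavior_cohort(CohortGenParams(group_week_stats=stats_))

    def test_design_missingness_matches_study(self, cohort):
        wss12 = cohort[(cohort.week == 12)].dropna(subset=["pct_wss"])
        assert len(wss12) == 44
        wss8 = cohort[(cohort.week == 8)].dropna(subset=["pct_wss"])
        assert len(wss8) == 42        # two partial-therapy animals missing
        fp = cohort.dropna(subset=["failure_point_pct"])
        assert fp["animal_id"].nunique() == 39


class TestStepLogGenerator:
    @pytest.mark.parametrize("p,expected", [(1.0, 100.0), (0.0, 0.0)])
    def test_extreme_support_probabilities(self, p, expected):
        from recortex.behavior import percent_wss

        log = gen_step_log(n_cycles=100, p_support=p, seed=0)
        assert percent_wss(log).pct == expected

    def test_binomial_expectation_of_support_rate(self):
        from recortex.behavior import percent_wss

        vals = [
            percent_wss(gen_step_log(n_cycles=100, p_support=0.25, seed=s)).pct
            for s in range(60)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 25.0) < 3 * se

    def test_ground_truth_consistent_with_flags(self):
        log = gen_step_log(n_cycles=200, p_support=0.3, seed=4)
        flags = [f"{paw}_{c}" for paw in ("left", "right") for c in "abcde"]
        derived = log[flags].all(axis=1)
        pd.testing.assert_series_equal(
            derived, log["supported_truth"], check_names=False
        )


class TestAxonGenerator:
    def test_zero_rate_gives_zero_counts(self):
        p = AxonGenParams(rates={"sham": {"T1": 0.0, "T4": 0.0, "T7": 0.0}})
        assert (gen_axon_counts(p)["count"] == 0).all()

    def test_fixed_seed_reproducible(self):
        a = gen_axon_counts(AxonGenParams(seed=5))
        b = gen_axon_counts(AxonGenParams(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_design_shape(self):
        df = gen_axon_counts(AxonGenParams())
        assert len(df) == 90  # 3 groups x 2 animals x 3 levels x 5 slices
        assert set(df["level"]) == {"T1", "T4", "T7"}
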