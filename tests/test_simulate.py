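"""Synthetic-cohort generator: design counts, behaviour model, BOLD
structure, confounds, structural matrices and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from wmnet.simulate import (BehaviorParams, CohortConfig, GroundTruth,
                            SubjectSpec, draw_subject_spec, generate_cohort,
                            generate_structural_matrix, generate_trial_table,
                            load_cohort, simulate_behavior,
                            simulate_timeseries, stage_rng)

PARAMS = BehaviorParams()


def _spec(start=4, **kw):
    return SubjectSpec(1, start, start + 1.5, **kw)


class TestTrialTable:
    def test_counts_probes_and_determinism(self):
        t1 = generate_trial_table(_spec(), np.random.default_rng(0))
        t2 = generate_trial_table(_spec(), np.random.default_rng(0))
        assert t1.equals(t2)
        assert len(t1) == 120
        assert t1.groupby("level").size().tolist() == [30, 30, 30, 30]
        assert t1["probe_type"].value_counts().to_dict() == {
            "valid": 48, "invalid": 48, "new": 24}
        # levels balanced within runs too (7 or 8 each)
        per_run = t1.groupby(["run", "level"]).size()
        assert per_run.min() >= 7 and per_run.max() <= 8

    def test_timing_fits_the_run(self):
        t = generate_trial_table(_spec(6), np.random.default_rng(1))
        for _, run in t.groupby("run"):
            assert (run["onset_probe"] + 4.0 <= 508.0 + 1e-9).all()
            assert run["onset_array"].is_monotonic_increasing
            assert run["iti"].between(2.0, 10.0).all()
        assert abs(t["iti"].mean() - 5.0) < 1.0

    def test_abs_size_tracks_level_and_steps_recorded(self):
        t = generate_trial_table(_spec(5), np.random.default_rng(2))
        assert (t["abs_set_size"] == 5 + t["level"] - 1).all()
        assert t["steps"].between(0, 8).all()
        assert (t["letters"].str.len() == t["abs_set_size"]).all()


class TestBehavior:
    @pytest.mark.parametrize("level,steps,p_true", [
        (1, 0, expit(PARAMS.acc_intercept + PARAMS.acc_set_size)),   # ~0.959
        (4, 7, expit(PARAMS.acc_intercept + 4 * PARAMS.acc_set_size
                     + 7 * PARAMS.acc_steps
                     + 28 * PARAMS.acc_interaction)),                # ~0.498
    ])
    def test_accuracy_probabilities_match_linear_predictor(self, level, steps,
                                                           p_true):
        n = 6000
        table = pd.DataFrame({"level": level, "steps": steps,
                              "run": 1, "trial": np.arange(n)})
        out = simulate_behavior(table, PARAMS, _spec(), np.random.default_rng(8))
        rate = out.loc[out["responded"], "correct"].mean()
        assert abs(rate - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n) + 0.005

    def test_rt_mean_matches_linear_model(self):
        n = 4000
        table = pd.DataFrame({"level": 1, "steps": 0, "run": 1,
                              "trial": np.arange(n)})
        out = simulate_behavior(table, PARAMS, _spec(), np.random.default_rng(9))
        expected = PARAMS.rt_intercept + PARAMS.rt_set_size  # ~1413.5 ms
        assert abs(out["rt_ms"].mean() - expected) < 20
        assert out["rt_ms"].max() <= 4000.0

    def test_non_response_rate_and_exclusions(self, behavior_cohort):
        tt = behavior_cohort.trial_table
        rate = 1.0 - tt["responded"].mean()
        assert 0.008 < rate < 0.026  # ~1.6% of 4920 trials
        assert tt.loc[~tt["responded"], "rt_ms"].isna().all()


class TestTimeseries:
    def test_shapes_and_finite(self, small_cohort):
        bundle = small_cohort.subjects[0].bundle
        assert sorted(bundle) == [1, 2, 3, 4]
        sig = bundle[1]["signal"]
        assert sig.shape == (254, 120) and np.isfinite(sig).all()
        assert list(bundle[1]["confounds"].columns) == [
            "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
            "wm", "csf"]

    def test_noise_sd_conserved_at_zero_signal(self):
        """With no task signal the series SD matches the configured noise."""
        rng = np.random.default_rng(3)
        truth = GroundTruth.default(
            rng, n_rois=40, nodes_per_network=4,
            base_amp=np.zeros(40), amp_set=np.zeros(4), amp_steps=np.zeros(4),
            w_maint=0.0, w_manip=0.0, static_sd=0.0, recon_sd=0.0,
            confound_mix_sd=0.0, noise_sd=1.0)
        spec = _spec()
        trials = generate_trial_table(spec, rng)
        trials = simulate_behavior(trials, PARAMS, spec, rng)
        bundle = simulate_timeseries(trials, truth, spec, rng)
        sds = np.concatenate([b["signal"].std(axis=0) for b in bundle.values()])
        assert abs(sds.mean() - 1.0) < 0.05

    def test_latent_coupling_declines_with_level(self):
        """Per-trial latent correlations follow rho(level)."""
        rng = np.random.default_rng(4)
        truth = GroundTruth.default(rng, n_rois=30, nodes_per_network=4)
        spec = _spec()
        lat = []
        for i in range(30):
            trials = generate_trial_table(spec, np.random.default_rng(i))
            trials = simulate_behavior(trials, PARAMS, spec,
                                       np.random.default_rng(i))
            bundle = simulate_timeseries(trials, truth, spec,
                                         np.random.default_rng(i))
            lat.extend(entry["latents"] for entry in bundle.values())
        lat = pd.concat(lat)
        est = lat.groupby("level").apply(
            lambda g: np.corrcoef(g["lam_maint"], g["lam_manip"])[0, 1],
            include_groups=False)
        assert est.loc[1.0] > est.loc[4.0]
        assert (est < 0).all()


class TestStructural:
    def test_bounds_and_margin(self, rng):
        truth = GroundTruth.default(rng, n_rois=60, nodes_per_network=6)
        fa = generate_structural_matrix(truth, rng)
        assert fa.min() >= 0.0 and fa.max() <= 1.0
        assert np.allclose(fa, fa.T)

    def test_zero_margin_centres_difference(self, rng):
        truth = GroundTruth.default(rng, n_rois=60, nodes_per_network=6)
        diffs = []
        for i in range(40):
            fa = generate_structural_matrix(truth, np.random.default_rng(i),
                                            margin=0.0)
            k = 6
            iu = np.triu_indices(k, 1)
            within = 0.5 * (fa[:k, :k][iu].mean() + fa[k:, k:][iu].mean())
            diffs.append(within - fa[:k, k:].mean())
        t, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01

    def test_default_margin_detectable_across_29_subjects(self, rng):
        truth = GroundTruth.default(rng, n_rois=60, nodes_per_network=6)
        k = 6
        iu = np.triu_indices(k, 1)
        within, between = [], []
        for i in range(29):
            fa = generate_structural_matrix(truth, np.random.default_rng(100 + i))
            within.append(0.5 * (fa[:k, :k][iu].mean() + fa[k:, k:][iu].mean()))
            between.append(fa[:k, k:].mean())
        t, p = stats.ttest_rel(within, between)
        assert t > 0 and p / 2 < 1e-3  # one-sided


class TestCohort:
    def test_default_cohort_shape(self, behavior_cohort):
        tt = behavior_cohort.trial_table
        assert len(tt) == 41 * 120 == 4920
        starts = {s.spec.starting_set_size for s in behavior_cohort.subjects}
        assert starts <= {3, 4, 5, 6}

    def test_subject_spec_criterion_consistent_with_start(self, rng):
        for i in range(50):
            spec = draw_subject_spec(i, stage_rng(0, "spec", i))
            assert spec.starting_set_size + 1 <= spec.criterion_set_size
            assert spec.criterion_set_size < spec.starting_set_size + 2
            assert spec.reconfiguration_gain >= 0

    def test_same_seed_identical_manifest(self, tmp_path):
        cfg = CohortConfig.behavior_only(n_subjects=3)
        p1 = generate_cohort(cfg, master_seed=5).write(tmp_path / "a")
        p2 = generate_cohort(cfg, master_seed=5).write(tmp_path / "b")
        assert (p1 / "manifest.json").read_text() == (p2 / "manifest.json").read_text()
        assert (p1 / "trials.tsv").read_bytes() == (p2 / "trials.tsv").read_bytes()

    def test_write_load_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_subjects=2, n_rois=30, nodes_per_network=3)
        cohort = generate_cohort(cfg, master_seed=9)
        cohort.write(tmp_path / "c")
        back = load_cohort(tmp_path / "c")
        assert len(back.subjects) == 2
        s0, b0 = cohort.subjects[0], back.subjects[0]
        assert b0.spec.criterion_set_size == pytest.approx(
            s0.spec.criterion_set_size)
        pd.testing.assert_frame_equal(
            b0.trials, s0.trials, check_exact=False, atol=1e-9)
        np.testing.assert_allclose(b0.bundle[1]["signal"],
                                   s0.bundle[1]["signal"], atol=1e-9)
        np.testing.assert_allclose(b0.fa, s0.fa, atol=1e-9)


def test_ground_truth_validation(rng):
    with pytest.raises(ValueError):
        GroundTruth(maintenance_nodes=[1, 2], manipulation_nodes=[2, 3],
                    base_amp=np.zeros(10), amp_set=np.zeros(2),
                    amp_steps=np.zeros(2))
    with pytest.raises(ValueError):
        GroundTruth.default(rng, n_rois=20, nodes_per_network=2,
                            rho0=0.5, delta=0.5)


def test_events_export_is_bids_shaped():
    spec = _spec()
    rng = np.random.default_rng(6)
    trials = simulate_behavior(generate_trial_table(spec, rng), PARAMS, spec,
                               rng)
    from wmnet.simulate import trials_to_events
    ev = trials_to_events(trials)
    assert list(ev.columns[:3]) == ["onset", "duration", "trial_type"]
    assert len(ev) == 3 * len(trials)
    per_run = ev[ev["run"] == 1]
    assert per_run["onset"].is_monotonic_increasing
    probes = ev[ev["trial_type"] == "probe"]
    assert probes["duration"].between(0.1, 4.0).all()
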