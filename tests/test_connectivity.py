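"""cPPI estimation against naive oracles; rebinning; condition tensors."""

import numpy as np
import pandas as pd
import pytest

from wmnet.connectivity import (ConnectivityError, add_steps_levels,
                                build_condition_regressor, cppi_matrix,
                                condition_tensor, ppi_terms, rebin_steps)
from wmnet.connectivity import _run_cppi
from wmnet.glm import HRFModel, convolve_events


def naive_cppi(sig, psych, conf, i, j):
    """Independent pairwise implementation: explicit residual regression."""
    T = len(sig)
    tc = sig - sig.mean(axis=0)
    g = psych - psych.mean()
    pi, pj = tc[:, i] * g, tc[:, j] * g
    Z = np.column_stack([np.ones(T), g, sig[:, i], sig[:, j], conf])
    ri = pi - Z @ np.linalg.lstsq(Z, pi, rcond=None)[0]
    rj = pj - Z @ np.linalg.lstsq(Z, pj, rcond=None)[0]
    return np.corrcoef(ri, rj)[0, 1]


class TestRebin:
    def test_even_split_in_steps_order(self):
        t = pd.DataFrame({"steps": [0, 0, 1, 1, 2, 2, 3, 3]})
        assert list(rebin_steps(t)) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_120_trials_30_per_bin(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"steps": rng.integers(0, 8, size=120)})
        lv = rebin_steps(t)
        assert lv.value_counts().tolist() == [30, 30, 30, 30]
        # bins ordered by steps
        assert t.loc[lv == 1, "steps"].max() <= t.loc[lv == 4, "steps"].min() + 7

    def test_stable_tie_break_by_trial_order(self):
        t = pd.DataFrame({"steps": [1, 1, 1, 1, 2, 2, 2, 2]})
        lv = rebin_steps(t)
        # earlier trials fill the lower bins within the tied block
        assert list(lv) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_degenerate_single_value_rejected(self):
        with pytest.raises(ConnectivityError):
            rebin_steps(pd.DataFrame({"steps": [2, 2, 2, 2]}))

    def test_per_subject_rebin(self, behavior_cohort):
        tt = add_steps_levels(behavior_cohort.trial_table)
        counts = tt.groupby(["subject", "steps_level"]).size()
        assert counts.min() == counts.max() == 30


class TestConditionRegressor:
    def _table(self, levels):
        onsets = 3.0 + 20.0 * np.arange(len(levels))
        return pd.DataFrame({"onset_delay": onsets, "level": levels})

    def test_empty_level_errors(self):
        with pytest.raises(ConnectivityError):
            build_condition_regressor(self._table([1, 1, 2]), "set_size", 4)

    def test_all_trials_one_level_equals_demeaned_delay(self):
        t = self._table([2] * 8)
        reg = build_condition_regressor(t, "set_size", 2)
        ref = convolve_events(t["onset_delay"], 5.0, HRFModel())
        np.testing.assert_allclose(reg, ref - ref.mean(), atol=1e-12)
        assert abs(reg.mean()) < 1e-12

    def test_unknown_demand_rejected(self):
        with pytest.raises(ConnectivityError):
            build_condition_regressor(self._table([1]), "difficulty", 1)


class TestCPPI:
    def test_matches_naive_oracle_small_instance(self):
        """Partial correlation equals brute-force residualisation, 1e-10."""
        rng = np.random.default_rng(5)
        sig = rng.normal(size=(20, 3))
        psych = rng.normal(size=20)
        conf = rng.normal(size=(20, 4))
        mat = _run_cppi(sig, np.arange(3), psych, conf)
        for i in range(3):
            for j in range(i + 1, 3):
                assert mat[i, j] == pytest.approx(
                    naive_cppi(sig, psych, conf, i, j), abs=1e-10)

    def test_matches_pingouin_partial_corr(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        sig = rng.normal(size=(60, 2))
        psych = rng.normal(size=60)
        conf = rng.normal(size=(60, 8))
        mat = _run_cppi(sig, np.arange(2), psych, conf)
        tc = sig - sig.mean(axis=0)
        g = psych - psych.mean()
        df = pd.DataFrame({"pi": tc[:, 0] * g, "pj": tc[:, 1] * g, "g": psych,
                           "ti": sig[:, 0], "tj": sig[:, 1],
                           **{f"c{k}": conf[:, k] for k in range(8)}})
        ref = pingouin.partial_corr(
            df, x="pi", y="pj",
            covar=["g", "ti", "tj"] + [f"c{k}" for k in range(8)])
        assert mat[0, 1] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        sig, psych, conf = (rng.normal(size=(100, 6)), rng.normal(size=100),
                            rng.normal(size=(100, 8)))
        mat = _run_cppi(sig, np.arange(6), psych, conf)
        off = ~np.eye(6, dtype=bool)
        assert np.nanmax(np.abs(mat - mat.T)) < 1e-12
        assert np.all(np.abs(mat[off]) <= 1.0)

    def test_constant_timecourse_flagged_nan(self):
        rng = np.random.default_rng(8)
        sig = rng.normal(size=(50, 3))
        sig[:, 1] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            mat = _run_cppi(sig, np.arange(3), rng.normal(size=50),
                            rng.normal(size=(50, 2)))
        assert np.isnan(mat[0, 1]) and np.isfinite(mat[0, 2])

    def test_shared_task_modulation_detected_positive(self):
        """Nodes driven by the same trialwise task amplitude correlate."""
        rng = np.random.default_rng(9)
        hrf = HRFModel()
        onsets = 3.0 + 16.0 * np.arange(15)
        X = np.stack([convolve_events([o], 5.0, hrf, run_duration=254 * 2.0)
                      for o in onsets], axis=1)
        rhos = []
        for _ in range(10):
            amp = rng.normal(size=15)
            sig = np.column_stack([
                X @ (2.0 * amp) + 0.3 * rng.normal(size=254),
                X @ (2.0 * amp) + 0.3 * rng.normal(size=254)])
            psych = X.sum(axis=1)
            mat = _run_cppi(sig, np.arange(2), psych,
                            rng.normal(size=(254, 2)))
            rhos.append(mat[0, 1])
        assert np.mean(rhos) > 0.3

    def test_independent_noise_node_near_zero(self):
        rng = np.random.default_rng(10)
        vals = []
        for _ in range(20):
            sig = rng.normal(size=(254, 2))
            psych = rng.normal(size=254)
            mat = _run_cppi(sig, np.arange(2), psych, rng.normal(size=(254, 2)))
            vals.append(mat[0, 1])
        assert abs(np.mean(vals)) < 0.05

    def test_fisher_average_invariant_to_run_order(self):
        rng = np.random.default_rng(11)
        bundle = {r: {"signal": rng.normal(size=(40, 4)),
                      "confounds": rng.normal(size=(40, 3))} for r in (1, 2, 3)}
        psych = {r: rng.normal(size=40) for r in (1, 2, 3)}
        m1 = cppi_matrix(bundle, range(4), psych)
        m2 = cppi_matrix(bundle, range(4), {r: psych[r] for r in (3, 1, 2)})
        np.testing.assert_allclose(m1, m2, atol=1e-12, equal_nan=True)


class TestConditionTensor:
    def test_eight_matrices_with_manifest(self, small_cohort, truth_partition):
        sub = small_cohort.subjects[0]
        tensor = condition_tensor(sub.bundle, truth_partition, sub.trials)
        mats = tensor["matrices"]
        assert len(mats) == 8
        for (demand, level), mat in mats.items():
            assert demand in ("set_size", "steps") and level in (1, 2, 3, 4)
            assert mat.shape == (24, 24)
            off = ~np.eye(24, dtype=bool)
            assert np.isfinite(mat[off]).all()
        counts = tensor["manifest"]["trial_counts"]
        assert sum(v for k, v in counts.items() if k.startswith("set_size")) == 120

    def test_ppi_terms_definition(self, rng):
        """PPI term is the elementwise product of the demeaned series."""
        tc = rng.normal(size=(30, 3))
        psych = rng.normal(size=30)
        terms = ppi_terms(tc, psych)
        expected = (tc - tc.mean(axis=0)) * (psych - psych.mean())[:, None]
        np.testing.assert_allclose(terms, expected, atol=1e-14)
        # for task-unrelated series the term mean (a sample covariance)
        # is near zero
        assert np.all(np.abs(terms.mean(axis=0)) < 0.5)
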