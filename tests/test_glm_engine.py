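"""Design construction, OLS estimation, filtering, and pooling."""

import warnings

import numpy as np
import pytest
from scipy import stats

from vmchoice import bold_sim as bs
from vmchoice import glm_engine as ge
from vmchoice import tasks_agents as ta
from vmchoice import valuation as vl

GLM2_NAMES = ["cs_cue", "cs_outcome", "nocs_cue", "nocs_outcome",
              "cs_cue_x_sum", "cs_cue_x_diff",
              "resp_left", "resp_left_raw", "resp_right", "resp_right_raw"]


@pytest.fixture
def session_with_regressors(lessismore_session):
    values, regs = vl.regressors_from_trials(lessismore_session)
    return lessismore_session, values, regs


class TestBuildGLM2:
    def test_ten_documented_columns(self, session_with_regressors):
        trials, _, regs = session_with_regressors
        design = ge.build_glm2(trials, regs)
        assert design.names == GLM2_NAMES
        assert design.X.shape[1] == 10

    def test_modulators_orthogonal_to_parent(self):
        # events far apart on a TR-aligned grid: centering makes the
        # modulator column exactly orthogonal to its parent event column
        rng = np.random.default_rng(8)
        n = 20
        onsets = 10.0 + np.arange(n) * 30.0
        tr = 2.0
        amps = rng.standard_normal(n)
        amps -= amps.mean()
        n_vol = int((onsets[-1] + 30.0) / tr)
        parent = bs.convolve_events(onsets, 1.0, tr=tr, n_volumes=n_vol).values
        modulated = bs.convolve_events(onsets, amps, tr=tr, n_volumes=n_vol).values
        r = parent @ modulated / np.linalg.norm(parent) / np.linalg.norm(modulated)
        assert abs(r) < 1e-10

    def test_all_cs_chosen_drops_empty_columns(self):
        cfg = ta.LessIsMoreConfig(seed=7, p_choice_csminus=0.0)
        agent = ta.SubjectiveAgent(temperature=1e-4)  # never skips, never CS-
        trials = ta.generate_lessismore_session(cfg, agent, ta.RTModel(noise_sd=0))
        _, regs = vl.regressors_from_trials(trials)
        with pytest.warns(UserWarning, match="dropped"):
            design = ge.build_glm2(trials, regs)
        assert "nocs_cue" in design.dropped and "nocs_outcome" in design.dropped

    def test_misaligned_regressors_rejected(self, session_with_regressors):
        trials, _, regs = session_with_regressors
        import dataclasses
        short = dataclasses.replace(
            regs, diff_z=regs.diff_z[:-1])
        with pytest.raises(ge.DesignError):
            ge.build_glm2(trials, short)


class TestBuildGLM1:
    def test_twenty_four_columns_with_discards(self, lessismore_session):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = ge.build_glm1(lessismore_session, discarded=[0])
        present = len(design.names) + len(design.dropped)
        assert present == 24
        # a session covering every condition and a discard keeps all 24
        covered = {ge.glm1_condition(t) for t in lessismore_session if t.index != 0}
        if covered == set(ge.GLM1_CONDITIONS):
            assert len(design.names) == 24

    def test_absent_condition_dropped_with_warning(self, greedy_session):
        # greedy agent never skips: the skip condition column is empty
        with pytest.warns(UserWarning, match="dropped"):
            design = ge.build_glm1(greedy_session)
        assert any("single_skip" in name for name in design.dropped)

    def test_cue_and_outcome_are_distinct_columns(self, lessismore_session):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = ge.build_glm1(lessismore_session)
        cue = design.column("single_HV_cue")
        out = design.column("single_HV_outcome")
        # outcome regressor lags the cue regressor by the response + delay
        lag_cue = np.argmax(cue)
        lag_out = np.argmax(out)
        assert lag_out > lag_cue
        assert not np.allclose(cue, out)


class TestFitAndContrast:
    def test_noiseless_forward_model_recovered_exactly(self, rng):
        n = 50
        onsets = np.arange(n) * 12.0 + 4
        diff_z = vl.zscore(rng.standard_normal(n))
        sum_z = vl.zscore(rng.standard_normal(n))
        bold = bs.generate_linear_roi(onsets, diff_z, sum_z,
                                      betas=bs.LinearBetas(decision=1.0, diff=-0.5,
                                                           sum=0.3, outcome=0.0))
        X = np.column_stack([
            bs.convolve_events(onsets, 1.0, tr=bold.tr, n_volumes=bold.n_volumes).values,
            bs.convolve_events(onsets, diff_z, tr=bold.tr, n_volumes=bold.n_volumes).values,
            bs.convolve_events(onsets, sum_z, tr=bold.tr, n_volumes=bold.n_volumes).values])
        design = ge.DesignMatrix(names=["dec", "diff", "sum"], X=X, tr=bold.tr,
                                 convolved=[True] * 3)
        fit = ge.fit_session(bold, design)
        np.testing.assert_allclose(fit.betas, [1.0, -0.5, 0.3], atol=1e-8)

    def test_ols_equals_normal_equations_oracle(self, rng):
        # 10-volume toy problem, no filtering
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        design = ge.DesignMatrix(names=["a", "b"], X=X, tr=1.0, convolved=[True, True])
        fit = ge.fit_session(bs.BoldSeries(values=y, tr=1.0), design,
                             highpass_cutoff=None)
        Xi = np.column_stack([X, np.ones(10)])
        oracle = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        np.testing.assert_allclose(fit.betas, oracle, atol=1e-10)

    def test_contrast_t_matches_direct_formula(self, rng):
        X = rng.standard_normal((60, 3))
        y = X @ np.array([0.5, 0.0, -0.2]) + rng.standard_normal(60)
        design = ge.DesignMatrix(names=list("abc"), X=X, tr=1.0, convolved=[True] * 3)
        fit = ge.fit_session(bs.BoldSeries(values=y, tr=1.0), design,
                             highpass_cutoff=None)
        res = ge.contrast(fit, ge.ContrastSpec("a", (1, 0, 0, 0)))
        assert res.t == pytest.approx(fit.betas[0] / np.sqrt(fit.beta_vars[0]))
        assert 0.0 <= res.p <= 1.0

    def test_rank_deficient_duplicate_column_pruned(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, x, rng.standard_normal(30)])
        design = ge.DesignMatrix(names=["a", "a_dup", "b"], X=X, tr=1.0,
                                 convolved=[True] * 3)
        with pytest.warns(UserWarning, match="pruning"):
            fit = ge.fit_session(bs.BoldSeries(values=rng.standard_normal(30), tr=1.0),
                                 design, highpass_cutoff=None)
        assert "a_dup" not in fit.names


class TestHighpass:
    def test_removes_200s_cosine_below_one_percent(self):
        t = np.arange(300) * 2.28
        for phase in (0.0, 0.7, 2.1):
            drift = np.cos(2 * np.pi * t / 200.0 + phase)
            resid = ge.highpass(drift, 2.28, cutoff=100.0)
            assert np.abs(resid).max() < 0.01

    def test_preserves_event_speed_signal(self):
        onsets = np.arange(40) * 14.0
        series = bs.convolve_events(onsets, 1.0, tr=2.28, n_volumes=260).values
        filtered = ge.highpass(series, 2.28, cutoff=100.0)
        kept = np.corrcoef(series - series.mean(), filtered)[0, 1]
        assert kept > 0.98


class TestPooling:
    def test_equal_variance_fixed_effects_is_mean(self):
        eff, var = ge.fixed_effects(np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        assert eff == pytest.approx(2.0)
        assert var == pytest.approx(1.0)

    def test_single_session_passes_through(self):
        eff, var = ge.fixed_effects(np.array([0.7]), np.array([0.3]))
        assert (eff, var) == (pytest.approx(0.7), pytest.approx(0.3))

    def test_group_power_with_planted_negative_effect(self):
        # 4 subjects x 40 sessions, session effect -0.5 in units of the
        # session-level noise sd (analytic power 0.978): group t < 0 and
        # p < 0.05 in >= 90% of runs
        rng = np.random.default_rng(99)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            effects = []
            for _subj in range(4):
                sess = rng.normal(-0.5, 1.0, 40)
                eff, _ = ge.fixed_effects(sess, np.ones(40))
                effects.append(eff)
            t, p = ge.group_test(np.array(effects))
            hits += (t < 0) and (p < 0.05)
        assert hits / n_reps >= 0.90

    def test_null_group_p_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(2000):
            effects = rng.normal(0.0, 1.0, 6)
            pvals.append(ge.group_test(effects)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSignedVsAbsolute:
    @staticmethod
    def _session(rng, b_signed=0.0, b_abs=0.0, n=60, noise_sd=0.005):
        v1 = rng.uniform(0.1, 0.9, n)
        v2 = rng.uniform(0.1, 0.9, n)
        take_first = rng.random(n) < 1.0 / (1.0 + np.exp(-(v1 - v2) / 0.25))
        diff = np.where(take_first, v1 - v2, v2 - v1)
        diff_z = vl.zscore(diff)
        abs_z = vl.zscore(np.abs(diff_z))
        onsets = np.arange(n) * 11.0 + 4
        amps = 1.0 + b_signed * diff_z + b_abs * abs_z
        n_vol = int((onsets[-1] + 25.0) / 2.28)
        bold = bs.convolve_events(onsets, amps, tr=2.28, n_volumes=n_vol)
        bold.values = bold.values + rng.normal(0, noise_sd, n_vol)
        return onsets, diff_z, bold

    def test_reports_correlation_and_both_betas(self, rng):
        onsets, diff_z, bold = self._session(rng, b_signed=-0.4)
        out = ge.signed_vs_absolute(onsets, diff_z, bold)
        assert abs(out["correlation"]) < 0.9
        assert out["signed_diff"]["beta"] < 0
        assert {"beta", "se", "t", "p"} <= set(out["signed_diff"])

    def test_collinear_modulators_refused(self, rng):
        onsets = np.arange(30) * 11.0
        diff_z = np.abs(rng.standard_normal(30)) + 0.1  # all positive: signed ~ abs
        bold = bs.convolve_events(onsets, 1.0, tr=2.28, n_volumes=160)
        with pytest.raises(ge.CollinearityError):
            ge.signed_vs_absolute(onsets, diff_z, bold)

    def test_orthogonalized_fit_agrees_when_uncorrelated(self):
        # symmetric +/- pattern: corr(signed, |signed|) is exactly zero
        diff_z = np.tile([2.0, 1.0, -1.0, -2.0], 10)
        onsets = np.arange(40) * 11.0 + 4
        rng = np.random.default_rng(12)
        amps = 1.0 - 0.3 * vl.zscore(diff_z)
        n_vol = int((onsets[-1] + 25.0) / 2.28)
        bold = bs.convolve_events(onsets, amps, tr=2.28, n_volumes=n_vol)
        bold.values = bold.values + rng.normal(0, 0.003, n_vol)
        plain = ge.signed_vs_absolute(onsets, diff_z, bold, orthogonalize=False)
        ortho = ge.signed_vs_absolute(onsets, diff_z, bold, orthogonalize=True)
        assert plain["signed_diff"]["beta"] == pytest.approx(
            ortho["signed_diff"]["beta"], abs=1e-6)
        assert plain["abs_diff"]["beta"] == pytest.approx(
            ortho["abs_diff"]["beta"], abs=1e-6)


class TestDesignExport:
    def test_tsv_with_manifest(self, tmp_path, session_with_regressors):
        import json
        trials, _, regs = session_with_regressors
        design = ge.build_glm2(trials, regs)
        path = tmp_path / "design.tsv"
        design.to_tsv(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        assert manifest["columns"] == design.names
        assert manifest["tr"] == 2.28
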