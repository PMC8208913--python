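"""Trial-sequence constraints, behavioral generative model, EEG injection."""

from dataclasses import replace

import numpy as np
import pytest

from erroraware.simulate import (
    TaskDesign, GroundTruth, generate_trial_sequence, simulate_behavior,
    simulate_eeg, simulate_subject, check_sequence, trial_duration_bounds,
    component_topographies,
)


def zeroed_truth(**overrides) -> GroundTruth:
    """Ground truth with every injected effect switched off."""
    base = GroundTruth()
    rt = {k: (v if k == "intercept" else 0.0)
          for k, v in base.rt_betas.items()}
    acc = {k: (v if k == "intercept" else 0.0)
           for k, v in base.acc_betas.items()}
    kw = dict(rt_betas=rt, acc_betas=acc, rt_noise_sd=0.0, pes_aware_ms=0.0,
              miss_rate=0.0, multiple_rate=0.0, invalid_judgment_rate=0.0,
              ern_gain=0.0, ern_conf=0.0, ern_interaction=0.0,
              pe_gain=0.0, pe_conf=0.0, pe_interaction=0.0)
    kw.update(overrides)
    return replace(base, **kw)


# ---------------------------------------------------------------------------
# trial sequences
# ---------------------------------------------------------------------------

class TestTrialSequence:
    def test_default_design_composition(self):
        """Default design: 1,000 trials split 800/100/100 with all
        constraints (adjacency, congruency balance, transitions)."""
        design = TaskDesign()
        df = generate_trial_sequence(design, seed=0)
        assert len(df) == 1000
        counts = df["trial_type"].value_counts()
        assert counts["standard"] == 800
        assert counts["number_target"] == 100
        assert counts["repeat_target"] == 100
        assert check_sequence(df, design) == []

    def test_adjacent_target_scan(self):
        """Brute-force scan: no two target trials ever adjacent."""
        df = generate_trial_sequence(TaskDesign(), seed=42)
        is_target = (df["trial_type"] != "standard").to_numpy()
        assert int(np.sum(is_target[:-1] & is_target[1:])) == 0

    def test_transition_counterbalancing(self):
        inc = (generate_trial_sequence(TaskDesign(), seed=9)["congruency"]
               == "incongruent").to_numpy()
        trans = [np.sum(~inc[:-1] & ~inc[1:]), np.sum(~inc[:-1] & inc[1:]),
                 np.sum(inc[:-1] & ~inc[1:]), np.sum(inc[:-1] & inc[1:])]
        assert max(trans) - min(trans) <= 2
        assert abs(inc.sum() - 500) <= 1

    def test_congruency_follows_font_size_rule(self):
        df = generate_trial_sequence(TaskDesign(), seed=3)
        congr = df["congruency"] == "congruent"
        rule = (df["font_size"] == "large") == (df["number"] > 55)
        assert (congr == rule).all()
        # targets follow the same rule (49 below / 62 above the reference)
        tg = df[df["trial_type"] == "number_target"]
        assert set(tg["number"]) <= {49, 62}

    def test_all_standard_design(self):
        design = TaskDesign(n_trials=50, n_standard=50, n_number_target=0,
                            n_repeat_target=0)
        df = generate_trial_sequence(design, seed=1)
        assert (df["trial_type"] == "standard").all()
        assert check_sequence(df, design) == []

    @pytest.mark.parametrize("seed", range(40))
    def test_constraint_sweep_default_design(self, seed):
        df = generate_trial_sequence(TaskDesign(), seed=seed)
        assert check_sequence(df, TaskDesign()) == []

    @pytest.mark.parametrize("seed", range(60))
    def test_constraint_sweep_small_design(self, seed):
        design = TaskDesign(n_trials=200, n_standard=160,
                            n_number_target=20, n_repeat_target=20)
        assert check_sequence(generate_trial_sequence(design, seed),
                              design) == []

    def test_unsatisfiable_design_rejected(self):
        with pytest.raises(ValueError):
            TaskDesign(n_trials=10, n_standard=2, n_number_target=4,
                       n_repeat_target=4)

    def test_timing_bounds(self):
        """Printed timing parameters: trial duration spans 3,200-3,350 ms."""
        lo, hi = trial_duration_bounds(TaskDesign())
        assert (lo, hi) == (3200, 3350)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

class TestBehaviorGenerator:
    def test_zero_betas_zero_noise_constant_rt(self, small_design):
        trials = generate_trial_sequence(small_design, seed=0)
        truth = zeroed_truth()
        out = simulate_behavior(trials, truth, small_design, seed=0)
        rts = out["rt_ms"].dropna()
        assert np.allclose(rts, rts.iloc[0])
        # accuracy governed by the intercept alone
        acc = (out["accuracy"] == "correct").mean()
        expect = 1 / (1 + np.exp(-truth.acc_betas["intercept"]))
        assert abs(acc - expect) < 0.12

    def test_congruency_effect_closed_form(self):
        """With +-1 coding, E[logRT | inc] - E[logRT | con] = 2 * beta."""
        design = TaskDesign(n_trials=4000, n_standard=4000,
                            n_number_target=0, n_repeat_target=0)
        beta = 0.05
        truth = zeroed_truth(rt_noise_sd=0.05)
        truth.rt_betas["congruency"] = beta
        trials = generate_trial_sequence(design, seed=2)
        out = simulate_behavior(trials, truth, design, seed=2)
        lr = np.log(out["rt_ms"])
        diff = lr[out["congruency"] == "incongruent"].mean() \
            - lr[out["congruency"] == "congruent"].mean()
        se = 0.05 * np.sqrt(2 / 2000)
        assert abs(diff - 2 * beta) < 4 * se

    def test_post_error_slowing_magnitude(self):
        """Injected 11.5 ms aware-only slowing appears as the mean RT
        difference between post-aware-error and post-correct trials."""
        design = TaskDesign(n_trials=6000, n_standard=4800,
                            n_number_target=600, n_repeat_target=600)
        truth = zeroed_truth(rt_noise_sd=0.02, pes_aware_ms=11.5)
        # errors must occur for PES to be observable
        truth.acc_betas["intercept"] = 1.2
        trials = generate_trial_sequence(design, seed=7)
        out = simulate_behavior(trials, truth, design, seed=7)
        prev_aw = out["awareness"].shift(1)
        prev_acc = out["accuracy"].shift(1)
        post_aware = out.loc[prev_aw == "aware_error", "rt_ms"]
        post_correct = out.loc[prev_acc == "correct", "rt_ms"]
        diff = post_aware.mean() - post_correct.mean()
        se = out["rt_ms"].std() * np.sqrt(1 / len(post_aware)
                                          + 1 / len(post_correct))
        assert abs(diff - 11.5) < 3 * se + 0.5
        # unaware errors produce no slowing
        post_unaware = out.loc[prev_aw == "unaware_error", "rt_ms"]
        assert abs(post_unaware.mean() - post_correct.mean()) < 3 * se + 0.5

    def test_aware_errors_slower(self, behavior_subject):
        """Awareness probability increases with RT, so aware errors are
        slower on average (as reported for this task)."""
        err = behavior_subject[behavior_subject["accuracy"] == "error"]
        aware = err.loc[err["awareness"] == "aware_error", "rt_ms"]
        unaware = err.loc[err["awareness"] == "unaware_error", "rt_ms"]
        assert aware.mean() > unaware.mean()

    def test_invalid_parameters_rejected(self):
        truth = zeroed_truth(pes_aware_ms=-1e9)
        with pytest.raises(ValueError):
            truth.validate()
        bad = zeroed_truth()
        bad.rt_betas["congruency"] = np.nan
        with pytest.raises(ValueError):
            bad.validate()


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

class TestEegGenerator:
    def test_aware_unaware_pe_difference_noiseless(self, small_design,
                                                   montage61):
        """With pe_gain > 0 and no noise, the aware-unaware average
        difference at the Pe channel peaks positively in 200-300 ms."""
        trials = generate_trial_sequence(small_design, seed=1)
        truth = zeroed_truth(noise_sd=0.0, pe_gain=3.0,
                             aware_intercept=0.0)
        truth.acc_betas["intercept"] = 0.0  # plenty of errors
        out = simulate_behavior(trials, truth, small_design, seed=1)
        epochs = simulate_eeg(out, truth, montage61, seed=1)
        lab = out.loc[out["rt_ms"].notna(), "awareness"].to_numpy()
        pe_ch = int(np.argmax(component_topographies(montage61)["pe"]))
        aware_avg = epochs.data[pe_ch][:, lab == "aware_error"].mean(axis=1)
        unaware_avg = epochs.data[pe_ch][:, lab == "unaware_error"] \
            .mean(axis=1)
        diff = aware_avg - unaware_avg
        t = epochs.times
        peak = t[np.argmax(diff)]
        assert 0.2 <= peak <= 0.3
        assert diff.max() > 0

    def test_null_gains_no_awareness_difference(self, small_design,
                                                montage61):
        """All awareness gains zero: aware vs unaware grand averages differ
        only by noise (FDR-corrected pointwise t-tests reject ~nothing)."""
        import scipy.stats as st
        from statsmodels.stats.multitest import multipletests
        design = TaskDesign(n_trials=400, n_standard=320,
                            n_number_target=40, n_repeat_target=40)
        trials = generate_trial_sequence(design, seed=4)
        truth = zeroed_truth(noise_sd=10.0, aware_intercept=0.0,
                             phase_lock_aware=2.5)
        truth.acc_betas["intercept"] = 0.0
        out = simulate_behavior(trials, truth, design, seed=4)
        err = out[out["accuracy"] == "error"]
        epochs = simulate_eeg(err, truth, montage61, seed=4)
        lab = err.loc[err["rt_ms"].notna(), "awareness"].to_numpy()
        a = epochs.data[:, :, lab == "aware_error"]
        u = epochs.data[:, :, lab == "unaware_error"]
        t, p = st.ttest_ind(a, u, axis=2)
        rej = multipletests(p.ravel(), alpha=0.05, method="fdr_by")[0]
        assert rej.mean() <= 0.01

    def test_regeneration_bit_identical(self, small_design):
        t1, e1 = simulate_subject(small_design, seed=99, eeg_trials="error")
        t2, e2 = simulate_subject(small_design, seed=99, eeg_trials="error")
        assert t1.equals(t2)
        assert np.array_equal(e1.data, e2.data)
        assert np.array_equal(e1.trial_index, e2.trial_index)

    def test_topography_peaks_at_vertex(self, montage61):
        topo = component_topographies(montage61)
        assert montage61.ch_names[int(np.argmax(topo["ern"]))] == "Cz"
        assert montage61.ch_names[int(np.argmax(topo["pe"]))] == "Cz"
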