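"""Trial filtering, behavioral GLMs, and group-level inference."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from erroraware import behavior as bh
from erroraware.simulate import TaskDesign, simulate_subject
from _oracles import apply_filter_rules, irls_reference

from test_synthetic import zeroed_truth


def toy_table(rows: list[dict]) -> pd.DataFrame:
    defaults = dict(number=40, trial_type="standard", congruency="congruent",
                    jitter_ms=300, distance=15, response="button1",
                    rt_ms=400.0, accuracy="correct", judgment="said_correct",
                    judgment_rt_ms=600.0, awareness="n/a")
    out = []
    for i, row in enumerate(rows, start=1):
        rec = {**defaults, "trial_nr": i, **row}
        out.append(rec)
    return pd.DataFrame(out)


class TestFilterTrials:
    def test_miss_removes_self_and_following(self):
        """Six-trial toy: trial 3 is a miss, so 3 and 4 are removed."""
        df = toy_table([{}, {}, {"response": "miss", "rt_ms": np.nan,
                                 "accuracy": "n/a", "judgment": "invalid"},
                        {}, {}, {}])
        kept, log = bh.filter_trials(df, min_trials=1)
        assert list(kept["trial_nr"]) == [1, 2, 5, 6]
        assert log["n_invalid_response"] == 2

    def test_all_valid_table_untouched(self):
        df = toy_table([{} for _ in range(8)])
        kept, log = bh.filter_trials(df, min_trials=1)
        assert len(kept) == 8
        assert log["n_removed"] == 0

    def test_fast_rt_removed_without_neighbor(self):
        df = toy_table([{}, {"rt_ms": 50.0}, {}, {}])
        kept, _ = bh.filter_trials(df, min_trials=1)
        assert list(kept["trial_nr"]) == [1, 3, 4]

    def test_invalid_judgment_removes_following(self):
        df = toy_table([{}, {"judgment": "invalid"}, {}, {}])
        kept, _ = bh.filter_trials(df, min_trials=1)
        assert list(kept["trial_nr"]) == [1, 4]

    def test_matches_bruteforce_rule_application(self):
        """Random 50-trial tables: surviving set equals an independent
        row-by-row reapplication of the three rules."""
        rng = np.random.default_rng(21)
        for rep in range(5):
            rows = []
            for _ in range(50):
                r = {}
                u = rng.uniform()
                if u < 0.08:
                    r = {"response": "miss", "rt_ms": np.nan,
                         "accuracy": "n/a", "judgment": "invalid"}
                elif u < 0.14:
                    r = {"judgment": "invalid"}
                elif u < 0.20:
                    r = {"rt_ms": float(rng.uniform(10, 79))}
                rows.append(r)
            df = toy_table(rows)
            kept, _ = bh.filter_trials(df, min_trials=1)
            oracle = apply_filter_rules(df)
            assert list(kept["trial_nr"]) == list(df["trial_nr"][oracle])

    def test_idempotent(self, behavior_subject):
        once, _ = bh.filter_trials(behavior_subject)
        twice, log = bh.filter_trials(once)
        assert log["n_removed"] == 0
        assert once.equals(twice)

    def test_minimum_survivors_enforced(self):
        df = toy_table([{"rt_ms": 10.0} for _ in range(6)])
        with pytest.raises(ValueError):
            bh.filter_trials(df, min_trials=5)


class TestRtGlm:
    def test_noiseless_recovery_six_digits(self, small_design):
        """With zero noise every injected slope is recovered to at least
        six significant digits."""
        truth = zeroed_truth()
        truth.rt_betas.update(trial_type=0.03, congruency=0.01,
                              jitter=-0.02, distance=-0.004,
                              confidence=0.05, trial_nr=-0.01)
        design = TaskDesign(n_trials=600, n_standard=480,
                            n_number_target=60, n_repeat_target=60)
        trials, _ = simulate_subject(design, truth, seed=13, with_eeg=False)
        trials = bh.add_previous_trial_columns(trials)
        kept, _ = bh.filter_trials(trials)
        fit = bh.fit_rt_glm(kept)
        assert fit.ok
        for name in ("trial_type", "congruency", "jitter", "distance",
                     "confidence", "trial_nr"):
            assert fit.betas[name] == pytest.approx(
                truth.rt_betas[name], rel=1e-6), name

    def test_matches_bruteforce_irls_oracle(self, behavior_subject):
        kept, _ = bh.filter_trials(behavior_subject)
        X = bh.build_design(kept, model="rt")
        y = X.pop("__y__").to_numpy()
        ref = irls_reference(X.to_numpy(), y)
        fit = bh.fit_rt_glm(kept)
        np.testing.assert_allclose(fit.betas.to_numpy(), ref, rtol=1e-6)

    def test_single_value_regressor_flagged(self):
        df = toy_table([{} for _ in range(30)])  # all same condition
        df["judgment_rt_ms"] = np.exp(np.random.default_rng(0)
                                      .normal(6.4, 0.2, 30))
        fit = bh.fit_rt_glm(bh.add_previous_trial_columns(df))
        assert not fit.ok

    def test_posterror_variant_trial_partitions(self, behavior_subject):
        """Aware/unaware model rows are disjoint except post-correct
        trials, which enter both models."""
        kept, _ = bh.filter_trials(behavior_subject)
        Xa = bh.build_design(kept, model="rt", posterror="aware")
        Xu = bh.build_design(kept, model="rt", posterror="unaware")
        rows_a, rows_u = set(Xa.index), set(Xu.index)
        post_correct = set(
            kept.index[kept["prev_accuracy"] == "correct"])
        both = rows_a & rows_u
        assert both <= post_correct
        only_a = kept.loc[list(rows_a - rows_u), "prev_awareness"]
        only_u = kept.loc[list(rows_u - rows_a), "prev_awareness"]
        assert set(only_a) <= {"aware_error"}
        assert set(only_u) <= {"unaware_error"}


class TestAccuracyGlm:
    def test_balanced_zero_effects(self):
        """Balanced factors with outcome independent of them: slopes ~0
        and the intercept matches the overall accuracy logit."""
        rng = np.random.default_rng(3)
        n = 4000
        df = toy_table([{} for _ in range(n)])
        df["trial_type"] = np.where(np.arange(n) % 2 == 0, "standard",
                                    "number_target")
        df["congruency"] = np.where(np.arange(n) % 4 < 2, "congruent",
                                    "incongruent")
        df["jitter_ms"] = np.where(np.arange(n) % 8 < 4, 300, 400)
        df["distance"] = rng.integers(1, 21, size=n)
        df["rt_ms"] = np.exp(rng.normal(6.0, 0.15, size=n))
        df["judgment_rt_ms"] = np.exp(rng.normal(6.4, 0.2, size=n))
        acc = rng.uniform(size=n) < 0.85
        df["accuracy"] = np.where(acc, "correct", "error")
        dfp = bh.add_previous_trial_columns(df)
        fit = bh.fit_accuracy_glm(dfp)
        assert fit.ok
        p_hat = acc[1:].mean()  # first trial drops (no prev judgment)
        for name in ("trial_type", "congruency", "jitter"):
            assert abs(fit.betas[name]) < 0.15
        X = bh.build_design(dfp, model="accuracy")
        X.pop("__y__")
        fitted = 1 / (1 + np.exp(-(X.to_numpy() @ fit.betas.to_numpy())))
        assert fitted.mean() == pytest.approx(p_hat, abs=0.01)

    def test_speed_accuracy_tradeoff_recovered(self):
        """Positive log-RT effect on accuracy yields a positive group t."""
        truth = zeroed_truth(rt_noise_sd=0.18)
        truth.acc_betas.update(intercept=1.5, log_rt=1.2)
        design = TaskDesign(n_trials=500, n_standard=400,
                            n_number_target=50, n_repeat_target=50)
        tables = []
        for s in range(8):
            tr, _ = simulate_subject(design, truth, seed=100 + s,
                                     with_eeg=False)
            tables.append(bh.filter_trials(
                bh.add_previous_trial_columns(tr))[0])
        res = bh.fit_group(tables, model="accuracy")
        row = res.group.loc["log_rt"]
        assert row["t"] > 0
        assert row["p_corrected"] < 0.05

    def test_complete_separation_flagged(self):
        df = toy_table([{} for _ in range(60)])
        rng = np.random.default_rng(0)
        df["judgment_rt_ms"] = np.exp(rng.normal(6.4, 0.2, 60))
        df["distance"] = rng.integers(1, 21, size=60)
        df["congruency"] = rng.choice(["congruent", "incongruent"], 60)
        df["trial_type"] = rng.choice(["standard", "number_target"], 60)
        df["jitter_ms"] = rng.choice([300, 450], 60)
        # outcome perfectly separated by RT
        df["rt_ms"] = np.where(np.arange(60) < 30, 300.0, 500.0)
        df["accuracy"] = np.where(np.arange(60) < 30, "error", "correct")
        fit = bh.fit_accuracy_glm(bh.add_previous_trial_columns(df))
        assert not fit.ok


class TestGroupTest:
    def test_zero_variance_degenerate(self):
        vals = pd.DataFrame({"a": [2.0] * 10, "b": np.arange(10.0)})
        res = bh.group_test(vals)
        assert bool(res.loc["a", "degenerate"])
        assert not bool(res.loc["b", "degenerate"])

    def test_null_calibration_bonferroni(self):
        """t-values ~ N(0,1): per-regressor rejection rate at the
        Bonferroni-corrected level is ~alpha/k."""
        rng = np.random.default_rng(11)
        k, n_sub, reps = 7, 30, 1500
        hits = 0
        for _ in range(reps):
            vals = pd.DataFrame(rng.standard_normal((n_sub, k)),
                                columns=[f"r{i}" for i in range(k)])
            hits += int(bh.group_test(vals)["significant"].sum())
        rate = hits / (reps * k)
        expect = 0.05 / k
        se = np.sqrt(expect * (1 - expect) / (reps * k))
        assert abs(rate - expect) < 4 * se + 1e-4

    def test_power_matches_noncentral_t(self):
        """t-values ~ N(1,1), n = 58: empirical power of the two-sided
        test matches the noncentral-t closed form."""
        rng = np.random.default_rng(12)
        n, reps, alpha = 58, 3000, 0.05
        tcrit = st.t.ppf(1 - alpha / 2, n - 1)
        nc = 1.0 * np.sqrt(n)
        power = (1 - st.nct.cdf(tcrit, n - 1, nc)
                 + st.nct.cdf(-tcrit, n - 1, nc))
        x = rng.standard_normal((reps, n)) + 1.0
        tt = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
        emp = np.mean(2 * st.t.sf(np.abs(tt), n - 1) < alpha)
        assert abs(emp - power) < 4 * np.sqrt(power * (1 - power) / reps)
        # spot check through group_test itself
        vals = pd.DataFrame({"r0": x[0]})
        row = bh.group_test(vals).loc["r0"]
        assert row["p"] == pytest.approx(2 * st.t.sf(abs(tt[0]), n - 1))

    def test_ci_contains_mean(self):
        rng = np.random.default_rng(13)
        vals = pd.DataFrame({"a": rng.standard_normal(40)})
        row = bh.group_test(vals).loc["a"]
        assert row["ci99_low"] < row["mean"] < row["ci99_high"]
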