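import itertools

import numpy as np
import pytest

import bmifes as b
from bmifes.classifier import CVReport, online_decide, score
from conftest import FAST_GRID, make_mi_features


def run_probability(n, k, p):
    """DP oracle: P(a run of >= k successes occurs in n iid Bernoulli(p))."""
    # state = current trailing run length (0..k-1); absorbing once run hits k
    state = np.zeros(k)
    state[0] = 1.0
    absorbed = 0.0
    for _ in range(n):
        new = np.zeros(k)
        new[0] = state.sum() * (1 - p)
        absorbed += state[k - 1] * p
        new[1:] = state[:-1] * p
        state = new
    return absorbed + 0.0


def _report(task, rest, total):
    n = len(total)
    return CVReport(list(range(n)), np.array(task), np.array(rest),
                    np.array(total))


class TestSubsampleRest:
    @pytest.fixture()
    def trialset(self, strong_mi_trialset):
        return strong_mi_trialset[1]

    def test_ratio_two_doubles_task_count(self, trialset):
        sub = b.subsample_rest(trialset, 2, seed=0)
        c = sub.counts
        assert c["rest"] == 2 * c["task"]

    def test_ratio_one_balances(self, trialset):
        c = b.subsample_rest(trialset, 1, seed=0).counts
        assert c["rest"] == c["task"]

    def test_seed_reproducibility(self, trialset):
        a = b.subsample_rest(trialset, 1, seed=5)
        c = b.subsample_rest(trialset, 1, seed=5)
        d = b.subsample_rest(trialset, 1, seed=6)
        key = lambda ts: [(t.run, t.t0) for t in ts]
        assert key(a) == key(c)
        assert key(a) != key(d)

    def test_insufficient_rest_rejected(self, trialset):
        with pytest.raises(ValueError, match="rest"):
            b.subsample_rest(trialset, 100, seed=0)


class TestTrainModel:
    def _blobs(self, n=100, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n, 5)),
                       rng.normal(sep, 1, (n, 5))])
        y = np.array(["rest"] * n + ["task"] * n)
        return X, y

    def test_separable_blobs_fit_perfectly(self):
        X, y = self._blobs()
        model = b.train_model(X, y, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="class"):
            b.train_model(X, ["task"] * 10, seed=0)

    def test_duplicated_training_set_gives_same_decisions(self):
        X, y = self._blobs(n=40)
        rng = np.random.default_rng(1)
        probe = rng.normal(5, 3, (50, 5))
        m1 = b.train_model(X, y, seed=0, grid=FAST_GRID)
        m2 = b.train_model(np.vstack([X, X]), np.concatenate([y, y]),
                           seed=0, grid=FAST_GRID)
        assert np.array_equal(m1.predict(probe), m2.predict(probe))

    def test_shuffled_labels_stay_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((240, 10))
        y = np.array(["task", "rest"] * 120)
        runs = np.repeat(np.arange(4), 60)
        rep = b.crossval_by_run(X, y, runs, seed=0, grid=FAST_GRID)
        assert 35.0 <= rep.mean_total <= 65.0

    def test_feature_layout_mismatch_rejected(self):
        X, y = self._blobs(n=20)
        model = b.train_model(X, y, seed=0, grid=FAST_GRID)
        with pytest.raises(ValueError, match="layout"):
            model.predict(np.zeros((2, 7)))


class TestCrossvalByRun:
    def test_separable_runs_give_100_sd_0(self):
        X, y = [], []
        rng = np.random.default_rng(0)
        runs = np.repeat(np.arange(4), 40)
        for _ in range(4):
            X.append(np.vstack([rng.normal(0, 0.5, (20, 4)),
                                rng.normal(8, 0.5, (20, 4))]))
            y.extend(["rest"] * 20 + ["task"] * 20)
        rep = b.crossval_by_run(np.vstack(X), np.array(y), runs, seed=0,
                                grid=FAST_GRID)
        assert rep.mean_total == 100.0
        assert np.std(rep.total_acc) == 0.0

    def test_each_run_is_one_fold(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 4))
        y = np.array(["task", "rest"] * 60)
        runs = np.repeat(np.arange(4), 30)
        rep = b.crossval_by_run(X, y, runs, seed=0, grid=FAST_GRID)
        assert rep.fold_runs == [0, 1, 2, 3]

    def test_fold_missing_a_class_is_skipped(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((90, 4))
        y = np.array(["task", "rest"] * 30 + ["task"] * 30)
        runs = np.repeat(np.arange(3), 30)
        with pytest.warns(UserWarning, match="missing"):
            rep = b.crossval_by_run(X, y, runs, seed=0, grid=FAST_GRID)
        assert rep.skipped == [2]
        assert rep.fold_runs == [0, 1]

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="runs"):
            b.crossval_by_run(np.zeros((10, 2)), np.array(["task"] * 10),
                              np.zeros(10, int), seed=0)


class TestSelection:
    def test_dominating_ratio_selected(self):
        reports = {1: _report([90], [95], [93]), 2: _report([80], [85], [82]),
                   3: _report([70], [75], [72])}
        assert b.select_ratio(reports) == 1

    def test_rest_accuracy_wins_within_margin(self):
        # rest accuracies 56.3/87.5/99.5 with totals 54.3/49.8/49.9:
        # all totals are within 5 points of the best, so rest accuracy decides
        reports = {1: _report([52.3], [56.3], [54.3]),
                   2: _report([12.2], [87.5], [49.8]),
                   3: _report([0.3], [99.5], [49.9])}
        assert b.select_ratio(reports, margin=5.0) == 3

    def test_identical_reports_tie_break_to_larger_ratio(self):
        reports = {k: _report([50], [80], [65]) for k in (1, 2, 3)}
        assert b.select_ratio(reports) == 3

    def test_strictly_best_combo_selected(self):
        reports = {i: _report([50], [50], [50]) for i in range(1, 8)}
        reports[5] = _report([90], [90], [90])
        assert b.select_combo(reports) == 5

    def test_equal_combos_tie_break_to_all_bands(self):
        reports = {i: _report([70], [70], [70]) for i in range(1, 8)}
        assert b.select_combo(reports) == 7

    def test_mu_only_modulation_selects_mu_combo(self):
        # rhythms exist only in mu, so combos lacking mu carry no class signal
        sched = b.build_intention_schedule(runs=3, moves_per_run=4)
        p = b.ERDParams(band_amp={"mu": 4.0, "low_beta": 0.0,
                                  "high_beta": 0.0},
                        erd_depth=0.6, seed=21)
        rec, _ = b.generate_session(sched, p)
        proc = b.preprocess_recording(rec)
        ts = b.segment_trials(proc, sched)
        combos = {c.id: c for c in b.enumerate_combos()}
        reports = {}
        for cid, combo in combos.items():
            X, y, runs = b.feature_matrix(ts, "bandpower", combo=combo)
            reports[cid] = b.crossval_by_run(X, y, runs, seed=0,
                                             grid=FAST_GRID)
        best = b.select_combo(reports, combos)
        assert "mu" in combos[best].bands


class TestOnlineDecide:
    def _stream(self, preds, period=0, truth="rest"):
        return [(period, truth, p) for p in preds]

    def test_three_consecutive_emit_one_command(self):
        trace = online_decide(self._stream(["task"] * 3, truth="task"))
        assert len(trace.commands) == 1
        assert trace.commands[0].time == 2.0  # third window

    def test_alternating_predictions_emit_nothing(self):
        trace = online_decide(self._stream(["task", "rest"] * 10))
        assert trace.commands == []

    def test_counter_resets_after_command(self):
        trace = online_decide(self._stream(["task"] * 7, truth="task"))
        assert len(trace.commands) == 2  # windows 3 and 6; counter restarts

    def test_counter_resets_at_period_boundary(self):
        stream = (self._stream(["task", "task"], period=0)
                  + self._stream(["task", "task"], period=1))
        assert online_decide(stream).commands == []

    def test_commands_alternate_extension_then_flexion(self):
        stream = self._stream(["task"] * 3, period=0, truth="task") \
            + self._stream(["task"] * 3, period=1, truth="task")
        cmds = online_decide(stream).commands
        assert [c.kind for c in cmds] == ["extension", "flexion"]

    def test_suppressed_command_does_not_flip_arm(self):
        stream = self._stream(["task"] * 3, period=0, truth="rest") \
            + self._stream(["task"] * 3, period=1, truth="task")
        cmds = online_decide(stream).commands
        assert cmds[0].suppressed and not cmds[1].suppressed
        assert [c.kind for c in cmds] == ["extension", "extension"]

    def test_n_consecutive_one_fires_immediately(self):
        trace = online_decide(self._stream(["task"]), n_consecutive=1)
        assert len(trace.commands) == 1

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            online_decide([], n_consecutive=0)


class TestFalseCommandProbability:
    def test_exhaustive_enumeration_matches_dp(self):
        # every length-10 prediction sequence, probability-weighted at p=0.3
        n, p = 10, 0.3
        total = 0.0
        for bits in itertools.product([0, 1], repeat=n):
            preds = ["task" if bi else "rest" for bi in bits]
            trace = online_decide([(0, "rest", q) for q in preds])
            if trace.commands:
                k = sum(bits)
                total += p**k * (1 - p) ** (n - k)
        assert total == pytest.approx(run_probability(n, 3, p), abs=1e-12)

    def test_monte_carlo_19_window_rest_period(self):
        n, p = 19, 0.3
        rng = np.random.default_rng(0)
        hits = 0
        trials = 20000
        for _ in range(trials):
            preds = np.where(rng.random(n) < p, "task", "rest")
            if online_decide([(0, "rest", q) for q in preds]).commands:
                hits += 1
        expect = run_probability(n, 3, p)
        se = np.sqrt(expect * (1 - expect) / trials)
        assert abs(hits / trials - expect) < 4 * se

    def test_probability_nonincreasing_in_n_consecutive(self):
        probs = [run_probability(19, k, 0.3) for k in range(1, 7)]
        assert all(a >= bq for a, bq in zip(probs, probs[1:]))
        # and empirically through the decision rule itself
        rng = np.random.default_rng(1)
        streams = [np.where(rng.random(19) < 0.3, "task", "rest")
                   for _ in range(2000)]
        rates = []
        for k in (3, 5):
            hits = sum(bool(online_decide([(0, "rest", q) for q in s],
                                          n_consecutive=k).commands)
                       for s in streams)
            rates.append(hits)
        assert rates[0] >= rates[1]


class TestScore:
    def _trace(self, task_hits, rest_hits, n_task=10, n_rest=10):
        labels = {i: "task" for i in range(n_task)}
        labels.update({n_task + i: "rest" for i in range(n_rest)})
        cmds = [b.classifier.Command(0.0, "extension", i, False)
                for i in range(task_hits)]
        cmds += [b.classifier.Command(0.0, "extension", n_task + i, True)
                 for i in range(rest_hits)]
        return b.DecisionTrace([], cmds, labels)

    def test_perfect_run(self):
        m = score(self._trace(10, 0))
        assert (m.tpr, m.fpr, m.acc) == (100.0, 0.0, 100.0)

    def test_nine_of_ten_with_one_violation(self):
        m = score(self._trace(9, 1))
        assert (m.tpr, m.fpr, m.acc) == (90.0, 10.0, 90.0)

    def test_no_commands_scores_half(self):
        m = score(self._trace(0, 0))
        assert (m.tpr, m.fpr, m.acc) == (0.0, 0.0, 50.0)

    def test_counts_consistent(self):
        m = score(self._trace(7, 2))
        assert m.n_task_detected == 7 and m.n_rest_violated == 2
        assert m.acc == pytest.approx(100 * (7 + 8) / 20)

    def test_missing_class_rejected(self):
        trace = b.DecisionTrace([], [], {0: "task"})
        with pytest.raises(ValueError):
            score(trace)


class TestRecoveryBenchmark:
    def test_strong_erd_recovers_above_90(self):
        X, y, runs = make_mi_features(depth=0.6, seed=31)
        rep = b.crossval_by_run(X, y, runs, seed=0, grid=FAST_GRID)
        assert rep.mean_total >= 90.0

    def test_null_depth_within_chance_band(self):
        X, y, runs = make_mi_features(depth=0.0, seed=32)
        rep = b.crossval_by_run(X, y, runs, seed=0, grid=FAST_GRID)
        assert 35.0 <= rep.mean_total <= 65.0
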