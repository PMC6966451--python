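import numpy as np
import pandas as pd
import pytest

from tadprog import simulate, survival
from tadprog.genome_io import SurvivalRecord


def rec(pid, time, event, ctype="SIM", age=60.0, sex="male"):
    return SurvivalRecord(pid, ctype, time, event, age, sex)


def brute_force_cindex(scores, times, events):
    """All-pairs Harrell's c: higher score must mean shorter survival."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i]:
                continue
            if times[i] < times[j] or (times[i] == times[j] and not events[j]):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestEligibility:
    def test_inclusion_arithmetic(self):
        # 15/120 = 12.5% lethal -> included; 99 patients -> too few;
        # 10/200 = 5% -> too few events
        recs = []
        recs += [rec(f"A{i}", 100, int(i < 15), "A") for i in range(120)]
        recs += [rec(f"B{i}", 100, 1, "B") for i in range(99)]
        recs += [rec(f"C{i}", 100, int(i < 10), "C") for i in range(200)]
        assert survival.eligible_cohorts(recs) == ["A"]

    def test_patients_without_cnvs_removed_first(self):
        recs = [rec(f"A{i}", 100, 1, "A") for i in range(100)]
        with_cnv = {f"A{i}" for i in range(99)}
        assert survival.eligible_cohorts(recs, patients_with_cnvs=with_cnv) == []


class TestEncodeFeatures:
    def make(self):
        recs = [rec("P1", 100, 1, age=70, sex="male"),
                rec("P2", 200, 0, age=65, sex="female"),
                rec("P3", 300, 1, age=50, sex="female")]
        mat = pd.DataFrame({"tadA": [1, 0, 1], "tadB": [0, 1, 1]},
                           index=["P1", "P2", "P3"])
        return recs, mat

    def test_age_above_median_encoded_one(self):
        recs, mat = self.make()
        X = survival.encode_features(recs, mat, median_age=65.0)
        assert X.loc["P1", "age_high"] == 1
        # age exactly at the median is "not larger" -> 0
        assert X.loc["P2", "age_high"] == 0
        assert X.loc["P2", "sex"] == 1 and X.loc["P1", "sex"] == 0

    def test_constant_column_dropped(self, caplog):
        recs = [rec("P1", 100, 1, sex="female"), rec("P2", 200, 0, sex="female"),
                rec("P3", 150, 1, sex="female")]
        mat = pd.DataFrame({"tadA": [1, 0, 1]}, index=["P1", "P2", "P3"])
        with caplog.at_level("WARNING"):
            X = survival.encode_features(recs, mat)
        assert "sex" not in X.columns


class TestConcordance:
    def test_perfect_reverse_ranking_is_one(self):
        recs = [rec(f"P{i}", t, 1) for i, t in enumerate([50, 120, 300, 700])]
        scores = pd.Series([4.0, 3.0, 2.0, 1.0], index=[f"P{i}" for i in range(4)])
        assert survival.concordance_index(scores, recs) == 1.0

    def test_random_scores_near_half(self, rng):
        recs = [rec(f"P{i}", float(t), 1) for i, t in
                enumerate(rng.exponential(100, size=2000))]
        scores = pd.Series(rng.random(2000), index=[f"P{i}" for i in range(2000)])
        assert survival.concordance_index(scores, recs) == pytest.approx(0.5, abs=0.03)

    def test_matches_brute_force_with_censoring_and_ties(self, rng):
        for trial in range(5):
            n = 30
            times = rng.integers(1, 15, n).astype(float)  # many time ties
            events = rng.integers(0, 2, n)
            if not events.any():
                events[0] = 1
            scores = rng.integers(0, 5, n).astype(float)  # many score ties
            recs = [rec(f"P{i}", times[i], int(events[i])) for i in range(n)]
            got = survival.concordance_index(
                pd.Series(scores, index=[f"P{i}" for i in range(n)]), recs)
            want = brute_force_cindex(scores, times, events)
            assert got == pytest.approx(want, abs=1e-12)

    def test_no_events_raises(self):
        recs = [rec("P1", 100, 0), rec("P2", 200, 0)]
        with pytest.raises(ValueError, match="comparable"):
            survival.concordance_index(pd.Series([1.0, 2.0], index=["P1", "P2"]), recs)


class TestAggregateFeatures:
    def run(self, i, sel, ci):
        return survival.ModelRun(i, [], [], sel, pd.Series(dtype=float), 0.1, ci)

    def test_single_run_gives_unit_weight(self):
        runs = [self.run(0, ("f1",), 0.6)]
        out = survival.aggregate_features(runs)
        assert out.loc[0, "P"] == pytest.approx(1.0)

    def test_low_ci_run_gets_zero_weight(self):
        runs = [self.run(0, ("f1",), 0.45), self.run(1, ("f2",), 0.7)]
        out = survival.aggregate_features(runs).set_index("feature")
        assert out.loc["f1", "P"] == pytest.approx(0.0)
        assert out.loc["f2", "P"] == pytest.approx(1.0)

    def test_two_run_hand_computation(self):
        # CI 0.7/0.5 -> devCI +-0.1 -> raw weights 1 and 0.25 -> 0.8/0.2
        runs = [self.run(0, ("f1",), 0.7), self.run(1, ("f2",), 0.5)]
        out = survival.aggregate_features(runs).set_index("feature")
        assert out.loc["f1", "P"] == pytest.approx(0.8)
        assert out.loc["f2", "P"] == pytest.approx(0.2)

    def test_weight_doubles_per_tenth_of_cindex(self):
        # three runs, one 0.1 above the mean: its raw weight is exactly twice
        # that of a run at the mean
        runs = [self.run(0, ("a",), 0.7), self.run(1, ("b",), 0.6),
                self.run(2, ("c",), 0.5)]
        out = survival.aggregate_features(runs).set_index("feature")
        assert out.loc["a", "P"] / out.loc["b", "P"] == pytest.approx(2.0)
        assert out.loc["b", "P"] / out.loc["c", "P"] == pytest.approx(2.0)

    def test_all_uninformative_raises(self):
        runs = [self.run(0, ("f1",), 0.4)]
        with pytest.raises(ValueError, match="no informative"):
            survival.aggregate_features(runs)

    def test_p_bounds_and_full_selection(self):
        runs = [self.run(0, ("f1", "f2"), 0.7), self.run(1, ("f1",), 0.6)]
        out = survival.aggregate_features(runs).set_index("feature")
        assert out.loc["f1", "P"] == pytest.approx(1.0)
        assert 0 < out.loc["f2", "P"] < 1


def simulated_cohort(seed, n=300, n_tads=30, betas=(np.log(2),) * 3, censor=0.25):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame((rng.random((n, n_tads)) < 0.25).astype(np.int8),
                     index=[f"P{i:04d}" for i in range(n)],
                     columns=[f"tad_{j:02d}" for j in range(n_tads)])
    cfg = simulate.SimulationConfig(
        seed=seed,
        causal_tads={i: b for i, b in enumerate(betas)},
        censoring_fraction=censor,
    )
    recs = simulate.simulate_survival(X, cfg, seed=seed + 1)
    return X, recs, cfg


class TestRepeatedModels:
    def test_strong_single_feature_dominates(self):
        rng = np.random.default_rng(0)
        n = 120
        X = pd.DataFrame({"driver": rng.integers(0, 2, n),
                          "noise": rng.integers(0, 2, n)},
                         index=[f"P{i}" for i in range(n)]).astype(np.int8)
        cfg = simulate.SimulationConfig(seed=0, causal_tads={0: 3.0},
                                        censoring_fraction=0.0)
        recs = simulate.simulate_survival(X, cfg)
        feats = survival.encode_features(recs, X)
        runs = survival.run_repeated_models(feats, recs, K=3, seed=4)
        done = [r for r in runs if not r.failed]
        assert all("driver" in r.selected for r in done)
        # a single binary covariate leaves same-valued pairs at chance, so
        # even a huge effect tops out near 0.75
        assert np.mean([r.ci for r in done]) > 0.7

    def test_pure_noise_ci_near_half(self):
        rng = np.random.default_rng(3)
        n = 150
        X = pd.DataFrame(rng.integers(0, 2, (n, 5)),
                         index=[f"P{i}" for i in range(n)],
                         columns=[f"f{j}" for j in range(5)]).astype(np.int8)
        cfg = simulate.SimulationConfig(seed=3, censoring_fraction=0.2)
        recs = simulate.simulate_survival(X, cfg, seed=9)
        feats = X  # skip demographics so every feature is pure noise
        runs = survival.run_repeated_models(feats, recs, K=25, seed=5)
        done = [r for r in runs if not r.failed]
        assert np.mean([r.ci for r in done]) == pytest.approx(0.5, abs=0.06)

    def test_same_seed_reproduces_runs(self):
        X, recs, _ = simulated_cohort(17, n=90, n_tads=6)
        feats = survival.encode_features(recs, X)
        a = survival.run_repeated_models(feats, recs, K=4, seed=11)
        b = survival.run_repeated_models(feats, recs, K=4, seed=11)
        for ra, rb in zip(a, b):
            assert ra.train_ids == rb.train_ids
            assert ra.selected == rb.selected
            assert ra.ci == pytest.approx(rb.ci)


class TestFinalModel:
    def test_hazard_ratio_recovery(self):
        X, recs, _ = simulated_cohort(23, n=300, n_tads=5, betas=(np.log(2),))
        fm = survival.fit_final_model(X, recs, ["tad_00"])
        assert "tad_00" in fm.features
        assert fm.hazard_ratios["tad_00"] == pytest.approx(2.0, rel=0.35)

    def test_collinear_duplicate_dropped_by_name(self):
        X, recs, _ = simulated_cohort(31, n=200, n_tads=3)
        X = X.copy()
        X["tad_dup"] = X["tad_00"]
        fm = survival.fit_final_model(X, recs, ["tad_00", "tad_dup"])
        assert "tad_dup" not in fm.features

    def test_noise_features_usually_eliminated(self):
        empty = 0
        for s in range(6):
            X, recs, _ = simulated_cohort(400 + s, n=150, n_tads=4, betas=())
            fm = survival.fit_final_model(X, recs, list(X.columns))
            empty += int(fm.empty)
        assert empty >= 3  # pure noise rarely survives backward elimination


class TestStratification:
    def test_strong_effect_separates_groups(self):
        X, recs, _ = simulated_cohort(5)
        fm = survival.fit_final_model(X, recs, ["tad_00", "tad_01", "tad_02"])
        strat = survival.stratify_and_test(fm, X, recs)
        assert strat.logrank_p < 0.05
        df = pd.DataFrame({"time": [r.time for r in recs],
                           "group": strat.groups.loc[[r.patient_id for r in recs]].values})
        assert (df[df.group == "high"]["time"].median()
                < df[df.group == "low"]["time"].median())

    def test_identical_scores_refused(self):
        X, recs, _ = simulated_cohort(7, n=60, n_tads=2, betas=(np.log(2),))
        fm = survival.FinalModel(["tad_00"], pd.Series({"tad_00": 0.0}),
                                 pd.Series({"tad_00": 1.0}), pd.Series({"tad_00": 1.0}),
                                 pd.Series({"tad_00": 1.0}))
        X0 = X.copy()
        X0["tad_00"] = 1
        with pytest.raises(ValueError, match="refused"):
            survival.stratify_and_test(fm, X0, recs)

    def test_even_split_with_distinct_scores(self):
        X, recs, _ = simulated_cohort(13, n=100, n_tads=4)
        rng = np.random.default_rng(0)
        fm = survival.FinalModel(
            ["tad_00"], pd.Series({"tad_00": 1.0}), pd.Series({"tad_00": np.e}),
            pd.Series({"tad_00": 0.01}), pd.Series({"tad_00": 0.01}))
        Xj = X.copy().astype(float)
        Xj["tad_00"] = rng.permutation(np.arange(len(X)))  # all distinct
        strat = survival.stratify_and_test(fm, Xj, recs)
        assert (strat.groups == "high").sum() == (strat.groups == "low").sum()


class TestExternalAndReliability:
    def test_external_cohort_generalization(self):
        X, recs, cfg = simulated_cohort(41)
        fm = survival.fit_final_model(X, recs, ["tad_00", "tad_01", "tad_02"])
        Xe, rece, _ = simulated_cohort(42)
        ci_int = survival.evaluate_external(fm, X, recs)
        ci_ext = survival.evaluate_external(fm, Xe, rece)
        assert ci_ext > 0.55
        assert ci_ext == pytest.approx(ci_int, abs=0.1)

    def test_permuted_external_survival_is_random(self):
        X, recs, _ = simulated_cohort(43)
        fm = survival.fit_final_model(X, recs, ["tad_00", "tad_01", "tad_02"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(recs))
        shuffled = [
            SurvivalRecord(recs[i].patient_id, "SIM", recs[perm[i]].time,
                           recs[perm[i]].event, recs[i].age, recs[i].sex)
            for i in range(len(recs))
        ]
        assert survival.evaluate_external(fm, X, shuffled) == pytest.approx(0.5, abs=0.07)

    def test_missing_feature_column_raises(self):
        X, recs, _ = simulated_cohort(44, n=80, n_tads=3)
        fm = survival.FinalModel(
            ["tad_00"], pd.Series({"tad_00": 0.7}), pd.Series({"tad_00": 2.0}),
            pd.Series({"tad_00": 0.01}), pd.Series({"tad_00": 0.01}))
        with pytest.raises(ValueError, match="tad_00"):
            survival.evaluate_external(fm, X.drop(columns=["tad_00"]), recs)

    @pytest.mark.parametrize("cis,expected", [
        ([0.58, 0.6, 0.56], True),   # median 0.58: reliable
        ([0.52, 0.53, 0.51], False), # median 0.52: unreliable
        ([0.9, 0.92, 0.88], False),  # above the band
    ])
    def test_reliability_band(self, cis, expected):
        runs = [survival.ModelRun(i, [], [], (), pd.Series(dtype=float), 0.1, c)
                for i, c in enumerate(cis)]
        assert survival.reliability_flag(runs) is expected
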