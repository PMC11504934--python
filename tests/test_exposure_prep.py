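import warnings

import numpy as np
import pandas as pd
import pytest

from exwaskit import (
    ExposureSpec, simulate_cohort, combine_hour_minute, filter_low_endorsement,
    remove_outliers, prune_collinear, impute_missforest, run_prep,
    specs_for_cohort,
)
from exwaskit.exposure_prep import _greedy_prune
from exwaskit.io import exposure_columns

from conftest import quick_config


def _spec(name, measurement="continuous", **kw):
    return ExposureSpec(name=name, measurement=measurement, **kw)


class TestCombineHourMinute:
    def _table(self, hours, minutes):
        return pd.DataFrame({"t_hours": hours, "t_minutes": minutes})

    def _specs(self):
        return [
            _spec("t_hours"),
            _spec("t_minutes", combine_with="t_hours"),
        ]

    def test_basic_arithmetic(self):
        out = combine_hour_minute(self._table([2.0], [30.0]), self._specs())
        assert out["t_hours"].iloc[0] == 2.5
        assert "t_minutes" not in out.columns

    def test_zero_case(self):
        out = combine_hour_minute(self._table([0.0], [0.0]), self._specs())
        assert out["t_hours"].iloc[0] == 0.0

    def test_missing_component_counts_as_zero(self):
        out = combine_hour_minute(self._table([np.nan], [45.0]), self._specs())
        assert out["t_hours"].iloc[0] == pytest.approx(0.75)

    def test_both_missing_stays_missing(self):
        out = combine_hour_minute(self._table([np.nan], [np.nan]), self._specs())
        assert np.isnan(out["t_hours"].iloc[0])

    def test_negative_fails(self):
        with pytest.raises(ValueError, match="negative"):
            combine_hour_minute(self._table([1.0], [-5.0]), self._specs())

    def test_dangling_target_fails(self):
        df = pd.DataFrame({"t_minutes": [3.0]})
        with pytest.raises(ValueError, match="no spec"):
            combine_hour_minute(df, [_spec("t_minutes", combine_with="gone")])


class TestEndorsementFilter:
    def test_below_threshold_dropped(self):
        df = pd.DataFrame({"b": [1.0] + [0.0] * 999})  # endorsement 0.001
        out, dropped = filter_low_endorsement(df, [_spec("b", "binary")])
        assert dropped == ["b"] and "b" not in out.columns

    def test_exactly_threshold_retained(self):
        df = pd.DataFrame({"b": [1.0] + [0.0] * 99})  # exactly 1%
        out, dropped = filter_low_endorsement(df, [_spec("b", "binary")])
        assert dropped == [] and "b" in out.columns

    def test_endorsement_over_nonmissing_only(self):
        # 1 of 50 observed = 2% endorsed even though 1 of 100 rows overall
        vals = [1.0] + [0.0] * 49 + [np.nan] * 50
        df = pd.DataFrame({"b": vals})
        _, dropped = filter_low_endorsement(df, [_spec("b", "binary")])
        assert dropped == []

    def test_generator_rare_variables_dropped(self):
        cfg = quick_config(n_families=3000, mean_children_per_family=1.0,
                           n_exposures=12, n_rare_binary=3,
                           missing_rate=0.0, seed=13)
        cohort, truth = simulate_cohort(cfg)
        specs = specs_for_cohort(truth)
        _, dropped = filter_low_endorsement(cohort, specs)
        assert sorted(dropped) == sorted(truth.rare_exposures)

    def test_non_binary_untouched(self):
        df = pd.DataFrame({"c": [0.001] * 100})
        _, dropped = filter_low_endorsement(df, [_spec("c", "continuous")])
        assert dropped == []


class TestOutlierRule:
    def test_hand_computed_four_point_sample(self):
        # order statistics: Q1=1, Q3=3, IQR=2 -> cut 3 + 3*2 = 9
        df = pd.DataFrame({"c": [1.0, 2.0, 3.0, 1000.0]})
        out, counts = remove_outliers(df, [_spec("c", outlier_rule_applies=True)])
        assert counts == {"c": 1}
        assert np.isnan(out["c"].iloc[3])

    def test_constant_variable_untouched(self):
        df = pd.DataFrame({"c": [5.0] * 20})
        out, counts = remove_outliers(df, [_spec("c", outlier_rule_applies=True)])
        assert counts == {} and not out["c"].isna().any()

    def test_infinite_k_is_noop(self):
        df = pd.DataFrame({"c": [1.0, 2.0, 3.0, 1e9]})
        out, counts = remove_outliers(df, [_spec("c", outlier_rule_applies=True)],
                                      k=np.inf)
        assert counts == {}
        pd.testing.assert_frame_equal(out, df)

    def test_only_flagged_continuous(self):
        df = pd.DataFrame({"c": [1.0, 2.0, 3.0, 1000.0],
                           "d": [1.0, 2.0, 3.0, 1000.0]})
        specs = [_spec("c", outlier_rule_applies=True), _spec("d")]
        out, counts = remove_outliers(df, specs)
        assert "d" not in counts and out["d"].iloc[3] == 1000.0

    def test_all_missing_warns_and_skips(self):
        df = pd.DataFrame({"c": [np.nan, np.nan]})
        with pytest.warns(RuntimeWarning, match="all missing"):
            _, counts = remove_outliers(df, [_spec("c", outlier_rule_applies=True)])
        assert counts == {}


class TestCollinearPruning:
    def test_greedy_hand_trace(self):
        corr = pd.DataFrame(
            [[1.0, 0.95, 0.5], [0.95, 1.0, 0.1], [0.5, 0.1, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        # mean |r|: A = .725 > B = .525 -> drop A
        assert _greedy_prune(corr, 0.9) == ["A"]

    def test_no_pair_exceeds_threshold(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        out, dropped = prune_collinear(df, list("abcd"))
        assert dropped == []

    def test_generator_collinear_pairs_pruned(self):
        cfg = quick_config(n_families=2000, n_collinear_pairs=4, n_exposures=16,
                           n_true_risk=2, n_true_protective=0,
                           missing_rate=0.0, seed=5)
        cohort, truth = simulate_cohort(cfg)
        out, dropped = prune_collinear(cohort, exposure_columns(cohort))
        assert len(dropped) == 4
        # exactly one member of each planted pair is gone
        for a, b in truth.collinear_pairs:
            assert (a in dropped) ^ (b in dropped)

    def test_row_order_invariance(self, small_cohort):
        cohort, _ = small_cohort
        shuffled = cohort.sample(frac=1.0, random_state=3)
        _, d1 = prune_collinear(cohort, exposure_columns(cohort))
        _, d2 = prune_collinear(shuffled, exposure_columns(shuffled))
        assert d1 == d2

    def test_train_only_decision(self, small_cohort):
        # corrupting test-subsample values must not change the decision
        cohort, _ = small_cohort
        rigged = cohort.copy()
        cols = exposure_columns(cohort)
        test_mask = rigged["subsample"] == "test"
        rigged.loc[test_mask, cols[0]] = rigged.loc[test_mask, cols[1]]
        _, d1 = prune_collinear(cohort, cols)
        _, d2 = prune_collinear(rigged, cols)
        assert d1 == d2

    def test_zero_variance_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=100),
                           "b": np.ones(100)})
        df["c"] = df["a"] * 0.99 + rng.normal(0, 0.01, 100)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            _, dropped = prune_collinear(df, ["a", "b", "c"])
        assert "b" not in dropped and len(dropped) == 1

    def test_too_few_exposures(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 2"):
            prune_collinear(df, ["a"])


class TestMissForest:
    def _mcar_copy_table(self, rng, n=400):
        base = rng.normal(size=n)
        df = pd.DataFrame({
            "x1": base,
            "x2": base.copy(),          # noiseless copy of x1
            "x3": rng.normal(size=n),
        })
        mask = rng.random(n) < 0.10
        truth = df["x2"].copy()
        df.loc[mask, "x2"] = np.nan
        return df, truth, mask

    def _specs(self, df):
        return [_spec(c, "continuous") for c in df.columns]

    def test_no_missing_returns_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x1", "x2", "x3"])
        out, report = impute_missforest(df, self._specs(df), seed=0)
        pd.testing.assert_frame_equal(out, df)
        assert report.imputation_iterations == 0

    def test_noiseless_copy_nrmse_small(self, rng):
        df, truth, mask = self._mcar_copy_table(rng)
        out, _ = impute_missforest(df, self._specs(df), n_trees=50, seed=0)
        err = out.loc[mask, "x2"] - truth[mask]
        nrmse = np.sqrt((err ** 2).mean()) / truth.std()
        assert nrmse < 0.05

    def test_seed_determinism(self, rng):
        df, _, _ = self._mcar_copy_table(rng)
        out1, _ = impute_missforest(df, self._specs(df), n_trees=20, seed=9)
        out2, _ = impute_missforest(df, self._specs(df), n_trees=20, seed=9)
        pd.testing.assert_frame_equal(out1, out2)

    def test_observed_cells_never_altered(self, rng):
        df, _, mask = self._mcar_copy_table(rng)
        out, _ = impute_missforest(df, self._specs(df), n_trees=20, seed=0)
        observed = df.notna()
        pd.testing.assert_frame_equal(out[observed], df[observed])
        assert not out.isna().any().any()

    def test_zero_observed_variable_fails(self):
        df = pd.DataFrame({"x1": [1.0, 2.0, 3.0], "x2": [np.nan] * 3})
        with pytest.raises(ValueError, match="x2"):
            impute_missforest(df, self._specs(df), seed=0)

    def test_binary_imputations_stay_binary(self, rng):
        n = 300
        df = pd.DataFrame({
            "b": (rng.random(n) < 0.4).astype(float),
            "x": rng.normal(size=n),
        })
        df.loc[rng.random(n) < 0.15, "b"] = np.nan
        specs = [_spec("b", "binary"), _spec("x", "continuous")]
        out, _ = impute_missforest(df, specs, n_trees=20, seed=1)
        assert set(out["b"].unique()) <= {0.0, 1.0}

    def test_train_test_imputed_separately(self, rng):
        n = 200
        df = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(n)],
            "subsample": ["train"] * (n // 2) + ["test"] * (n // 2),
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        })
        df.loc[rng.random(n) < 0.2, "x1"] = np.nan
        specs = [_spec("x1"), _spec("x2")]
        out_joint, _ = impute_missforest(df, specs, n_trees=15, seed=2)
        # altering only test rows must not change train imputations
        rigged = df.copy()
        rigged.loc[rigged["subsample"] == "test", "x2"] *= 10
        out_rigged, _ = impute_missforest(rigged, specs, n_trees=15, seed=2)
        train = df["subsample"] == "train"
        pd.testing.assert_series_equal(out_joint.loc[train, "x1"],
                                       out_rigged.loc[train, "x1"])

    def test_beats_mean_imputation_under_mar(self):
        # spec sanity bound, scaled down: forest beats column-mean fill
        wins = 0
        n_reps = 50
        for rep in range(n_reps):
            rng = np.random.default_rng(rep)
            n = 250
            driver = rng.normal(size=n)
            df = pd.DataFrame({
                "age": rng.normal(12, 0.6, n),
                "income_ordinal": rng.integers(1, 11, n).astype(float),
                "x1": driver + 0.3 * rng.normal(size=n),
                "x2": driver + 0.3 * rng.normal(size=n),
            })
            # MAR on covariates: low income more likely missing
            p = 1 / (1 + np.exp(0.5 * (df["income_ordinal"] - 5)))
            mask = rng.random(n) < 0.4 * p
            truth = df["x1"].copy()
            df.loc[mask, "x1"] = np.nan
            if mask.sum() < 5:
                continue
            specs = [_spec("x1"), _spec("x2")]
            out, _ = impute_missforest(df, specs, n_trees=15, max_iter=2,
                                       seed=rep)
            rf_err = ((out.loc[mask, "x1"] - truth[mask]) ** 2).mean()
            mean_err = ((df["x1"].mean() - truth[mask]) ** 2).mean()
            wins += rf_err < mean_err
        assert wins / n_reps > 0.9


class TestPipeline:
    def test_order_of_operations(self, monkeypatch, small_cohort):
        cohort, truth = small_cohort
        calls = []
        import exwaskit.exposure_prep as ep

        def tracker(name, fn):
            def wrapped(*a, **k):
                calls.append(name)
                return fn(*a, **k)
            return wrapped

        monkeypatch.setattr(ep, "combine_hour_minute",
                            tracker("combine", ep.combine_hour_minute))
        monkeypatch.setattr(ep, "filter_low_endorsement",
                            tracker("filter", ep.filter_low_endorsement))
        monkeypatch.setattr(ep, "remove_outliers",
                            tracker("outliers", ep.remove_outliers))
        monkeypatch.setattr(ep, "impute_missforest",
                            tracker("impute", ep.impute_missforest))
        monkeypatch.setattr(ep, "prune_collinear",
                            tracker("prune", ep.prune_collinear))
        ep.run_prep(cohort, specs_for_cohort(truth), n_trees=10, max_iter=1,
                    seed=0)
        assert calls == ["combine", "filter", "outliers", "impute", "prune"]

    def test_report_bookkeeping(self, small_cohort):
        cohort, truth = small_cohort
        prepped, report = run_prep(cohort, specs_for_cohort(truth),
                                   n_trees=10, max_iter=2, seed=0)
        assert report.n_retained == (report.n_input
                                     - len(report.dropped_low_endorsement)
                                     - len(report.dropped_collinear))
        retained = exposure_columns(prepped)
        assert len(retained) == report.n_retained
        assert not prepped[retained].isna().any().any()

    def test_listwise_variant_skips_imputation(self, small_cohort):
        cohort, truth = small_cohort
        prepped, report = run_prep(cohort, specs_for_cohort(truth),
                                   listwise=True, seed=0)
        assert report.imputation_iterations == 0
        assert prepped[exposure_columns(prepped)].isna().any().any()

    def test_no_outlier_removal_flag(self, small_cohort):
        cohort, truth = small_cohort
        _, report = run_prep(cohort, specs_for_cohort(truth),
                             no_outlier_removal=True, listwise=True, seed=0)
        assert report.outliers_removed == {}
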