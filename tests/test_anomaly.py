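"""One-class model: sample assembly, nu-property, CV grid, baselines."""

import math

import numpy as np
import pandas as pd
import pytest

from cagewatch.anomaly import (FEATURES, OneClassModel, assemble_samples,
                               baseline_compare, comparison_table,
                               debounce_alerts, fit_one_class, predict,
                               select_params, training_anomaly_fraction)
from cagewatch.config import ConfigError


def feature_frame(X, t0=0):
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(FEATURES))
    df.insert(0, "t", np.arange(t0, t0 + len(df)))
    return df


def gaussian_features(n, seed, loc=0.0):
    rng = np.random.default_rng(seed)
    return feature_frame(rng.normal(loc=loc, size=(n, 5)))


class TestAssembleSamples:
    def test_incomplete_frames_excluded(self):
        df = gaussian_features(10, 0)
        df.loc[[2, 4, 5, 8], "r"] = np.nan          # missing eye -> no r
        sm = assemble_samples(df)
        assert sm.n_samples == 6
        assert set(sm.frame_index) == {0, 1, 3, 6, 7, 9}

    def test_row_count_matches_bruteforce_flag_recount(self):
        rng = np.random.default_rng(5)
        df = gaussian_features(200, 5)
        for col in FEATURES:
            df.loc[rng.random(200) < 0.2, col] = np.nan
        sm = assemble_samples(df)
        brute = sum(1 for _, row in df.iterrows()
                    if all(not math.isnan(row[c]) for c in FEATURES))
        assert sm.n_samples == brute

    def test_constant_feature_dropped_with_warning(self):
        df = gaussian_features(50, 1)
        df["h"] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            sm = assemble_samples(df)
        assert "h" not in sm.feature_names and sm.X.shape[1] == 4

    def test_all_rows_incomplete_is_an_error(self):
        df = gaussian_features(5, 2)
        df["m"] = np.nan
        with pytest.raises(ConfigError, match="complete"):
            assemble_samples(df)

    def test_training_stats_reused_for_evaluation(self):
        train = gaussian_features(100, 3)
        ev = gaussian_features(50, 4, loc=2.0)
        sm_tr = assemble_samples(train)
        sm_ev = assemble_samples(ev, stats=(sm_tr.mean, sm_tr.sd))
        # eval standardized with *training* stats keeps the shift visible
        assert sm_ev.X.mean() == pytest.approx(2.0, abs=0.4)


class TestOneClassModel:
    def test_far_outlier_flagged_and_medoid_normal(self):
        train = gaussian_features(300, 0)
        sm = assemble_samples(train)
        model = fit_one_class(sm, nu=0.05, kernel_gamma=0.2)
        far = sm.X.mean(axis=0) + 10 * sm.X.std(axis=0) * 5
        medoid = sm.X[np.argmin(((sm.X - sm.X.mean(0)) ** 2).sum(1))]
        from cagewatch.anomaly import SampleMatrix
        probe = SampleMatrix(X=np.vstack([far, medoid]),
                             frame_index=np.array([0, 1]), mean=sm.mean,
                             sd=sm.sd, feature_names=sm.feature_names)
        f = predict(model, probe)["f"].to_numpy()
        assert f[0] == 1 and f[1] == 0

    @pytest.mark.parametrize("nu", [0.05, 0.2])
    def test_nu_property_across_seeds(self, nu):
        q = 400
        for seed in range(10):
            sm = assemble_samples(gaussian_features(q, seed))
            model = fit_one_class(sm, nu=nu, kernel_gamma=0.2)
            frac = training_anomaly_fraction(model, sm)
            assert frac <= nu + 2 / math.sqrt(q)

    def test_duplicated_rows_get_identical_labels(self):
        sm = assemble_samples(gaussian_features(100, 7))
        model = fit_one_class(sm, nu=0.1, kernel_gamma=0.3)
        from cagewatch.anomaly import SampleMatrix
        dup = SampleMatrix(X=np.vstack([sm.X, sm.X]),
                           frame_index=np.arange(2 * sm.n_samples),
                           mean=sm.mean, sd=sm.sd,
                           feature_names=sm.feature_names)
        f = predict(model, dup)["f"].to_numpy()
        assert np.array_equal(f[:sm.n_samples], f[sm.n_samples:])

    def test_scale_covariance_of_raw_features(self):
        df = gaussian_features(200, 8)
        scaled = df.copy()
        scaled["m"] = scaled["m"] * 10.0
        m1 = fit_one_class(assemble_samples(df), 0.05, 0.2)
        m2 = fit_one_class(assemble_samples(scaled), 0.05, 0.2)
        f1 = predict(m1, assemble_samples(df, stats=(m1.mean, m1.sd)))
        f2 = predict(m2, assemble_samples(scaled, stats=(m2.mean, m2.sd)))
        assert np.array_equal(f1["f"].to_numpy(), f2["f"].to_numpy())

    def test_empty_eval_and_column_mismatch(self):
        sm = assemble_samples(gaussian_features(50, 9))
        model = fit_one_class(sm, 0.1, 0.2)
        from cagewatch.anomaly import SampleMatrix
        empty = SampleMatrix(X=np.empty((0, 5)), frame_index=np.array([]),
                             mean=sm.mean, sd=sm.sd,
                             feature_names=sm.feature_names)
        assert len(predict(model, empty)) == 0
        bad = SampleMatrix(X=np.zeros((3, 2)), frame_index=np.arange(3),
                           mean=sm.mean[:2], sd=sm.sd[:2],
                           feature_names=("m", "r"))
        with pytest.raises(ConfigError):
            predict(model, bad)

    def test_parameter_validation(self):
        sm = assemble_samples(gaussian_features(10, 10))
        with pytest.raises(ConfigError):
            fit_one_class(sm, nu=0.0, kernel_gamma=0.2)
        with pytest.raises(ConfigError):
            fit_one_class(sm, nu=0.1, kernel_gamma=-1.0)

    def test_save_load_round_trip(self, tmp_path):
        sm = assemble_samples(gaussian_features(80, 11))
        model = fit_one_class(sm, 0.05, 0.25)
        path = tmp_path / "model.bin"
        model.save(path)
        loaded = OneClassModel.load(path)
        assert np.array_equal(predict(model, sm)["f"],
                              predict(loaded, sm)["f"])
        assert loaded.nu == model.nu and loaded.kernel_gamma == 0.25


class TestSelectParams:
    def test_tie_breaks_toward_smallest_parameters(self):
        # a tight cluster: every grid point classifies all held-out normal
        rng = np.random.default_rng(0)
        df = feature_frame(rng.normal(scale=0.01, size=(100, 5)))
        sm = assemble_samples(df)
        nu, gamma, report = select_params(sm, nu_grid=(0.01, 0.001),
                                          gamma_grid=(0.3, 0.1, 0.2),
                                          k_folds=3, seed=0)
        top = report["mean_normal_rate"].max()
        ties = report[report["mean_normal_rate"] == top]
        assert nu == ties["nu"].min()
        assert gamma == ties[ties["nu"] == nu]["gamma"].min()

    def test_deterministic_given_seed(self):
        sm = assemble_samples(gaussian_features(120, 12))
        r1 = select_params(sm, (0.001, 0.01), (0.1, 0.5), 3, seed=42)
        r2 = select_params(sm, (0.001, 0.01), (0.1, 0.5), 3, seed=42)
        assert r1[0] == r2[0] and r1[1] == r2[1]
        pd.testing.assert_frame_equal(r1[2], r2[2])

    def test_grid_validation(self):
        sm = assemble_samples(gaussian_features(20, 13))
        with pytest.raises(ConfigError):
            select_params(sm, (), (0.1,), 3, 0)
        with pytest.raises(ConfigError):
            select_params(sm, (0.01,), (0.1,), 1, 0)


class TestDebounce:
    def test_runs_shorter_than_threshold_suppressed(self):
        dec = pd.DataFrame({"t": range(10),
                            "f": [0, 1, 1, 0, 1, 1, 1, 1, 0, 1]})
        alerts = debounce_alerts(dec, consecutive=3)
        assert len(alerts) == 1
        assert alerts.iloc[0]["onset_frame"] == 4
        assert alerts.iloc[0]["alert_frame"] == 6

    def test_consecutive_one_reports_every_onset(self):
        dec = pd.DataFrame({"t": range(6), "f": [1, 0, 1, 1, 0, 1]})
        assert len(debounce_alerts(dec, consecutive=1)) == 3


class TestBaselineCompare:
    def _two_class(self, seed=0, n=150):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(loc=0.0, size=(n, 5))
        X1 = rng.normal(loc=4.0, size=(n, 5))
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        perm = rng.permutation(len(y))
        return X[perm], y[perm]

    def test_separable_classes_near_perfect(self):
        Xtr, ytr = self._two_class(0)
        Xev, yev = self._two_class(1)
        out = baseline_compare(Xtr, ytr, Xev, yev, seed=0)
        for name, m in out.items():
            acc = (m[0, 0] + m[1, 1]) / m.sum()
            assert acc >= 0.95, name

    def test_confusion_rows_sum_to_class_counts(self):
        Xtr, ytr = self._two_class(2)
        Xev, yev = self._two_class(3)
        out = baseline_compare(Xtr, ytr, Xev, yev, seed=0)
        for m in out.values():
            assert m[0].sum() == (yev == 0).sum()
            assert m[1].sum() == (yev == 1).sum()

    def test_shuffled_labels_fall_to_chance(self):
        # single-cloud data with hyperplane labels: after permuting the
        # training labels no local structure remains to exploit, so eval
        # accuracy must drop to the majority-class rate
        rng = np.random.default_rng(4)
        w = np.ones(5)
        Xtr = rng.normal(size=(300, 5))
        ytr = (Xtr @ w > 0).astype(int)
        Xev = rng.normal(size=(300, 5))
        yev = (Xev @ w > 0).astype(int)
        ytr_shuf = rng.permutation(ytr)
        out = baseline_compare(Xtr, ytr_shuf, Xev, yev, seed=0)
        majority = max((yev == 0).mean(), (yev == 1).mean())
        for name, m in out.items():
            acc = (m[0, 0] + m[1, 1]) / m.sum()
            assert acc <= majority + 0.15, name

    def test_single_class_training_rejected(self):
        X, y = self._two_class(6)
        with pytest.raises(ConfigError):
            baseline_compare(X, np.zeros_like(y), X, y)

    def test_markdown_table_lists_all_methods(self):
        X, y = self._two_class(7)
        out = baseline_compare(X, y, X, y, seed=0)
        text = comparison_table(out)
        for name in ("SVM", "LDA", "MLP"):
            assert name in text
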