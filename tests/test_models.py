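"""Boosted-tree training, tuning, metrics, importance, model comparison."""

import numpy as np
import pandas as pd
import pytest

import ioneff.models as m


def _matrix(rng, n=80, p=6):
    X = pd.DataFrame(
        (rng.random((n, p)) < 0.5).astype(float),
        columns=[f"f{i}" for i in range(p)],
    )
    return X


FAST = {"n_trees": 300, "min_samples_leaf": 4, "learning_rate": 0.1,
        "max_depth": 6, "subsample": 1.0, "colsample": 1.0, "random_state": 1}


class TestEvaluate:
    def test_perfect_fit(self):
        r = m.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.q2, r.mae, r.rmse) == (1.0, 0.0, 0.0)

    def test_mean_predictor_scores_zero(self):
        r = m.evaluate([0.0, 2.0], [1.0, 1.0])
        assert (r.q2, r.mae, r.rmse) == (0.0, 1.0, 1.0)

    def test_matches_formula_oracle(self, rng):
        y = rng.normal(size=50)
        p = y + rng.normal(scale=0.3, size=50)
        r = m.evaluate(y, p)
        assert r.q2 == pytest.approx(1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2))
        assert r.mae == pytest.approx(np.mean(np.abs(y - p)))
        assert r.rmse == pytest.approx(np.sqrt(np.mean((y - p) ** 2)))
        assert r.rmse >= r.mae >= 0

    def test_zero_variance_targets_undefined_q2(self):
        r = m.evaluate([1.0, 1.0, 1.0], [1.0, 0.5, 1.5])
        assert np.isnan(r.q2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            m.evaluate([1.0], [1.0, 2.0])


class TestTrainPredict:
    def test_constant_target_predicts_constant(self, rng):
        X = _matrix(rng)
        model = m.train(X, np.full(len(X), 2.5), FAST)
        assert m.predict(model, X) == pytest.approx(np.full(len(X), 2.5))

    def test_separable_signal_fits_to_zero_error(self, rng):
        X = _matrix(rng, n=100, p=3)
        y = 1.0 + 2.0 * X["f0"].to_numpy()
        model = m.train(X, y, FAST)
        assert m.evaluate(y, m.predict(model, X)).rmse < 1e-3

    def test_duplicated_row_duplicated_prediction(self, rng):
        X = _matrix(rng)
        model = m.train(X, rng.normal(size=len(X)), FAST)
        X2 = pd.concat([X.iloc[[0]], X.iloc[[0]]], ignore_index=True)
        p = m.predict(model, X2)
        assert p[0] == p[1]

    def test_permuted_rows_permuted_predictions(self, rng):
        X = _matrix(rng)
        model = m.train(X, rng.normal(size=len(X)), FAST)
        perm = rng.permutation(len(X))
        assert m.predict(model, X.iloc[perm]) == pytest.approx(
            m.predict(model, X)[perm]
        )

    def test_schema_mismatch_names_columns(self, rng):
        X = _matrix(rng)
        model = m.train(X, rng.normal(size=len(X)), FAST)
        bad = X.rename(columns={"f0": "other"})
        with pytest.raises(ValueError, match="f0"):
            m.predict(model, bad)

    def test_non_finite_targets_rejected(self, rng):
        X = _matrix(rng)
        with pytest.raises(ValueError):
            m.train(X, np.full(len(X), np.nan), FAST)

    def test_too_few_rows_rejected(self, rng):
        X = _matrix(rng, n=5)
        with pytest.raises(ValueError):
            m.train(X, np.zeros(5), FAST)

    def test_save_load_round_trip(self, rng, tmp_path):
        X = _matrix(rng)
        model = m.train(X, rng.normal(size=len(X)), FAST)
        m.save_model(model, tmp_path / "model.txt")
        loaded = m.load_model(tmp_path / "model.txt")
        assert m.predict(loaded, X) == pytest.approx(m.predict(model, X))
        assert loaded.feature_names == model.feature_names


class TestRandomizedSearch:
    def test_single_point_space(self, rng):
        X = _matrix(rng)
        y = rng.normal(size=len(X))
        space = m.SearchSpace({k: [v] for k, v in FAST.items()})
        best, trace = m.randomized_search(space, X, y, n_iter=3, seed=1)
        assert best == FAST
        assert len(trace) == 3

    def test_same_seed_identical_trace(self, rng):
        X = _matrix(rng)
        y = rng.normal(size=len(X))
        a = m.randomized_search(m.FP_SEARCH_SPACE, X, y, n_iter=3, seed=7)
        b = m.randomized_search(m.FP_SEARCH_SPACE, X, y, n_iter=3, seed=7)
        assert a == b

    def test_planted_better_point_wins(self, rng):
        X = _matrix(rng, n=120, p=4)
        y = 3.0 * X["f0"].to_numpy() + rng.normal(scale=0.05, size=len(X))
        # one point cannot learn anything (zero-ish trees budget), the other can
        space = m.SearchSpace(
            {**{k: [v] for k, v in FAST.items()}, "n_trees": [1, 300],
             "learning_rate": [0.1]}
        )
        best, trace = m.randomized_search(space, X, y, n_iter=12, seed=2)
        assert best["n_trees"] == 300

    def test_requires_positive_iterations(self, rng):
        X = _matrix(rng)
        with pytest.raises(ValueError):
            m.randomized_search(m.FP_SEARCH_SPACE, X, np.zeros(len(X)), n_iter=0)


class TestImportance:
    def test_percentages_sum_to_100_descending(self, rng):
        X = _matrix(rng, n=150, p=5)
        y = 2 * X["f1"].to_numpy() + X["f3"].to_numpy() + rng.normal(
            scale=0.1, size=len(X)
        )
        imp = m.feature_importance(m.train(X, y, FAST))
        assert imp["percent"].sum() == pytest.approx(100.0, abs=0.1)
        assert list(imp["percent"]) == sorted(imp["percent"], reverse=True)

    def test_single_informative_feature_takes_all(self, rng):
        X = _matrix(rng, n=100, p=1)
        y = X["f0"].to_numpy() * 2
        imp = m.feature_importance(m.train(X, y, FAST))
        assert imp.loc[0, "feature"] == "f0"
        assert imp.loc[0, "percent"] == pytest.approx(100.0)

    def test_unused_feature_scores_zero(self, rng):
        X = _matrix(rng, n=150, p=4)
        X["constant"] = 0.0  # never splittable
        y = X["f0"].to_numpy() + rng.normal(scale=0.05, size=len(X))
        imp = m.feature_importance(m.train(X, y, FAST)).set_index("feature")
        assert imp.loc["constant", "percent"] == 0.0

    def test_planted_dominant_feature_ranks_first(self, rng):
        X = _matrix(rng, n=200, p=6)
        y = 5 * X["f2"].to_numpy() + 0.2 * X["f0"].to_numpy() + rng.normal(
            scale=0.05, size=len(X)
        )
        imp = m.feature_importance(m.train(X, y, FAST))
        assert imp.loc[0, "feature"] == "f2"


class TestCompareFpCnl:
    def test_identical_predictions(self):
        s = m.compare_fp_cnl([1.0, 2.0], [1.0, 2.0])
        assert s["rmse"] == 0.0
        assert s["frac_within_factor_3"] == 1.0
        assert s["frac_within_bound"] == 1.0

    def test_factor_boundary_is_inclusive(self):
        res = np.full(4, np.log10(3.0))
        s = m.compare_fp_cnl(np.zeros(4), res)
        assert s["frac_within_factor_3"] == 1.0

    def test_matches_counting_oracle(self, rng):
        fp = rng.normal(size=100)
        cnl = fp + rng.normal(scale=0.8, size=100)
        s = m.compare_fp_cnl(fp, cnl, abs_error_bound=0.5)
        res = cnl - fp
        assert s["rmse"] == pytest.approx(np.sqrt(np.mean(res**2)))
        assert s["frac_within_bound"] == pytest.approx(
            np.mean(np.abs(res) <= 0.5)
        )
        assert s["frac_within_factor_10"] == pytest.approx(
            np.mean(10 ** np.abs(res) <= 10)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            m.compare_fp_cnl([1.0], [1.0, 2.0])


def test_q2_degrades_as_label_noise_grows():
    """Mean held-out Q² over 10 seeds falls monotonically for sigma in
    {0.1, 0.5, 1.0} on the synthetic CNL-track pipeline."""
    from ioneff.compounds import aggregate_measurements
    from ioneff.synthetic import (
        SimulationConfig, simulate_compounds, simulate_ie, simulate_spectra,
    )
    from ioneff.workflows import train_cnl_workflow

    light = {**FAST, "n_trees": 150, "cnl_min": 0, "s_min": 0.0,
             "consensus_algorithm": "filter"}
    means = []
    for sigma in (0.1, 0.5, 1.0):
        q2s = []
        for seed in range(10):
            config = SimulationConfig(
                seed=100 + seed, n_compounds=40, spectra_per_compound=1,
                ie_noise_sd=sigma,
            )
            compounds = simulate_compounds(config)
            entries = aggregate_measurements(simulate_ie(compounds, config))
            sim = simulate_spectra(compounds, config)
            result = train_cnl_workflow(
                entries, sim.spectra, params=light, seed=seed + 1
            )
            q2s.append(result.test_report.q2)
        means.append(np.mean(q2s))
    assert means[0] > means[1] > means[2]
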