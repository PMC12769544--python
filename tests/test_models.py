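"""Logistic combination models, cutoffs, combi-scores, and evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from panelroc import (
    Combination,
    CombinationModel,
    MarkerTable,
    cluster_median_scores,
    combi_score,
    evaluate_classification,
    fit_combination_model,
    optimal_cutoff,
    roc_auc,
    sigmoid,
)
from panelroc.errors import DegenerateCutoffError, MarkerMismatchError
from panelroc.threshold import ROCCoordinates


def make_model(members, intercept, coefs, cutoff=0.5):
    empty = np.array([])
    return CombinationModel(
        combination=Combination(id=1, members=tuple(members)),
        intercept=intercept,
        coefficients=dict(zip(members, coefs)),
        roc=ROCCoordinates(empty, empty, empty, empty),
        auc=1.0,
        optimal_cutoff=cutoff,
        training_se=1.0,
        training_sp=1.0,
    )


def simulate_logistic(rng, beta0, betas, n):
    X = rng.normal(5.0, 2.0, size=(n, len(betas)))
    p = sigmoid(beta0 + X @ np.array(betas))
    y = (rng.random(n) < p).astype(int)
    signals = pd.DataFrame(
        X, columns=[f"m{i}" for i in range(len(betas))],
        index=pd.Index([f"s{i}" for i in range(n)], name="ID"),
    )
    classes = pd.Series(np.where(y == 1, "case", "ctrl"), index=signals.index)
    return MarkerTable(signals=signals, classes=classes,
                       case_label="case", control_label="ctrl")


class TestOptimalCutoff:
    def test_perfect_separation_gives_midpoint(self):
        cutoff = optimal_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert cutoff == 0.5

    def test_matches_exhaustive_minimum_error_search(self):
        scores = np.array([0.9, 0.3, 0.8, 0.6, 0.2, 0.4, 0.7, 0.1])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])  # one misranked case
        cutoff = optimal_cutoff(scores, labels)
        distinct = np.unique(scores)
        candidates = (distinct[:-1] + distinct[1:]) / 2

        def errors(c):
            return int(((scores > c) != labels.astype(bool)).sum())

        best = min(errors(c) for c in candidates)
        assert errors(cutoff) == best

    @pytest.mark.parametrize("seed", range(5))
    def test_optimality_over_all_candidates(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(60), 2)
        labels = rng.integers(0, 2, 60)
        if len(np.unique(labels)) < 2 or len(np.unique(scores)) < 2:
            pytest.skip("degenerate draw")
        cutoff = optimal_cutoff(scores, labels)
        distinct = np.unique(scores)
        candidates = (distinct[:-1] + distinct[1:]) / 2
        err = lambda c: int(((scores > c) != labels.astype(bool)).sum())
        assert all(err(cutoff) <= err(c) for c in candidates)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(21)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        c1 = optimal_cutoff(scores, labels)
        c2 = optimal_cutoff(-scores, 1 - labels)
        err1 = int(((scores > c1) != labels.astype(bool)).sum())
        err2 = int(((-scores > c2) != (1 - labels).astype(bool)).sum())
        assert err1 == err2

    def test_identical_scores_rejected(self):
        with pytest.raises(DegenerateCutoffError):
            optimal_cutoff([0.5, 0.5, 0.5], [1, 0, 1])


class TestAUC:
    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(5, 250), rng.integers(5, 250)
        scores = np.concatenate([
            rng.normal(1, 1, n1), rng.normal(0, 1, n0)
        ])
        scores = np.round(scores, 1)  # force ties
        labels = np.array([1] * n1 + [0] * n0)
        _, auc = roc_auc(scores, labels)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0],
                         alternative="two-sided").statistic
        assert abs(auc - u / (n1 * n0)) < 1e-10


class TestFitting:
    def test_zero_linear_predictor_scores_half(self, tiny_table):
        model = make_model(["A", "B"], 0.0, [0.0, 0.0])
        res = combi_score(tiny_table, model)
        assert np.allclose(res.combi_score, 0.5)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(2024)
        true = np.array([-3.0, 0.8, -0.5])
        t = simulate_logistic(rng, true[0], true[1:], n=5000)
        model = fit_combination_model(t, Combination(id=1, members=("m0", "m1")))
        import statsmodels.api as sm

        X = sm.add_constant(t.signals[["m0", "m1"]].to_numpy())
        fit = sm.GLM(t.class_binary().to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        est = np.array([model.intercept, *model.coefficients.values()])
        assert np.all(np.abs(est - true) <= 3 * fit.bse)

    def test_independent_labels_give_null_auc(self):
        rng = np.random.default_rng(3)
        t = simulate_logistic(rng, 0.0, [0.0], n=2000)
        model = fit_combination_model(t, Combination(id=1, members=("m0",)))
        assert abs(model.auc - 0.5) < 0.05

    def test_separation_is_flagged_not_fatal(self):
        signals = pd.DataFrame(
            {"m": [10.0, 9.0, 8.0, 1.0, 2.0, 0.5]},
            index=pd.Index([f"s{i}" for i in range(6)], name="ID"),
        )
        classes = pd.Series(["c"] * 3 + ["n"] * 3, index=signals.index)
        t = MarkerTable(signals=signals, classes=classes,
                        case_label="c", control_label="n")
        with pytest.warns(UserWarning, match="separation"):
            model = fit_combination_model(t, Combination(id=1, members=("m",)))
        assert model.separation_detected
        assert model.auc == 1.0

    def test_missing_marker_raises(self, tiny_table):
        with pytest.raises(MarkerMismatchError, match="ZZZ"):
            fit_combination_model(tiny_table, Combination(id=1, members=("A", "ZZZ")))


class TestCombiScore:
    def test_score_at_cutoff_is_class_zero(self, tiny_table):
        # choose coefficients making one sample land exactly on the cutoff
        model = make_model(["A"], 0.0, [0.0], cutoff=0.5)
        res = combi_score(tiny_table, model)
        assert np.allclose(res.combi_score, 0.5)
        assert (res.predicted_class == 0).all()

    def test_training_round_trip_reproduces_se_sp(self, planted_table):
        table, _ = planted_table
        model = fit_combination_model(
            table, Combination(id=1, members=("M01", "M02", "M03"))
        )
        res = combi_score(table, model)
        truth = table.class_binary().to_numpy()
        se = res.predicted_class[truth == 1].mean()
        sp = 1 - res.predicted_class[truth == 0].mean()
        assert se == pytest.approx(model.training_se)
        assert sp == pytest.approx(model.training_sp)

    def test_all_zero_signals_score_sigmoid_intercept(self):
        signals = pd.DataFrame({"A": [0.0], "B": [0.0]},
                               index=pd.Index(["s"], name="ID"))
        t = MarkerTable(signals=signals)
        model = make_model(["A", "B"], -1.3, [2.0, 3.0])
        res = combi_score(t, model)
        assert res.combi_score[0] == pytest.approx(float(sigmoid(-1.3)))

    def test_monotone_in_each_marker_with_coefficient_sign(self):
        model = make_model(["up", "down"], 0.0, [1.5, -2.0])
        grid = np.linspace(0, 10, 25)
        up = pd.DataFrame({"up": grid, "down": np.full_like(grid, 5.0)},
                          index=pd.Index([f"a{i}" for i in range(25)], name="ID"))
        down = pd.DataFrame({"up": np.full_like(grid, 5.0), "down": grid},
                            index=pd.Index([f"b{i}" for i in range(25)], name="ID"))
        s_up = combi_score(MarkerTable(signals=up), model).combi_score
        s_down = combi_score(MarkerTable(signals=down), model).combi_score
        assert np.all(np.diff(s_up) > 0)
        assert np.all(np.diff(s_down) < 0)

    def test_json_round_trip(self, tmp_path, planted_table):
        table, _ = planted_table
        model = fit_combination_model(
            table, Combination(id=3, members=("M01", "M02"))
        )
        path = tmp_path / "model.json"
        model.to_json(str(path))
        back = CombinationModel.from_json(str(path))
        assert back.members == model.members
        assert back.intercept == model.intercept
        assert back.coefficients == model.coefficients
        assert back.optimal_cutoff == model.optimal_cutoff
        r1 = combi_score(table, model)
        r2 = combi_score(table, back)
        assert np.array_equal(r1.predicted_class, r2.predicted_class)


class TestEvaluation:
    def test_perfect_prediction(self):
        rep = evaluate_classification([1, 0, 1, 0], [1, 0, 1, 0])
        assert rep.f1 == 1.0 and rep.accuracy == 1.0

    def test_formula_application(self):
        # TP=8, FP=2, FN=4 -> F1 = 16/22
        predicted = [1] * 10 + [0] * 4
        truth = [1] * 8 + [0] * 2 + [1] * 4
        rep = evaluate_classification(predicted, truth)
        assert (rep.tp, rep.fp, rep.fn) == (8, 2, 4)
        assert rep.f1 == pytest.approx(16 / 22)

    def test_all_negative_with_positives_present(self):
        rep = evaluate_classification([0, 0, 0], [1, 1, 0])
        assert rep.f1 == 0.0 and rep.recall_defined

    def test_no_positive_truth_flags_recall(self):
        rep = evaluate_classification([1, 0], [0, 0])
        assert not rep.recall_defined

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(8)
        pred, truth = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        rep = evaluate_classification(pred, truth)
        assert rep.tp + rep.fp + rep.fn + rep.tn == 50


class TestClusterMedians:
    def test_one_row_per_cluster(self):
        from panelroc.models import ScoreResult

        res = ScoreResult(
            sample_ids=[f"c{i}" for i in range(6)],
            combi_score=np.array([0.9, 0.8, 0.1, 0.2, 0.5, 0.4]),
            predicted_class=np.array([1, 1, 0, 0, 0, 0]),
            model_id=1,
        )
        med = cluster_median_scores(res, ["NK", "NK", "T", "T", "B", "B"])
        assert list(med["cluster"]) == ["B", "NK", "T"]
        assert list(med["n_cells"]) == [2, 2, 2]
        assert med.loc[med["cluster"] == "NK", "median_combi_score"].item() == pytest.approx(0.85)
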