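import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from inph_rsfc.classify import (
    ClassifierConfig,
    LabeledFeatures,
    accuracy_percent,
    binomial_band,
    binomial_test,
    fit_linear_svm,
    loocv,
    one_vs_all_fit,
    predict_binary,
    predict_one_vs_all,
    scale_features,
    ttest_filter,
)
from inph_rsfc.errors import InvalidInputError


def make_dataset(rng, n_per_group=11, n_edges=200, shift_edges=(), shift=2.0,
                 severity=None):
    """Gaussian features; listed edges get a group mean shift."""
    n = 2 * n_per_group
    x = rng.standard_normal((n, n_edges))
    groups = np.array(["iNPH"] * n_per_group + ["HC"] * n_per_group)
    for e in shift_edges:
        x[groups == "iNPH", e] += shift
    if severity is None:
        severity = pd.DataFrame(
            {
                "gs_gait": [2] * n_per_group + [0] * n_per_group,
                "gs_cognition": [1] * n_per_group + [0] * n_per_group,
                "gs_urinary": [1] * n_per_group + [0] * n_per_group,
            }
        )
    return LabeledFeatures(
        features=x,
        subject_ids=[f"s{k}" for k in range(n)],
        groups=groups,
        severity=severity,
    )


class TestTtestFilter:
    def test_identical_groups_select_nothing(self, rng):
        half = rng.standard_normal((5, 50))
        x = np.vstack([half, half])  # duplicated -> all t == 0
        g = np.array(["iNPH"] * 5 + ["HC"] * 5)
        assert ttest_filter(x, g, 0.05).size == 0

    def test_large_shift_selected(self, rng):
        ds = make_dataset(rng, shift_edges=[7], shift=10.0)
        sel = ttest_filter(ds.features, ds.groups, 0.05)
        assert 7 in sel

    def test_matches_scipy_pooled_t(self, rng):
        ds = make_dataset(rng)
        sel = set(ttest_filter(ds.features, ds.groups, 0.05).tolist())
        for e in range(ds.features.shape[1]):
            a = ds.features[ds.groups == "HC", e]
            b = ds.features[ds.groups == "iNPH", e]
            _, p = stats.ttest_ind(a, b, equal_var=True)
            assert (e in sel) == (p < 0.05)

    def test_small_group_rejected(self, rng):
        x = rng.standard_normal((3, 10))
        g = np.array(["iNPH", "HC", "HC"])
        with pytest.raises(InvalidInputError):
            ttest_filter(x, g, 0.05)

    def test_zero_variance_edge_excluded_not_fatal(self, rng):
        x = rng.standard_normal((10, 5))
        x[:, 2] = 1.0  # constant in both groups
        g = np.array(["iNPH"] * 5 + ["HC"] * 5)
        sel = ttest_filter(x, g, 0.5)
        assert 2 not in sel


class TestScaleFeatures:
    def test_train_standardized(self, rng):
        x = rng.standard_normal((20, 6)) * 3 + 1
        scaled, _, _ = scale_features(x)
        assert np.allclose(scaled.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(scaled.var(axis=0), 1, atol=1e-10)

    def test_constant_column_floored_to_zero(self, rng):
        x = rng.standard_normal((10, 3))
        x[:, 1] = 4.2
        scaled, _, _ = scale_features(x)
        assert np.allclose(scaled[:, 1], 0.0)

    def test_heldout_at_train_mean_scales_to_zero(self, rng):
        x = rng.standard_normal((20, 4))
        _, held, _ = scale_features(x, x.mean(axis=0, keepdims=True))
        assert np.allclose(held, 0.0, atol=1e-10)


class TestLinearSvm:
    def test_symmetric_two_point_problem(self):
        x = np.array([[-1.0], [1.0]])
        y = np.array(["A", "B"])
        model = fit_linear_svm(x, y)
        assert model.b == pytest.approx(0.0, abs=1e-9)
        assert (predict_binary(model, x) == y).all()

    def test_separable_2d_training_accuracy(self, rng):
        x = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        y = np.array(["A"] * 10 + ["B"] * 10)
        model = fit_linear_svm(x, y)
        assert (predict_binary(model, x) == y).mean() == 1.0

    def test_matches_grid_search_oracle_1d(self):
        # three points, unbalanced classes, inverse-count class weights:
        # minimize 0.5 w^2 + C sum_i cw_i hinge(y_i (w x_i + b))
        x = np.array([[-1.0], [1.0], [1.2]])
        y = np.array(["A", "B", "B"])
        model = fit_linear_svm(x, y, ClassifierConfig(cost=1.0))
        sign = np.where(y == "B", 1.0, -1.0)
        cw = np.where(y == "B", 0.5, 1.0)

        def objective(p):
            w, b = p
            margins = 1 - sign * (w * x[:, 0] + b)
            return 0.5 * w * w + np.sum(cw * np.maximum(0, margins))

        best = None
        for w0 in np.linspace(-3, 3, 25):
            for b0 in np.linspace(-3, 3, 25):
                r = optimize.minimize(
                    objective, [w0, b0], method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-14},
                )
                if best is None or r.fun < best.fun:
                    best = r
        assert model.w[0] == pytest.approx(best.x[0], abs=1e-3)
        assert objective([model.w[0], model.b]) == pytest.approx(best.fun, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_linear_svm(np.zeros((3, 2)), np.array(["A", "A", "A"]))

    def test_margin_scaling_never_hurts_training_accuracy(self, rng):
        x = np.vstack([rng.normal(-1, 0.2, (8, 3)), rng.normal(1, 0.2, (8, 3))])
        y = np.array(["A"] * 8 + ["B"] * 8)
        acc = []
        for scale in (1.0, 2.0, 5.0):
            model = fit_linear_svm(x * scale, y)
            acc.append((predict_binary(model, x * scale) == y).mean())
        assert acc == sorted(acc)


class TestOneVsAll:
    def test_two_class_reduces_to_binary(self, rng):
        x = np.vstack([rng.normal(-2, 0.5, (8, 4)), rng.normal(2, 0.5, (8, 4))])
        y = np.array([0] * 8 + [2] * 8)
        machines = one_vs_all_fit(x, y)
        binary = fit_linear_svm(x, y)
        test = rng.standard_normal((30, 4)) * 3
        assert (predict_one_vs_all(machines, test) == predict_binary(binary, test)).all()

    def test_three_class_separable(self, rng):
        centers = {0: [-4, 0], 1: [4, 0], 3: [0, 5]}
        xs, ys = [], []
        for lab, c in centers.items():
            xs.append(rng.normal(c, 0.3, (10, 2)))
            ys += [lab] * 10
        x = np.vstack(xs)
        y = np.array(ys)
        machines = one_vs_all_fit(x, y)
        assert set(machines) == {0, 1, 3}
        assert (predict_one_vs_all(machines, x) == y).mean() == 1.0

    def test_tie_breaks_to_lowest_label(self):
        from inph_rsfc.classify import LinearModel

        machines = {
            2: LinearModel(np.array([0.0]), 0.3, [0, 1]),
            1: LinearModel(np.array([0.0]), 0.3, [0, 1]),
            4: LinearModel(np.array([0.0]), -1.0, [0, 1]),
        }
        pred = predict_one_vs_all(machines, np.array([[0.5]]))
        assert pred[0] == 1


class TestLoocv:
    def test_fold_count_matches_subjects(self, rng):
        ds = make_dataset(rng, shift_edges=range(10), shift=3.0)
        res = loocv(ds, "diagnosis")
        assert res.n_folds == 22
        assert len(res.folds) == 22
        assert {f.subject_id for f in res.folds} == set(ds.subject_ids)

    def test_separable_cohort_classified_perfectly(self, rng):
        ds = make_dataset(rng, shift_edges=range(20), shift=8.0)
        res = loocv(ds, "diagnosis")
        assert res.accuracy == 1.0
        assert res.p_binomial < 1e-5

    def test_accuracy_equals_mean_fold_correctness(self, rng):
        ds = make_dataset(rng, shift_edges=range(5), shift=1.0)
        res = loocv(ds, "diagnosis", ClassifierConfig(selection_scope="pooled"))
        manual = np.mean([f.true_label == f.predicted_label for f in res.folds])
        assert res.accuracy == pytest.approx(manual, abs=1e-12)

    def test_permuted_labels_near_chance(self, rng):
        # permutation null: mean accuracy across seeds within the central
        # 95% binomial band around 0.5
        accs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            ds = make_dataset(r, n_edges=100, shift_edges=range(10), shift=2.0)
            perm = r.permutation(len(ds.groups))
            ds_null = LabeledFeatures(
                features=ds.features,
                subject_ids=ds.subject_ids,
                groups=ds.groups[perm],
                severity=ds.severity.iloc[perm].reset_index(drop=True),
            )
            accs.append(loocv(ds_null, "diagnosis").accuracy)
        lo, hi = binomial_band(22, 0.5, 0.95)
        assert lo / 22 <= np.mean(accs) <= hi / 22

    def test_severity_restricted_accuracy_recomputed_over_patients(self, rng):
        ds = make_dataset(rng, shift_edges=range(10), shift=4.0)
        res = loocv(ds, "gs_gait", ClassifierConfig(selection_scope="pooled"))
        patients = [f for f in res.folds if f.subject_id in ds.subject_ids[:11]]
        manual = np.mean([f.true_label == f.predicted_label for f in patients])
        assert res.restricted_n == 11
        assert res.restricted_accuracy == pytest.approx(manual, abs=1e-12)

    def test_per_fold_scope_ignores_held_out_subject(self, rng):
        # leakage check: corrupting the held-out subject's features must not
        # change that fold's selected edge count or the other folds at all
        ds = make_dataset(rng, shift_edges=range(8), shift=2.0)
        res1 = loocv(ds, "diagnosis", ClassifierConfig(selection_scope="per_fold"))
        corrupted = ds.features.copy()
        corrupted[3] = 1e6
        ds2 = LabeledFeatures(
            features=corrupted,
            subject_ids=ds.subject_ids,
            groups=ds.groups,
            severity=ds.severity,
        )
        res2 = loocv(ds2, "diagnosis", ClassifierConfig(selection_scope="per_fold"))
        assert res1.folds[3].n_selected == res2.folds[3].n_selected

    def test_pooled_scope_recorded_in_result(self, rng):
        ds = make_dataset(rng, shift_edges=range(8), shift=2.0)
        res = loocv(ds, "diagnosis", ClassifierConfig(selection_scope="pooled"))
        assert res.config["selection_scope"] == "pooled"
        assert res.selected_pooled is not None

    def test_unknown_task_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            loocv(make_dataset(rng), "age")


class TestBinomialTest:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (14, 22, 0.2863),
            (18, 22, 0.00434),
            (11, 22, 1.0),
        ],
    )
    def test_reference_values(self, k, n, expected):
        assert binomial_test(k, n, 0.5) == pytest.approx(expected, rel=1e-2)

    def test_agrees_with_full_enumeration_up_to_n30(self):
        from math import comb

        for n in (5, 11, 22, 30):
            for p0 in (0.25, 0.5):
                pmf = np.array([comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)])
                for k in range(n + 1):
                    expected = min(1.0, 2.0 * min(pmf[: k + 1].sum(), pmf[k:].sum()))
                    assert binomial_test(k, n, p0) == pytest.approx(expected, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            binomial_test(5, 4, 0.5)
        with pytest.raises(InvalidInputError):
            binomial_test(1, 4, 1.5)


class TestAccuracyPercent:
    @pytest.mark.parametrize(
        "k, n, pct", [(14, 22, 63), (18, 22, 81), (9, 11, 81), (8, 11, 72), (11, 22, 50)]
    )
    def test_truncation_convention(self, k, n, pct):
        assert accuracy_percent(k, n) == pct
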