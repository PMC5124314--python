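"""Metrics, SVM training, cross-validation, ROC, scanning, and EAE."""

import math

import numpy as np
import pytest
from sklearn import metrics as skm

import lbsizecleav as lb
from lbsizecleav.encoding import EncodingScheme
from lbsizecleav.model import (
    ConfusionCounts,
    assign_folds,
    compute_metrics,
    cross_validate,
    eae_profile,
    end_absolute_error,
    fit,
    roc_curve,
)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert m == {"Sn": 1.0, "Sp": 1.0, "Ac": 1.0, "MCC": 1.0}

    def test_zero_denominator_mcc_convention(self):
        m = compute_metrics(ConfusionCounts(TP=3, FN=1, TN=0, FP=0))
        assert m["Sn"] == 0.75 and m["MCC"] == 0.0

    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionCounts(TP=8, FP=2, TN=7, FN=3))
        assert m["Sn"] == pytest.approx(8 / 11)
        assert m["Sp"] == pytest.approx(7 / 9)
        assert m["Ac"] == pytest.approx(15 / 20)
        assert m["MCC"] == pytest.approx((8 * 7 - 2 * 3) / math.sqrt(10 * 11 * 9 * 10))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_per_example_tally(self, rng):
        # independent oracle: sklearn metrics on random label/prediction pairs
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.choice([-1, 1], size=n)
            p = rng.choice([-1, 1], size=n)
            if len(np.unique(y)) < 2:
                continue
            m = compute_metrics(ConfusionCounts.from_predictions(y, p))
            assert m["Sn"] == pytest.approx(skm.recall_score(y, p, pos_label=1))
            assert m["Sp"] == pytest.approx(skm.recall_score(y, p, pos_label=-1))
            assert m["Ac"] == pytest.approx(skm.accuracy_score(y, p))
            assert m["MCC"] == pytest.approx(skm.matthews_corrcoef(y, p))
            assert -1.0 <= m["MCC"] <= 1.0


SCHEME = EncodingScheme("lbsize", w=2, k=1, M=1)  # dims only; fit takes raw X


class TestFit:
    def test_separable_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, 1])
        model = fit(X, y, SCHEME, gamma=1.0, cost=1e3)
        assert (model.predict(X) == y).all()

    def test_contradictory_labels_cap_at_half(self):
        X = np.zeros((4, 2))
        y = np.array([1, -1, 1, -1])
        model = fit(X, y, SCHEME, gamma=1.0)
        assert (model.predict(X) == y).mean() == 0.5

    def test_xor_with_rbf(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([-1, 1, 1, -1])
        model = fit(X, y, SCHEME, gamma=1.0, cost=100.0)
        assert (model.predict(X) == y).all()

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="each class"):
            fit(np.eye(3), np.ones(3), SCHEME)

    def test_scores_invariant_to_all_zero_columns(self, rng):
        # gap placeholders (always-zero features) cannot change predictions
        X = rng.random((30, 10))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:2] = [1, -1]
        Xz = np.hstack([X, np.zeros((30, 4))])
        m1 = fit(X, y, SCHEME, gamma=0.5, cost=2.0)
        m2 = fit(Xz, y, SCHEME, gamma=0.5, cost=2.0)
        T = rng.random((10, 10))
        Tz = np.hstack([T, np.zeros((10, 4))])
        np.testing.assert_allclose(
            m1.decision_scores(T), m2.decision_scores(Tz), rtol=1e-10
        )


class TestCrossValidation:
    def test_fold_partition_arithmetic(self):
        fold_of = assign_folds([f"p{i}" for i in range(10)], folds=5, seed=3)
        sizes = np.bincount(list(fold_of.values()), minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_too_few_precursors(self):
        with pytest.raises(ValueError, match="at least"):
            assign_folds(["a", "b"], folds=5, seed=0)

    def test_planted_signal_is_perfectly_learned(self):
        # deterministic geometry (no background bulges, fixed mature
        # length): the signature loop separates the classes exactly
        params = lb.SyntheticParams(
            n_precursors=40,
            signal_strength=1.0,
            bulge_rate=0.0,
            mature_length=(22, 22),
        )
        precursors, _ = lb.generate_dataset(params, seed=5)
        windows, scheme = lb.build_windows(
            precursors, lb.RunConfig(scheme="lbsize", w=8, k=2, seed=5)
        )
        results = cross_validate(windows, scheme, seed=5)
        for res in results.values():
            assert res.mean["Ac"] == 1.0
            assert res.variance["Ac"] == 0.0

    def test_no_precursor_straddles_train_and_test(self, small_planted_dataset):
        _, precursors, _ = small_planted_dataset
        windows, scheme = lb.build_windows(
            precursors, lb.RunConfig(scheme="extended", w=8, seed=1)
        )
        results = cross_validate(windows, scheme, seed=1)
        for res in results.values():
            all_ids = [pid for fold in res.folds for pid in fold]
            assert len(all_ids) == len(set(all_ids))
            assert set(all_ids) == {w.precursor_id for w in windows if w.arm == res.arm}

    def test_null_labels_give_chance_accuracy(self, small_null_dataset):
        _, precursors, _ = small_null_dataset
        windows, scheme = lb.build_windows(
            precursors, lb.RunConfig(scheme="lbsize", w=8, k=2, seed=9)
        )
        results = cross_validate(windows, scheme, seed=9)
        for res in results.values():
            assert abs(res.mean["Ac"] - 0.5) < 0.1

    def test_leave_one_out_agrees_with_fivefold(self, small_planted_dataset):
        # on a cleanly separable set both protocols saturate
        _, precursors, _ = small_planted_dataset
        subset = precursors[:20]
        windows, scheme = lb.build_windows(
            subset, lb.RunConfig(scheme="lbsize", w=8, k=2, seed=2)
        )
        five = cross_validate(windows, scheme, folds=5, seed=2)
        loo = cross_validate(windows, scheme, folds=20, seed=2)
        for arm in five:
            assert abs(five[arm].mean["Ac"] - loo[arm].mean["Ac"]) < 0.05


class TestRocCurve:
    def test_perfect_scores(self):
        labels = np.array([1, 1, -1, -1])
        (_, _), auc = roc_curve(labels.astype(float), labels)
        assert auc == 1.0

    def test_reversal_symmetry(self, rng):
        labels = np.where(rng.random(200) < 0.5, 1, -1)
        labels[:2] = [1, -1]
        scores = rng.normal(size=200) + 0.5 * labels
        (_, _), auc = roc_curve(scores, labels)
        (_, _), auc_rev = roc_curve(-scores, labels)
        assert auc_rev == pytest.approx(1.0 - auc)

    def test_uninformative_scores_near_half(self, rng):
        labels = np.where(rng.random(1000) < 0.5, 1, -1)
        labels[:2] = [1, -1]
        (fpr, tpr), auc = roc_curve(rng.normal(size=1000), labels)
        assert abs(auc - 0.5) < 0.05
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])


@pytest.fixture(scope="module")
def scan_setup():
    params = lb.SyntheticParams(
        n_precursors=60, signal_mode="mixed", signal_strength=1.0
    )
    precursors, truth = lb.generate_dataset(params, seed=77)
    cfg = lb.RunConfig(scheme="lbsize", w=14, k=5, seed=77)
    _, models = lb.train_eval(precursors[:50], cfg)
    truth_map = {
        r["id"]: (int(r["cd5p"]), int(r["cd3p"])) for _, r in truth.iterrows()
    }
    return models, precursors[50:], truth_map


class TestScan:
    def test_profile_covers_every_full_window_site(self, scan_setup):
        models, held_out, _ = scan_setup
        res = lb.scan_precursor(models, held_out[0])
        assert len(res.sites) == len(held_out[0]) - models["5p"].scheme.w + 1

    def test_planted_sites_are_recovered(self, scan_setup):
        models, held_out, truth_map = scan_setup
        hits = 0
        for p in held_out:
            res = lb.scan_precursor(models, p)
            cd5p, cd3p = truth_map[p.id]
            hits += (res.predicted_cd5p == cd5p) + (res.predicted_cd3p == cd3p)
        assert hits >= 0.8 * 2 * len(held_out)

    def test_short_precursor_is_an_error(self, scan_setup):
        models, _, _ = scan_setup
        tiny = lb.Precursor(id="t", sequence="AUGCGA", structure="((..))")
        with pytest.raises(ValueError, match="shorter"):
            lb.scan_precursor(models, tiny)

    def test_ties_break_toward_five_prime(self):
        from lbsizecleav.model import _argmax_5prime

        sites = np.array([10, 11, 12, 13])
        scores = np.array([0.0, 0.0, 0.0, 0.0])
        assert _argmax_5prime(sites, scores) == 10

    def test_model_roundtrip_preserves_predictions(self, scan_setup, tmp_path):
        models, held_out, _ = scan_setup
        lb.save_model(models, tmp_path / "m.joblib")
        loaded = lb.load_model(tmp_path / "m.joblib")
        a = lb.scan_precursor(models, held_out[0])
        b = lb.scan_precursor(loaded, held_out[0])
        np.testing.assert_allclose(a.scores, b.scores)
        assert a.predicted_cd5p == b.predicted_cd5p


class TestEae:
    @pytest.mark.parametrize("pred,true,eae", [(22, 22, 0), (19, 22, 3), (45, 40, 5)])
    def test_end_absolute_error(self, pred, true, eae):
        assert end_absolute_error(pred, true) == eae

    def test_cumulative_profile(self):
        profile = eae_profile([0, 0, 1, 3])
        assert profile.tolist() == [0.5, 0.75, 0.75, 1.0]
        assert (np.diff(profile) >= 0).all()
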