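"""Split plans, evaluation metrics, the margin baseline, and the DeLong test."""

import numpy as np
import pytest
from scipy import stats

from marginrad.modeling import (
    auc_variance,
    delong_test,
    evaluate,
    make_split,
    margin_baseline,
    train_model,
    predict_scores,
    youden_threshold,
)


class TestMakeSplit:
    def test_stratified_counts(self):
        ids = [f"c{i}" for i in range(40)]
        labels = np.array([1] * 18 + [0] * 22)
        plan = make_split(ids, labels, seed=0)
        tr, te = plan.training_ids, plan.test_ids
        assert len(tr) == len(te) == 20
        lab = dict(zip(ids, labels))
        assert sum(lab[i] for i in tr) == 9
        assert sum(lab[i] for i in te) == 9

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(30)]
        labels = np.arange(30) % 2
        p1 = make_split(ids, labels, seed=5)
        p2 = make_split(ids, labels, seed=5)
        assert p1.assignment.equals(p2.assignment)

    def test_each_case_trains_about_half_the_time(self):
        ids = [f"c{i}" for i in range(20)]
        labels = np.arange(20) % 2
        counts = {i: 0 for i in ids}
        n = 200
        for seed in range(n):
            plan = make_split(ids, labels, seed=seed)
            for i in plan.training_ids:
                counts[i] += 1
        fracs = np.array(list(counts.values())) / n
        assert np.all(np.abs(fracs - 0.5) < 4 * np.sqrt(0.25 / n))


class TestEvaluate:
    def test_perfect_separation(self):
        rep = evaluate([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], threshold=0.5)
        assert rep.auc == 1.0
        for v in (rep.accuracy, rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert v == 1.0

    def test_tied_scores_auc_half(self):
        rep = evaluate([0.3] * 6, [1, 0, 1, 0, 1, 0], threshold=0.5)
        assert rep.auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle(self, rng):
        scores = rng.normal(size=1000)
        labels = rng.random(1000) < 0.4
        rep = evaluate(scores, labels, threshold=0.0)
        pos = scores[labels]
        neg = scores[~labels]
        oracle = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        assert rep.auc == pytest.approx(oracle, abs=1e-12)

    def test_metrics_reconstruct_confusion(self, rng):
        scores = rng.random(80)
        labels = rng.random(80) < 0.5
        rep = evaluate(scores, labels, threshold=0.6)
        c = rep.confusion
        assert c["tp"] + c["fn"] == labels.sum()
        assert c["tn"] + c["fp"] == (~labels).sum()
        assert rep.accuracy == pytest.approx((c["tp"] + c["tn"]) / 80)
        assert rep.sensitivity == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        a1 = evaluate(scores, labels, 0.0).auc
        a2 = evaluate(np.exp(3 * scores), labels, 1.0).auc
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestTrainModel:
    def test_separable_training_auc(self, rng):
        import pandas as pd

        n = 60
        y = np.arange(n) % 2
        X = pd.DataFrame({"sig": y + 0.3 * rng.normal(size=n), "noise": rng.normal(size=n)})
        model = train_model(X, y, n_estimators=100, seed=0)
        rep = evaluate(predict_scores(model, X), y, 0.5)
        assert rep.auc > 0.95

    def test_label_leak_feature_gives_auc_one(self, rng):
        import pandas as pd

        y = np.arange(40) % 2
        X = pd.DataFrame({"leak": y.astype(float)})
        model = train_model(X, y, n_estimators=50, seed=0)
        assert evaluate(predict_scores(model, X), y, 0.5).auc == 1.0

    def test_shuffled_labels_heldout_auc_near_half(self, rng):
        import pandas as pd

        aucs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(80, 10)), columns=[f"f{i}" for i in range(10)])
            y = r.permutation(np.arange(80) % 2)
            model = train_model(X.iloc[:40], y[:40], n_estimators=100, seed=seed)
            aucs.append(evaluate(predict_scores(model, X.iloc[40:]), y[40:], 0.5).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_empty_subset_rejected(self, rng):
        import pandas as pd

        with pytest.raises(ValueError, match="empty feature subset"):
            train_model(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1], feature_subset=[])


class TestMarginBaseline:
    def test_flag_equals_label(self):
        y = np.array([1, 1, 0, 0, 1])
        rep = margin_baseline(y.astype(bool), y)
        assert rep.auc == 1.0

    def test_flag_auc_equals_balanced_accuracy(self, rng):
        flags = rng.random(200) < 0.4
        y = rng.random(200) < 0.35
        rep = margin_baseline(flags, y)
        sens = np.mean(flags[y])
        spec = np.mean(~flags[~y])
        assert rep.auc == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_independent_flag_near_half_over_seeds(self):
        aucs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            aucs.append(margin_baseline(r.random(60) < 0.4, r.random(60) < 0.35).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_planted_rates_recovered(self, rng):
        n = 2000
        y = rng.random(n) < 0.4
        flags = np.where(y, rng.random(n) < 0.65, rng.random(n) < 0.29)
        rep = margin_baseline(flags, y)
        assert rep.sensitivity == pytest.approx(0.65, abs=4 * np.sqrt(0.65 * 0.35 / y.sum()))
        assert rep.specificity == pytest.approx(0.71, abs=4 * np.sqrt(0.71 * 0.29 / (~y).sum()))


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=50)
        y = rng.random(50) < 0.5
        out = delong_test(s, s.copy(), y)
        assert out["p"] == 1.0
        assert out["auc_a"] == out["auc_b"]

    def test_variance_matches_placement_oracle(self, rng):
        scores = rng.normal(size=30)
        y = np.array([1] * 12 + [0] * 18)
        auc, var = auc_variance(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        v10 = [np.mean((p > neg) + 0.5 * (p == neg)) for p in pos]
        v01 = [np.mean((pos > n) + 0.5 * (pos == n)) for n in neg]
        assert auc == pytest.approx(np.mean(v10))
        expect = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
        assert var == pytest.approx(expect, abs=1e-12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_test(rng.normal(size=5), rng.normal(size=5), np.ones(5))

    def test_null_type_one_error(self):
        """Two noisy copies of one latent score: rejection at alpha=0.05
        stays near nominal (a scaled-down version of the acceptance run)."""
        n_rep = 800
        rejections = 0
        rng = np.random.default_rng(12345)
        for _ in range(n_rep):
            n = 60
            y = np.r_[np.ones(25), np.zeros(35)].astype(int)
            latent = y * 0.8 + rng.normal(size=n)
            a = latent + 0.7 * rng.normal(size=n)
            b = latent + 0.7 * rng.normal(size=n)
            if delong_test(a, b, y)["p"] < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 0.025

    def test_detects_real_difference(self, rng):
        n = 400
        y = (rng.random(n) < 0.5).astype(int)
        good = y + 0.5 * rng.normal(size=n)
        bad = y + 3.0 * rng.normal(size=n)
        out = delong_test(good, bad, y)
        assert out["auc_a"] > out["auc_b"]
        assert out["p"] < 0.01


class TestYouden:
    def test_threshold_maximizes_j(self, rng):
        scores = rng.random(100)
        y = (rng.random(100) < 0.5).astype(int)
        thr = youden_threshold(scores, y)
        rep = evaluate(scores, y, thr)
        j_star = rep.sensitivity + rep.specificity - 1
        for t in np.linspace(0.01, 0.99, 33):
            r = evaluate(scores, y, t)
            assert j_star >= r.sensitivity + r.specificity - 1 - 1e-12
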