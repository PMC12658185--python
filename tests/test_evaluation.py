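"""Confusion-matrix metrics, ROC/AUC, Cohen's kappa, Grad-CAM."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from lightmg.evaluation import (
    CLASS_ORDER,
    classification_metrics,
    cohens_kappa,
    confusion_matrix,
    grad_cam,
    metrics_report,
    one_vs_rest_counts,
    roc_auc,
)


def brute_force_counts(y_true, y_pred, cls):
    tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
    fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
    fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
    tn = sum(t != cls and p != cls for t, p in zip(y_true, y_pred))
    return tp, tn, fp, fn


class TestConfusionMatrix:
    def test_agreement_gives_diagonal(self):
        y = ["ERD", "RRD", "TRD", "Healthy", "RRD"]
        cm = confusion_matrix(y, y)
        assert np.all(cm == np.diag(np.diag(cm)))
        assert cm.sum() == len(y)

    def test_empty_inputs_give_zero_matrix(self):
        assert confusion_matrix([], []).sum() == 0

    def test_small_enumeration(self):
        cm = confusion_matrix(["ERD", "ERD", "RRD"], ["ERD", "RRD", "RRD"])
        i = {c: k for k, c in enumerate(CLASS_ORDER)}
        assert cm[i["ERD"], i["ERD"]] == 1
        assert cm[i["ERD"], i["RRD"]] == 1
        assert cm[i["RRD"], i["RRD"]] == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["ERD"], ["XYZ"])


class TestOneVsRest:
    def test_diagonal_matrix_has_no_errors(self):
        cm = np.diag([5, 6, 7, 8])
        for k in range(4):
            tp, tn, fp, fn = one_vs_rest_counts(cm, k)
            assert fp == 0 and fn == 0 and tp == cm[k, k]

    def test_counts_partition_the_total(self, rng):
        cm = rng.integers(0, 10, size=(4, 4))
        for k in range(4):
            assert sum(one_vs_rest_counts(cm, k)) == cm.sum()

    def test_single_off_diagonal_entry(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 2] = 1  # true ERD predicted RRD
        tp, tn, fp, fn = one_vs_rest_counts(cm, 2)
        assert tp == 0 and fp == 1


class TestClassificationMetrics:
    def test_hand_computed_example(self):
        m = classification_metrics(tp=90, tn=80, fp=10, fn=20)
        assert m.accuracy == pytest.approx(0.85)
        assert m.precision == pytest.approx(0.90)
        assert m.sensitivity == pytest.approx(90 / 110)
        assert m.f1 == pytest.approx(2 * 0.9 * (90 / 110) / (0.9 + 90 / 110))

    def test_half_recall(self):
        assert classification_metrics(50, 0, 0, 50).sensitivity == pytest.approx(0.5)

    def test_perfect_classifier_has_unit_mcc(self):
        assert classification_metrics(10, 30, 0, 0).mcc == pytest.approx(1.0)

    def test_zero_denominators_flagged_not_fatal(self):
        m = classification_metrics(0, 5, 0, 0)
        assert m.sensitivity == 0.0 and "sensitivity" in m.undefined
        assert m.precision == 0.0 and "precision" in m.undefined

    def test_matches_brute_force_recount_on_random_datasets(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            y_true = rng.choice(CLASS_ORDER, size=n)
            y_pred = rng.choice(CLASS_ORDER, size=n)
            cm = confusion_matrix(y_true, y_pred)
            for k, cls in enumerate(CLASS_ORDER):
                got = one_vs_rest_counts(cm, k)
                assert got == brute_force_counts(y_true, y_pred, cls)
                m = classification_metrics(*got)
                assert -1.0 <= m.mcc <= 1.0
                tp, tn, fp, fn = got
                if tp + fn:
                    assert m.sensitivity == pytest.approx(tp / (tp + fn))
                if tp + fp:
                    assert m.precision == pytest.approx(tp / (tp + fp))


class TestROCAUC:
    def _scores(self, y, good=True):
        s = np.zeros((len(y), 4))
        for i, t in enumerate(y):
            k = CLASS_ORDER.index(t)
            s[i, k] = 1.0 if good else -1.0
        return s

    def test_perfect_and_inverted_separation(self):
        y = ["ERD"] * 5 + ["Healthy"] * 5
        assert roc_auc(self._scores(y, True), y, 0) == 1.0
        assert roc_auc(self._scores(y, False), y, 0) == 0.0

    def test_random_scores_near_half(self, rng):
        y = rng.choice(CLASS_ORDER, size=2000)
        s = rng.uniform(size=(2000, 4))
        assert roc_auc(s, y, "RRD") == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self, rng):
        y = rng.choice(CLASS_ORDER, size=100)
        s = rng.uniform(size=(100, 4))
        a = roc_auc(s, y, 1)
        b = roc_auc(np.exp(5 * s), y, 1)
        assert a == pytest.approx(b)

    def test_matches_sklearn_on_random_data(self, rng):
        y = rng.choice(CLASS_ORDER, size=300)
        s = rng.normal(size=(300, 4))
        for k, cls in enumerate(CLASS_ORDER):
            ours = roc_auc(s, y, k)
            ref = roc_auc_score((y == cls).astype(int), s[:, k])
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_absent_class_is_an_error(self):
        y = ["ERD"] * 4
        with pytest.raises(ValueError):
            roc_auc(np.zeros((4, 4)), y, "TRD")


class TestKappa:
    def test_identical_sequences_give_one(self):
        y = ["ERD", "RRD", "TRD", "Healthy", "ERD"]
        r = cohens_kappa(y, y)
        assert r.kappa == pytest.approx(1.0) and r.p_o == 1.0

    def test_chance_level_agreement_gives_zero(self):
        # p_o = 0.5 exactly equals p_e from balanced marginals
        a = ["yes"] * 50 + ["no"] * 50
        b = ["yes", "no"] * 50
        r = cohens_kappa(a, b)
        assert r.p_o == pytest.approx(r.p_e) == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.0)

    def test_two_class_toy_hand_arithmetic(self):
        a = ["y"] * 55 + ["n"] * 45
        b = ["y"] * 40 + ["n"] * 15 + ["y"] * 15 + ["n"] * 30
        r = cohens_kappa(a, b)
        assert r.p_o == pytest.approx(0.70)
        p_e = 0.55 * 0.55 + 0.45 * 0.45
        assert r.p_e == pytest.approx(p_e)
        assert r.kappa == pytest.approx((0.70 - p_e) / (1 - p_e))

    def test_degenerate_constant_raters(self):
        r = cohens_kappa(["A"] * 5, ["A"] * 5)
        assert r.kappa == 1.0 and r.degenerate

    def test_symmetry_and_sklearn_agreement(self, rng):
        for _ in range(20):
            a = rng.choice(["w", "x", "y", "z"], size=60)
            b = rng.choice(["w", "x", "y", "z"], size=60)
            r1 = cohens_kappa(a, b)
            r2 = cohens_kappa(b, a)
            assert r1.kappa == pytest.approx(r2.kappa)
            assert r1.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa(["A"], ["A", "B"])


class TestReport:
    def test_report_contains_all_classes_and_macro(self, rng):
        y_true = rng.choice(CLASS_ORDER, size=80)
        y_pred = rng.choice(CLASS_ORDER, size=80)
        scores = rng.uniform(size=(80, 4))
        rep = metrics_report(y_true, y_pred, scores)
        assert set(rep.per_class) == set(CLASS_ORDER)
        assert 0 <= rep.overall_accuracy <= 1
        assert set(rep.auc) == set(CLASS_ORDER)
        # macro one-vs-rest accuracy generally differs from overall accuracy;
        # both must be present and internally consistent
        assert rep.macro["accuracy"] == pytest.approx(
            np.mean([m.accuracy for m in rep.per_class.values()])
        )


class TestGradCam:
    @pytest.fixture(scope="class")
    def tiny_net(self):
        from lightmg.network import NetworkConfig, build_network

        return build_network(NetworkConfig(input_size=64), seed=0)

    def test_zero_head_gives_zero_map(self, tiny_net, rng):
        params = {p["name"]: p for p in tiny_net.parameters()}
        saved = (params["fc2.W"]["value"].copy(), params["fc2.b"]["value"].copy())
        params["fc2.W"]["value"][...] = 0
        params["fc2.b"]["value"][...] = 0
        cam = grad_cam(tiny_net, rng.uniform(size=(64, 64, 3)), target_class=1)
        assert np.all(cam.heatmap == 0)
        params["fc2.W"]["value"][...] = saved[0]
        params["fc2.b"]["value"][...] = saved[1]

    def test_map_nonnegative_normalized_and_input_sized(self, tiny_net, rng):
        cam = grad_cam(tiny_net, rng.uniform(size=(64, 64, 3)), target_class=2)
        assert cam.heatmap.shape == (64, 64)
        assert cam.heatmap.min() >= 0
        assert cam.heatmap.max() == pytest.approx(1.0) or cam.heatmap.max() == 0

    def test_rejects_non_spatial_layer(self, tiny_net, rng):
        with pytest.raises(ValueError):
            grad_cam(tiny_net, rng.uniform(size=(64, 64, 3)), 0, layer="fc1")

    def test_localizes_quadrant_cue_after_training(self):
        """A classifier trained to detect a bright disc confined to one
        quadrant should place at least half the heatmap mass there."""
        from lightmg.network import Hyperparams, NetworkConfig, build_network, train

        def binary_images(n, seed):
            r = np.random.default_rng(seed)
            xs, ys = [], []
            for cls in (0, 1):
                for _ in range(n):
                    img = r.uniform(0, 30, size=(64, 64, 3))
                    if cls == 1:
                        img[8:28, 8:28] += 190  # disc in the upper-left quadrant
                    xs.append(img)
                    ys.append(cls)
            return np.stack(xs), np.array(ys)

        x, y = binary_images(20, seed=3)
        net = build_network(NetworkConfig(input_size=64, n_classes=2), seed=1)
        train(net, x / 255.0, y, Hyperparams(epochs=5), seed=1)
        xt, yt = binary_images(4, seed=4)
        fractions = []
        for img in xt[yt == 1]:
            cam = grad_cam(net, img / 255.0, target_class=1).heatmap
            fractions.append(cam[:32, :32].sum() / max(cam.sum(), 1e-12))
        assert np.mean(fractions) >= 0.5
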