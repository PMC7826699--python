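"""Evaluation indexes against hand-worked values and independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from olce import (
    BaselineSpec,
    ConfusionMatrix,
    UndefinedKappaError,
    build_baseline,
    comparison_table,
    confusion,
    kappa,
    metric_panel,
    render_table,
    run_experiment,
)


def brute_force_kappa(counts):
    """Independent oracle: explicit double loop over classes."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    po = sum(counts[i, i] for i in range(len(counts))) / n
    pe = 0.0
    for i in range(len(counts)):
        a_i = sum(counts[i, j] for j in range(len(counts)))
        b_i = sum(counts[j, i] for j in range(len(counts)))
        pe += a_i * b_i
    pe /= n * n
    return (po - pe) / (1 - pe)


def cm(counts):
    counts = np.asarray(counts)
    return ConfusionMatrix(counts=counts,
                           class_names=[str(i) for i in range(len(counts))])


class TestConfusion:
    def test_direct_count_example(self):
        m = confusion([0, 0, 1], [0, 1, 1], class_names=[0, 1])
        np.testing.assert_array_equal(m.counts, [[1, 1], [0, 1]])

    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 1, 0]
        m = confusion(y, y, class_names=[0, 1, 2])
        assert np.all(m.counts == np.diag(np.diag(m.counts)))

    def test_total_count_conserved_on_random_pairs(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(2, 6))
            yt = rng.integers(0, k, n)
            yp = rng.integers(0, k, n)
            assert confusion(yt, yp, class_names=list(range(k))).n == n

    def test_length_mismatch_and_unknown_label_raise(self):
        with pytest.raises(ValueError, match="length"):
            confusion([0, 1], [0], class_names=[0, 1])
        with pytest.raises(ValueError, match="unknown"):
            confusion(["A"], ["C"], class_names=["A", "B"])


class TestKappa:
    def test_perfect_agreement_is_one(self):
        assert kappa(cm(np.diag([25] * 7))) == pytest.approx(1.0)

    def test_hand_worked_zero(self):
        # Po = 0.5 and Pe = 0.5 -> kappa 0
        assert kappa(cm([[50, 0], [50, 0]])) == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_point_four(self):
        # Po = 0.7, Pe = 0.5 -> kappa 0.4
        assert kappa(cm([[40, 10], [20, 30]])) == pytest.approx(0.4, abs=1e-15)

    def test_degenerate_single_class_raises(self):
        with pytest.raises(UndefinedKappaError):
            kappa(cm([[5, 0], [0, 0]]))

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 8))
            counts = rng.integers(0, 30, (k, k))
            counts[0, 1] += 1  # keep Pe < 1
            counts[1, 0] += 1
            assert kappa(cm(counts)) == pytest.approx(
                brute_force_kappa(counts), abs=1e-12
            )

    def test_matches_sklearn_on_label_vectors(self, rng):
        yt = rng.integers(0, 4, 300)
        yp = rng.integers(0, 4, 300)
        m = confusion(yt, yp, class_names=list(range(4)))
        assert kappa(m) == pytest.approx(cohen_kappa_score(yt, yp), abs=1e-12)


class TestMetricPanel:
    def test_hand_worked_macro_values(self):
        panel = metric_panel(cm([[40, 10], [20, 30]]))
        assert panel.accuracy == pytest.approx(0.7)
        assert panel.precision == pytest.approx((40 / 60 + 30 / 40) / 2)
        assert panel.recall == pytest.approx((0.8 + 0.6) / 2)
        assert panel.kappa == pytest.approx(0.4)

    def test_perfect_diagonal_panel(self):
        panel = metric_panel(cm(np.diag([10, 20, 30])))
        assert (panel.accuracy, panel.precision, panel.recall, panel.f1,
                panel.kappa) == (1.0, 1.0, 1.0, 1.0, 1.0)
        assert panel.hamming_loss == 0.0

    def test_never_predicted_class_contributes_zero_precision(self):
        panel = metric_panel(cm([[5, 0], [5, 0]]))
        assert np.isfinite(panel.precision)
        assert panel.precision == pytest.approx(0.25)  # (5/10 + 0)/2

    def test_accuracy_is_one_minus_hamming_loss(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 20, (k, k)) + np.eye(k, dtype=int)
            panel = metric_panel(cm(counts))
            assert panel.accuracy == pytest.approx(1 - panel.hamming_loss)

    def test_macro_values_match_sklearn(self, rng):
        yt = rng.integers(0, 5, 400)
        yp = rng.integers(0, 5, 400)
        panel = metric_panel(confusion(yt, yp, class_names=list(range(5))))
        p, r, f, _ = precision_recall_fscore_support(
            yt, yp, average="macro", zero_division=0
        )
        assert panel.precision == pytest.approx(p, abs=1e-12)
        assert panel.recall == pytest.approx(r, abs=1e-12)
        assert panel.f1 == pytest.approx(f, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        counts = rng.integers(0, 20, (4, 4)) + np.eye(4, dtype=int)
        perm = rng.permutation(4)
        base = metric_panel(cm(counts))
        permuted = metric_panel(cm(counts[np.ix_(perm, perm)]))
        for attr in ("accuracy", "f1", "kappa"):
            assert getattr(base, attr) == pytest.approx(
                getattr(permuted, attr), abs=1e-12
            )


class TestHarness:
    def test_single_run_summary_degenerates(self, small_dataset):
        rep = run_experiment(
            lambda s: build_baseline(BaselineSpec("lda", seed=s)),
            small_dataset, n_runs=1, base_seed=0,
        )
        s = rep.summary()
        assert s["max"] == s["min"] == s["ave"]
        assert s["var"] == 0.0

    def test_multi_run_order_statistics(self, small_dataset):
        rep = run_experiment(
            lambda s: build_baseline(BaselineSpec("dt", seed=s)),
            small_dataset, n_runs=4, base_seed=0,
        )
        assert len(rep.records) == 4
        s = rep.summary()
        assert s["min"] <= s["ave"] <= s["max"]
        assert s["var"] >= 0
        # population variance recomputable from the records
        acc = rep.accuracies()
        assert s["var"] == pytest.approx(np.mean((acc - acc.mean()) ** 2))

    def test_identical_base_seed_reproduces_report(self, small_dataset):
        mk = lambda: run_experiment(
            lambda s: build_baseline(BaselineSpec("dt", seed=s)),
            small_dataset, n_runs=3, base_seed=5,
        )
        a, b = mk(), mk()
        assert [r.panel.as_dict() for r in a.records] == [
            r.panel.as_dict() for r in b.records
        ]

    def test_comparison_table_layout_and_round_trip(self, small_dataset, tmp_path):
        reports = []
        for name in ("lda", "dt"):
            rep = run_experiment(
                lambda s, _n=name: build_baseline(BaselineSpec(_n, seed=s)),
                small_dataset, n_runs=3, base_seed=0,
            )
            reports.append((name, rep))
        table = comparison_table(reports)
        assert list(table.columns) == [
            "Models", "1st", "2nd", "3rd", "Max.", "Min.", "Ave.", "Var."
        ]
        assert len(table) == 2
        path = tmp_path / "cmp.csv"
        render_table(table, path)
        import pandas as pd
        back = pd.read_csv(path)
        np.testing.assert_allclose(
            back["Ave."].to_numpy(), table["Ave."].to_numpy(), rtol=1e-5
        )

    def test_empty_report_list_rejected(self):
        with pytest.raises(ValueError):
            comparison_table([])


class TestDecodedOverlay:
    def test_writes_one_figure_per_sample_and_is_deterministic(
        self, toy2_normalized, tmp_path
    ):
        from olce import OlceClassifier, TrainConfig, decoded_overlay

        clf = OlceClassifier(train_config=TrainConfig(epochs=2), seed=0)
        clf.fit(toy2_normalized)
        samples = toy2_normalized.samples[:2]
        p1 = decoded_overlay(clf.model, samples, tmp_path / "a")
        p2 = decoded_overlay(clf.model, samples, tmp_path / "b")
        assert len(p1) == len(p2) == 2
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_grid_mode_writes_single_file(self, toy2_normalized, tmp_path):
        from olce import OlceClassifier, TrainConfig, decoded_overlay

        clf = OlceClassifier(train_config=TrainConfig(epochs=1), seed=0)
        clf.fit(toy2_normalized)
        paths = decoded_overlay(
            clf.model, toy2_normalized.samples[:3], tmp_path, grid=True
        )
        assert len(paths) == 1 and paths[0].exists()
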