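"""Scoring layer: confusion matrices, one-vs-rest metrics, kappa, sweeps."""

from math import isnan

import numpy as np
import pandas as pd
import pytest

from sentifuse.backends import MockParams
from sentifuse.corpus import SentimentLabel
from sentifuse.evaluation import (
    class_metrics,
    cohen_kappa,
    confusion_matrix,
    format_pct,
    fuse_records,
    overall_accuracy,
    sweep_combinations,
)
from sentifuse.errors import InputError
from sentifuse.synthetic import SimulationConfig, simulate_corpus, simulate_ensemble_outputs

NEG, NEU, POS = "negative", "neutral", "positive"


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        gold = [NEG, NEU, POS, NEG, NEU]
        cm = confusion_matrix(gold, gold)
        assert np.trace(cm) == 5 and cm.sum() == 5

    def test_degenerate_single_cell(self):
        cm = confusion_matrix([NEG] * 4, [POS] * 4)
        assert cm[0, 2] == 4 and cm.sum() == 4

    def test_hand_tallied_mixed_fixture(self):
        gold = [NEG, NEG, NEU, POS, POS, NEU]
        pred = [NEG, NEU, NEU, POS, NEG, NEU]
        cm = confusion_matrix(gold, pred)
        np.testing.assert_array_equal(cm, [[1, 1, 0], [0, 2, 0], [1, 0, 1]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            confusion_matrix([NEG], [NEG, POS])

    def test_micro_accuracy_equals_exact_match_fraction(self, rng):
        gold = rng.choice([NEG, NEU, POS], size=500)
        pred = rng.choice([NEG, NEU, POS], size=500)
        cm = confusion_matrix(gold, pred)
        assert overall_accuracy(cm) == pytest.approx((gold == pred).mean())


class TestClassMetrics:
    def test_direct_formula_fixture(self):
        # TP=3, FN=2, FP=1, TN=4 encoded for the negative class
        cm = np.array([[3, 2, 0], [1, 4, 0], [0, 0, 0]])
        m = class_metrics(cm, SentimentLabel.NEGATIVE)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.precision == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.7)
        assert m.f1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_perfect_matrix_all_ones(self):
        cm = np.diag([5, 3, 2])
        for lab in SentimentLabel:
            m = class_metrics(cm, lab)
            assert (m.sensitivity, m.precision, m.accuracy, m.f1) == (1, 1, 1, 1)
            assert not m.undefined

    def test_vacuous_class_flagged_not_zeroed(self):
        # positive never appears in gold or predictions
        cm = np.array([[4, 1, 0], [2, 3, 0], [0, 0, 0]])
        m = class_metrics(cm, SentimentLabel.POSITIVE)
        assert isnan(m.sensitivity) and "sensitivity" in m.undefined
        assert isnan(m.precision) and "precision" in m.undefined
        assert m.accuracy == 1.0

    def test_metrics_within_unit_interval(self, rng):
        for _ in range(50):
            cm = rng.integers(0, 20, size=(3, 3))
            if cm.sum() == 0:
                continue
            for lab in SentimentLabel:
                m = class_metrics(cm, lab)
                for v in (m.sensitivity, m.precision, m.accuracy, m.f1):
                    assert isnan(v) or 0 <= v <= 1


class TestOverallAccuracy:
    def test_examples(self):
        assert overall_accuracy(np.diag([4, 3, 3])) == 1.0
        assert overall_accuracy(np.array([[0, 5, 0], [0, 0, 5], [5, 0, 0]])) == 0.0
        # 241 correct of 300 prints as 80.3%
        cm = np.diag([100, 100, 41])
        cm[0, 1] = 59
        assert overall_accuracy(cm) == pytest.approx(241 / 300)
        assert format_pct(241 / 300) == 80.3


class TestCohenKappa:
    def test_perfect_agreement(self):
        seq = [NEG, NEU, POS, NEG]
        assert cohen_kappa(seq, seq) == pytest.approx(1.0)

    def test_two_by_two_agreement_table(self):
        """Agreement table [[40,10],[20,30]] over two labels: p_o=0.7,
        p_e=0.5, kappa=0.4."""
        a = [NEG] * 50 + [NEU] * 50
        b = [NEG] * 40 + [NEU] * 10 + [NEG] * 20 + [NEU] * 30
        assert cohen_kappa(a, b) == pytest.approx(0.4)

    def test_symmetric(self, rng):
        a = rng.choice([NEG, NEU, POS], size=200).tolist()
        b = rng.choice([NEG, NEU, POS], size=200).tolist()
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a))

    def test_independent_raters_near_zero(self, rng):
        n = 30_000
        a = rng.choice([NEG, NEU, POS], size=n).tolist()
        b = rng.choice([NEG, NEU, POS], size=n).tolist()
        # kappa of independent raters ~ N(0, ~1/n); generous 3-sigma band
        assert abs(cohen_kappa(a, b)) < 3 * 2 / np.sqrt(n)

    def test_degenerate_constant_identical_is_undefined(self):
        assert isnan(cohen_kappa([NEG] * 5, [NEG] * 5))


class TestFusionSweep:
    def _mock_setup(self, accuracies, n=2000, seed=5):
        cfg = SimulationConfig(n_pre=n // 2, n_peri=n // 2, seed=seed)
        corpus = simulate_corpus(cfg, with_text=False)
        mocks = [MockParams.symmetric(a, seed=seed + i) for i, a in enumerate(accuracies)]
        tables = simulate_ensemble_outputs(corpus, mocks, seed=seed)
        gold = {r.id: r.gold_label for r in corpus}
        return tables, gold

    def test_identical_models_fuse_to_same_accuracy(self):
        """Two copies of the same model output: consensus fusion sharpens
        masses but cannot change any argmax decision."""
        tables, gold = self._mock_setup([0.7], n=1000)
        twin = {"model1": tables["model1"], "twin": tables["model1"].copy()}
        report = sweep_combinations(twin, gold, [["model1", "twin"]])
        by = report.set_index("subset")
        assert (
            by.loc["model1+twin", "accuracy"] == by.loc["model1", "accuracy"]
        )

    def test_independent_equal_mocks_improve_on_best_individual(self):
        tables, gold = self._mock_setup([0.7, 0.7, 0.7], n=5000, seed=31)
        report = sweep_combinations(
            tables, gold, [["model1", "model2", "model3"]]
        ).set_index("subset")
        best_single = report.loc[["model1", "model2", "model3"], "accuracy"].max()
        assert report.loc["model1+model2+model3", "accuracy"] > best_single

    def test_empty_subset_list_gives_empty_report(self):
        tables, gold = self._mock_setup([0.7], n=100)
        assert len(sweep_combinations(tables, gold, [])) == 0

    def test_unknown_model_rejected(self):
        tables, gold = self._mock_setup([0.7], n=100)
        with pytest.raises(InputError):
            sweep_combinations(tables, gold, [["nope"]])

    def test_random_partner_harmless_only_when_discounted(self):
        """A uniform-confusion partner is uninformative only in expectation:
        its realized outputs are random tilts that flip product-fused
        decisions, degrading a 90%-accurate model. Discounting the ensemble
        toward vacuity is the remedy: with a heavy discount the partner's
        BBA approaches the vacuous identity and the strong model's decisions
        come back."""
        from sentifuse.dst import bba_from_probs, combine, decide

        cfg = SimulationConfig(n_pre=2500, n_peri=2500, seed=8)
        corpus = simulate_corpus(cfg, with_text=False)
        strong = MockParams.symmetric(0.9, seed=1)
        uniform = MockParams(confusion=tuple((1 / 3,) * 3 for _ in range(3)),
                             concentration=20.0, seed=2)
        tables = simulate_ensemble_outputs(corpus, [strong, uniform], seed=8)
        gold = {r.id: r.gold_label for r in corpus}
        report = sweep_combinations(
            tables, gold, [["model1", "model2"]]
        ).set_index("subset")
        assert (
            report.loc["model1+model2", "accuracy"]
            < report.loc["model1", "accuracy"] - 0.05
        )

        strong_probs = tables["model1"].to_numpy()
        partner_probs = tables["model2"].to_numpy()
        agree = 0
        for k in range(len(strong_probs)):
            solo = decide(bba_from_probs(strong_probs[k]))
            fused = decide(
                combine(
                    bba_from_probs(strong_probs[k]),
                    bba_from_probs(partner_probs[k], discount=0.02),
                ).combined
            )
            agree += solo.label is fused.label
        assert agree / len(strong_probs) > 0.99


def test_fuse_records_output_shape():
    probs = pd.DataFrame(
        {"p_negative": [0.6, 0.2], "p_neutral": [0.3, 0.3], "p_positive": [0.1, 0.5]},
        index=pd.Index(["t1", "t2"], name="id"),
    )
    fused = fuse_records({"m": probs}, ["m"])
    assert list(fused.columns) == [
        "m_negative", "m_neutral", "m_positive", "m_theta",
        "conflict", "decision", "tie_flag",
    ]
    assert fused.loc["t1", "decision"] == NEG
    assert fused.loc["t2", "decision"] == POS
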