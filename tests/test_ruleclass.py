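"""One-R induction, cross-validation, confusion metrics, cohort and
prognosis evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import best_threshold_rule_error, separable_table
from tracecond.eda import cr_from_features_table, features_table
from tracecond.ruleclass import (
    cohort_summary,
    cross_validate,
    evaluate_prognosis,
    load_cohort_fixture,
    metrics_from_confusion,
    oner_discretize,
    oner_fit,
    oner_predict,
    read_cohort,
)
from tracecond.synthgen import DEFAULT_ARCHETYPES, simulate_gsr


class TestDiscretize:
    def test_separable_midpoint(self):
        cuts, classes = oner_discretize(
            [1, 2, 3, 10, 11, 12], ["A", "A", "A", "B", "B", "B"], min_bucket=1
        )
        assert cuts == (6.5,)
        assert classes == ("A", "B")

    def test_single_class_single_bin(self):
        cuts, classes = oner_discretize([5, 1, 9, 3], ["A"] * 4, min_bucket=2)
        assert cuts == ()
        assert classes == ("A",)

    def test_hand_traced_interleaved_example(self):
        # min_bucket=3 trace: bin grows over values 1..4 (A reaches 3),
        # extends through 5, 6 (class A); second bin grows over 7..10 and
        # extends through 12; cut at the midpoint 6.5.
        values = list(range(1, 13))
        labels = list("AABAAABBABBB")
        cuts, classes = oner_discretize(values, labels, min_bucket=3)
        assert cuts == (6.5,)
        assert classes == ("A", "B")

    def test_fewer_values_than_bucket(self):
        cuts, classes = oner_discretize([1.0, 2.0], ["A", "B"], min_bucket=6)
        assert cuts == ()
        assert len(classes) == 1

    def test_strictly_increasing_cuts_and_alternating_classes(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=40)
        lab = np.where(np.sin(v * 3) > 0, "A", "B")
        cuts, classes = oner_discretize(v, lab, min_bucket=3)
        assert all(a < b for a, b in zip(cuts, cuts[1:]))
        assert all(a != b for a, b in zip(classes, classes[1:]))


class TestFit:
    def test_perfect_attribute_selected(self):
        df = separable_table(np.random.default_rng(0), n_per_class=10)
        model = oner_fit(df, "cls", min_bucket=6)
        assert model.selected.attribute == "informative"
        assert model.selected.training_error == 0

    def test_tie_broken_by_column_order(self):
        df = pd.DataFrame({
            "a1": [1, 2, 3, 4, 10, 11, 12, 13.0],
            "a2": [1, 2, 3, 4, 10, 11, 12, 13.0],
            "cls": list("XXXXYYYY"),
        })
        model = oner_fit(df, "cls", min_bucket=2)
        assert model.rules["a1"].training_error == model.rules["a2"].training_error
        assert model.selected.attribute == "a1"

    def test_error_never_worse_than_majority_rule(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(10, 41))
            df = pd.DataFrame({
                "x": rng.normal(size=n),
                "cls": rng.choice(["P", "N"], size=n),
            })
            model = oner_fit(df, "cls", min_bucket=6)
            labels = df["cls"].to_numpy()
            majority_err = min((labels != c).sum() for c in ("P", "N"))
            assert model.selected.training_error <= majority_err

    def test_matches_exhaustive_threshold_search(self):
        """On threshold-separable tables the greedy binning attains the
        brute-force optimum."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            df = separable_table(rng, n_per_class=int(rng.integers(8, 21)),
                                 margin=rng.uniform(1.0, 3.0))
            model = oner_fit(df, "cls", min_bucket=6)
            assert model.selected.training_error == best_threshold_rule_error(
                df, "cls", min_bucket=6
            )

    def test_hand_traced_table_matches_oracle(self):
        df = pd.DataFrame({
            "x": list(range(1, 13)),
            "cls": list("AABAAABBABBB"),
        })
        model = oner_fit(df, "cls", min_bucket=3)
        assert model.selected.training_error == 2
        assert model.selected.training_error == best_threshold_rule_error(df, "cls", 3)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            oner_fit(pd.DataFrame({"x": [], "cls": []}), "cls")


class TestPredict:
    @pytest.fixture()
    def magnitude_rule_model(self):
        # realises the printed-style rule "magnitude < 0.05 -> no CR"
        df = pd.DataFrame({
            "magnitude": [0.01, 0.02, 0.03, 0.04, 0.06, 0.07, 0.2, 0.3],
            "cls": ["no_cr"] * 4 + ["cr"] * 4,
        })
        return oner_fit(df, "cls", min_bucket=2)

    def test_threshold_rule(self, magnitude_rule_model):
        assert oner_predict(magnitude_rule_model, {"magnitude": 0.03}) == "no_cr"
        assert oner_predict(magnitude_rule_model, {"magnitude": 0.30}) == "cr"

    def test_boundary_falls_in_lower_bin(self, magnitude_rule_model):
        cut = magnitude_rule_model.selected.cut_points[0]
        assert oner_predict(magnitude_rule_model, {"magnitude": cut}) == "no_cr"

    def test_missing_attribute_rejected(self, magnitude_rule_model):
        with pytest.raises(KeyError):
            oner_predict(magnitude_rule_model, {"other": 1.0})


class TestCrossValidate:
    def test_seed_determinism(self):
        df = separable_table(np.random.default_rng(1), n_per_class=20, margin=0.2)
        a = cross_validate(df, "cls", "pos", k=10, seed=3)
        b = cross_validate(df, "cls", "pos", k=10, seed=3)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)

    def test_instance_order_invariance(self):
        df = separable_table(np.random.default_rng(2), n_per_class=20, margin=0.2)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = cross_validate(df, "cls", "pos", k=10, seed=3)
        b = cross_validate(shuffled, "cls", "pos", k=10, seed=3)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)

    def test_wide_margin_perfect_accuracy(self):
        df = separable_table(np.random.default_rng(3), n_per_class=20, margin=3.0)
        m = cross_validate(df, "cls", "pos", k=10, seed=1)
        assert m.accuracy == 100.0

    def test_minimal_two_fold(self):
        df = pd.DataFrame({
            "x": [1.0, 2.0, 10.0, 11.0],
            "cls": ["n", "n", "p", "p"],
        })
        m = cross_validate(df, "cls", "p", k=2, seed=1, min_bucket=1)
        assert m.tp + m.fp + m.tn + m.fn == 4

    def test_oversized_k_rejected(self):
        df = separable_table(np.random.default_rng(0), n_per_class=4)
        with pytest.raises(ValueError):
            cross_validate(df, "cls", "pos", k=5, seed=1)


class TestConfusionMetrics:
    def test_cohort_contingency_values(self):
        m = metrics_from_confusion(tp=8, fp=1, tn=21, fn=0)
        assert m.sensitivity == 100.0
        assert m.specificity == pytest.approx(95.4545, abs=1e-3)
        assert m.accuracy == pytest.approx(96.6667, abs=1e-3)
        assert m.precision == pytest.approx(88.8889, abs=1e-3)
        assert m.fpr == pytest.approx(4.5455, abs=1e-3)
        assert m.fnr == 0.0
        assert m.rounded == {
            "sensitivity": 100, "specificity": 95, "precision": 89,
            "accuracy": 97, "fpr": 5, "fnr": 0,
        }

    def test_perfect_classifier(self):
        m = metrics_from_confusion(tp=5, fp=0, tn=7, fn=0)
        for v in (m.sensitivity, m.specificity, m.precision, m.accuracy):
            assert v == 100.0
        assert (m.fpr, m.fnr) == (0.0, 0.0)
        assert m.f1 == 1.0

    def test_f1_harmonic_mean_identity(self):
        m = metrics_from_confusion(tp=6, fp=2, tn=10, fn=2)
        assert m.precision == m.sensitivity == 75.0
        assert m.f1 == 0.75

    def test_rate_identities(self):
        m = metrics_from_confusion(tp=3, fp=4, tn=5, fn=6)
        assert m.fpr + m.specificity == 100.0
        assert m.fnr + m.sensitivity == 100.0
        assert m.accuracy == pytest.approx(100.0 * 8 / 18)

    def test_undefined_margins_flagged(self):
        m = metrics_from_confusion(tp=0, fp=0, tn=5, fn=0)
        assert math.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined and "precision" in m.undefined


class TestCohort:
    def test_fixture_counts(self):
        records = load_cohort_fixture()
        s = cohort_summary(records)
        assert s["n_patients"] == 30
        assert s["n_cr_positive"] == 9
        assert s["pct_cr_positive"] == pytest.approx(30.0)
        assert s["n_final_mcs"] == 8
        assert s["n_late_evolvers"] == 2
        assert s["pct_cr_positive_mcs"] == pytest.approx(88.89, abs=0.01)

    def test_invalid_cr_response_rejected(self, tmp_path):
        df = pd.read_csv(
            __import__("tracecond.ruleclass", fromlist=["x"]).cohort_fixture_path()
        )
        df.loc[0, "cr_response"] = 2
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="cr_response"):
            read_cohort(bad)

    def test_prognosis_contingency(self):
        m = evaluate_prognosis(load_cohort_fixture())
        assert (m.tp, m.fp, m.tn, m.fn) == (8, 1, 21, 0)

    def test_identity_predictor_perfect(self, tmp_path):
        df = pd.read_csv(
            __import__("tracecond.ruleclass", fromlist=["x"]).cohort_fixture_path()
        )
        df["cr_response"] = (df["final_diagnosis"] == "MCS").astype(int)
        path = tmp_path / "ident.csv"
        df.to_csv(path, index=False)
        m = evaluate_prognosis(read_cohort(path))
        assert (m.fp, m.fn) == (0, 0)
        assert m.accuracy == 100.0

    def test_late_evolvers_widen_false_negatives(self):
        records = load_cohort_fixture()
        m = evaluate_prognosis(records, late_as_positive=True)
        assert m.fn == 2
        assert m.sensitivity < 100.0


class TestPipelineRecovery:
    def test_magnitude_rule_separates_archetypes(self, timeline):
        """Simulated cohort -> features -> NOC* magnitude -> One-R yields a
        near-separating threshold rule (20 seeds x 40 subjects)."""
        for seed in range(20):
            rows = []
            for i in range(40):
                name = "UWS_CR" if i < 16 else "UWS_NOCR"
                rec, _ = simulate_gsr(
                    timeline, DEFAULT_ARCHETYPES[name], seed=100_000 + seed * 100 + i
                )
                tab = features_table(rec, timeline)
                mag = float(
                    tab.set_index("event_label").loc["NOC_STAR", "peak_magnitude_uS"]
                )
                rows.append({"magnitude_NOC_STAR": mag, "cls": name})
            df = pd.DataFrame(rows)
            model = oner_fit(df, "cls", min_bucket=6)
            assert model.selected.training_error <= 0.05 * len(df)
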