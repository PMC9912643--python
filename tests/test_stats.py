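import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from _oracles import fisher_p_two_sided
from hlaase.errors import ParameterError
from hlaase.stats import (
    ConfusionCounts,
    cohort_loss_frequency,
    confusion_metrics,
    evaluate_calls,
    fisher_exact,
    roc_auc,
)


class TestConfusionMetrics:
    def test_validation_counts_round_to_one_decimal(self):
        sens, _ = confusion_metrics(ConfusionCounts(tp=324, fp=0, tn=0, fn=58))
        _, spec = confusion_metrics(ConfusionCounts(tp=0, fp=15, tn=688, fn=0))
        assert round(sens, 1) == 84.8
        assert round(spec, 1) == 97.9

    def test_perfect_sensitivity(self):
        sens, _ = confusion_metrics(ConfusionCounts(tp=10, fp=0, tn=0, fn=0))
        assert sens == 100.0

    def test_zero_denominator_is_undefined_not_zero(self):
        sens, spec = confusion_metrics(ConfusionCounts(tp=0, fp=3, tn=7, fn=0))
        assert sens is None and spec == 70.0

    def test_label_swap_exchanges_metric_names(self):
        counts = ConfusionCounts(tp=30, fp=5, tn=50, fn=15)
        swapped = ConfusionCounts(tp=counts.tn, fp=counts.fn, tn=counts.tp, fn=counts.fp)
        assert confusion_metrics(counts) == confusion_metrics(swapped)[::-1]

    def test_from_labels(self):
        counts = ConfusionCounts.from_labels(
            predicted=[1, 1, 0, 0, 1], truth=[1, 0, 0, 1, 1]
        )
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (2, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_enumerated_pairs(self):
        # pos (0.1, 0.4) vs neg (0.3, 0.9): 3 of 4 pairs concordant
        assert roc_auc([0.1, 0.4, 0.3, 0.9], [1, 1, 0, 0]) == 0.75

    def test_orientation_flag(self):
        scores, labels = [0.1, 0.4, 0.3, 0.9], [1, 1, 0, 0]
        low = roc_auc(scores, labels, lower_is_positive=True)
        high = roc_auc(scores, labels, lower_is_positive=False)
        assert low + high == pytest.approx(1.0)

    def test_rank_statistic_matches_trapezoid_auc(self):
        rng = np.random.default_rng(11)
        scores = np.round(rng.normal(size=300), 1)  # rounding forces ties
        labels = rng.random(300) < 0.4
        mine = roc_auc(scores, labels, lower_is_positive=False)
        sk = roc_auc_score(labels.astype(int), scores)
        assert mine == pytest.approx(sk, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc([0.1, 0.2], [1, 1])


class TestFisherExact:
    def test_odds_ratio_and_enumeration_p(self):
        odds, p = fisher_exact(10, 5, 10, 20)
        assert odds == pytest.approx(4.0)
        assert p == pytest.approx(fisher_p_two_sided(10, 5, 10, 20), abs=1e-10)

    def test_infinite_odds_ratio_convention(self):
        odds, p = fisher_exact(5, 0, 2, 10)
        assert odds == math.inf
        assert 0 < p <= 1

    def test_symmetric_table(self):
        odds, p = fisher_exact(1, 1, 1, 1)
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact(0, 0, 0, 0)

    def test_zero_products_give_nan_odds(self):
        odds, _ = fisher_exact(0, 3, 0, 5)
        assert math.isnan(odds)

    @pytest.mark.parametrize(
        "table", [(3, 1, 1, 3), (0, 4, 4, 0), (2, 2, 3, 5), (7, 0, 0, 7), (1, 0, 5, 6)]
    )
    def test_small_tables_match_exact_enumeration(self, table):
        _, p = fisher_exact(*table)
        assert p == pytest.approx(fisher_p_two_sided(*table), abs=1e-12)


class TestCohortFrequencies:
    def _summary(self):
        rows = []
        for i in range(100):
            loss = i < 86
            rows.append(
                {
                    "sample": f"s{i}",
                    "purity_pass": True,
                    "n_assessable": 3,
                    "any_loss": loss,
                    "loss_A": loss and i % 2 == 0,
                    "loss_B": loss and i % 3 == 0,
                    "loss_C": loss,
                }
            )
        return pd.DataFrame(rows)

    def test_loss_fraction(self):
        out = cohort_loss_frequency(self._summary())
        assert out.loc[0, "loss_fraction"] == pytest.approx(0.86)
        assert out.loc[0, "n_assessable_cases"] == 100

    def test_gene_attribution_fractions(self):
        out = cohort_loss_frequency(self._summary())
        loss = self._summary().query("any_loss")
        assert out.loc[0, "frac_A"] == pytest.approx(loss["loss_A"].mean())
        assert out.loc[0, "frac_all_three"] == pytest.approx(
            (loss[["loss_A", "loss_B", "loss_C"]].all(axis=1)).mean()
        )

    def test_empty_group_omitted_with_warning(self):
        df = self._summary()
        df["group"] = "g1"
        extra = df.iloc[:2].copy()
        extra["group"] = "g2"
        extra["n_assessable"] = 0
        df = pd.concat([df, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="g2"):
            out = cohort_loss_frequency(df, group_col="group")
        assert list(out["group"]) == ["g1"]

    def test_evaluate_calls_joins_labels(self):
        summary = pd.DataFrame(
            {
                "sample": ["a", "b", "c", "d"],
                "purity_pass": [True, True, True, False],
                "n_assessable": [3, 3, 3, 3],
                "any_loss": [True, False, True, True],
                "min_minor_expCN": [0.2, 1.0, 0.4, 0.1],
                "min_minor_AF": [0.1, 0.5, 0.2, 0.05],
            }
        )
        labels = pd.DataFrame({"sample": ["a", "b", "c", "d"], "label": [1, 0, 0, 1]})
        metrics = evaluate_calls(summary, labels)
        # case d fails the purity filter and must not enter the metrics
        assert metrics["n_cases"] == 3
        assert metrics["tp"] == 1 and metrics["fp"] == 1
        assert metrics["sensitivity_pct"] == 100.0
        assert metrics["specificity_pct"] == 50.0
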