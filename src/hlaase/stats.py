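"""Validation and association statistics for ASE-loss calling.

Sensitivity/specificity from labeled positive/negative controls, ROC AUC of
the continuous loss score by the rank (Mann-Whitney) statistic, Fisher's
exact test for enrichment with the conventional sample odds ratio
(ad/bc, infinite when bc = 0 and ad > 0), and cohort loss-frequency
summaries with per-gene attribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ParameterError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, predicted, truth) -> "ConfusionCounts":
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if predicted.shape != truth.shape:
            raise ParameterError("predicted and truth labels differ in length")
        return cls(
            tp=int((predicted & truth).sum()),
            fp=int((predicted & ~truth).sum()),
            tn=int((~predicted & ~truth).sum()),
            fn=int((~predicted & truth).sum()),
        )


def confusion_metrics(counts: ConfusionCounts):
    """Sensitivity and specificity in percent.

    A metric with a zero denominator is undefined and returned as None,
    never as 0.
    """
    sens = (
        100.0 * counts.tp / (counts.tp + counts.fn)
        if counts.tp + counts.fn > 0
        else None
    )
    spec = (
        100.0 * counts.tn / (counts.tn + counts.fp)
        if counts.tn + counts.fp > 0
        else None
    )
    return sens, spec


def roc_auc(scores, labels, lower_is_positive: bool = True) -> float:
    """AUC as the rank statistic: the probability that a random positive
    case scores more loss-like than a random negative one (ties count 1/2).

    ``lower_is_positive`` states the score orientation explicitly; the
    package's loss scores (minor expressed copy number, minor AF) are low
    when loss-like.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC requires both classes present")
    oriented = -scores if lower_is_positive else scores
    ranks = scipy.stats.rankdata(oriented)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fisher_exact(a: int, b: int, c: int, d: int):
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p).  The odds ratio is the sample OR = ad / bc,
    reported as +inf when bc = 0 and ad > 0 (the "OR = inf." convention) and
    as NaN when both products vanish.  The two-sided p sums hypergeometric
    probabilities of tables at most as probable as the observed one.
    """
    table = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in table):
        raise ParameterError("contingency table entries must be non-negative integers")
    if sum(table) == 0:
        raise ParameterError("all-zero contingency table: odds ratio undefined")
    a, b, c, d = (int(x) for x in table)
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def cohort_loss_frequency(
    summary: pd.DataFrame, group_col: str | None = None
) -> pd.DataFrame:
    """Cohort loss fractions from a case-summary table.

    Input columns: ``purity_pass``, ``n_assessable``, ``any_loss`` and
    (optionally) ``loss_A``/``loss_B``/``loss_C`` plus a grouping column.
    Cases failing the purity filter or with no assessable gene are excluded
    from the denominators.  Per-gene attribution fractions are computed among
    loss cases; groups with zero assessable cases are omitted with a warning.
    """
    df = summary.copy()
    if group_col is None:
        df["_group"] = "all"
        group_col = "_group"
    rows = []
    for group, sub in df.groupby(group_col, sort=True):
        eligible = sub[(sub["purity_pass"]) & (sub["n_assessable"] > 0)]
        n = len(eligible)
        if n == 0:
            warnings.warn(f"group {group!r} has no assessable cases; omitted")
            continue
        loss = eligible[eligible["any_loss"].astype(bool)]
        row = {
            "group": group,
            "n_assessable_cases": n,
            "n_loss": len(loss),
            "loss_fraction": len(loss) / n,
        }
        gene_cols = [c for c in ("loss_A", "loss_B", "loss_C") if c in df.columns]
        if gene_cols and len(loss) > 0:
            for col in gene_cols:
                row[f"frac_{col.removeprefix('loss_')}"] = (
                    loss[col].astype(bool).sum() / len(loss)
                )
            row["frac_all_three"] = (
                loss[gene_cols].astype(bool).all(axis=1).sum() / len(loss)
            )
        elif gene_cols:
            for col in gene_cols:
                row[f"frac_{col.removeprefix('loss_')}"] = np.nan
            row["frac_all_three"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_calls(summary: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Join case summaries with truth labels and compute the validation
    metrics (sensitivity %, specificity %, AUC on each loss score).

    ``labels`` needs columns ``sample`` and ``label`` (1 = true loss).
    Only purity-passing, assessable cases enter the metrics.
    """
    merged = summary.merge(labels, on="sample", how="inner")
    merged = merged[(merged["purity_pass"]) & (merged["n_assessable"] > 0)]
    if merged.empty:
        raise ParameterError("no labeled assessable cases to evaluate")
    truth = merged["label"].astype(bool).to_numpy()
    predicted = merged["any_loss"].astype(bool).to_numpy()
    counts = ConfusionCounts.from_labels(predicted, truth)
    sens, spec = confusion_metrics(counts)
    metrics = {
        "n_cases": int(len(merged)),
        "tp": counts.tp,
        "fp": counts.fp,
        "tn": counts.tn,
        "fn": counts.fn,
        "sensitivity_pct": sens,
        "specificity_pct": spec,
    }
    if truth.any() and not truth.all():
        metrics["auc_min_minor_expCN"] = roc_auc(
            merged["min_minor_expCN"].to_numpy(), truth, lower_is_positive=True
        )
        metrics["auc_min_minor_AF"] = roc_auc(
            merged["min_minor_AF"].to_numpy(), truth, lower_is_positive=True
        )
    return metrics
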