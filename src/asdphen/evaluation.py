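"""Criterion- and case-level evaluation and 2x2 comparison statistics.

Metrics follow the standard confusion-matrix definitions:

    accuracy    = (TP + TN) / (P + N)
    precision   = TP / PP          (positive predictive value)
    recall      = TP / P           (sensitivity)
    F1          = 2*TP / (2*TP + FP + FN)
    specificity = TN / N

A 0/0 metric is *undefined* and reported as ``None`` rather than 0; a
formatting option restores the print-a-zero convention used for predictors
that assign no labels at all.

For 2x2 case-comparison tables the module reports both the two-sided Fisher
exact test (exact integer hypergeometric enumeration) and the Pearson
chi-square statistic with standardized residuals (O-E)/sqrt(E).
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from math import comb
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import ALL_CRITERIA, ConfusionCounts, MetricsReport, PredictionSet, Record


# ---------------------------------------------------------------------------
# confusion counts and metrics


def confusion(pred: Mapping[str, bool], gold: Mapping[str, bool]) -> ConfusionCounts:
    """Confusion counts for binary decisions keyed by the same ids.

    Raises ``ValueError`` listing the symmetric difference when the key sets
    differ — a silent join would hide dropped records.
    """
    pk, gk = set(pred), set(gold)
    if pk != gk:
        diff = sorted(pk.symmetric_difference(gk))
        raise ValueError(f"prediction/gold key mismatch: {diff}")
    tp = fp = fn = tn = 0
    for k in pk:
        p, g = bool(pred[k]), bool(gold[k])
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five metrics from confusion counts; 0-denominator -> ``None``."""
    return MetricsReport(
        precision=_ratio(c.TP, c.PP),
        recall=_ratio(c.TP, c.P),
        f1=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
        accuracy=_ratio(c.TP + c.TN, c.total),
        specificity=_ratio(c.TN, c.N),
    )


def majority_baseline(n_positive: int, n_total: int) -> float:
    """Accuracy of always predicting the most common case label."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return max(n_positive, n_total - n_positive) / n_total


# ---------------------------------------------------------------------------
# per-criterion sentence-level report


def per_criterion_report(
    pred: PredictionSet,
    records: Sequence[Record],
    zero_fill: bool = True,
) -> pd.DataFrame:
    """Precision/recall/F1 per criterion over all sentences, plus a mean row.

    Each criterion is scored as an independent binary task over every
    sentence in ``records``.  The ``Avg.`` row is the unweighted arithmetic
    mean of the seven per-criterion values; with ``zero_fill`` (the table
    convention) undefined values enter the mean as 0, otherwise they are
    skipped and reported as NaN.
    """
    rows = []
    for crit in ALL_CRITERIA:
        tp = fp = fn = tn = 0
        for rec in records:
            for sent in rec.sentences:
                g = crit in sent.gold_labels
                p = crit in pred.labels_for(sent.sentence_id)
                if p and g:
                    tp += 1
                elif p and not g:
                    fp += 1
                elif not p and g:
                    fn += 1
                else:
                    tn += 1
        m = metrics(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
        rows.append(
            {
                "criterion": crit.value,
                # NaN is the DataFrame representation of the undefined marker
                "precision": np.nan if m.precision is None else m.precision,
                "recall": np.nan if m.recall is None else m.recall,
                "f1": np.nan if m.f1 is None else m.f1,
                "support": tp + fn,
            }
        )
    df = pd.DataFrame(rows)
    avg = {"criterion": "Avg.", "support": int(df["support"].sum())}
    for col in ("precision", "recall", "f1"):
        vals = df[col].astype(float)
        if zero_fill:
            vals = vals.fillna(0.0)
        avg[col] = float(vals.mean()) if not vals.isna().all() else float("nan")
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def unweighted_mean(values: Sequence[Optional[float]], zero_fill: bool = True) -> float:
    """Unweighted mean across criteria (the tables' averaging convention)."""
    vals = [0.0 if (v is None or np.isnan(v)) and zero_fill else v for v in values]
    return float(np.mean([v for v in vals if v is not None and not np.isnan(v)]))


def sentence_micro_confusion(
    pred: PredictionSet, records: Sequence[Record]
) -> ConfusionCounts:
    """Micro-averaged confusion over all (sentence, criterion) pairs."""
    tp = fp = fn = tn = 0
    for rec in records:
        for sent in rec.sentences:
            p = pred.labels_for(sent.sentence_id)
            g = sent.gold_labels
            for crit in ALL_CRITERIA:
                if crit in p and crit in g:
                    tp += 1
                elif crit in p:
                    fp += 1
                elif crit in g:
                    fn += 1
                else:
                    tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


# ---------------------------------------------------------------------------
# 2x2 comparison statistics


@lru_cache(maxsize=4096)
def _hypergeom_table(n: int, r: int, k: int) -> Tuple[Tuple[int, ...], int]:
    """Exact hypergeometric numerators C(r,a)*C(n-r,k-a) over the support."""
    amin, amax = max(0, k - (n - r)), min(k, r)
    nums = tuple(comb(r, a) * comb(n - r, k - a) for a in range(amin, amax + 1))
    return nums, amin


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Computed by exact integer enumeration: with margins fixed, sum the
    hypergeometric probabilities of every table no more probable than the
    observed one.  Integer arithmetic makes tie handling exact.  A zero
    margin carries no information; p = 1 is returned with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("2x2 table has a zero margin; p-value is 1", stacklevel=2)
        return 1.0
    nums, amin = _hypergeom_table(n, a + b, a + c)
    obs = nums[a - amin]
    total = comb(n, a + c)
    return sum(v for v in nums if v <= obs) / total


def pearson_chi2(table) -> Tuple[float, float, np.ndarray]:
    """Pearson chi-square statistic, p-value, and standardized residuals.

    Residuals are (O - E)/sqrt(E) per cell.  No continuity correction is
    applied.  A zero margin returns (0.0, 1.0, zero residuals) with a
    warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if n <= 0 or rows.min() == 0 or cols.min() == 0:
        warnings.warn("2x2 table has a zero margin; chi-square undefined", stacklevel=2)
        return 0.0, 1.0, np.zeros((2, 2))
    expected = np.outer(rows, cols) / n
    residuals = (t - expected) / np.sqrt(expected)
    stat = float((residuals**2).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p, residuals


# ---------------------------------------------------------------------------
# case-level convenience


def case_confusion(
    pred_cases: Mapping[str, bool], gold_cases: Mapping[str, bool]
) -> ConfusionCounts:
    """Alias of :func:`confusion` for record-level ASD decisions."""
    return confusion(pred_cases, gold_cases)


def case_table(pred_cases: Mapping[str, bool], gold_cases: Mapping[str, bool]) -> np.ndarray:
    """2x2 table (rows predicted ASD/No ASD, columns gold ASD/No ASD)."""
    c = confusion(pred_cases, gold_cases)
    return np.array([[c.TP, c.FP], [c.FN, c.TN]], dtype=np.int64)


def metrics_row(name: str, c: ConfusionCounts, zero_fill: bool = False) -> Dict[str, object]:
    """One flat report row: name, counts, and the five metrics."""
    m = metrics(c).as_dict(zero_fill=zero_fill)
    return {"name": name, "TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN, **m}
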