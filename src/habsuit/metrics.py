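"""Threshold-independent validation metrics and the normalized average.

Models are compared on AUC-ROC, AUC-PR and the Pearson correlation between
predicted suitability and the 0/1 occurrence label. For rare species AUC-PR
is the most informative of the three because it ignores the overwhelming
true-negative mass. To rank models across all three, each metric column is
min-max scaled over the model table (the weighted-ensemble row included)
and the three scaled values averaged per model.

AUC-PR uses the average-precision (step) estimator, not trapezoidal
interpolation, which is optimistic in precision-recall space; ties are
handled by grouping equal scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricRow",
    "auc_roc",
    "auc_pr",
    "pearson_correlation",
    "metric_row",
    "normalized_average",
    "render_metric_table",
]

METRIC_COLUMNS = ["auc_roc", "auc_pr", "pearson_r"]


@dataclass
class MetricRow:
    """One model's threshold-independent validation metrics."""

    model_id: str
    auc_roc: float
    auc_pr: float
    pearson_r: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int)


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve: P(score+ > score-) + 0.5 P(tie)."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_pr(scores, labels) -> float:
    """Area under the precision-recall curve, average-precision form."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("at least one positive is required")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def pearson_correlation(scores, labels) -> float:
    """Pearson product-moment correlation of scores against 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.std() == 0 or labels.std() == 0:
        raise ValueError("zero variance in scores or labels")
    return float(stats.pearsonr(scores, labels).statistic)


def metric_row(model_id: str, scores, labels) -> MetricRow:
    return MetricRow(model_id, auc_roc(scores, labels), auc_pr(scores, labels),
                     pearson_correlation(scores, labels))


def normalized_average(rows) -> pd.DataFrame:
    """Min-max scale each metric column across all rows and average.

    ``rows`` is a list of :class:`MetricRow` or a DataFrame with columns
    model_id, auc_roc, auc_pr, pearson_r — including any ensemble row, which
    takes part in the scaling. A zero-range column contributes 0.5 for every
    model (an uninformative metric is neutral). Returns the input table with
    scaled columns and the ``normalized_average`` column appended.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame([r.__dict__ for r in rows])
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to normalize")
    out = rows.copy().reset_index(drop=True)
    scaled = {}
    for col in METRIC_COLUMNS:
        v = out[col].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values in metric column {col!r}")
        rng = v.max() - v.min()
        scaled[col] = np.full_like(v, 0.5) if rng == 0 else (v - v.min()) / rng
        out[f"scaled_{col}"] = scaled[col]
    out["normalized_average"] = np.mean([scaled[c] for c in METRIC_COLUMNS], axis=0)
    return out


def render_metric_table(table: pd.DataFrame) -> str:
    """Markdown metric table with each column's best value in bold."""
    cols = ["auc_roc", "auc_pr", "pearson_r", "normalized_average"]
    headers = ["Model", "AUC-ROC", "AUC-PR", "Correlation", "Normalized average"]
    lines = ["| " + " | ".join(headers) + " |",
             "|" + "---|" * len(headers)]
    best = {c: table[c].max() for c in cols if c in table}
    for rec in table.itertuples(index=False):
        cells = [str(rec.model_id)]
        for c in cols:
            if c not in table:
                cells.append("")
                continue
            v = getattr(rec, c)
            s = f"{v:.3f}"
            cells.append(f"**{s}**" if np.isclose(v, best[c]) else s)
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
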