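"""Confusion matrices with per-class row rates.

The report follows the convention of per-activity confusion tables in the
activity-recognition literature: rows are true classes, columns are
predictions, and the trailing percentage column is the row-normalized
diagonal rate (diagonal / row total).  Note this quantity is the per-class
recall; some tables label the same arithmetic "precision" — the report calls
it ``row_rate`` and keeps the arithmetic.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["ConfusionReport", "confusion_matrix", "report_text", "parse_report_text"]


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(
        Decimal(repr(float(x))).quantize(
            Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP
        )
    )


@dataclasses.dataclass
class ConfusionReport:
    """K x K confusion counts plus row rates and overall accuracy.

    ``row_rates`` are percentages at full precision (NaN for empty rows —
    reported as NA, never as 0%); ``overall_accuracy`` is
    100 * trace / total.
    """

    counts: np.ndarray
    labels: list
    row_rates: np.ndarray
    overall_accuracy: float

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def rounded_row_rates(self) -> list:
        """Row rates rounded half-up to 2 decimals (display convention)."""
        return [
            None if np.isnan(r) else _round_half_up(r) for r in self.row_rates
        ]


def confusion_matrix(y_true, y_pred, labels=None) -> ConfusionReport:
    """Tally a confusion report.

    ``labels`` fixes the row/column order; by default the sorted union of
    observed labels.  Predicted labels outside the label set are an error.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} truths, {y_pred.shape[0]} "
            "predictions"
        )
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    labels = list(labels)
    label_set = set(labels)
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        unknown = set(arr.tolist()) - label_set
        if unknown:
            raise ValueError(f"unknown {name} label(s): {sorted(unknown)}")
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_rates = np.where(
            row_tot > 0, 100.0 * np.diag(counts) / np.where(row_tot == 0, 1, row_tot), np.nan
        )
    total = counts.sum()
    overall = 100.0 * np.trace(counts) / total if total else float("nan")
    return ConfusionReport(
        counts=counts, labels=labels, row_rates=row_rates, overall_accuracy=overall
    )


def report_text(report: ConfusionReport) -> str:
    """Fixed-width text table: one row per true class, trailing rate column."""
    labels = [str(l) for l in report.labels]
    width = max(10, max(len(l) for l in labels) + 2)
    cw = max(8, max(len(l) for l in labels) + 2)
    header = "".join(
        [" " * width] + [l.rjust(cw) for l in labels] + ["row_rate".rjust(10)]
    )
    lines = [header]
    for i, lab in enumerate(labels):
        rate = report.row_rates[i]
        rate_s = "NA" if np.isnan(rate) else f"{_round_half_up(rate):.2f}%"
        cells = "".join(str(int(c)).rjust(cw) for c in report.counts[i])
        lines.append(lab.ljust(width) + cells + rate_s.rjust(10))
    lines.append(
        f"overall accuracy: {_round_half_up(report.overall_accuracy):.2f}% "
        f"({int(np.trace(report.counts))}/{report.n_total})"
    )
    return "\n".join(lines) + "\n"


def parse_report_text(text: str) -> tuple[np.ndarray, list[str]]:
    """Recover (counts, labels) from :func:`report_text` output."""
    lines = [l for l in text.splitlines() if l.strip()]
    body = lines[1:-1]
    labels, rows = [], []
    for line in body:
        tokens = line.split()
        labels.append(tokens[0])
        rows.append([int(t) for t in tokens[1:-1]])
    return np.asarray(rows, dtype=int), labels
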