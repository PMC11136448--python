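"""Agreement metrics between predicted and reference annotations.

Overall accuracy is the percentage of exactly matching labels; precision,
recall and F1 are computed one-vs-rest per reference label, with
zero-denominator fractions defined as 0.  The headline per-dataset summary
is the median of the per-label F1 scores.  "unknown"/"unclassified" count
as ordinary labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import AnnotationVector, UNKNOWN, UNCLASSIFIED


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for one label."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_list(v: AnnotationVector | list[str]) -> list[str]:
    return v.labels if isinstance(v, AnnotationVector) else list(v)


def _check_lengths(predicted, reference) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(_as_list(predicted), dtype=object)
    ref = np.asarray(_as_list(reference), dtype=object)
    if len(pred) != len(ref):
        raise ParameterError(
            f"length mismatch: {len(pred)} predicted vs {len(ref)} reference"
        )
    if len(pred) == 0:
        raise ParameterError("empty label vectors")
    return pred, ref


def confusion_counts(predicted, reference) -> dict[str, ConfusionCounts]:
    """One-vs-rest counts for every label of the reference set."""
    pred, ref = _check_lengths(predicted, reference)
    n = len(ref)
    out = {}
    for label in sorted(set(ref)):
        tp = int(((ref == label) & (pred == label)).sum())
        fp = int(((ref != label) & (pred == label)).sum())
        fn = int(((ref == label) & (pred != label)).sum())
        out[label] = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn)
    return out


def overall_accuracy(predicted, reference) -> float:
    """Percentage of cells whose predicted label equals the reference."""
    pred, ref = _check_lengths(predicted, reference)
    return 100.0 * float((pred == ref).sum()) / len(ref)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def per_label_prf(predicted, reference) -> dict[str, tuple[float, float, float]]:
    """Per reference label: (precision, recall, F1), zero-denominator -> 0."""
    out = {}
    for label, c in confusion_counts(predicted, reference).items():
        precision = _safe_div(c.tp, c.tp + c.fp)
        recall = _safe_div(c.tp, c.tp + c.fn)
        f1 = _safe_div(2 * precision * recall, precision + recall)
        out[label] = (precision, recall, f1)
    return out


def median_f1(per_label: dict[str, tuple[float, float, float]], include_unknown: bool = True) -> float:
    """Median of the per-label F1 scores (even counts: mean of the middle pair)."""
    items = per_label
    if not include_unknown:
        items = {
            k: v for k, v in per_label.items() if k not in (UNKNOWN, UNCLASSIFIED)
        }
    if not items:
        raise ParameterError("no labels to take the median over")
    return float(np.median([f1 for _, _, f1 in items.values()]))


def metrics_report(predicted, reference):
    """Tidy per-label report plus the overall summary row."""
    import pandas as pd

    prf = per_label_prf(predicted, reference)
    rows = [
        {"label": label, "precision": p, "recall": r, "F1": f}
        for label, (p, r, f) in sorted(prf.items())
    ]
    summary = {
        "accuracy_percent": overall_accuracy(predicted, reference),
        "median_F1": median_f1(prf),
        "median_F1_excl_unknown": (
            median_f1(prf, include_unknown=False)
            if any(k not in (UNKNOWN, UNCLASSIFIED) for k in prf)
            else float("nan")
        ),
    }
    return pd.DataFrame(rows), summary
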