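"""Classification metric panel and locus-level aggregation.

The panel reports accuracy, precision, sensitivity (recall), specificity, F1
(harmonic mean of precision and sensitivity) and AUROC from the confusion
matrix; AUROC uses the rank statistic with tie correction (equivalent to the
Mann-Whitney U) and is reported as missing when only one class is present.

Locus-level evaluation aggregates transcript calls to gene loci: by default a
locus is predicted true iff any of its transcripts is predicted true, and its
ground truth is true iff any transcript is labeled true (a majority rule is
available). It should be applied to loci whose transcripts are all putative
lncRNAs, so a locus call is not diluted by non-lncRNA isoforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score

from .errors import ConfigurationError


@dataclass
class MetricPanel:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auroc: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "auroc": self.auroc,
        }

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else math.nan


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricPanel:
    """Metric panel from labels, predictions and (optionally) scores."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ConfigurationError("labels and predictions differ in length")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    f1 = (
        _safe_div(2 * precision * sensitivity, precision + sensitivity)
        if not (math.isnan(precision) or math.isnan(sensitivity))
        else math.nan
    )
    auroc = None
    if scores is not None and len(np.unique(y_true)) == 2:
        auroc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return MetricPanel(
        tp=int(tp),
        fp=int(fp),
        fn=int(fn),
        tn=int(tn),
        accuracy=_safe_div(tp + tn, tp + fp + fn + tn),
        precision=precision,
        sensitivity=sensitivity,
        specificity=_safe_div(tn, tn + fp),
        f1=f1,
        auroc=auroc,
    )


def locus_level_metrics(
    transcript_ids: Sequence[str],
    y_true: Sequence[int],
    y_pred: Sequence[int],
    locus_map: Mapping[str, str],
    rule: str = "any",
) -> MetricPanel:
    """Aggregate transcript-level calls to loci and score the loci.

    ``rule='any'`` (default): a locus is positive when any member transcript
    is; ``rule='majority'``: when more than half are. With all-singleton loci
    either rule reduces to transcript-level metrics.
    """
    if rule not in ("any", "majority"):
        raise ConfigurationError("rule must be 'any' or 'majority'")
    missing = [t for t in transcript_ids if t not in locus_map]
    if missing:
        raise ConfigurationError(
            "transcripts missing from locus map: " + ", ".join(missing[:10])
        )
    per_locus: dict[str, list[tuple[int, int]]] = {}
    for tid, yt, yp in zip(transcript_ids, y_true, y_pred):
        per_locus.setdefault(locus_map[tid], []).append((int(yt), int(yp)))

    def agg(vals: list[int]) -> int:
        if rule == "any":
            return int(any(vals))
        return int(sum(vals) * 2 > len(vals))

    loci = sorted(per_locus)
    lt = [agg([v[0] for v in per_locus[L]]) for L in loci]
    lp = [agg([v[1] for v in per_locus[L]]) for L in loci]
    return compute_metrics(lt, lp)
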