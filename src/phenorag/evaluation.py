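"""Scoring predictions against gold term labels: TP/FP/FN, sensitivity, PPV, F1.

Each test sentence carries exactly one gold HPO term (the term it was
generated for). Two scoring rules apply:

* **top-1** (single prediction per sentence): a correct prediction is a TP; a
  wrong prediction counts as both an FP *and* an FN (the sentence was
  assigned another term and missed its own); an abstention is an FN only.
  Hence TP + FN always equals the number of sentences scored.
* **top-k** (ranked list): gold anywhere in the list is a TP, otherwise an
  FN; every non-gold occurrence in the list counts toward FP. By default
  duplicate wrong labels each count (``multiset``); the ``distinct`` policy
  counts each unique wrong label once.

Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP), F1 = 2·TP/(2·TP+FP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import pandas as pd

from .corpus import SyntheticSentence
from .embeddings import BackendSpec
from .errors import ValidationError
from .fusion import fuse_k1, fuse_topk
from .knowledge_base import KnowledgeBase
from .taggers import PredictionSet, em_predict

FpPolicy = Literal["multiset", "distinct"]
Mode = Literal["em", "pt", "fused"]

#: Per-sentence tagger hook used for the PT side of evaluation:
#: (sentence_text, sentence_key, k) -> PredictionSet.
SentenceTagger = Callable[[str, str, int], PredictionSet]


@dataclass(frozen=True)
class EvalRecord:
    """One scored sentence: its gold term and the model's ranked labels."""

    sentence_key: str
    gold: str
    predicted: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    ppv: float
    f1: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "f1": self.f1,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }


def score_top1(records: Sequence[EvalRecord]) -> ConfusionCounts:
    """Score single-prediction records; wrong predictions count as FP and FN."""
    tp = fp = fn = 0
    for rec in records:
        if len(rec.predicted) > 1:
            raise ValidationError(
                f"record {rec.sentence_key!r} has {len(rec.predicted)} "
                "predictions; use score_topk"
            )
        if not rec.predicted:
            fn += 1
        elif rec.predicted[0] == rec.gold:
            tp += 1
        else:
            fp += 1
            fn += 1
    return ConfusionCounts(tp, fp, fn)


def score_topk(
    records: Sequence[EvalRecord],
    k: int,
    fp_policy: FpPolicy = "multiset",
) -> ConfusionCounts:
    """Score ranked-list records: gold-in-list recall, occurrence-level FP."""
    tp = fp = fn = 0
    for rec in records:
        if len(rec.predicted) > k:
            raise ValidationError(
                f"record {rec.sentence_key!r} has {len(rec.predicted)} "
                f"predictions for k={k}"
            )
        if rec.gold in rec.predicted:
            tp += 1
        else:
            fn += 1
        wrong = [p for p in rec.predicted if p != rec.gold]
        fp += len(set(wrong)) if fp_policy == "distinct" else len(wrong)
    return ConfusionCounts(tp, fp, fn)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, PPV, and F1 from a confusion tally.

    PPV is defined as 0 when nothing was predicted (TP+FP = 0); F1 is 0 when
    TP = 0. Requires at least one gold-bearing record (TP+FN > 0).
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fn == 0:
        raise ValidationError("no gold-bearing records (tp + fn == 0)")
    sensitivity = tp / (tp + fn)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) > 0 else 0.0
    return MetricsReport(sensitivity=sensitivity, ppv=ppv, f1=f1, counts=counts)


def evaluate_pipeline(
    test_sentences: Sequence[SyntheticSentence],
    kb: KnowledgeBase | None,
    backend_spec: BackendSpec | None,
    tagger: SentenceTagger | None,
    mode: Mode,
    k: int = 1,
    fp_policy: FpPolicy = "multiset",
    audit_path: str | Path | None = None,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Run one prediction path over held-out sentences and score it.

    ``mode="em"`` retrieves from ``kb``; ``mode="pt"`` calls ``tagger``;
    ``mode="fused"`` runs both and fuses (PT precedence at k=1, pooled
    majority vote otherwise — fused output is a single label, scored top-1).
    Returns the metrics plus a per-sentence audit table; the table is also
    written as TSV when ``audit_path`` is given.
    """
    needs_em = mode in ("em", "fused")
    needs_pt = mode in ("pt", "fused")
    if needs_em and (kb is None or backend_spec is None):
        raise ValidationError(f"mode={mode!r} requires a knowledge base and backend")
    if needs_pt and tagger is None:
        raise ValidationError(f"mode={mode!r} requires a tagger")

    rows = []
    records = []
    for s in test_sentences:
        key = f"{s.term_id}:{s.index}"
        em_set = (
            em_predict(s.text, kb, backend_spec, k, sentence_key=key)
            if needs_em
            else None
        )
        pt_set = tagger(s.text, key, k) if needs_pt else None
        fused_label = None
        if mode == "em":
            predicted = em_set.labels
        elif mode == "pt":
            predicted = pt_set.labels
        else:
            result = fuse_k1(pt_set, em_set) if k == 1 else fuse_topk(pt_set, em_set, k)
            fused_label = result.fused_label
            predicted = (fused_label,) if fused_label else ()
        records.append(EvalRecord(sentence_key=key, gold=s.term_id, predicted=predicted))
        if mode == "fused" or k == 1:
            top = predicted[0] if predicted else None
            outcome = "tp" if top == s.term_id else ("fn" if top is None else "fp+fn")
        else:
            outcome = "tp" if s.term_id in predicted else "fn"
        rows.append(
            {
                "sentence_key": key,
                "gold": s.term_id,
                "em_labels": ",".join(em_set.labels) if em_set else "",
                "pt_labels": ",".join(pt_set.labels) if pt_set else "",
                "fused_label": fused_label or "",
                "predicted": ",".join(predicted),
                "outcome": outcome,
            }
        )

    if mode == "fused" or k == 1:
        counts = score_top1(records)
    else:
        counts = score_topk(records, k, fp_policy)
    audit = pd.DataFrame(rows)
    if audit_path is not None:
        audit.to_csv(audit_path, sep="\t", index=False)
    return compute_metrics(counts), audit
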