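"""Late decision fusion of two ranked prediction sets (the Fused Model).

The external tagger (PT) and the embedding-retrieval model (EM) each emit an
ordered multiset of up to k term ids per sentence. Fusion pools the two
multisets and takes the label with the highest combined vote count.

At k = 1 there is nothing to count, so the rule degenerates to precedence:
agreement wins outright, disagreement defers to PT, and an empty side falls
through to the other. At k ≥ 2 ties in the pooled count are broken by best
(lowest) rank in PT, then best rank in EM, then ascending term id — a total,
deterministic order that generalizes the k = 1 PT-precedence rule. All votes
weigh 1; similarity scores do not enter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal

from .errors import ValidationError
from .taggers import PredictionSet

Rule = Literal[
    "unanimous_k1", "pt_precedence_k1", "majority_k5", "tie_break_k5",
    "no_prediction",
]


@dataclass(frozen=True)
class FusionResult:
    """Outcome of fusing one sentence's PT and EM predictions."""

    sentence_key: str
    fused_label: str | None
    pooled_counts: dict[str, int] = field(default_factory=dict)
    rule_applied: Rule = "no_prediction"


def _pool(pt: PredictionSet, em: PredictionSet) -> dict[str, int]:
    return dict(Counter(pt.labels) + Counter(em.labels))


def fuse_k1(pt: PredictionSet, em: PredictionSet) -> FusionResult:
    """Fuse two single-label predictions with PT precedence.

    Both agree → that label; both present but different → PT's label; one
    side empty → the other's label; both empty → no prediction.
    """
    if pt.k != 1 or em.k != 1:
        raise ValidationError(
            f"fuse_k1 requires k=1 on both inputs (got pt.k={pt.k}, em.k={em.k})"
        )
    counts = _pool(pt, em)
    key = pt.sentence_key or em.sentence_key
    if not pt.labels and not em.labels:
        return FusionResult(key, None, counts, "no_prediction")
    if not pt.labels:
        return FusionResult(key, em.labels[0], counts, "pt_precedence_k1")
    if not em.labels:
        return FusionResult(key, pt.labels[0], counts, "pt_precedence_k1")
    if pt.labels[0] == em.labels[0]:
        return FusionResult(key, pt.labels[0], counts, "unanimous_k1")
    return FusionResult(key, pt.labels[0], counts, "pt_precedence_k1")


def fuse_topk(pt: PredictionSet, em: PredictionSet, k: int) -> FusionResult:
    """Majority vote over the pooled top-k multisets of both models.

    The fused label is the one with the maximal pooled count; ties are broken
    by best rank in PT, then best rank in EM, then ascending term id.
    """
    if k < 2:
        raise ValidationError("fuse_topk requires k >= 2; use fuse_k1 for k=1")
    if pt.k != k or em.k != k:
        raise ValidationError(
            f"mismatched k: expected {k}, got pt.k={pt.k}, em.k={em.k}"
        )
    counts = _pool(pt, em)
    key = pt.sentence_key or em.sentence_key
    if not counts:
        return FusionResult(key, None, counts, "no_prediction")

    def best_rank(label: str, labels: tuple[str, ...]) -> int:
        return labels.index(label) if label in labels else len(labels) + k

    ordered = sorted(
        counts,
        key=lambda lab: (
            -counts[lab],
            best_rank(lab, pt.labels),
            best_rank(lab, em.labels),
            lab,
        ),
    )
    winner = ordered[0]
    tie = len(ordered) > 1 and counts[ordered[1]] == counts[winner]
    return FusionResult(
        key, winner, counts, "tie_break_k5" if tie else "majority_k5"
    )
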