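"""Subject-wise leave-one-out cross-validation of the threshold tree.

The unit left out is the *subject*, never the hemisphere or the single
measurement: all of one subject's feature vectors (both hemispheres) form the
test fold while the tree thresholds are tuned on the remaining subjects.
Per-subject error E_i is the percentage of that subject's vectors that the
tuned tree misclassifies, and the overall error is the unweighted mean

    E = (1 / N) * sum_i E_i

over the N subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .errors import TuningError, ValidationError
from .features import FeatureVector
from .tree import TreeSpec, classify, tune_thresholds

__all__ = ["SubjectResult", "LoocvReport", "subject_error", "aggregate_errors", "loocv"]

logger = logging.getLogger(__name__)


def subject_error(predicted: Sequence[str], actual: Sequence[str]) -> float:
    """Percentage of misclassified records: 100 * mismatches / n."""
    if len(predicted) == 0 or len(predicted) != len(actual):
        raise ValidationError(
            f"need equal non-empty label lists, got {len(predicted)} vs {len(actual)}"
        )
    wrong = sum(p != a for p, a in zip(predicted, actual))
    return 100.0 * wrong / len(predicted)


def aggregate_errors(per_subject: Sequence[float]) -> float:
    """Overall error E: the arithmetic mean of the per-subject errors."""
    if len(per_subject) == 0:
        raise ValidationError("cannot aggregate an empty error list")
    return float(sum(per_subject)) / len(per_subject)


@dataclass(frozen=True)
class SubjectResult:
    """One cross-validation fold: the held-out subject and its error."""

    subject_id: str
    error_percent: Optional[float]  # None when the fold was invalid
    n_vectors: int
    tuned_thresholds: Optional[tuple] = None
    valid: bool = True
    note: str = ""


@dataclass(frozen=True)
class LoocvReport:
    """Cross-validation summary: per-subject errors and their mean."""

    per_subject: List[SubjectResult]
    overall_error_percent: float
    n_subjects: int  # iterations performed (valid + invalid)

    @property
    def per_subject_errors(self) -> List[tuple]:
        return [
            (r.subject_id, r.error_percent) for r in self.per_subject if r.valid
        ]


def loocv(vectors: Sequence[FeatureVector], skeleton: TreeSpec) -> LoocvReport:
    """Leave-one-subject-out cross-validation over labelled feature vectors.

    For each subject, thresholds are tuned on every other subject's vectors
    and the held-out subject's vectors are classified with the tuned tree.
    A fold whose training set degenerates to a single class is marked
    invalid, logged, and excluded from the overall mean (but still counted
    as an iteration).  Deterministic for fixed inputs; subject order does
    not affect the overall error.
    """
    by_subject: Dict[str, List[FeatureVector]] = {}
    for v in vectors:
        if v.subject_id is None or v.label is None:
            raise ValidationError("every vector needs subject_id and label")
        by_subject.setdefault(v.subject_id, []).append(v)
    if len(by_subject) < 2:
        raise ValidationError("leave-one-out needs at least 2 subjects")

    results: List[SubjectResult] = []
    for sid in sorted(by_subject):
        test = by_subject[sid]
        train = [v for s, vs in by_subject.items() if s != sid for v in vs]
        assert all(v.subject_id != sid for v in train)
        try:
            tuned = tune_thresholds(train, skeleton)
        except TuningError as exc:
            logger.warning("fold %s invalid: %s", sid, exc)
            results.append(
                SubjectResult(
                    subject_id=sid,
                    error_percent=None,
                    n_vectors=len(test),
                    valid=False,
                    note=str(exc),
                )
            )
            continue
        predicted = [classify(v, tuned).predicted_label for v in test]
        actual = [v.label for v in test]
        e_i = subject_error(predicted, actual)
        results.append(
            SubjectResult(
                subject_id=sid,
                error_percent=e_i,
                n_vectors=len(test),
                tuned_thresholds=tuple(n.threshold for n in tuned.nodes),
            )
        )

    valid_errors = [r.error_percent for r in results if r.valid]
    if not valid_errors:
        raise ValidationError("no valid cross-validation fold")
    return LoocvReport(
        per_subject=results,
        overall_error_percent=aggregate_errors(valid_errors),
        n_subjects=len(results),
    )
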