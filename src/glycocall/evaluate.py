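"""Caller evaluation against simulated truth, threshold sweeps, reports.

A called protein is a true positive iff it is flagged a candidate and
its latent class is glycoprotein; nonspecific binders and non-binders
that get called are false positives.  Proteins that were never evaluable
(unpaired between scans, or all replicates flagged) are excluded from
the confusion matrix and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyInputError, JoinError, ParameterError
from .microarray_io import ArrayScan
from .scoring import (
    CallThresholds,
    CompetitionResult,
    PairScores,
    call_candidates,
    protein_snr,
    round_half_up,
    score_pair,
)
from .simulate import GroundTruth, ProteinClass

__all__ = [
    "CallEvaluation",
    "CategorySummary",
    "evaluate_calls",
    "threshold_sweep",
    "category_summary",
    "write_report",
]

#: Bucket for candidates absent from the annotation map.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True, slots=True)
class CallEvaluation:
    """Confusion matrix of one thresholded call set against truth.

    ``precision`` is ``None`` (undefined) when no calls were made.
    """

    n_true_positive: int
    n_false_positive: int
    n_false_negative: int
    n_true_negative: int
    precision: float | None
    recall: float
    thresholds: CallThresholds

    @property
    def n_evaluated(self) -> int:
        return (
            self.n_true_positive
            + self.n_false_positive
            + self.n_false_negative
            + self.n_true_negative
        )


@dataclass(frozen=True)
class CategorySummary:
    """Per-category counts and per-assignment proportions.

    Multi-label annotations contribute one assignment per label, so
    counts may exceed the number of candidates while proportions (over
    assignments) still sum to 1.
    """

    categories: Mapping[str, tuple[int, float]]

    def count(self, category: str) -> int:
        return self.categories[category][0]

    def proportion(self, category: str) -> float:
        return self.categories[category][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.categories),
                "count": [c for c, _ in self.categories.values()],
                "proportion": [p for _, p in self.categories.values()],
            }
        )


def evaluate_calls(
    results: Sequence[CompetitionResult],
    truth: GroundTruth,
    thresholds: CallThresholds = CallThresholds(),
) -> CallEvaluation:
    """Confusion matrix of a scored result set against the latent truth.

    Every result's protein must exist in ``truth`` (unknown identifiers
    raise :class:`JoinError`); only scored proteins are counted.
    """
    tp = fp = fn = tn = 0
    for r in results:
        if r.protein_id not in truth:
            raise JoinError(f"protein {r.protein_id!r} absent from ground truth")
        is_glyco = truth[r.protein_id].protein_class is ProteinClass.GLYCOPROTEIN
        if r.is_candidate:
            if is_glyco:
                tp += 1
            else:
                fp += 1
        else:
            if is_glyco:
                fn += 1
            else:
                tn += 1
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return CallEvaluation(
        n_true_positive=tp,
        n_false_positive=fp,
        n_false_negative=fn,
        n_true_negative=tn,
        precision=precision,
        recall=recall,
        thresholds=thresholds,
    )


def threshold_sweep(
    minus: ArrayScan,
    plus: ArrayScan,
    truth: GroundTruth,
    grid: Sequence[CallThresholds],
) -> list[CallEvaluation]:
    """Evaluate the caller over a grid of threshold pairs.

    SNRs are computed once; only the (cheap) thresholding is repeated
    per grid point, so a dense grid costs one scoring pass.
    """
    if not grid:
        raise ParameterError("threshold grid must be non-empty")
    snr_minus = protein_snr(minus).as_dict()
    snr_plus = protein_snr(plus).as_dict()
    shared = sorted(snr_minus.keys() & snr_plus.keys())
    triples = [(pid, snr_minus[pid].snr, snr_plus[pid].snr) for pid in shared]
    evaluations = []
    for thresholds in grid:
        results = call_candidates(triples, thresholds)
        evaluations.append(evaluate_calls(results, truth, thresholds))
    return evaluations


def category_summary(
    candidates: Iterable[str],
    annotation_map: Mapping[str, Sequence[str]],
) -> CategorySummary:
    """Summarize candidate annotations into category counts/proportions.

    ``annotation_map`` may be partial; candidates without labels count
    under ``unclassified``.  Proportions are per-assignment: a candidate
    with two labels contributes two assignments of weight 1 each.
    """
    candidates = list(candidates)
    if not candidates:
        raise EmptyInputError("no candidates to summarize")
    counts: dict[str, int] = {}
    total = 0
    for pid in candidates:
        labels = list(annotation_map.get(pid, ())) or [UNCLASSIFIED]
        for label in labels:
            counts[label] = counts.get(label, 0) + 1
            total += 1
    categories = {
        label: (count, count / total) for label, count in sorted(counts.items())
    }
    return CategorySummary(categories=categories)


def _format_score(score: float | None) -> str:
    return "NA" if score is None else f"{round_half_up(score):.2f}"


def write_report(
    results: Sequence[CompetitionResult] | PairScores,
    path: str | Path,
    evaluation: CallEvaluation | None = None,
) -> None:
    """Write a candidate report TSV in the published table's column order.

    Columns: rank, protein_id, snr_minus, snr_plus, calling_score,
    is_candidate, flags, annotation.  Values are rounded half-up to two
    decimals for display only.  Output is deterministic; an optional
    evaluation block is appended as comment lines.
    """
    rows = list(results)
    lines = [
        "\t".join(
            (
                "rank",
                "protein_id",
                "snr_minus",
                "snr_plus",
                "calling_score",
                "is_candidate",
                "flags",
                "annotation",
            )
        )
    ]
    for rank, r in enumerate(rows, start=1):
        lines.append(
            "\t".join(
                (
                    str(rank),
                    r.protein_id,
                    f"{round_half_up(r.snr_minus):.2f}",
                    f"{round_half_up(r.snr_plus):.2f}",
                    _format_score(r.calling_score),
                    str(r.is_candidate),
                    ",".join(r.flags),
                    r.annotation or "",
                )
            )
        )
    if evaluation is not None:
        prec = "NA" if evaluation.precision is None else f"{evaluation.precision:.4f}"
        lines += [
            f"# thresholds: snr_minus_min={evaluation.thresholds.snr_minus_min} "
            f"calling_score_min={evaluation.thresholds.calling_score_min}",
            f"# TP={evaluation.n_true_positive} FP={evaluation.n_false_positive} "
            f"FN={evaluation.n_false_negative} TN={evaluation.n_true_negative}",
            f"# precision={prec} recall={evaluation.recall:.4f}",
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
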