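"""Proximal-credit accuracy, replicate summaries, and fiber ranking.

The accuracy statistic grants half credit to proximal predictions:

    accuracy = (n_correct + 0.5 * n_similar) / n_total

where ``n_similar`` counts mispredictions whose layer difference from the
truth equals the study's minimal inter-class difference. Replicate networks
with very low accuracy (below chance by default) are excluded from the
mean +/- stddev summary, with the exclusion logged. Fiber specs (5 singles,
10 pairs) are ranked by mean accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .constructs import StudyDesign, is_proximal
from .cnn import TrainedReplicate, fiber_spec_name


@dataclass
class EvaluationResult:
    """Eq.-style accuracy decomposition plus the raw confusion matrix."""

    n_correct: int
    n_similar: int
    n_total: int
    accuracy: float
    confusion: pd.DataFrame  # rows = truth, columns = prediction, raw counts


def classification_accuracy(
    predictions: Sequence[str],
    truths: Sequence[str],
    design: StudyDesign,
) -> EvaluationResult:
    """Proximal-credit accuracy of a prediction list against the truths.

    The confusion matrix counts raw argmax predictions; proximal credit
    enters only the scalar accuracy.
    """
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("predictions and truths must be equal-length, non-empty")
    confusion = pd.DataFrame(
        0, index=list(design.classes), columns=list(design.classes), dtype=int
    )
    n_correct = n_similar = 0
    for pred, truth in zip(predictions, truths):
        if pred == truth:
            n_correct += 1
        elif is_proximal(pred, truth, design):  # also validates membership
            n_similar += 1
        confusion.loc[truth, pred] += 1
    n_total = len(predictions)
    return EvaluationResult(
        n_correct=n_correct,
        n_similar=n_similar,
        n_total=n_total,
        accuracy=(n_correct + 0.5 * n_similar) / n_total,
        confusion=confusion,
    )


@dataclass
class ReplicateSummary:
    """Mean +/- sample stddev of surviving replicate accuracies."""

    mean_accuracy: float
    stddev_accuracy: float
    replicate_accuracies: List[float]
    excluded: List[dict]  # {replicate, accuracy, reason}
    single_replicate: bool = False

    @property
    def n_used(self) -> int:
        return len(self.replicate_accuracies) - len(self.excluded)


def summarize_replicates(
    replicate_results: Sequence[EvaluationResult],
    exclusion_threshold: Optional[float] = None,
    n_classes: Optional[int] = None,
) -> ReplicateSummary:
    """Summarize replicate accuracies, excluding very-low-accuracy networks.

    The default exclusion threshold is chance level ``1 / n_classes``
    (replicates strictly below it are dropped, each with a logged reason).
    Raises if every replicate is excluded. A single surviving replicate gets
    stddev 0 with the ``single_replicate`` flag set.
    """
    if len(replicate_results) == 0:
        raise ValueError("need at least one replicate result")
    if exclusion_threshold is None:
        if n_classes is None:
            raise ValueError("provide exclusion_threshold or n_classes for the default")
        exclusion_threshold = 1.0 / n_classes
    accs = [r.accuracy for r in replicate_results]
    excluded = [
        {
            "replicate": i,
            "accuracy": a,
            "reason": f"accuracy {a:.4f} below exclusion threshold {exclusion_threshold:.4f}",
        }
        for i, a in enumerate(accs)
        if a < exclusion_threshold
    ]
    survivors = [a for a in accs if a >= exclusion_threshold]
    if not survivors:
        raise ValueError("all replicates fell below the exclusion threshold")
    single = len(survivors) == 1
    return ReplicateSummary(
        mean_accuracy=float(np.mean(survivors)),
        stddev_accuracy=0.0 if single else float(np.std(survivors, ddof=1)),
        replicate_accuracies=accs,
        excluded=excluded,
        single_replicate=single,
    )


def evaluate_replicates(
    replicates: Sequence[TrainedReplicate],
    design: StudyDesign,
    exclusion_threshold: Optional[float] = None,
) -> tuple:
    """Per-replicate accuracy + pooled confusion for trained replicates.

    Returns ``(results, summary, pooled_confusion)``; the pooled confusion
    matrix aggregates the raw test predictions of all replicates.
    """
    results = [
        classification_accuracy(
            rep.test_predictions["prediction"], rep.test_predictions["truth"], design
        )
        for rep in replicates
    ]
    summary = summarize_replicates(results, exclusion_threshold, design.n_classes)
    pooled = results[0].confusion.copy()
    for r in results[1:]:
        pooled += r.confusion
    return results, summary, pooled


@dataclass
class FiberRanking:
    """Fiber specs sorted by mean accuracy (ties: lower stddev, then name)."""

    table: pd.DataFrame  # columns: fiber_spec, n_fibers, mean_accuracy, stddev_accuracy
    pair_minus_single_gap: Optional[float]

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["fiber_spec"])


def rank_fiber_combinations(summaries: Dict[str, ReplicateSummary]) -> FiberRanking:
    """Rank fiber specs by mean accuracy and report the pair-vs-single gap.

    ``summaries`` maps fiber spec names ('R4' or 'R1R5') to their replicate
    summaries. The gap is mean over pair specs minus mean over single specs
    of the mean accuracies (None when either side is absent).
    """
    if not summaries:
        raise ValueError("need at least one fiber-spec summary")
    rows = []
    for spec, summ in summaries.items():
        name = fiber_spec_name(spec)
        rows.append(
            {
                "fiber_spec": name,
                "n_fibers": 2 if len(name) == 4 else 1,
                "mean_accuracy": summ.mean_accuracy,
                "stddev_accuracy": summ.stddev_accuracy,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        by=["mean_accuracy", "stddev_accuracy", "fiber_spec"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    singles = table.loc[table["n_fibers"] == 1, "mean_accuracy"]
    pairs = table.loc[table["n_fibers"] == 2, "mean_accuracy"]
    gap = float(pairs.mean() - singles.mean()) if len(singles) and len(pairs) else None
    return FiberRanking(table=table, pair_minus_single_gap=gap)
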