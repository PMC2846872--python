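"""Majority-rule consensus over per-partition best feature subsets.

Each resampled partition yields one best subset from its elimination run.
A feature's vote count is the number of partitions whose best subset contains
it; features chosen by at least half the classifiers (inclusive) form the
majority list.  The final consensus subset is then picked from the nested
prefixes of the count-ranked list: for each prefix, one classifier per
partition is retrained on exactly those features and the test accuracies are
averaged; the smallest prefix attaining the maximal mean accuracy wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PANEL
from .resampling import PartitionPlan
from .simulate import Cohort
from .svm_rfe import KernelConfig, RFEResult, evaluate_subset

__all__ = [
    "VoteTally",
    "ComboCurve",
    "tally_votes",
    "majority_features",
    "combo_accuracy_curve",
    "select_final_subset",
    "subset_mean_accuracy",
]


@dataclass
class VoteTally:
    """Per-feature membership counts across R best subsets."""

    counts: dict[int, int]
    total_partitions: int

    def ranked_features(self) -> list[int]:
        """Panel indices by descending count, ties by ascending index.

        Features with zero votes are excluded.
        """
        voted = [i for i, c in self.counts.items() if c > 0]
        return sorted(voted, key=lambda i: (-self.counts[i], i))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": r + 1,
                "index": i,
                "name": PANEL.name_of(i),
                "count": self.counts[i],
                "count_pct": 100.0 * self.counts[i] / self.total_partitions,
            }
            for r, i in enumerate(self.ranked_features())
        ]
        return pd.DataFrame(
            rows, columns=["rank", "index", "name", "count", "count_pct"]
        )


def tally_votes(results: list[RFEResult]) -> VoteTally:
    """Count, for every panel feature, the partitions whose best subset
    contains it."""
    if not results:
        raise ValueError("no elimination results to tally")
    counts = {i: 0 for i in PANEL.indices}
    for res in results:
        for i in res.best_subset:
            counts[i] += 1
    return VoteTally(counts=counts, total_partitions=len(results))


def majority_features(tally: VoteTally, threshold: float = 0.5) -> list[int]:
    """Features present in at least ``threshold`` of the best subsets.

    The cut is inclusive: with R = 300 and threshold 0.5, a count of exactly
    150 qualifies.  Returned in count-rank order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    cut = threshold * tally.total_partitions
    return [i for i in tally.ranked_features() if tally.counts[i] >= cut]


@dataclass
class ComboCurve:
    """Mean test accuracy (percent) of nested prefixes of a ranked list."""

    features: list[int]                 # ranked features; prefix k = first k
    mean_accuracy_pct: list[float]      # one value per prefix

    def __len__(self) -> int:
        return len(self.features)

    def prefix(self, k: int) -> tuple[int, ...]:
        if not 1 <= k <= len(self.features):
            raise ValueError("prefix length out of range")
        return tuple(self.features[:k])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": k + 1,
                "index": i,
                "name": PANEL.name_of(i),
                "combination": "+".join(str(j) for j in self.features[: k + 1]),
                "mean_accuracy_pct": self.mean_accuracy_pct[k],
            }
            for k, i in enumerate(self.features)
        ]
        return pd.DataFrame(rows)


def subset_mean_accuracy(features, plan: PartitionPlan, cohort: Cohort,
                         config: KernelConfig = KernelConfig()) -> float:
    """Mean test accuracy (percent) over all partitions of classifiers
    restricted to ``features``."""
    accs = [
        evaluate_subset(p, cohort, features, config).P for p in plan
    ]
    return 100.0 * float(np.mean(accs))


def combo_accuracy_curve(ordered_features, plan: PartitionPlan,
                         cohort: Cohort,
                         config: KernelConfig = KernelConfig()) -> ComboCurve:
    """Retrain per partition on each nested prefix of ``ordered_features``
    and average test accuracy.

    Training failures propagate with the offending prefix attached.
    """
    features = [PANEL.resolve(f) for f in ordered_features]
    if not features:
        raise ValueError("ordered_features must be non-empty")
    means = []
    for k in range(1, len(features) + 1):
        prefix = features[:k]
        try:
            means.append(subset_mean_accuracy(prefix, plan, cohort, config))
        except Exception as exc:
            raise RuntimeError(
                f"combination accuracy failed on prefix "
                f"{[PANEL.name_of(i) for i in prefix]}: {exc}"
            ) from exc
    return ComboCurve(features=features, mean_accuracy_pct=means)


def select_final_subset(curve: ComboCurve) -> tuple[int, ...]:
    """Smallest prefix of the curve achieving the maximal mean accuracy."""
    if len(curve) == 0:
        raise ValueError("empty accuracy curve")
    best_k = int(np.argmax(curve.mean_accuracy_pct)) + 1  # argmax -> first max
    return curve.prefix(best_k)
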