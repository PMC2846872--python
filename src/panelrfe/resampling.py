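"""Repeated random train/test partitions at seven train:test mixing ratios.

The study design trains one classifier per random holdout partition and lets
the ensemble vote.  Partitions are drawn at seven train:test ratios (1:1
through 4:1) with the total count spread across ratios as evenly as possible.
By default rows (sample vectors) are assigned to train/test independently, so
a subject's pre and post rows may land on opposite sides of the split — this
is the study-faithful mode; ``by_subject=True`` keeps each subject's pair
together for leakage sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .simulate import Cohort

__all__ = [
    "DEFAULT_RATIOS",
    "Partition",
    "PartitionPlan",
    "make_partitions",
    "check_no_conflicts",
]

DEFAULT_RATIOS: tuple[str, ...] = (
    "1:1", "1.5:1", "2:1", "2.5:1", "3:1", "3.5:1", "4:1",
)


def _ratio_value(tag: str) -> float:
    train, _, test = tag.partition(":")
    return float(Fraction(train) / Fraction(test or "1"))


@dataclass(frozen=True)
class Partition:
    """One train/test split of cohort row indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio_tag: str

    def __post_init__(self):
        train = set(self.train_indices.tolist())
        test = set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


@dataclass
class PartitionPlan:
    """Ordered list of partitions plus the seed they were drawn from."""

    partitions: list[Partition]
    seed: int
    stratified: bool = True
    by_subject: bool = False
    ratio_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    def to_frame(self) -> pd.DataFrame:
        """Plain index-list serialisation: one record per partition."""
        return pd.DataFrame(
            {
                "ratio_tag": [p.ratio_tag for p in self.partitions],
                "train_indices": [
                    " ".join(map(str, p.train_indices)) for p in self.partitions
                ],
                "test_indices": [
                    " ".join(map(str, p.test_indices)) for p in self.partitions
                ],
            }
        )


def allocate_counts(ratios, total_count: int) -> dict[str, int]:
    """Spread ``total_count`` partitions over ratios as evenly as possible.

    The remainder goes to the smallest ratios: 300 over the seven default
    ratios gives 43 each for 1:1 .. 3.5:1 and 42 for 4:1.
    """
    ratios = list(ratios)
    if total_count < len(ratios):
        raise ValueError("total_count must be >= number of ratios")
    order = sorted(ratios, key=_ratio_value)
    base, rem = divmod(total_count, len(ratios))
    counts = {tag: base for tag in ratios}
    for tag in order[:rem]:
        counts[tag] += 1
    return counts


def _split_sizes(n: int, ratio: float) -> tuple[int, int]:
    n_train = int(round(n * ratio / (1.0 + ratio)))
    return n_train, n - n_train


def make_partitions(
    cohort: Cohort,
    ratios=DEFAULT_RATIOS,
    total_count: int = 300,
    seed: int = 0,
    stratified: bool = True,
    by_subject: bool = False,
) -> PartitionPlan:
    """Draw ``total_count`` independent random holdout partitions.

    Parameters
    ----------
    cohort
        Cohort to split; both labels must be present.
    ratios
        Train:test ratio tags, e.g. ``"2:1"``.
    stratified
        Keep the +1/-1 proportion of the training set within one sample of
        the cohort's (default).  Set False for fully unconstrained sampling.
    by_subject
        Assign whole subjects (pre+post pair together) instead of rows.
    """
    y = cohort.y
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both pre and post samples")
    counts = allocate_counts(ratios, total_count)
    n = len(cohort)
    for tag in ratios:
        if by_subject:
            units = len(np.unique(cohort.subject_ids))
        else:
            units = n
        n_train, n_test = _split_sizes(units, _ratio_value(tag))
        if n_test < 1:
            raise ValueError(f"ratio {tag} produces an empty test set")
        if n_train < 1:
            raise ValueError(f"ratio {tag} produces an empty training set")

    rng = np.random.default_rng(seed)
    partitions: list[Partition] = []
    for tag in ratios:
        ratio = _ratio_value(tag)
        for _ in range(counts[tag]):
            if by_subject:
                partitions.append(_draw_subject_split(cohort, ratio, tag, rng))
            elif stratified:
                partitions.append(_draw_stratified(y, ratio, tag, rng))
            else:
                partitions.append(_draw_plain(n, ratio, tag, rng))
    return PartitionPlan(
        partitions=partitions,
        seed=seed,
        stratified=stratified,
        by_subject=by_subject,
        ratio_counts=counts,
    )


def _draw_plain(n: int, ratio: float, tag: str, rng) -> Partition:
    n_train, _ = _split_sizes(n, ratio)
    perm = rng.permutation(n)
    return Partition(np.sort(perm[:n_train]), np.sort(perm[n_train:]), tag)


def _draw_stratified(y: np.ndarray, ratio: float, tag: str, rng) -> Partition:
    n = len(y)
    n_train, _ = _split_sizes(n, ratio)
    train_parts, test_parts = [], []
    # largest-remainder apportionment of the train budget across classes
    classes = np.unique(y)
    exact = {c: n_train * np.sum(y == c) / n for c in classes}
    take = {c: int(np.floor(exact[c])) for c in classes}
    short = n_train - sum(take.values())
    for c in sorted(classes, key=lambda c: exact[c] - take[c], reverse=True):
        if short <= 0:
            break
        take[c] += 1
        short -= 1
    for c in classes:
        idx = np.flatnonzero(y == c)
        perm = rng.permutation(idx)
        train_parts.append(perm[: take[c]])
        test_parts.append(perm[take[c]:])
    return Partition(
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
        tag,
    )


def _draw_subject_split(cohort: Cohort, ratio: float, tag: str, rng) -> Partition:
    subjects = np.unique(cohort.subject_ids)
    n_train, _ = _split_sizes(len(subjects), ratio)
    perm = rng.permutation(subjects)
    train_sub = set(perm[:n_train].tolist())
    mask = np.array([s in train_sub for s in cohort.subject_ids])
    return Partition(np.flatnonzero(mask), np.flatnonzero(~mask), tag)


def check_no_conflicts(cohort: Cohort) -> pd.DataFrame:
    """Report pairs of identical 41-vectors carrying different labels.

    Identical vectors with opposite labels are irreducible noise for any
    classifier; a freshly simulated continuous cohort reports none.

    Returns
    -------
    DataFrame
        One row per conflicting pair of cohort rows (``row_a``, ``row_b``);
        empty on clean data.
    """
    X = cohort.X
    y = cohort.y
    order = np.lexsort(X.T[::-1])
    conflicts = []
    i = 0
    while i < len(order):
        j = i + 1
        while j < len(order) and np.array_equal(X[order[i]], X[order[j]]):
            j += 1
        group = order[i:j]
        if len(group) > 1 and len(np.unique(y[group])) > 1:
            pos = [int(r) for r in group if y[r] == 1]
            neg = [int(r) for r in group if y[r] == -1]
            for a in pos:
                for b in neg:
                    conflicts.append({"row_a": a, "row_b": b})
        i = j
    return pd.DataFrame(conflicts, columns=["row_a", "row_b"])
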