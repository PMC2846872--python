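"""Per-analyte distribution specs and bundled reference tables.

The original paired cohort (170 seamen sampled before and after a three-month
ocean voyage) is not publicly deposited; what is public are per-analyte
summary statistics: mean +/- SD before and after the voyage for 29 analytes
that moved under a paired t-test screen, with the 9 consensus analytes
re-tabulated (the re-tabulated values take precedence where the two listings
disagree).  ``load_reference_spec`` turns those printed numbers into a
:class:`CohortSpec` that the simulator consumes.  The 12 analytes absent from
both listings carry invented, clinically plausible means/SDs with *no*
pre/post shift (``null_default`` provenance) — only their null behaviour
matters to the analysis, never their location.

Also bundled, as plain-text package data, are the published consensus vote
table (counts out of 300 classifiers plus nested mean accuracies) and the
published t-test screen (29 rows with raw p-values).  These are *reference*
rankings for comparison utilities, not recomputation targets: the paired
per-subject SDs behind the printed p-values were never published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .panel import PANEL, FeaturePanel

__all__ = [
    "MeasureSpec",
    "CohortSpec",
    "load_reference_spec",
    "reference_consensus_table",
    "reference_ttest_table",
    "reference_consensus_ranking",
    "reference_ttest_ranking",
]

PROVENANCES = ("table4", "table5", "null_default")


@dataclass(frozen=True)
class MeasureSpec:
    """Gaussian pre/post marginals for one panel analyte.

    ``suspect`` flags entries whose printed source values look like a
    typesetting error (the TBA row duplicates FRUC's numbers verbatim); the
    values are shipped as printed.
    """

    feature_index: int
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    provenance: str = "null_default"
    suspect: bool = False

    def __post_init__(self):
        if self.pre_sd <= 0 or self.post_sd <= 0:
            raise ValueError(
                f"feature {self.feature_index}: SDs must be strictly positive"
            )
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "null_default" and (
            self.pre_mean != self.post_mean or self.pre_sd != self.post_sd
        ):
            raise ValueError(
                f"feature {self.feature_index}: null_default entries must have "
                "identical pre and post parameters"
            )

    @property
    def name(self) -> str:
        return PANEL.name_of(self.feature_index)


@dataclass
class CohortSpec:
    """Full simulator configuration: 41 measure specs plus cohort shape.

    Parameters
    ----------
    measures
        One :class:`MeasureSpec` per panel index 1..41.
    n_subjects
        Number of paired subjects (each contributes a pre and a post row).
    within_subject_corr
        Correlation rho in [0, 1) between a subject's pre and post value of
        the same analyte (bivariate-normal construction).
    seed
        Seed for the generator; identical spec + seed reproduces the cohort
        bit for bit.
    """

    measures: dict[int, MeasureSpec]
    n_subjects: int = 170
    within_subject_corr: float = 0.5
    seed: int = 0
    panel: FeaturePanel = field(default_factory=lambda: PANEL, repr=False)

    def __post_init__(self):
        want = set(self.panel.indices)
        got = set(self.measures)
        if got != want:
            missing = sorted(want - got)
            extra = sorted(got - want)
            raise ValueError(
                f"need one MeasureSpec per panel index; missing {missing}, "
                f"unexpected {extra}"
            )
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.within_subject_corr < 1.0:
            raise ValueError("within_subject_corr must lie in [0, 1)")

    def measure(self, key) -> MeasureSpec:
        """Look up a MeasureSpec by panel index or analyte name."""
        return self.measures[self.panel.resolve(key)]

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-analyte parameter table (round-trips via CSV)."""
        rows = [
            {
                "index": m.feature_index,
                "name": m.name,
                "pre_mean": m.pre_mean,
                "pre_sd": m.pre_sd,
                "post_mean": m.post_mean,
                "post_sd": m.post_sd,
                "provenance": m.provenance,
            }
            for m in (self.measures[i] for i in self.panel.indices)
        ]
        return pd.DataFrame(rows)


def _data_path(fname: str):
    return resources.files("panelrfe.data").joinpath(fname)


def _read_spec_table() -> pd.DataFrame:
    with resources.as_file(_data_path("reference_spec.csv")) as p:
        return pd.read_csv(p)


def load_reference_spec(
    overrides: dict | None = None,
    *,
    n_subjects: int = 170,
    within_subject_corr: float = 0.5,
    seed: int = 0,
) -> CohortSpec:
    """Build the default :class:`CohortSpec` from the published statistics.

    Parameters
    ----------
    overrides
        Optional ``{analyte name or panel index: {field: value, ...}}``
        mapping replacing individual MeasureSpec fields (e.g.
        ``{"MAO": {"post_mean": 0.85, "post_sd": 0.21}}`` to null an effect).
        Unknown analytes or fields are rejected, naming the offending key.

    Returns
    -------
    CohortSpec
        Re-tabulated consensus values for the 9 consensus analytes, screen
        values for the remaining 20 listed analytes, null defaults for the
        12 unlisted ones.
    """
    table = _read_spec_table()
    params: dict[int, dict] = {}
    for row in table.itertuples(index=False):
        params[int(row.index)] = dict(
            feature_index=int(row.index),
            pre_mean=float(row.pre_mean),
            pre_sd=float(row.pre_sd),
            post_mean=float(row.post_mean),
            post_sd=float(row.post_sd),
            provenance=str(row.provenance),
            suspect=(row.suspect == "yes"),
        )
    if overrides:
        allowed = {"pre_mean", "pre_sd", "post_mean", "post_sd",
                   "provenance", "suspect"}
        for key, fields in overrides.items():
            try:
                idx = PANEL.resolve(key)
            except KeyError as exc:
                raise KeyError(f"override for unknown analyte {key!r}") from exc
            bad = set(fields) - allowed
            if bad:
                raise KeyError(
                    f"override for {key!r} has unknown fields {sorted(bad)}"
                )
            params[idx].update(fields)
    measures = {i: MeasureSpec(**kw) for i, kw in params.items()}
    return CohortSpec(
        measures=measures,
        n_subjects=n_subjects,
        within_subject_corr=within_subject_corr,
        seed=seed,
    )


def reference_consensus_table() -> pd.DataFrame:
    """Published consensus vote table: rank, analyte, count of 300, nested
    mean accuracy (%)."""
    with resources.as_file(_data_path("consensus_reference.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def reference_ttest_table() -> pd.DataFrame:
    """Published paired t-test screen: 29 analytes with raw p-values, in
    printed order."""
    with resources.as_file(_data_path("ttest_reference.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def reference_consensus_ranking() -> list[str]:
    """Analyte names in published consensus (vote-count) rank order."""
    return reference_consensus_table()["name"].tolist()


def reference_ttest_ranking() -> list[str]:
    """Analyte names in published t-test rank order (ascending p as printed)."""
    return reference_ttest_table()["name"].tolist()
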