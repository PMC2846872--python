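"""Synthetic paired-cohort generation and cohort CSV input/output.

The generator emulates the study design: each subject yields one pre-voyage
and one post-voyage 41-analyte vector.  Per analyte, the pre and post values
of a subject are bivariate normal with the spec's marginal means/SDs and
within-subject correlation rho; different analytes are drawn independently
unless a cross-analyte correlation matrix is supplied.  Values are not
truncated at zero despite physical non-negativity — at the shipped parameters
negative draws are vanishingly rare, and truncation would bias the moments
the simulator exists to reproduce.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import PANEL
from .reference import CohortSpec

__all__ = ["Cohort", "generate_cohort", "write_cohort", "read_cohort"]

PRE_LABEL = 1   # y = +1 marks a pre-voyage sample
POST_LABEL = -1

_META_COLS = ["subject_id", "phase"]


class Cohort:
    """Labelled collection of 41-analyte sample vectors.

    Wraps a tidy DataFrame with columns ``subject_id``, ``phase`` ("pre" or
    "post") and the 41 analyte columns in panel order.  The class label is
    derived from the phase: y = +1 for pre-voyage rows, -1 for post-voyage.
    """

    def __init__(self, frame: pd.DataFrame, dropped_rows: int = 0):
        expected = _META_COLS + PANEL.names
        if list(frame.columns) != expected:
            raise ValueError(
                "cohort frame must have columns subject_id, phase, then the "
                "41 panel analytes in panel order"
            )
        bad = set(frame["phase"].unique()) - {"pre", "post"}
        if bad:
            raise ValueError(f"unknown phase tokens {sorted(bad)}")
        if (frame.groupby(["subject_id", "phase"]).size() > 1).any():
            raise ValueError("a subject may appear at most once per phase")
        if frame[PANEL.names].isna().any().any():
            raise ValueError("cohort rows must not contain missing values")
        self.frame = frame.reset_index(drop=True)
        #: rows discarded on read because of missing values
        self.dropped_rows = dropped_rows

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """(M, 41) float matrix of analyte values, panel order."""
        return self.frame[PANEL.names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """(M,) labels: +1 pre-voyage, -1 post-voyage."""
        return np.where(self.frame["phase"].to_numpy() == "pre",
                        PRE_LABEL, POST_LABEL)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def phase_frame(self, phase: str) -> pd.DataFrame:
        if phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")
        return self.frame[self.frame["phase"] == phase]

    def complete_pairs(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Aligned (pre, post) frames for subjects present in both phases."""
        pre = self.phase_frame("pre").set_index("subject_id")
        post = self.phase_frame("post").set_index("subject_id")
        common = pre.index.intersection(post.index)
        return pre.loc[common], post.loc[common]

    def values_of(self, key, phase: str | None = None) -> np.ndarray:
        """One analyte column, optionally restricted to a phase."""
        name = PANEL.name_of(PANEL.resolve(key))
        frame = self.frame if phase is None else self.phase_frame(phase)
        return frame[name].to_numpy(dtype=float)


def generate_cohort(spec: CohortSpec,
                    analyte_corr: np.ndarray | None = None) -> Cohort:
    """Draw a paired cohort from a :class:`CohortSpec`.

    Parameters
    ----------
    spec
        Validated cohort specification (marginals, n_subjects, rho, seed).
    analyte_corr
        Optional (41, 41) cross-analyte correlation matrix applied to the
        latent standard-normal draws of both phases; by default analytes are
        independent.

    Returns
    -------
    Cohort
        ``2 * n_subjects`` rows: the pre block (subjects s001..), then the
        post block, each subject appearing exactly once per phase.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    d = len(spec.panel)
    rho = spec.within_subject_corr

    z1 = rng.standard_normal((n, d))   # latent pre
    z2 = rng.standard_normal((n, d))   # latent post innovation
    if analyte_corr is not None:
        corr = np.asarray(analyte_corr, dtype=float)
        if corr.shape != (d, d):
            raise ValueError(f"analyte_corr must be ({d}, {d})")
        L = np.linalg.cholesky(corr)
        z1 = z1 @ L.T
        z2 = z2 @ L.T
    # bivariate-normal pairing: corr(pre, post) = rho per analyte
    z_post = rho * z1 + np.sqrt(1.0 - rho**2) * z2

    pre_mean = np.array([spec.measures[i].pre_mean for i in spec.panel.indices])
    pre_sd = np.array([spec.measures[i].pre_sd for i in spec.panel.indices])
    post_mean = np.array([spec.measures[i].post_mean for i in spec.panel.indices])
    post_sd = np.array([spec.measures[i].post_sd for i in spec.panel.indices])

    pre_vals = pre_mean + pre_sd * z1
    post_vals = post_mean + post_sd * z_post

    width = len(str(n))
    subjects = [f"s{i + 1:0{width}d}" for i in range(n)]
    pre_df = pd.DataFrame(pre_vals, columns=PANEL.names)
    pre_df.insert(0, "phase", "pre")
    pre_df.insert(0, "subject_id", subjects)
    post_df = pd.DataFrame(post_vals, columns=PANEL.names)
    post_df.insert(0, "phase", "post")
    post_df.insert(0, "subject_id", subjects)
    return Cohort(pd.concat([pre_df, post_df], ignore_index=True))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (header: subject_id, phase, 41 analytes)."""
    cohort.frame.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV, dropping rows with missing analyte values.

    Mirrors the study's handling of incomplete records: any row with a
    missing analyte value is discarded and the number of discarded rows is
    reported on ``Cohort.dropped_rows``.  Malformed headers, non-numeric
    analyte cells and unknown phase tokens are rejected with the offending
    row/column named.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str, "phase": str})
    expected = _META_COLS + PANEL.names
    if list(frame.columns) != expected:
        raise ValueError(
            f"malformed cohort header: expected {expected[:3]}..., "
            f"got {list(frame.columns)[:3]}..."
        )
    bad_phase = ~frame["phase"].isin(["pre", "post"])
    if bad_phase.any():
        row = int(np.flatnonzero(bad_phase.to_numpy())[0])
        raise ValueError(
            f"unknown phase token {frame['phase'].iloc[row]!r} at data row {row}"
        )
    for col in PANEL.names:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        newly_bad = coerced.isna() & frame[col].notna()
        if newly_bad.any():
            row = int(np.flatnonzero(newly_bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {frame[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        frame[col] = coerced
    keep = frame[PANEL.names].notna().all(axis=1)
    dropped = int((~keep).sum())
    return Cohort(frame.loc[keep].reset_index(drop=True), dropped_rows=dropped)
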