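"""End-to-end consensus SVM-RFE analysis as a model/results pair.

``ConsensusSVMRFE`` is built from a cohort (loaded or simulated) plus the
resampling and kernel settings; ``fit`` runs the whole procedure — partition,
per-partition recursive elimination, majority vote, nested combination
accuracies, final subset, paired t-test screen and top-k ranking overlap —
and returns a ``ConsensusSVMRFEResults`` carrying every intermediate table,
a text ``summary()`` and TSV/JSON report writers.  All randomness descends
from the single seed passed to ``fit``, so identical configuration and seed
reproduce every output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .consensus import (
    ComboCurve,
    VoteTally,
    combo_accuracy_curve,
    majority_features,
    select_final_subset,
    tally_votes,
)
from .panel import PANEL
from .reference import CohortSpec, load_reference_spec, reference_ttest_ranking
from .resampling import DEFAULT_RATIOS, PartitionPlan, make_partitions
from .simulate import Cohort, generate_cohort, read_cohort
from .svm_rfe import KernelConfig, RFEResult, rfe_run
from .ttest import screen_features, topk_overlap

__all__ = ["ConsensusSVMRFE", "ConsensusSVMRFEResults"]


@dataclass
class _RunSettings:
    ratios: tuple[str, ...] = DEFAULT_RATIOS
    n_partitions: int = 50
    stratified: bool = True
    by_subject: bool = False
    vote_threshold: float = 0.5
    alpha: float = 0.05
    gamma: float | None = None
    C: float = 1.0
    standardize: bool = True
    overlap_k: int = 9


class ConsensusSVMRFE:
    """Consensus SVM-RFE feature selection over a paired pre/post cohort.

    Parameters
    ----------
    cohort
        A :class:`~panelrfe.simulate.Cohort` of labelled 41-analyte vectors.
    ratios
        Train:test mixing ratios for the repeated random holdouts.
    n_partitions
        Number of resampled partitions R (ensemble size).  50 is the
        packaged quick-run default; 300 is the full published scale.
    vote_threshold
        Majority cut as a fraction of R (inclusive).
    alpha
        Significance level of the paired t-test screen.
    gamma, C, standardize
        RBF-SVM hyperparameters, see :class:`~panelrfe.svm_rfe.KernelConfig`.
    stratified, by_subject
        Partition drawing options, see
        :func:`~panelrfe.resampling.make_partitions`.
    """

    def __init__(self, cohort: Cohort, *, ratios=DEFAULT_RATIOS,
                 n_partitions: int = 50, stratified: bool = True,
                 by_subject: bool = False, vote_threshold: float = 0.5,
                 alpha: float = 0.05, gamma: float | None = None,
                 C: float = 1.0, standardize: bool = True,
                 overlap_k: int = 9):
        self.cohort = cohort
        self.settings = _RunSettings(
            ratios=tuple(ratios), n_partitions=n_partitions,
            stratified=stratified, by_subject=by_subject,
            vote_threshold=vote_threshold, alpha=alpha, gamma=gamma, C=C,
            standardize=standardize, overlap_k=overlap_k,
        )
        self._sim_manifest: dict | None = None

    @classmethod
    def from_simulation(cls, spec: CohortSpec | None = None, *,
                        n_subjects: int = 170, rho: float = 0.5,
                        seed: int = 0, **kwargs) -> "ConsensusSVMRFE":
        """Build the model on a freshly simulated cohort.

        With ``spec=None`` the default reference specification (published
        means/SDs) is used at the given size, correlation and seed.
        """
        if spec is None:
            spec = load_reference_spec(
                n_subjects=n_subjects, within_subject_corr=rho, seed=seed
            )
        model = cls(generate_cohort(spec), **kwargs)
        model._sim_manifest = {
            "n_subjects": spec.n_subjects,
            "within_subject_corr": spec.within_subject_corr,
            "seed": spec.seed,
        }
        return model

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ConsensusSVMRFE":
        return cls(read_cohort(path), **kwargs)

    @property
    def kernel_config(self) -> KernelConfig:
        s = self.settings
        return KernelConfig(gamma=s.gamma, C=s.C, standardize=s.standardize)

    def fit(self, seed: int = 0, progress: bool = False,
            log=None) -> "ConsensusSVMRFEResults":
        """Run the full pipeline; all randomness descends from ``seed``."""
        s = self.settings
        config = self.kernel_config
        plan = make_partitions(
            self.cohort, ratios=s.ratios, total_count=s.n_partitions,
            seed=seed, stratified=s.stratified, by_subject=s.by_subject,
        )
        results: list[RFEResult] = []
        for k, part in enumerate(plan):
            try:
                results.append(rfe_run(part, self.cohort, config))
            except Exception as exc:
                raise RuntimeError(
                    f"elimination stage failed on partition {k} "
                    f"(ratio {part.ratio_tag}): {exc}"
                ) from exc
            if progress or log is not None:
                msg = (f"partition {k + 1}/{len(plan)} done "
                       f"(best {results[-1].best_accuracy:.3f} with "
                       f"{len(results[-1].best_subset)} features)")
                (log or print)(msg)
        tally = tally_votes(results)
        majority = majority_features(tally, s.vote_threshold)
        if majority:
            curve = combo_accuracy_curve(majority, plan, self.cohort, config)
            consensus = select_final_subset(curve)
        else:
            curve = ComboCurve(features=[], mean_accuracy_pct=[])
            consensus = ()
        screen = screen_features(self.cohort, alpha=s.alpha)
        rfe_ranking = [PANEL.name_of(i) for i in tally.ranked_features()]
        ttest_ranking = screen["name"].tolist()
        k_cap = min(s.overlap_k, len(rfe_ranking), len(ttest_ranking))
        overlap = topk_overlap(rfe_ranking, ttest_ranking, k_cap) if k_cap else 0
        return ConsensusSVMRFEResults(
            model=self, seed=seed, plan=plan, rfe_results=results,
            vote_tally=tally, majority=majority, combo_curve=curve,
            consensus_features=consensus, ttest_screen=screen,
            overlap_top_k=k_cap, overlap=overlap,
        )


@dataclass
class ConsensusSVMRFEResults:
    """Everything the fitted pipeline produced, with report writers."""

    model: ConsensusSVMRFE
    seed: int
    plan: PartitionPlan
    rfe_results: list[RFEResult]
    vote_tally: VoteTally
    majority: list[int]
    combo_curve: ComboCurve
    consensus_features: tuple[int, ...]
    ttest_screen: pd.DataFrame
    overlap_top_k: int
    overlap: int
    _cached: dict = field(default_factory=dict, repr=False)

    # ---------------- derived tables ----------------

    @property
    def consensus_names(self) -> list[str]:
        return [PANEL.name_of(i) for i in self.consensus_features]

    def vote_table(self) -> pd.DataFrame:
        """Vote counts joined with the nested mean-accuracy column."""
        table = self.vote_tally.to_frame()
        curve = self.combo_curve
        acc = {f: a for f, a in zip(curve.features, curve.mean_accuracy_pct)}
        combo = {
            f: "+".join(str(j) for j in curve.features[: k + 1])
            for k, f in enumerate(curve.features)
        }
        table["combination"] = table["index"].map(combo).fillna("")
        table["mean_accuracy_pct"] = table["index"].map(acc)
        return table

    def ranking_archive(self) -> pd.DataFrame:
        """One row per partition: ratio, elimination order, best subset."""
        rows = []
        for k, res in enumerate(self.rfe_results):
            rows.append(
                {
                    "partition": k,
                    "ratio_tag": res.ratio_tag,
                    "best_accuracy": res.best_accuracy,
                    "best_subset": "+".join(map(str, res.best_subset)),
                    "elimination_order": "+".join(
                        map(str, res.elimination_order)
                    ),
                }
            )
        return pd.DataFrame(rows)

    def consensus_summary(self) -> pd.DataFrame:
        """Pre/post mean +/- SD of the consensus analytes in this cohort."""
        pre, post = self.model.cohort.complete_pairs()
        rows = []
        for i in self.consensus_features:
            name = PANEL.name_of(i)
            rows.append(
                {
                    "index": i,
                    "name": name,
                    "pre_mean": pre[name].mean(),
                    "pre_sd": pre[name].std(ddof=1),
                    "post_mean": post[name].mean(),
                    "post_sd": post[name].std(ddof=1),
                }
            )
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        """Full configuration needed to regenerate every output."""
        return {
            "package": "panelrfe",
            "version": _pkg_version,
            "seed": self.seed,
            "settings": asdict(self.model.settings),
            "simulation": self.model._sim_manifest,
            "n_cohort_rows": len(self.model.cohort),
        }

    # ---------------- presentation ----------------

    def summary(self) -> str:
        s = self.model.settings
        lines = [
            "Consensus SVM-RFE feature selection",
            "=" * 64,
            f"cohort rows: {len(self.model.cohort)}   "
            f"partitions (R): {len(self.plan)}   "
            f"ratios: {', '.join(s.ratios)}",
            f"kernel: RBF (C={s.C}, gamma="
            f"{'auto' if s.gamma is None else s.gamma}, "
            f"standardize={s.standardize})   seed: {self.seed}",
            "",
            f"majority features (vote >= {s.vote_threshold:.0%} of R): "
            f"{len(self.majority)}",
            "",
            "rank  feature      count    count%   mean acc% (nested prefix)",
        ]
        table = self.vote_table()
        for row in table.itertuples(index=False):
            acc = ("" if pd.isna(row.mean_accuracy_pct)
                   else f"{row.mean_accuracy_pct:8.2f}")
            lines.append(
                f"{row.rank:>4}  {row.name:<11}  {row.count:>5}  "
                f"{row.count_pct:>7.2f}  {acc}"
            )
        lines += [
            "",
            f"consensus subset ({len(self.consensus_features)} features): "
            + ", ".join(self.consensus_names),
        ]
        if len(self.combo_curve):
            best = max(self.combo_curve.mean_accuracy_pct)
            lines.append(f"consensus mean test accuracy: {best:.2f}%")
        n_sig = int(self.ttest_screen["significant"].sum())
        lines += [
            f"paired t-test screen: {n_sig} analytes significant at "
            f"alpha={s.alpha}",
            f"top-{self.overlap_top_k} overlap (consensus vs t-test ranking): "
            f"{self.overlap}",
        ]
        return "\n".join(lines)

    def reference_overlap(self, k: int = 9) -> int:
        """Top-k overlap of this run's consensus ranking with the published
        t-test ranking."""
        names = [PANEL.name_of(i) for i in self.vote_tally.ranked_features()]
        return topk_overlap(names, reference_ttest_ranking(), k)

    def save(self, outdir) -> dict[str, Path]:
        """Write the report bundle (TSVs + JSON manifest); returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _tsv(name: str, frame: pd.DataFrame):
            p = outdir / name
            frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths[name] = p

        _tsv("votes.tsv", self.vote_table())
        _tsv("rankings.tsv", self.ranking_archive())
        _tsv("ttest.tsv", self.ttest_screen)
        _tsv("consensus.tsv", self.consensus_summary())
        _tsv("partitions.tsv", self.plan.to_frame())
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n"
        )
        paths["manifest.json"] = manifest_path
        summary_path = outdir / "summary.txt"
        summary_path.write_text(self.summary() + "\n")
        paths["summary.txt"] = summary_path
        return paths


def refit_from_manifest(path) -> ConsensusSVMRFEResults:
    """Re-run a pipeline from a saved ``manifest.json``.

    Only simulated-cohort runs are self-contained enough to refit (a loaded
    CSV cohort's path is not stored); the refit reproduces every report
    byte for byte.
    """
    manifest = json.loads(Path(path).read_text())
    sim = manifest.get("simulation")
    if sim is None:
        raise ValueError("manifest does not describe a simulated cohort")
    settings = manifest["settings"]
    settings["ratios"] = tuple(settings["ratios"])
    model = ConsensusSVMRFE.from_simulation(
        n_subjects=sim["n_subjects"], rho=sim["within_subject_corr"],
        seed=sim["seed"], **{k: v for k, v in settings.items()},
    )
    return model.fit(seed=manifest["seed"])
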