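# Methods

## Model

Samples are 41-dimensional vectors of serum analyte concentrations, labelled
y = +1 (pre-voyage) or −1 (post-voyage). The classifier is the soft-margin
SVM: minimise ½‖ω‖² + C Σξ_k subject to y_k(ω·φ(x_k) + b) ≥ 1 − ξ_k, solved
in its dual form

max_α Σα_k − ½ αᵀHα,  0 ≤ α_k ≤ C,  Σ α_k y_k = 0,
H_hk = y_h y_k K(x_h, x_k),

with the Gaussian kernel K(x, x′) = exp(−γ‖x − x′‖²). The decision rule is
sign(Σ_SV α_k y_k K(x_k, x) + b). The dual optimum is obtained from
scikit-learn's SMO solver; multipliers, bias and support set are extracted
and every downstream quantity (decision values, elimination scores) is
computed from them directly. Dual feasibility (Σαy = 0 within 1e-6,
0 ≤ α ≤ C) is asserted on every fit.

### Elimination criterion

Feature *i* is scored by the change in the dual quadratic form when it is
deleted with α frozen at the trained solution:

DJ(i) = ½ |αᵀHα − αᵀH(−i)α|.

For the RBF kernel, deleting one coordinate factorises out of the squared
distance, so K(−i)_hk = K_hk · exp(γ(x_hi − x_ki)²) — a multiplicative
downdate evaluated on support vectors only, verified in the tests against
full kernel recomputation to 1e-10 and, for the linear kernel, against the
closed form DJ(i) = ½w_i². The absolute value is taken because with a
nonlinear kernel the objective change can have either sign. Ties are broken
by removing the higher panel index first, making runs fully deterministic.

### One kernel scale per elimination run

When γ is not given it defaults to 1/(d · pooled variance) of the
standardised training matrix (≈ 1/41 on the full panel, since z-scored
features have unit pooled variance). Within one elimination run this width
is resolved **once**, on the full starting panel, and held fixed for every
retrain: DJ scores from successive stages are only comparable on a single
kernel scale, and a width that re-inflates as 1/d while the active set
shrinks makes the absolute-value criterion favour noise features near the
end of the path (deleting a noise coordinate then changes the quadratic form
by a larger magnitude — with opposite sign — than deleting the informative
one; empirically this drops single-informative-feature recovery from 100% to
0%). Standalone classifiers trained on a fixed subset (the combination
curves) resolve γ on their own matrix, the standard per-fit heuristic.

### Standardisation

z-scoring by training-set statistics is on by default and the scaler learned
on each training set is reapplied to its test set. Raw analytes span four
orders of magnitude (Na ≈ 144 mmol/L vs MAO ≈ 0.85 U/L); an unscaled RBF
distance would be dominated by the large-valued analytes. With
standardisation on, the elimination order is invariant to rescaling any raw
column (tested at ×1000).

### Resampling and consensus

R partitions are drawn at seven train:test ratios (1:1, 1.5:1, 2:1, 2.5:1,
3:1, 3.5:1, 4:1), allocated as evenly as possible with the remainder to the
smallest ratios (300 → 43,43,43,43,43,43,42). Rows are assigned
independently at random; a subject's pre and post rows may land in different
sets (study-faithful default; `by_subject=True` keeps pairs together for
leakage sensitivity analysis). Splits are stratified by label by default —
small unstratified splits can degenerate to one class — with a flag for
fully unconstrained sampling. Each run's *best subset* is the active set
maximising test accuracy (smallest on ties); this reuse of the test set for
subset selection is optimistic by construction and is reported as such, not
corrected, because the consensus vote across partitions is the actual
selection mechanism. Features kept by ≥ 50% of runs (inclusive) are ranked
by vote count (ties by panel index), one classifier per partition is
retrained on every nested prefix of that ranking, and the smallest prefix
with maximal mean test accuracy is the consensus subset. Only the nested
prefixes are evaluated, not all 2^m − 1 subsets.

### Paired t-test baseline

Per analyte, t = mean(d)/(sd(d)/√n) on within-subject differences
d = pre − post, two-sided p with n−1 df (scipy's paired test behind the
`paired_t` surface; the longhand formula is the independent oracle in the
tests). Raw p-values at α = 0.05, no multiple-testing correction — matching
the baseline being reproduced — with an optional Bonferroni flag. The screen
is ranked by ascending p and compared to the consensus ranking by top-k
intersection.

## Synthetic cohorts

The simulator draws, per analyte, a subject's (pre, post) pair from a
bivariate normal with the published marginal means/SDs and within-subject
correlation ρ; analytes are independent unless a correlation matrix is
supplied. Defaults are the study conditions: 170 subjects, ρ = 0.5 (the
value is unstated; a paired design implies positive correlation, and the
classification results are insensitive to ρ because vectors are classified
independently — only the paired t-test's power depends on it). The 12
analytes without published statistics get invented plausible values with no
pre/post shift, shipped in `data/reference_spec.csv` under provenance
`null_default`; only their null behaviour matters. The TBA row of the
published screen duplicates FRUC's numbers verbatim (an apparent typesetting
error); the values are shipped as printed with a `suspect` flag. Values are
not truncated at zero: at the shipped parameters negative draws are
vanishingly rare (the most exposed analyte, MAO post-voyage, sits 2 SDs from
zero), and truncation would bias the moments the simulator exists to match.

What the simulator does *not* emulate: cross-analyte correlation (none was
published), non-Gaussian tails, age/sex structure, batch effects. Passing
tests therefore demonstrate the pipeline's behaviour under independent
Gaussian marginals at the published effect sizes — not performance on real
serum panels. One visible consequence: with many mutually independent null
features that barely hurt an RBF classifier, per-partition best subsets are
larger and vote counts less sparse than on the original data; the strongly
shifted analytes still dominate the vote ranking and the consensus subset.

## Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| C | 1 | soft-margin penalty (unstated in the source; standard default) |
| γ | 1/(d · pooled var) | RBF width, frozen per elimination run (see above) |
| standardize | on | z-score by training-set statistics |
| R | 50 | partitions in the packaged quick run; 300 = original scale |
| ratios | 1:1 … 4:1 | seven train:test mixing ratios |
| vote threshold | 0.5 (inclusive) | majority cut |
| ρ | 0.5 | within-subject pre/post correlation |
| α | 0.05 | t-test significance level |

Because C and γ were never published, the single-split 98.3% accuracy of the
original analysis is not a reproduction target; the packaged defaults give
mean accuracies in the same band as the published consensus table (≈ 87–89%
for MAO alone against a Gaussian Bayes rate of ≈ 89.6%; ≈ 94.5–97% for the
nine-analyte consensus subset against a Bayes rate of ≈ 96.4%).

## Problem sizes

The packaged runs use R = 50 partitions on the 170-pair cohort (the original
analysis used R = 300; `--full` restores it) and the property tests use
reduced cohorts (30–60 subjects) and 20-seed recovery ensembles. These sizes
were chosen so the whole suite exercises every code path in seconds while
keeping Monte-Carlo error well inside the asserted tolerances.

## Numerical choices and edge cases

- Decision value exactly 0 predicts +1 (arbitrary, fixed, documented).
- Equal DJ scores remove the higher panel index first.
- Constant features get scale 1 in the z-scorer (they carry no information;
  their DJ is exactly 0, so they are eliminated first).
- Rows with missing analyte values are dropped on CSV read and counted;
  subjects thereby left with a single phase remain in the cohort (vectors
  are classified independently) but are excluded from the paired t-test by
  `complete_pairs()`.
- All randomness flows from explicit integer seeds through numpy
  Generators; identical configuration and seed reproduce cohorts,
  partitions and reports bit for bit, and `manifest.json` is sufficient to
  regenerate a simulated-cohort run byte for byte.

## Known limitations

- The test-set-argmax best subset is optimistically biased; accuracy curves
  are reported for ranking, not as unbiased generalisation estimates.
- Stability selection is performed at one (C, γ) setting; no nested
  hyperparameter search inside partitions.
- Binary phases only; no longitudinal modelling of repeated voyages.
- The simulator's independence assumption makes redundancy among analytes
  (e.g. CK vs CK-MB) invisible to the elimination criterion, which on real
  data is exactly where RFE's mutual-information handling matters.
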