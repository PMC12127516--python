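# Methods

## The workflow model

`memclinic` implements a four-stage clinical decision pipeline for memory
clinics, operating on per-subject tabular data (neuropsychological scores,
MRI-derived regional volumes, CSF biomarkers, an FDG-PET read):

1. **Normative flagging.** Each cognitive test score is compared against a
   cutoff in its impaired direction; a domain (memory, attention/executive,
   visuoconstructive, language, global) is impaired iff at least one of its
   tests is. Functional impairment counts FAQ items at or above a per-item
   threshold. Each regional volume is atrophic iff strictly below the 10th
   percentile of a reference population; composite patterns are pure
   functions of the regional flags (medial temporal = hippocampus ∪
   parahippocampus ∪ medio-temporal cortex; parieto-occipital =
   parieto-occipital cortex ∪ precuneus; frontotemporal = fronto-temporal
   cortex; dominant-hemisphere focal = left medio-/fronto-temporal volume
   atrophic with the homologous right spared).
2. **Staging.** Three literal rules assign MSD, MCI/MD or HS/SCI/WW from the
   impairment counts and MMSE. The rules neither partition nor cover the
   input space (e.g. one impairment with MMSE 25 matches none), so the
   engine evaluates them in severity order and routes uncovered inputs
   through a flagged fallback: any cognitive impairment → MCI/MD, else
   HS/SCI/WW. `matched_rule` and `fallback_used` make every gap auditable.
3. **Profiling and causal hypothesis.** Syndrome rules are evaluated in a
   fixed listing order, so a subject matching several (memory + language
   impairment with both atrophy patterns) resolves to the earliest — typical
   AD. The base hypothesis map sends typical AD/PCA/lvPPA to suspected AD and
   svPPA/nfvPPA/bvFTD-fvAD to suspected FTLD; a high predicted conversion
   risk then reclassifies bvFTD/fvAD and unclear cases to suspected AD.
   Reclassification only ever moves labels toward suspected AD.
4. **Biomarker adjudication.** CSF t-tau/Aβ42 strictly above 0.23 confirms
   AD; with the ratio at/below the cutoff, a concordantly negative
   single-marker panel excludes AD, and a discordant panel
   (amyloid+/tau− or amyloid−/tau+) defers to the FDG-PET read for the
   syndrome-specific hypometabolic pattern. Without CSF, a positive
   syndrome-specific PET confirms. The amyloid+/tau+ corner with a low
   ratio is not covered by the rule as stated and is returned inconclusive
   rather than silently resolved.

## Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| CSF ratio cutoff | 0.23 | – | the workflow's defining biological-AD threshold |
| Amyloid-positive below | 1000 | pg/mL Aβ42 | near the cohort group means; **not a published value**, required config |
| Tau-positive above | 300 | pg/mL t-tau | same caveat |
| Atrophy percentile | 10th | – | normative volumetry convention |
| Cognitive cutoff percentile | 5th | – | impaired direction of a reference cohort |
| FAQ item threshold | 2 | 0–4 scale | "needs assistance" severity; configurable |
| Significant cognitive impairment | ≥3 domains | – | mirrors the ≥3-impairment staging rule |
| PCA variance retained | 95% | – | then top-10 components by Fisher Discriminant Ratio |
| Ensemble members | 21 | – | odd count avoids vote ties; bootstrap fraction 0.8 |
| Vote threshold | 0.5 | – | majority consensus; ties at the threshold are high-risk |
| Label noise | 0.15 | – | makes ~85% the Bayes accuracy, matching realistic separability |

The dominant hemisphere is assumed left for all subjects; handedness is
carried as information only. Language-variant subtyping (logopenic vs
semantic vs agrammatic) cannot be derived from this test battery, so the
deficit profile carries a `language_subtype` annotation defaulting to
logopenic, and rule (f)'s behavioral arm is an optional flag beside the
dysexecutive arm, since the battery contains no disinhibition measure.

## The synthetic generator: what it does and does not emulate

The generator draws each variable independently from a truncated Gaussian
(rejection sampling, cap 1000 attempts, then clipping) parameterized by the
published group mean ± SD, with bounds at each variable's valid range.
Integer-valued scores are rounded then clipped; binary 0/1 subscores are
Bernoulli with the published mean, because rounding a narrow Gaussian at 0.5
would distort P(1) far beyond sampling error. Structural fields are derived,
not drawn: lateralized totals = right + left, asymmetry = 100·(R−L)/(R+L),
percent-over-TIV = 100·total/TIV, clock and FAQ totals as item sums, and the
CSF ratio from its components — so the schema invariants hold for every
subject. Conversion labels in the risk groups are the group identity flipped
with probability 0.15.

What this emulates: group-conditional marginals, the monotone
volume–biomarker contrasts between groups (induced by group mixing), and
imperfect label separability. What it does not: within-subject correlation
structure beyond the derived fields (the published tables print only
marginals), site/scanner effects, longitudinal trajectories, non-Gaussian
shapes of boundary-concentrated count variables, and a genuinely healthy
reference group (none is printed; the low-risk group, the closest printed
approximation, anchors the default normative derivation). Passing tests
therefore demonstrate correctness of the decision logic and statistics and
plausible end-to-end behavior — not performance on real clinical data.

**Moment recovery and truncation.** Truncating a Gaussian shifts its mean;
for variables concentrated at a boundary (an FAQ item printed as 0.41 ± 0.99
on 0–4, or MMSE near its ceiling of 30) no truncated Gaussian attains the
printed moments — on [0, ∞) a log-concave family cannot have SD exceed the
mean. Mean-recovery checks therefore target (a) the analytic
truncated-normal mean for generator correctness, and (b) the printed means
for the subset of variables whose untruncated Gaussian mass outside the
bounds is below 5% (`recoverable_variables`; 106 of 176 risk-group
variables). The remainder are documented as distribution-distorted rather
than silently asserted.

## Evaluation statistics

Count-based metrics carry their integer counts and Clopper–Pearson exact
intervals (beta-quantile construction via statsmodels); percentages are
rendered half-away-from-zero to integer percent (one decimal optional),
percent differences anchored on the first group to two decimals. Cohen's κ
is computed from the contingency table with marginal-product chance
agreement; the degenerate case p_e = 1 is defined as κ = 1 with a warning,
and the CI uses the large-sample standard error (no κ interval is published
to match). ROC AUC uses the Mann–Whitney midrank construction; its variance
and the paired-difference test use the DeLong structural components (no
installed Python package provides these, so they are implemented here and
cross-checked against the brute-force pairwise statistic and scikit-learn's
AUC). Group comparisons gate on Shapiro–Wilk at α = 0.05 per group (capped
at n = 5000 for the test's validity range): both normal → Student's
t-test, else Mann–Whitney U with midranks and continuity correction;
Bonferroni adjustment is min(1, m·p). Two identical groups return p = 1
through an explicit degenerate path, since the rank test is undefined under
total ties.

## Numerical and design choices

- Strict inequalities where the rules say "greater than"/"below": ratio
  exactly 0.23 does not confirm; a volume exactly at the 10th percentile is
  not atrophic.
- Quantiles use linear interpolation (numpy default), so the 10th percentile
  of 1..100 is 10.9.
- The risk ensemble uses `LinearSVC(dual=False)` for determinism; bootstrap
  resamples are redrawn until both classes are present; PCA spans are
  row-order invariant up to component sign.
- Cross-validated metrics in the pipeline report come from pooled held-out
  votes (5-fold stratified), not from refitting on the full data, to avoid
  optimism.
- Problem sizes in the shipped tests and acceptance checks — 400 subjects
  per risk group for end-to-end recovery, 20,000 replicates for interval
  coverage, exhaustive grids of a few thousand cells for the decision
  oracles — were chosen to give stable verdicts at interactive runtimes.

## Known limitations

- The proprietary classifier this architecture class describes is not
  reproduced weight-for-weight; kernel, component and member counts are
  unpublished and configurable here.
- Single-marker CSF cutoffs are unpublished; adjudication of discordant
  profiles depends on these configured defaults.
- The cross-tabulated concordance accuracy recomputes from labels; an
  alternative published tabulation (100/112) is not reconstructible from
  the published flow counts and is surfaced in the concordance docstring
  rather than resolved.
- Staging agreement measured on synthetic cohorts reflects the generator's
  marginal design, not clinician behavior; κ values on synthetic data are
  not comparable to published inter-rater agreement.
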