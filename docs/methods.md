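# Methods

## The partitioning procedure

`roctree` fits a binary decision tree to a subjects × features table with
a binary remission outcome. At each node every candidate predictor
contributes one candidate cut-point per distinct observed value *v*,
splitting the node's subjects into {x ≥ v} and {x < v}. The candidate's
score is the unweighted Cohen's kappa of the 2×2 table crossing branch
membership with the observed outcome, where the branch with the higher
non-remission fraction is taken to predict non-remission (ties go to the
≥ branch). Kappa is (observed − chance agreement)/(1 − chance agreement)
and is defined as 0 when a margin is degenerate (chance agreement 1);
degenerate candidates can never win because their association p-value
is 1. The node splits on the best candidate whose two-sided Fisher exact
p is below `alpha` (default 0.01), and recursion continues in both
children until no candidate qualifies, a node is outcome-pure, or fewer
than four subjects remain.

Determinism and tie handling. Fitting has no random element: ties in
kappa break by smaller Fisher p, then by the position of the feature in
the caller-supplied list, then by the smaller threshold. Kappas and
p-values are compared with a small tolerance (1e−12 absolute on kappa,
1e−9 relative on p) because mathematically identical candidates can
differ in the last float ulp depending on evaluation order; without the
tolerance the feature-order tie-break would be decided by rounding noise.

Candidate admissibility. A candidate must leave at least two subjects on
each side (`MIN_BRANCH = 2`): Fisher's test is degenerate below that,
and the empty-branch candidate at the observed minimum is always dropped.
`enumerate_cutpoints` (the audit-level API) applies only the
empty-branch exclusion, so candidate lists reflect every non-trivial
observed split; the two-per-branch floor is enforced at selection time.

Significance machinery. The stopping test is the two-sided Fisher exact
test (probability-ordering rule), chosen over Pearson chi-square because
it remains valid at the small node sizes the recursion reaches; the
choice is recorded in tree metadata. No multiple-testing correction is
applied across candidates — the method is deliberately faithful to the
raw p < 0.01 stopping rule rather than statistically conservative, which
is why fitted trees on noisy data can contain extra significant-looking
deep splits. For speed, candidates are screened by a vectorized
one-sided hypergeometric tail, which lower-bounds the two-sided Fisher p
(the hypergeometric pmf is unimodal, so the same-direction tail is always
contained in the two-sided sum); only survivors get the exact test.

Missing data. Candidates are evaluated per feature on the subjects who
have that feature (complete-case per feature). When a chosen split
feature is missing for a subject, the subject is left unrouted at fit
time (counted on the node) and reported as "unclassified" at apply time.
In the canonical per-modality analyses missingness is all-or-none (a
subject lacks the whole scan), so fitted trees conserve counts exactly.

## Rules, application, combination

An *actionable rule* is the conjunction of conditions on a root-to-node
path whose node is at least 80% non-remitters (`min_accuracy`
configurable); every qualifying node contributes a rule, in preorder.
Thresholds use ≥ on the positive side everywhere; a subject exactly at a
threshold follows the ≥ branch. Serial combination of two rule sets
selects the intersection of their selections (order-invariant), parallel
the union; accuracies are computed on the combined selection.

## Validation statistics

* Replication: one-sided lower-tail exact binomial,
  P(X ≤ observed correct | n selected, p₀ = fit accuracy). Small p means
  the new-cohort accuracy is credibly *below* the fit accuracy (failure
  to replicate).
* Chance: one-sided upper-tail exact binomial with
  p₀ = 1 − 0.35 = 0.65, the probability a selected subject is a
  non-remitter if selection were unrelated to outcome (35% is the
  literature remission rate; configurable).
* Group characterization: pooled-variance independent t-tests for
  continuous covariates (Welch by flag) and Pearson chi-square without
  continuity correction for binary ones, mirroring the era-typical
  presentation; no multiplicity correction.
* Bootstrap cross-validation: `n_iter` draws of `m` subjects (default
  1000 × 100) from the pooled cohorts, without replacement within a draw
  ("randomly chosen", not a with-replacement resample; a flag switches).
  Per draw the fixed rule set is applied and two quantities recorded:
  specificity (fraction of selected subjects who are non-remitters) and
  coverage (fraction of the draw's non-remitters selected). Draws with an
  empty selection (or no non-remitters) are recorded as undefined,
  excluded from the mean ± sd and counted. With m equal to the pool size
  every draw is the pool and the sd is exactly 0.

All exact tails are computed through scipy's binomial/hypergeometric
machinery behind this module's interface; the test suite checks them
against independent log-factorial summation oracles to 1e−12 relative
error, and checks the cut-point selector against exhaustive brute force.

## The synthetic cohort generator

The generator emulates the data structure of a two-cohort antidepressant
trial with structural imaging: per subject, 116 AAL region volumes (mL,
truncated normal, > 0), 46 JHU ICBM-DTI-81 tract FA values (truncated
normal in [0, 1]), clinical covariates (age, sex, baseline and week-8
HRSD17, melancholia, prior treatment, arm, dose — drawn from
summary-statistic models, independent of imaging), and a remission label
defined as week-8 HRSD17 ≤ 7 (the week-8 score is drawn conditional on
the label, so the criterion holds by construction).

A *planted tree* is an ordered chain of (feature, threshold) splits with
per-leaf target counts and remission probabilities. Subjects are first
partitioned into leaves at exactly the target counts, then each split
feature is drawn truncated to the subject's side of the threshold, so
planted node counts are reachable exactly; all non-split features are
drawn independently of the label. Two label modes:

* Bernoulli (default): each subject's label is a Bernoulli draw at its
  leaf probability — compositions fluctuate binomially, which is what
  the sampling-property tests exercise.
* exact (`exact_counts=True`): leaf compositions
  (remitters/non-remitters) are realized exactly, so applying the
  published thresholds reproduces published node counts *by
  construction*. This mode underlies the worked-example checks.

When one cohort plants a tree per modality, both trees share the single
remission label; leaf memberships are assigned independently per
modality conditional on that label. In exact mode the per-modality
remitter totals fixed by the leaf compositions are reconciled through
the modality-missing subjects (see below).

The canonical configuration (`default_paper_config`) encodes the
published structure: a test cohort of 80 treatment completers of whom 6
lack the DTI scan (FA analysis n = 74) and 4 lack the T1 scan
(volumetric analysis n = 76); a fully observed validation cohort of 83.
The planted volumetric chain is left middle frontal gyrus at 14.82 mL
then right angular gyrus at 6.25 mL with test-cohort leaf compositions
25/33, 3/29, 7/14 (remitters/subjects); the FA chain is left cingulum
(cingulate) 0.63, right superior fronto-occipital fasciculus 0.54, right
superior longitudinal fasciculus 0.50 with compositions 17/22, 2/20,
2/13 and a leftover node of 13/19 obtained by subtraction from the
cohort totals (its composition was not printed). Validation-cohort
compositions beyond the printed actionable nodes (7/38 volumetric; 4/13
and 1/6 FA) are not published; the remaining allocations (11/30 and 2/15
volumetric; 10/30 and 5/34 FA) were chosen once, consistent with the
cohort totals of 83 subjects and 20 remitters, and are not calibrated
further. The overall test-cohort remitter count (37/80) likewise follows
from reconciling the two modality totals (34/74 and 35/76) at the
configured 46% rate.

Feature distribution defaults place each planted threshold at its
feature's distribution center (volumes: sd 2.0 for the 14.82 mL split,
1.0 for the 6.25 mL split; FA: sd 0.05), so both branch sides are
populated; noise volumes are N(10, 2.5) truncated positive and noise FA
N(0.50, 0.07) truncated to [0, 1]. These are generic anatomical scales,
not calibrated to real morphometry — the generator reproduces the
*structure* the analysis assumes (planted thresholds, node compositions,
label noise, modality missingness), not spatial covariance between
neighboring regions, scanner effects, or longitudinal symptom
trajectories. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure under the stated
noise, not anatomical realism.

A separate pooled fixture (`combination_reference_cohort`, 157 subjects,
103 non-remitters) realizes the published overlap between the volumetric
rule and the replicated FA rule, derived by inclusion–exclusion from the
published serial (10 non-remitters, 0 remitters) and parallel (63
non-remitters, 13 remitters) combination counts; that derivation also
implies the pooled FA selection used only the replicated deep path
(19 selected, 16 non-remitters), which matches the published 16/103
coverage.

Randomness: one integer seed drives the whole table through numpy's
PCG64 via `SeedSequence` spawning (one child stream per cohort); the
generator name and scheme are recorded in run manifests
(`GENERATOR_VERSION`).

## Known numerical discrepancies and conventions

* The published chance-test p-values 0.002 (test) and 0.019 (validation)
  are not exactly reproduced by the exact upper binomial tail at
  p₀ = 0.65, which gives 0.0026 and 0.0205 on the same counts; the exact
  tail is reported as computed. The published cohort-difference
  chi-square of 8.02 on the remission rates likewise matches neither the
  Pearson (8.28) nor the Yates-corrected (7.34) statistic on the printed
  counts and is not used as a test vector.
* Coverage denominators follow the published accounting: "all
  non-remitters pooled across cohorts" counts the clinical (DTI-complete)
  cohorts, 74 + 83 subjects with 103 non-remitters.
* Thresholds rounded differently in different parts of the source
  material (14.8/6.3 vs 14.82/6.25) are taken at their unrounded values;
  "greater than" phrasing at a cut-point always means ≥.
* The fit-accuracy reference for the replication binomial test is capped
  just below 1 so the test remains defined for perfectly pure fit nodes.

## Problem sizes

Default test runs and the acceptance script use the study-scale cohorts
(80 + 83 subjects, 162 imaging features), 100 simulations for the
planted-recovery rate (n = 150 each, full 116-feature search), and the
full 1000 × 100 bootstrap. These sizes complete in about a minute each
on a single CPU.

## Limitations

The method inherits the published procedure's caveats: raw p < 0.01
stopping without multiplicity control tends to overgrow trees on noisy
data; accuracy is defined only on the selected subgroup, leaving the
rest "unclassified"; and the synthetic validation can only show that the
pipeline recovers what was planted, not that the published anatomical
findings generalize.
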