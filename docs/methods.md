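# Methods

`ventwarn` implements an end-to-end early-warning pipeline for invasive
mechanical ventilation (MV) in pediatric intensive care, exercised entirely on
a synthetic EHR generator. This note documents the models, the generator's
contract, the tunable parameters, and the numerical choices, in the package's
own terms.

## Problem and outcome definition

Each PICU encounter is a stream of irregularly timed events: vital signs,
nursing assessments, labs, intake/output volumes, PEWS scores, and medication
administration records. The prediction target is whether the patient will
receive invasive MV for respiratory failure. Time is measured in integer
minutes since PICU admission throughout.

The 30 minutes before MV onset are the *preparation window*: hypnotics and
anesthetics given there are a direct consequence of the decision to intubate,
so every grid sample in `[prep, onset)` is removed from training and
evaluation. Risk scores for MV encounters are therefore defined on
`[admission, prep)` and for controls on the whole stay.

## Cohort filters

The inclusion/exclusion flowchart retains encounters with age 0–21 years,
complete age/gender/weight/LOS, and at least one vital sign, and removes
tracheostomy patients, cyanotic-heart-disease patients whose SpO2 sat below
90% for ≥ 75% of the stay (computed on the 5-minute LOCF grid — the natural
time-weighted reading, since no aggregation rule is standard), manually
flagged transcription errors, and MV cases whose onset was < 12 h after
admission, whose MV lasted < 12 h, whose onset fell within 90 min *after* a
documented procedure (the forward direction is the clinically sensible one:
procedural intubations), or who lacked a respiratory/cardiovascular/sepsis
diagnosis. Rules fire in flowchart order; each removed encounter is logged
once with the first rule that applied.

The 80/20 train/test split is stratified by MV outcome, gender, age group
(<1, 1–4, 5–11, 12–21 years — conventional PICU reporting bins) and
non-invasive-ventilation status. Within each stratum the train share is
`round(0.8 n)`; singletons go to train with a warning.

## Feature engineering

Observations are resampled to a 5-minute grid by last observation carried
forward. Every LOCF series carries a `__missing` indicator column: labs are
drawn when clinicians are worried, so missingness is informative and the tree
model can use it (the indicator is harmless to the linear model).
Physiologic numerics are standardized to z-scores against an age-banded
normal-range table; the packaged default table is **synthetic** — generated
from the same age-dependent baselines the cohort generator uses — and a site
running on real data supplies its own reference table (e.g. Harriet Lane
ranges) as CSV. Missing height maps to z = 0; weight is required by the
cohort filter. Intake/output volumes become trailing 6-hour rates with the
denominator truncated at admission. All trailing windows are half-open
`(t − w, t]` to avoid double counting.

Medications enter two ways:

1. **Indicators** — for medications selected on the training split (given to
   ≥ 10% of MV patients, or with a ≥-one-dose prevalence gap > 5 percentage
   points between groups), a binary column per medication marks any event in
   the previous 6 hours.
2. **History sentences** — the ordered (medication, action) stream in a
   window is a sentence ("med_a given med_b given med_a rate_changed ...");
   an empty window is the sentinel token `<no_meds>`. GloVe vectors
   (dimension 10, context window 25, weighted least squares on symmetric
   within-sentence co-occurrence with 1/distance weights, AdaGrad) are
   trained on one full-history sentence per training encounter (up to prep
   for cases, whole stay for controls). A small convolutional classifier
   (five filters each of token lengths 4/5/6 over the frozen embeddings,
   global max-pooling, dropout 0.5, softmax) is trained on the same corpus
   with the MV outcome as label; its pooled penultimate layer
   (`medhist1..medhist15`) is the learned medication-history representation,
   computed at scoring time from the trailing 6-hour window. The
   full-history-for-training / trailing-window-for-scoring asymmetry is
   intentional and mirrors how the representation is deployed.

### CNN numerical choices

The extractor max-pools the *raw* convolution outputs (no ReLU before
pooling): the pooled maximum is itself the nonlinearity, and this keeps a
gradient path alive for every filter. With ReLU-before-pool, a few aggressive
early updates can silence all 15 filters simultaneously (pooled activations
identically zero), after which no gradient ever flows — we observed exactly
this collapse on planted-motif corpora. Pooling is masked to windows that
start inside the true sentence, so pad positions can never win the max.
Training uses Adam (lr 5e-3, batch 64, 40 epochs, seeded shuffling);
shorter schedules (20 epochs at 1e-3) reliably underfit this small
architecture. Ten-fold cross-validation reports held-out AUROC as an
architecture sanity check; the deployed extractor is refit on the full
training corpus. Sentences are head-truncated to the most recent 512 tokens
(recent history is the clinically relevant tail).

Because the embeddings are frozen, tokens are only distinguishable insofar as
their co-occurrence statistics differ — a medication that appears in exactly
the same contexts as every other medication is invisible to the extractor no
matter how outcome-associated it is. The planted medication signal in the
generator therefore perturbs *sequences* (escalation chains), not just
frequencies.

## Risk models

Four feature sets are compared: **A** = clinical + medhist, **B** = clinical
+ indicators, **C** = clinical only, **D** = medhist only. The default
learner is a gradient-boosted tree ensemble (XGBoost: depth 6, eta 0.1,
subsample/colsample 0.8, up to 200 rounds with AUC early stopping on a seeded
10% validation split, one thread for determinism) consuming missing values
natively. The comparator is an L1-regularized logistic regression
(cross-validated penalty) on the median-imputed matrix, medians fitted on
training data only.

Training instances are balanced: all grid rows in the 12 h before each
case's preparation time (144 rows per case), plus an equal number of rows
drawn uniformly without replacement across all control rows (row-level
sampling, no per-encounter quota).

Model selection carries a **chance-level guard**: if the best validation AUC
is below 0.5 + 3 standard errors (Hanley–McNeil null SE for the validation
split), the fitted ensemble is judged indistinguishable from chance and the
deployed scorer is the constant prior. A model that found nothing should not
emit noise: because encounters are ranked by their *maximum* score and
controls are scored over several times more grid rows than MV cases (whose
scoring stops at the preparation time), spurious score variance
systematically inflates control maxima and drags a truly null AUROC well
below 0.5. The guard never triggers on informative data (validation AUC
≈ 0.95 in the planted-signal runs) and makes a no-signal cohort evaluate at
exactly chance.

Risk scores over the *training* encounters — used for threshold selection and
for the training trajectories — are produced out-of-fold: encounters are
split into 10 stratified folds and each fold's full course is scored by a
model fitted on the other folds with fresh balanced sampling. In-sample
scores are optimistically inflated and would push the threshold far above
what the deployed (refit) model emits on held-out patients.

Feature importance is reported two ways: the ensemble's split-gain
attribution, and mean |SHAP| over training rows via TreeSHAP (the exact
algorithm for tree ensembles, computed by the booster itself), which
satisfies per-row additivity to the model margin.

## Alerting, EPP, EWT

The operating threshold maximizes F1 over the unique per-encounter maximum
out-of-fold scores of the training split, ties broken toward the higher
threshold (higher specificity). An encounter is predicted positive iff its
score series ever reaches the threshold; the first crossing is the early
prediction point (EPP) and, for true positives, `(onset − EPP)` in hours is
the early warning time (EWT). AUROC/AUPRC rank encounters by maximum score
over the scoring span — the reduction consistent with a first-crossing
classifier. EWT quartiles use linear-interpolation (type-7) quantiles.

Two alternative alerting policies are parameterized rather than asserted:

* **dual threshold** — a second, higher threshold must fire strictly after a
  first-threshold crossing and within 6 h of it (simultaneous satisfaction is
  not enough: allowing it would collapse the scheme to a single threshold at
  the higher value). The default selection takes the primary threshold from
  max-F1 and the confirmation threshold as the precision maximizer retaining
  ≥ 90% of the primary sensitivity.
* **waiting period** — a crossing counts only if the score stays at or above
  the threshold for a sustained run (default 1 h of consecutive grid
  points); the EPP is the start of the run.

A PEWS comparator evaluates the same encounter-level task from recorded PEWS
values (the scoring rubric is input data, never recomputed): a max-PEWS > 5
rule over the scoring horizon, and a daily rule (24-h interval positive iff
its max PEWS > 6, labeled by MV onset in the following 24 h).

## Risk grouping

Positive predictions are stratified by the shape of the risk trajectory over
`[EPP, EPP + 6 h]` (73 points at 5-minute resolution). Trajectories cut short
by prep/discharge are excluded from clustering but still receive a
transferred label from their last-value-padded prefix, so the groups always
partition the positive predictions. Clustering is the standard normalized
spectral recipe: symmetric binary KNN graph (edge if either point is in the
other's K-neighborhood, Euclidean distance on raw trajectories — no warping
or derivatives), symmetric normalized Laplacian, cluster count k by maximum
eigengap over k ∈ [2, 8], seeded k-means on the row-normalized spectral
embedding. Groups are ordered by mean score at EPP (low < medium < high);
test encounters get labels by majority vote among the 15 nearest training
trajectories, ties toward the higher-risk group.

**Choosing K.** A KNN graph only carries cluster structure while K is smaller
than the groups it should separate: with K at or above the group size every
point is forced to adopt out-of-group neighbors and the graph approaches
completeness. The reference value K = 200 comes from a positive set several
hundred strong (≈ n/4); the pipeline therefore defaults to
`K = min(200, max(10, n/4))`, and the 600-trajectory fixture analyses use
K = 100, below the smallest bundle's size within an 80% subsample (≈ 160).

Stability is assessed by 50 subsamples of 80% without replacement: each
subsample is reclustered with the same K and the reference k (fixing k
isolates assignment stability from model-selection variability), and each
reference cluster records its best Jaccard overlap (restricted to subsampled
points) against the subsample clusters; per-cluster means are reported.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
pediatric physiology or pharmacology. Defaults (the study conditions):
MV prevalence 1176/13651 ≈ 8.61% (a second reported figure, 8.06%, is
inconsistent with the cohort counts; the count-derived value is used),
median LOS 19.4 vs 3.1 *days* for MV vs control (the day-scale table values;
an "hours" reading elsewhere is impossible given the ≥ 12 h filters), median
age 1.2 vs 4.8 years, NIV prevalence 28.4% vs 10.7%, one observation per
vital per hour (labs daily), 0.3 medication events/h, 60 medications of
which 8 are predictive, drift lead 12 h, `signal_strength = 3`.

Planted signal in MV encounters, all scaled by `signal_strength`:
physiologic drift (respiratory rate +10·w, heart rate +12·w, SpO2 −4·w,
PEWS +4·w rounded, IV volumes ×(1+2w)) where w ramps linearly over the lead
window and scales with a per-encounter severity level in {1, 2, 3}; and
medication-sequence structure — within the 12 h pre-onset the medication
choice mixes toward the predictive subset with weight `1 − exp(−g·sev/6)`
and repeated predictive medications escalate to "rate changed" with raised
probability. Severity links trajectory shape to outcome confidence, which is
what makes the risk groups' positive predictive values ordered. A small
fraction of controls (8%) carry a brief, weak "decoy" excursion so that
false positives with decaying trajectories exist. Planted filter violators
(early MV onset, short MV, post-procedure onset, missing demographics,
tracheostomy, chronically low SpO2, absent diagnoses) exercise every
exclusion rule.

**Null-calibration contract.** Every outcome-dependent contrast — age, LOS,
NIV *and* the planted drift and medication effects — scales with
`min(1, signal_strength/3)`. At the default the Table-style marginal
contrasts are reproduced; at `signal_strength = 0` the two outcome groups
are exchangeable up to a 26-h lower bound on MV length of stay (needed so
that onset ≥ 12 h and duration ≥ 12 h fit inside the stay), and the
downstream held-out AUROC sits at chance. Without this gating the
demographic contrasts alone would be predictive and a "no-signal" cohort
would not be null.

What the generator does *not* emulate: physiologic autocorrelation beyond a
per-encounter random offset, unit/assay heterogeneity, care-process feedback
(treatment changing vitals), inter-variable correlation structure, and
realistic medication vocabularies. Passing tests on this generator
demonstrate that the pipeline recovers the kinds of structure it plants —
monotone drift, sequence motifs, severity-linked trajectories — not clinical
performance on real data.

Trajectory fixture bundles mimic the qualitative post-alert shapes seen in
practice: sustained-high (≈ 0.9), sustained-medium (≈ 0.6), and a low bundle
decaying from ≈ 0.45, with additive Gaussian noise clipped to [0, 1].

## Problem sizes used in the shipped analyses

The packaged test suite and acceptance script run the full pipeline on a
2,000-encounter cohort (Model A, 10-fold out-of-fold scoring), the
cluster-stability and recovery analyses on the 600-trajectory fixture, and
oracle-equivalence checks on 1,000 random draws each. These sizes were chosen
as the smallest at which the respective statistics are stable; the generator
scales to the full 13,651-encounter cohort for encounter-level analyses.

## Known limitations

* The default normal-range table is synthetic and must be replaced for any
  real deployment.
* The feature dictionary is ~30 variables, a compact stand-in for a full
  188-feature EHR dictionary; it is configuration, not code.
* The CNN extractor's capacity (15 filters, dim-10 embeddings) matches the
  synthetic vocabulary; real medication vocabularies (>1,000 names) would
  warrant larger embeddings and more filters.
* Exact definitions of the dual-threshold and waiting-period alerting
  variants are parameterized choices, not reproductions of a published
  procedure.
* No probability calibration is applied; the risk score is the raw class-1
  probability.
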