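# Methods

## Problem setting

Registries derive ICCC (third edition) childhood-cancer groups from
ICD-O-3 abstractions rather than coding them directly. The package
implements and compares, on synthetic corpora, the two automation
designs for assigning ICCC codes to pathology-report text — multitask
ICD-O-3 classification followed by deterministic recoding (Model 1)
versus direct 47-class ICCC classification (Model 2) — together with a
Bayes-posterior confidence score that lets the classifier abstain on
uncertain cases.

## Recoding model

A recode table is an ordered list of rules, each mapping a set of
histology values/ranges, a set of topography ranges and an optional
behavior set to one ICCC subgroup. `recode` returns the first matching
rule's subgroup and "999" (not classified / in situ) when no rule
matches, so the mapping is total over syntactically valid codes. Tables
load from CSV (`iccc_subgroup,histology_spec,site_spec,behavior_spec`,
semicolon-separated values or inclusive `lo-hi` ranges, sites as
`C40.0-C41.9` compared on the numeric value of `dd.d`). In strict mode
(the default) loading rejects tables in which two rules with different
subgroups match a common triple, which makes first-match order
immaterial.

The bundled fixture table is **synthetic**: the licensed SEER recode
table cannot be redistributed, so each of the 47 subgroups receives two
rules with disjoint histology blocks and rule-specific site ranges
(plus a realistic osteosarcoma rule, histology 9180–9187 at bone sites
C40.0–C41.9). Only behaviors 1 and 3 are mapped; in-situ (behavior 2)
triples fall through to 999, as in the real classification. The
two-rules-per-subgroup structure matters scientifically: a predicted
histology from one rule combined with a predicted site from the other
matches nothing and recodes to 999, reproducing the failure mode that
penalizes the recode pipeline when site and histology are predicted
independently. A user-supplied table in the same schema can replace the
fixture everywhere.

CCDI eligibility is the fixed set {061, 071, 081–085, 091} at ages
20–39; the published augmentation counts (total 1055) ship as reference
data.

## Synthetic corpus

Each record carries tokenized text, an age, an ICD-O-3 triple and its
ICCC labels. Class proportions default to the published childhood-corpus
frequencies (counts/29 206, 011 = 27.5%, 093 = 6 cases), so the severe
imbalance — the central difficulty of the task — is preserved. Ages are
drawn from per-main-group categorical profiles over 0–39 shaped to the
qualitative published incidence pattern (leukemia/neuroblastoma young,
lymphoma/germ-cell/epithelial adolescent, a mid-childhood dip);
subgroups inherit their main group's profile because per-subgroup age
distributions are not published. Only the four main groups containing
CCDI subgroups (renal, hepatic, bone, soft tissue) place mass on ages
20–39; their adult shares (3.0%, 2.5%, 38.5%, 8.2%) equal the published
ratio of augmentation cases to all cases of those groups.

Text is a whitespace-joined stream of `text_length` (default 50)
synthetic tokens: with probability `signal_strength` a token comes from
the subgroup's dedicated vocabulary (`t011_03`, …, `vocab_per_label`
= 20 types per subgroup), otherwise from a shared vocabulary
(`common_17`, 200 types). Tokens are deliberately non-clinical so
generated text cannot be mistaken for real reports. `signal_strength`
(default 0.9) is the single difficulty knob: 0 makes the text
uninformative, 1 perfectly separable. The ICD-O-3 triple is drawn
uniformly from the combinations of one randomly chosen rule of the
record's subgroup, which guarantees exact recode round-trip for every
record. The generator is deterministic given (config, seed), and the
TSV writer is byte-stable.

What the generator does **not** emulate: clinical language and its
ambiguity, patient-level report correlation (the real corpus had 29 206
reports from 11 274 patients), registry formatting, and any coupling
between text difficulty and class rarity beyond sample size. Passing
tests therefore demonstrate correctness of the pipeline and the
direction of its comparative findings under controlled conditions, not
expected accuracy on real reports.

## Classifier

TextCNN: learned embedding (padding row pinned to zero), parallel 1-D
convolutions of widths 3/4/5, ReLU, global max-pooling, dropout, and a
softmax decision layer; MT-CNN shares the trunk and attaches one softmax
head per task, minimizing the sum of per-task cross-entropies. Model 1
uses three heads — site, histology, behavior — the fields recoding
needs. With one task the multitask model is exactly TextCNN. The
implementation is plain numpy with Adam; a single seeded generator
drives initialization, shuffling and dropout, so training is
bit-reproducible. Argmax ties break to the lowest class index.

Published work does not state optimizer, embedding size or epochs; the
library defaults (embedding 64, 64 filters per width, dropout 0.5,
max_len 256, 10 epochs, Adam 1e-3, batch 64) follow common TextCNN
convention. The packaged study uses a desk-scale variant sized for
single-core runs: embedding 32, 32 filters per width, dropout 0.3,
max_len 50 (the generated text length), 8 epochs, learning rate 2e-3 —
chosen once for adequate capacity on 47 classes at corpus sizes of a
few thousand. No class weighting or resampling is applied; macro-F1 is
left to expose the cost of imbalance.

## Confidence and abstention

For each validation case the score is the maximum softmax probability
and correctness is recorded; priors are the relative frequencies of
correct/incorrect. Conditional likelihoods are empirical tail
probabilities: `p(y|correct)` is the survival function of the correct
stratum at the new score, `p(y|incorrect)` the survival function of the
incorrect stratum, each floored at 1e-6. (Both conditionals use the
survival direction: incorrect predictions concentrate at low scores, so
their survival decays faster and the posterior is increasing in the
score; using the CDF for the incorrect stratum would invert the
selectivity.) The posterior `p(correct|y)` follows by Bayes' theorem; a
case abstains when it falls strictly below the threshold (default 0.9,
equality assigns). `tau` (default 0) optionally trims each stratum to
its [tau, 1-tau] quantile range before the distributions are built.
`score_mode="raw"` thresholds the max-softmax score directly instead —
the published description is ambiguous between the two, so both are
exposed.

Two structural properties are worth knowing. With a perfectly accurate
validation split the incorrect prior is zero, every confidence is 1 and
nothing abstains. More generally the posterior tends to the correct
prior as the score decreases (both survivals approach 1), so when
validation accuracy already exceeds the threshold almost nothing
abstains; abstention engages exactly when the base accuracy is below
the target confidence level, and then removes the lowest-score cases
first. Calibration always uses held-out data, never training
predictions.

## Evaluation harness

Records are assigned to k folds stratified on the ICCC subgroup by a
custom dealer (per-class shuffle, one global rotating fold pointer):
overall fold sizes and per-class counts both stay within ±1 of
proportionality, and classes with fewer than k members are kept —
distributed as evenly as possible — never dropped (the real corpus has
a 6-case class under 10-fold CV, which the common library splitter
rejects outright). Training populations per scenario: 1a all ages,
1b/2a childhood only, 2b childhood plus CCDI-eligible records;
evaluation is always the fold's childhood (0–19) records. Model 1
predictions recode the independently predicted (site, histology,
behavior); inconsistent triples fall to 999 with no repair. With
abstention enabled, one extra training fold per round is carved out and
the confidence model is fitted on its childhood records (matching the
deployment population); for the multitask model the calibration score
is the product of per-task maximum probabilities. Folds are stratified
on the ICCC subgroup for all scenarios.

Metrics: per-class F1 (0 when P+R=0), micro-F1 pooled over the full
class list, macro-F1 averaged over every class present in the
evaluation truth set including never-predicted ones. Abstained cases
are excluded from the headline F1 (the retained-case scores); the same
predictions scored without exclusion are reported alongside
(`micro_f1_all`, `macro_f1_all`), so the retained-vs-all comparison is
paired by construction. Per-class retention counts and abstention rates
((cases − retained)/cases) complete the report.

## Packaged study conditions

The shipped reproduction (`icccml.study`, used by `scripts/acceptance.py`
and the acceptance tests) runs ten replicates of: a 1500-report corpus at
the default imbalanced proportions and signal 0.9, 4-fold
cross-validation, and the desk-scale CNN above — sizes chosen so a full
replicate set completes in minutes on one core while keeping ≥35
subgroups represented per corpus. Parameter recovery uses balanced
10-class corpora of 2000 reports (held-out accuracy ≥0.90 at signal 0.9;
at signal 0, accuracy within 0.05 of the majority rate). Scenario
master seeds derive from one seed via a seed sequence.

## Known limitations

* Absolute F1 values on synthetic corpora are not comparable to the
  published real-data scores; only directions and orderings are.
* The fixture recode table is far smaller than the real SEER table
  (~95 rules vs thousands) and its ICD-O-3 label space (~1000 observed
  site/histology values) correspondingly coarser.
* The empirical-survival likelihoods are step functions; with small
  calibration strata the confidence takes few distinct values, making
  the abstention fraction a coarse function of the threshold.
* Each report is independent; there is no patient-level clustering, so
  cross-validation leakage through near-duplicate reports — a real
  registry concern — is out of scope.
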