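# Methods

## The problem

Single biomarkers from a signature — a protein panel in a case/control
assay, or a cell-type gene signature in single-cell RNA-seq — are often
individually unspecific: a gene that marks NK cells may also be highly
expressed in CD8+ T cells or dendritic cells. `panelroc` refines a
signature into small marker *combinations* whose joint positivity pattern
discriminates better than any member alone, and turns the selected
combinations into portable logistic classifiers.

The pipeline has four stages, all operating on a *marker table*: one row
per sample (or cell), an ID, an optional two-level Class, one numeric
signal column per marker.

## 1. Global signal threshold

All markers' signals are pooled into a single case pool and a single
control pool, and an exact empirical ROC is traced over candidate
thresholds.  Candidates are the midpoints between consecutive distinct
pooled values plus one sentinel below the minimum and one above the
maximum.  With the strict positivity rule *positive ⇔ signal > t* this grid
realises every attainable (SE, SP) operating point exactly, makes SE/SP
step functions reproducible, and is shift-equivariant (adding a constant to
all signals shifts every candidate, hence the suggestion, by that
constant).  SE(t) is the fraction of case values above t; SP(t) the
fraction of control values at or below t; the Youden index is
J(t) = SE + SP − 1.

Two suggestion rules are implemented, because both are defensible readings
of "the threshold at which SE and SP meet their user minima":

* `median_of_qualifying` (default): the median of all candidate thresholds
  with SE ≥ min_SE and SP ≥ min_SP;
* `max_youden_qualifying`: the qualifying threshold with maximal J.

`min_SE = min_SP = 0` defaults are kept, which makes the median rule
degenerate to the median of *all* candidate thresholds — documented, and a
reason to prefer the max-Youden mode (or nonzero minima) when no external
guideline fixes the threshold.  When the two modes disagree by more than
one grid step the discrepancy is logged.  An unsatisfiable constraint set
raises an explicit error; there is no silent fallback.

Per-class Gaussian KDE curves (Silverman bandwidth, shared grid padded by
three bandwidths) are provided for the usual overlapping-distributions
plot.  They are presentation-only and never feed the suggestion.

## 2. Exhaustive combination scoring

Every combination of 1..`max_length` markers is enumerated — ascending
length, lexicographic within length over alphabetized marker names, IDs
1..N in that order.  The order is a convention of this package: combination
IDs from other software follow different (undocumented) enumeration orders,
so combinations must be compared by member sets, never by ID.

A sample is positive for a combination when at least `combithr` (default 1)
of its members exceed `signalthr` strictly.  Equality at the threshold is
*not* positive; the same strict convention is used in the threshold finder,
the score cutoff (below), and the signature score.  SE is the positive
fraction among cases, SP the negative fraction among controls; combinations
are ranked by J descending with ties broken by shorter length then smaller
ID.  The per-marker binarization is computed once; combinations are scored
in a streaming pass (no all-combinations × all-samples mask is ever held).
30 markers at max length 5 is 174,436 combinations and takes seconds.

## 3. Per-combination logistic model and combi-score

For a selected combination, class is regressed on the member signals with a
binomial GLM: f(x) = β₀ + Σ βᵢxᵢ, p(x) = 1/(1+e^(−f(x))).  Fitting is
statsmodels IRLS with a 25-iteration cap and deviance tolerance 1e-8 —
conventional defaults for an unpenalized logistic fit.  Complete separation
is detected (|coefficient| > 100, or all fitted probabilities within 1e-6
of {0,1} — the band must be looser than the deviance stopping tolerance,
which halts iteration while probabilities are still ~1e-9 from the
boundary) and flagged; coefficients are reported as fitted with no silent
regularization, so the user sees the pathology instead of a masked one.

The training scores give a ROC and its trapezoidal AUC.  Coordinates are
integrated in threshold order: along ascending cutoffs both TPR and FPR are
non-increasing, so the sequence already traces the curve and tied-FPR
vertical segments stay intact; the resulting area equals the Mann–Whitney
concordance probability with ties counted ½ (verified against
`scipy.stats.mannwhitneyu` to 1e-10 in the tests).

The *optimal cutoff* is the candidate probability (midpoints between
consecutive distinct scores) minimizing training misclassifications under
"predict case ⇔ p(x) > cutoff"; ties go to maximal Youden, then the lowest
cutoff.  These tie-breaks are arbitrary but fixed, so results are
reproducible.  New samples get a *combi-score* p(x) and class
C(x) = 1 if p(x) > cutoff, 0 if p(x) ≤ cutoff (a score exactly at the
cutoff is class 0).  Classification against ground truth is summarized by
confusion counts, precision, recall, F1 (of the case class) and accuracy;
when cluster labels are supplied, the per-cluster median combi-score is
exported.  Multiple selected combinations yield one score set per model; no
ensemble is formed.

## 4. Harmonization and the signature score

Expression matrices (10x MTX triplets — densified only for the requested
genes — or dense gene×cell text) are harmonized into marker tables:
min-max rescaling to [0, 10], subsetting to the alphabetically ordered
signature genes, transposition so cells become rows, and optional Class
assignment from cell annotations (annotation == case label → case, all else
→ control).  Scaling is **global** (one min/max over the whole matrix,
computed before subsetting) by default: the positivity rule compares
markers against one shared threshold, so preserving relative gene
magnitudes matters; per-gene scaling is available as an option for
workflows that want each gene to span the full range.  Genes requested but
absent from a matrix are dropped with a warning (models whose members are
missing refuse to score, listing the absentees).

The per-cell gene-signature score for a gene set G is

    score_c = (k_c / |G|) · Σ_{g∈G} x_gc,   k_c = |{g ∈ G : x_gc > thr}|

with expressed-threshold 0 by default.  The score is directly proportional
to the number of expressed signature genes and to their summed expression;
a cell expressing no signature gene scores exactly 0.  This product form is
this package's concrete definition of that two-proportionality principle
and sits behind one function so an alternative arithmetic can be swapped
in.

## Synthetic data: what it emulates and what it does not

`generate_two_class_table` draws log-normal signals (non-negative,
right-skewed, like assay intensities): baseline arithmetic mean 100, sd 25,
10 markers, 100 samples per class by default.  Planted markers gain a
location shift `effect` (default 100 = 4× the noise sd) in the case class,
in one of two geometries:

* **uniform** (default): every case sample's planted markers are shifted.
  Each planted marker is then individually near-sufficient, and with
  combithr=1 the Youden-optimal "combination" is typically a single planted
  marker — unions add little SE and multiply away SP.
* **complementary**: each case sample elevates exactly one planted marker
  (round-robin).  No single marker covers the cases, so the full planted
  set is the genuinely optimal combination.  This is the regime a
  combinatorial panel search exists for, and the one used by the recovery
  study.

`generate_expression_fixture` builds the annotation-transfer scenario: a
target cluster (150 cells) elevates all 12 signature genes to mean 6, a
confounder cluster (300 cells) elevates a 3-gene overlapping subset to the
same level, 150 other cells stay at baseline 1; Gaussian noise (sd 1),
truncation at 0, and 20% independent dropout.  The confounder outnumbers
the target so each overlapping gene's target-vs-rest AUC stays below 0.7
while the non-overlapping genes support a near-perfect combination.

Neither generator models library-size variation, negative-binomial counts,
batch effects or doublets; passing tests show the pipeline's statistical
machinery behaves as designed, not that any particular real dataset will
yield panels of a given quality.

## Validation studies (`panelroc.studies`)

Problem sizes are chosen so the whole battery runs in seconds on one CPU:

* **planted recovery** — 100 replicates, complementary mode, n=200/class,
  effect 4×sd, threshold auto-suggested (max-Youden mode; the median rule
  at 0/0 minima is its documented degenerate form and not a usable
  operating point), max length 3.  Measures how often the top-ranked
  combination contains all planted markers (~97% under these conditions).
* **null calibration** — one seeded zero-effect dataset, threshold at the
  pooled median (a neutral operating point; a Youden-maximizing threshold
  on null data would inflate the statistic by construction).  The
  within-dataset max |J| over all 175 combinations is reported; 0.15 is
  ~3× the binomial sd of a single Youden statistic at n=200/class, and the
  maximum over combinations exceeds it for roughly 1 seed in 20.
* **coefficient recovery** — logistic data simulated at n=5,000 from known
  (β₀, β₁, β₂); estimates should land within 3 standard errors.
* **overlap transfer** — train on one expression fixture, score an
  independently generated one with the top combination's model; reports
  per-overlap-gene AUC and held-out F1.

## Known limitations

* One global signal threshold for all markers (by design; no per-marker
  thresholds).
* Exhaustive enumeration only: cost grows as Σ C(n,k); beyond ~30 markers
  at max length 5, expect minutes rather than seconds.
* Unpenalized logistic fits: separated fits are flagged, not repaired; use
  the flags before trusting coefficients.
* The score cutoff optimizes raw misclassification count, which is
  sensible for balanced training classes; heavily imbalanced training data
  may warrant class-weighted selection, which is not implemented.
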