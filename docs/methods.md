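# Methods

## Standardization and deduplication

Input structures are normalized before anything else sees them:

1. water fragments (`O`, hydroxide, hydronium) are dropped; of the
   remaining fragments the largest *organic* one (most heavy atoms,
   carbon-containing preferred) is kept, so salts and mixtures reduce
   to their parent compound;
2. aromaticity is perceived on sanitization;
3. adjacent opposite formal charges are collapsed into an incremented
   bond order (e.g. an S⁺–O⁻ sulfoxide zwitterion becomes S=O), but
   only where the resulting valence is legal — a nitro group, whose
   neutral form would need pentavalent nitrogen, passes through
   unchanged with a warning;
4. hydrogen bookkeeping is normalized into the canonical SMILES's
   implicit-H counts.

The standardized structure gets an InChIKey, which drives duplicate
removal: first occurrence wins, and any InChIKey appearing under
*conflicting* taste labels is removed entirely — a structure labeled
both sweet and bitter cannot be trained on. Standardization is
idempotent, so re-processing a processed dataset is a no-op.

Tautomer canonicalization and stereochemistry repair are deliberately
out of scope; InChIKey-based deduplication already collapses most
tautomer pairs, and the fingerprints used here are 2-D.

## Fingerprints

Four binary encodings: Morgan (circular, radius 2, 2,048 bits —
radius 2 being the community's ECFP4-equivalent default), a
pharmacophoric-invariant Morgan variant (same radius and width, atom
environments described by donor/acceptor/aromatic/... roles instead of
element identities), hashed atom pairs (1,024 bits) and topological
torsions (1,024 bits). Hash collisions fold with OR semantics —
strictly binary presence/absence, no counts. Fingerprints are computed
on the standardized heavy-atom graph with implicit hydrogens; they are
invariant to SMILES atom ordering.

Tanimoto similarity is |A∩B|/|A∪B| over on-bit sets, defined as 1.0
for two empty fingerprints (identical all-zero encodings).

## Classifier

`RandomForestClassifier` with 1,000 trees, Gini impurity, √d features
per split, bootstrap sampling, fixed seed. 1,000 trees is past the
point of diminishing returns for this feature width; the only cost of
more is runtime. Class scores are soft votes (mean of per-tree class
probabilities), giving a continuous confidence in [0, 1] that
thresholds cleanly at 0.60/0.75/0.95; hard vote fractions are available
as a config option and recorded in the model bundle. An exact 0.5 tie
is assigned to bitter, deterministically — in taste data bitter is the
larger class, making it the lower-risk default call.

The stratified 80/20 split draws per-class test counts as
`round(0.2 · class size)` (round-half-even). Leave-one-out
cross-validation is the documented evaluation mode for datasets of a
thousand compounds; stratified 10-fold is the fast alternative for
anything larger, and is what the bundled benchmark uses.

**A note on LOO at small n:** leave-one-out on a small balanced
two-class set is pessimistically biased — removing one sweet molecule
leaves training data tilted 29-vs-30 toward bitter, nudging every
held-out score toward the wrong class. On signal-free data at n = 60
this pushes LOO AUC well below 0.5 (≈ 0.35 in our measurements) without
any real signal being present. Null-control checks therefore use
stratified k-fold, which keeps folds balanced.

The model bundle (joblib archive) carries a JSON metadata document
(config, seed, classes, class counts, format version) plus the pickled
ensemble and the training fingerprint matrix — the latter so that
applicability-domain assessment needs nothing but the bundle.

## Metric panel

All threshold metrics derive from the confusion counts for a chosen
positive class; a full evaluation reports both class perspectives
(sensitivity for sweet-positive equals specificity for
bitter-positive). Undefined ratios (zero denominators) are NaN, never
silently 0. Sensitivity is TP/(TP+FN) — the true-positive rate. NER is
the non-error rate, the mean of sensitivity and specificity. Cohen's κ
uses chance agreement from the marginal products. ROC-AUC is computed
by the midrank Mann–Whitney formula, which equals trapezoidal
integration of the empirical ROC curve exactly, ties contributing ½.
Reports store fractions; percent formatting is presentation-layer only.

## Feature discrimination

Per Morgan bit: relative frequency in each class; the Bayesian
probability P(class | F) as a pure ratio of carrier counts (no
smoothing by default — a smoothing pseudocount is available but off,
since the score is meant to be a plain ratio; bits with zero carriers
have *undefined* probabilities, kept as NaN). The active-feature rule
uses strict inequalities — frequency above the own-class average
relative frequency *and* below the other class's average; equality is
inactive. Top-k ranking is by own-class frequency descending, ties to
the lower bit index; the Bayesian score is reported alongside but is
not the sort key. Feature-pair dissimilarity is 1 − Pearson r of two
features' class-score vectors, exposed generically over equal-length
vectors (the composition of the score vector is the caller's choice);
zero-variance vectors raise rather than fabricate a correlation.

Circular bits are inverted to substructures through the generator's
bit-info map: every (center, radius) environment hashing to the bit is
rendered as a fragment SMILES with its atom indices, which is what
links a discriminative bit to actual chemistry.

## Applicability domain and screening

AD score = maximum Tanimoto to any retained training fingerprint,
default cutoff 0.25 max-Tanimoto — a permissive, widely used choice,
always echoed in the report and configurable. AD is advisory:
out-of-domain queries are predicted and flagged, with confidence
thresholds doing the hard filtering in batch screens. Screen summaries
count predictions at or above the cutoff per class, with fractions over
the *whole* library; a threshold sweep re-thresholds one prediction
pass, so retained counts are non-increasing by construction.

## Synthetic fixtures

The generator emulates the statistical shape of curated taste data —
two classes of valid, distinct, drug-like molecules with
class-enriched substructure motifs — without any of its chemistry
being real. Molecules are random scaffolds (benzene, cyclohexane,
pyridine, furan, thiophene, THF, piperidine, chains) decorated with
1–3 random substituents from a 14-fragment vocabulary; the sweet motif
is a sulfonamide (saccharin's family), the bitter motif a quinoline
(alkaloid-like), both attached by a single bond at a random H-bearing
site. Distinctness is enforced by InChIKey with bounded retries;
generation is byte-deterministic per seed.

Motif planting is *symmetric contamination*: each molecule carries its
own class's motif with probability `motif_purity` and the other
class's motif with probability `1 − motif_purity`, independently. This
makes purity the single signal dial with two exact endpoints: purity
1.0 is perfectly separable, purity 0.5 makes the class-conditional
structure distributions identical — a true permutation null, so
cross-validated AUC must sit at 0.5 up to sampling noise. Defaults
(300 molecules/class, purity 0.9) are the package's standard benchmark
conditions: large enough for stable CV estimates on one CPU, impure
enough that the task is non-trivial.

One consequence, worth knowing when interpreting the feature analysis:
at purity 0.9 a motif-*interior* bit appears in ~10% of the other
class, which is above the per-bit average frequency (~0.02), so such
bits fail the strict active-feature rule; the bits that *are* active
are the attachment-context environments spanning the motif–scaffold
junction, which dilute across scaffolds and stay rare in the other
class. Motif recovery is therefore checked as: a top-10 active bit has
an atom environment sharing at least one atom with the planted motif.
Each record carries its motif match's atom indices in `meta` to make
that check exact.

What passing on these fixtures does **not** show: real taste data has
correlated features, activity cliffs, class imbalance and label noise
that no planted-motif generator reproduces; results here validate the
machinery (formulas, determinism, signal recovery, null behavior), not
taste-prediction accuracy on real chemistry.

The confusion-case generator produces random label/prediction/score
vectors (12–100 entries, both classes guaranteed, every tenth case a
perfect classifier) together with independently loop-counted confusion
cells, as ground truth for the metric panel.

## Numerical choices

- Exact-equality contracts (frequencies, Bayesian ratios, confusion
  counts) are integer-arithmetic-backed and compared bitwise.
- Rank-AUC vs trapezoidal integration agree to < 1e−12; Cohen's κ
  computed under different association orders of the chance term can
  differ by one ulp.
- Class scores sum to 1 within 1e−9 (they are normalized tree-vote
  means).
- Degenerate inputs fail loudly: water-only structures, single-class
  training sets, zero-variance correlation inputs, off-bit
  substructure queries, unsorted threshold lists all raise.

## Problem sizes

The bundled benchmark uses 300 molecules/class with 10-fold CV for the
1,000-tree forest (~1 minute end to end), 30/class for the null
control, and 100/class for screening libraries — sizes chosen so the
full reproduction script completes in a few minutes on a single CPU
while keeping CV estimates stable. LOO remains available and tested at
small n.
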