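# Methods

This note documents the models, numerical choices, and limitations of
`phagenn`, in the order data flows through the pipeline.

## Sequence handling

Sequences are upper-cased; `*` and `-` are stripped. Three ambiguity
policies exist: `strict` (any non-canonical letter is an error),
`drop-ambiguous` (the record is skipped with a warning), and the default
`map-ambiguous` (B→D, Z→E, U→C, J→L; X is retained). X is treated as
"unknown residue" everywhere downstream: k-mer windows containing X are
excluded from both the numerator and the denominator of the frequency
computation, the physicochemical features are computed on the X-free
sequence, and only the length feature counts X. The default maximizes
usable data, which matters for real corpora where rare ambiguity codes
are common; `strict` exists for controlled tests.

Class labels can come from description-term matching (case-insensitive
substring, a record matching terms of two classes stays unlabeled), but
the canonical path is an explicit `id<TAB>class` table, because curation
of real corpora is a manual process that term lists only approximate.

## Features

All k-mer blocks use overlapping windows and are normalized by the
number of valid windows, so each block of a sequence of length ≥ k sums
to exactly 1; sequences shorter than k get an all-zero block with a
warning rather than an error, to tolerate very short ORFs. Feature order
within a block is lexicographic in the k-mer string.

The reduced side-chain alphabet maps the 20 amino acids onto 7 chemical
groups. The default partition is aliphatic {A,V,L,I}, aromatic {F,W,Y},
basic {K,R,H}, acidic {D,E}, polar amide/hydroxyl {S,T,N,Q}, sulfur
{C,M}, conformationally special {G,P}. The alphabet is injectable — any
total 7-group mapping preserves every dimensionality (49/343/2,401) —
so an alternative grouping can be dropped in without touching anything
else.

The "extra" block has exactly 8 features. The naming in the literature
sometimes lists hydrophobicity and GRAVY separately, but the model
arithmetic (8,000 + 2,401 + extras = 10,409 for `tetra_sc_tri_p`)
forces 8, and GRAVY *is* mean Kyte–Doolittle hydropathy, so they are one
feature here. The features are computed with Biopython's ProtParam
(average residue masses; Henderson–Hasselbalch bisection for the
isoelectric point; the Guruprasad DIWV table for the instability index;
extinction coefficients 5,500·nW + 1,490·nY, plus 125 per cystine pair,
counting floor(nC/2) pairs since a disulfide bond needs two cysteines).
Relying on one widely used, versioned implementation keeps these
constants consistent and externally auditable.

Feature vectors are extracted raw; standardization is a training-time
concern (below), so that a stored feature matrix is independent of any
particular split.

## Pairwise identity and clustering

Identity between two sequences is matched columns divided by alignment
length, on a global alignment scored match +1, mismatch 0, affine gaps
open −10 / extend −0.5 (Biopython `PairwiseAligner`). The scoring only
shapes the alignment. Two consequences worth knowing:

- The heavy gap-open cost prevents alignments of *unrelated* sequences
  from scavenging spurious matches through scattered gaps; random
  same-composition protein pairs score ~0.1–0.25 identity rather than
  ~0.3 as under unit-cost edit alignments.
- Near sequence ends, a single-residue indel can be cheaper to absorb
  as a short run of mismatches than as a gap, so observed identity of
  genuinely homologous short sequences can dip below the substitution
  identity by up to ~10/L. Family members in the synthetic corpus
  therefore occasionally show ~0.6 identity at L≈60 despite ~0.9
  design identity — still far above the 0.40 clustering threshold.

This denominator (alignment length) differs from CD-HIT's convention
(shorter-sequence length); on the gap-free, length-matched families the
synthetic generator produces, the two agree. A `identity_at_least`
shortcut skips the alignment when the length ratio alone caps identity
below the threshold.

Clustering is greedy and incremental in the CD-HIT style: sequences
sorted by descending length (ties by id), each joining the first
existing cluster whose representative it matches at ≥ threshold, else
founding a new cluster. Representatives are therefore the longest
members. Greedy clustering does not guarantee that two members of
*different* clusters are below threshold on adversarial near-threshold
chains; the pipeline's no-leakage guarantee is stated — and verified
exhaustively — on corpora whose identity structure has a wide gap
around the threshold, which the synthetic generator enforces.

## The split

Per class: cluster at 40% identity → shuffle clusters with a seeded
generator and deal them round-robin (from a seeded random starting set)
into 11 subsets, so per-set cluster counts differ by at most one →
expand each subset by replacing representatives with their full
clusters. Subsets are then merged across classes into 1D–10D and TEST,
and byte-identical duplicates are removed, keeping the earliest
occurrence by (set order, id order) — the tie-break is a convention, any
fixed rule preserves the no-leakage property. Balance is by cluster
count, not expanded sequence count; "equal size" is ambiguous and
cluster count is the quantity the dealing controls directly.

The background corpus is first purged of cross-homologs: background and
class sequences are co-clustered at 60% identity and any background
sequence sharing a cluster with a class sequence is dropped. Then the
background is split exactly like a class.

With `expand=False` only representatives are retained (the unexpanded
baseline for measuring the effect of cluster expansion).

An audit table records, per class, the raw count, the cluster count
(the 40% dereplication), and the retained count after expansion and
100% dereplication.

## Networks and training

Each ensemble member is a multilayer perceptron: input → 200 ReLU → 
dropout 0.2 → 200 ReLU → dropout 0.2 → softmax over the class list.
Loss is categorical cross-entropy with per-class weights
w_c = N/(K·n_c) (inversely proportional to class size, mean 1 for
balanced data). The implementation is plain numpy with inverted dropout
and Adam (lr 1e-3, β₁ 0.9, β₂ 0.999); the networks are small enough
that batched matrix products dominate and one CPU suffices, while every
numerical choice stays explicit and seed-reproducible.

Training runs in minibatches of 256 for at most 200 epochs, stopping
when the *training* loss has not improved for 10 consecutive epochs;
the parameters kept are those of the epoch with the lowest *validation*
loss. Monitoring training loss for patience while selecting on
validation loss is unusual but intentional — both rules are part of the
method being implemented. Each fold fits its own per-feature z-score
standardizer on its training matrix only (k-mer frequencies and
physicochemical features differ by orders of magnitude in scale);
constant features pass through centered. Weight init is He-normal.

Cross-validation: fold *i* validates on set *i*D and trains on the
other nine; TEST is never touched by training or standardization. One
master seed fans out per-fold seeds through a seeded generator.

## Scoring and calibration

The ensemble score of a query is the per-class sum of the 10 members'
softmax outputs: each score is in [0, 10] and the scores sum to 10.
Classification is arg-max with ties broken by class-list order; an
optional abstain threshold maps sub-threshold maxima to
"not classified".

The confidence table is built on TEST: for class c and threshold s,
confidence(c, s) is the fraction of test queries predicted as c with
score ≥ s whose true class is c. Thresholds are a fixed 0–10 grid at
step 0.1 plus every observed score; grid points above the highest
observed score carry the nearest lower defined value and a sparse-data
flag; a class never predicted in calibration is flagged whole. At the
lowest threshold the confidence equals the per-class precision on TEST
— an identity the tests assert exactly. Lookup uses the largest
tabulated threshold not exceeding the query's score.

Evaluation reports per-class precision/recall/F1/support, macro and
support-weighted averages (weighted recall equals accuracy), the
confusion matrix (optionally row-normalized), and one-vs-rest ROC on
the per-class score divided by the member count. At a score cutoff s,
queries below s are excluded and the retained fraction is reported —
computed over all queries, not per class. Metric computation uses
scikit-learn; the tests check it against a direct counting oracle.

## Synthetic corpora

The generator emulates the two statistical properties the pipeline
assumes of real corpora: classes are unions of homologous families, and
classes differ in residue composition.

- Background residue frequencies are mildly non-uniform (common
  residues like L/A/G enriched, W/C rare), fixed across seeds.
- Class profiles tilt the background: profile_c ∝ background ·
  exp(strength · g_c), g_c a standard-normal draw per class. Strength
  defaults to 1.0 (preferences differing by factors of ~e^±1 — strong
  but not degenerate signal); at strength 0 every class equals the
  background, the negative-control condition. Tilts are redrawn until
  the profile concentration (Σp², the per-column match probability of
  unrelated sequences) stays ≤ 2.2× the background's, so a "bias"
  shifts preferences without collapsing the profile onto a few residues
  and making unrelated sequences of one class look spuriously
  homologous.
- Families: an ancestor drawn from the class profile; each member
  substitutes an exact fraction of sites (substitutions drawn from the
  profile, never the original residue) plus single-residue indels at
  0.01/site. `within_family_identity` (default 0.90) is the expected
  *pairwise* identity between members, so each member diverges from the
  ancestor by half the complementary rate; exact counts (rather than
  binomial draws) keep divergence controlled.
- Ancestors are rejection-sampled until ≤ 0.25 identity to every
  previously accepted ancestor across all classes (cap 200 attempts,
  then an error suggesting longer sequences or fewer families). The
  resulting gap — ~0.9 within families, ≤0.25 between, with the 0.40
  clustering threshold in between — is what makes the split's
  no-leakage property exhaustively verifiable.
- Defaults: 11 classes (the last is the background), 11 families per
  class (one per cross-validation set, so every set receives every
  class), 4 members per family (484 sequences), lengths 80–600.

The signal is composition-level, not motif-level, by design: the
classifier's features are composition-based, so the generator plants
exactly the signal the model can detect, making recovery a fair
positive control. What the generator does *not* emulate: real phage
protein length distributions per class, motif- or structure-level
signal, annotation noise, and the extreme class imbalance of real
corpora. Passing the recovery controls therefore shows the pipeline is
correctly wired and can learn compositional signal under honest
homology separation — not that real-corpus accuracy will match.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale,
as the package's own test conditions: recovery controls on the
484-sequence default corpus with the 57-feature `di_sc_p` model (the
composition signal lives at residue level, so the smallest model with
the extras block is the appropriate probe); the exhaustive no-leakage
check on a 242-sequence corpus (two members per family). Every source
of randomness — corpus generation, partitioning, weight initialization,
minibatch order, dropout — flows from explicit integer seeds, and
fixed seeds reproduce results to the byte (corpora, splits) or to
floating-point equality on one platform (network predictions).

## Known limitations

- Greedy clustering order-dependence: identity to the *representative*
  defines membership, so borderline members of elongated families can
  found their own cluster. Harmless for splitting (more clusters only
  tightens separation) but cluster counts are not canonical.
- The confidence table is only as good as TEST is large; per-class
  precision from a few dozen test queries carries wide uncertainty that
  the table does not quantify (sparse bins are flagged, not smoothed).
- The identity definition penalizes terminal indels on short sequences
  (see above); users clustering real corpora at tight thresholds should
  prefer the CD-HIT adapter convention they are calibrated to.
- Training is single-threaded numpy; fine for feature models up to a
  few hundred inputs and corpora up to tens of thousands of sequences,
  slow for the 10,409-feature production model on very large corpora.
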