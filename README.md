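# phagenn

Classification of phage virion (structural) proteins from amino-acid
sequence alone. Given a protein, `phagenn` scores it against ten phage
structural classes — Major capsid, Minor capsid, Baseplate, Major tail,
Minor tail, Portal, Tail fiber, Tail sheath, Collar, Head-Tail joining —
plus a background class "others", using an ensemble of feed-forward
neural networks over sequence-composition features.

It is aimed at phage genome annotation: most ORFs in a phage genome have
no detectable homolog with a useful annotation, but virion proteins have
distinctive amino-acid composition that a fast alignment-free classifier
can exploit.

## Method

**Features.** Each protein is summarized by overlapping k-mer frequency
vectors over two alphabets — the 20 canonical amino acids (2-mers: 400
features; 3-mers: 8,000) and a reduced 7-group "side-chain" alphabet
(2-mers: 49; 3-mers: 343; 4-mers: 2,401) — plus 8 physicochemical
features (isoelectric point, instability index, length, aromaticity,
molar extinction coefficient under reduced and disulfide assumptions,
GRAVY hydropathy, molecular weight). Twelve named feature models combine
these blocks; the full model (`all`) has 11,201 features and the default
production model (`tetra_sc_tri_p` = amino-acid 3-mers + side-chain
4-mers + extras) has 10,409.

**Homology-aware split.** Honest evaluation requires that homologous
proteins never straddle a train/test boundary. Each class is clustered
at 40% identity (greedy incremental clustering with global-alignment
identity), cluster representatives are randomly dealt into 11 equal
subsets, and each subset is *expanded* by replacing every representative
with its whole cluster — keeping all sequence diversity while confining
every homologous family to one subset. The merged subsets form the
cross-validation sets 1D–10D and TEST; identical sequences are removed,
and background sequences ≥60% identical to any class sequence are purged
first.

**Ensemble and score.** Ten networks (two ReLU hidden layers of 200
units, dropout 0.2, softmax output over the 11 classes, class-weighted
cross-entropy) are trained in 10-fold cross-validation over 1D–10D. A
query's score for class *c* is the **sum of the ten softmax outputs**
for *c*: scores lie in [0, 10], sum to 10 across classes, and the query
is assigned the arg-max class. A per-class **confidence table**, built
on TEST, converts a score *s* into the empirical precision among test
queries predicted as that class with score ≥ *s*.

Everything is testable offline: a synthetic-corpus generator produces
labeled protein families with controlled within-family identity (~0.9),
controlled between-family divergence (≤0.25), and class-specific
composition biases, plus an unbiased background class.

## Worked example

```bash
# 1. a synthetic corpus: 11 classes x 11 families x 2 members
phagenn simulate --out-fasta corpus.fasta --out-labels labels.tsv \
    --families-per-class 11 --members-per-family 2 --seed 3
# wrote 242 sequences to corpus.fasta

# 2. homology-aware split (cluster at 40%, expand, dedup, purge at 60%)
phagenn split corpus.fasta labels.tsv --out-manifest split.tsv \
    --out-audit audit.csv --seed 5
# wrote split of 242 sequences to split.tsv

# 3. train the 10-member ensemble, calibrate confidence on TEST
phagenn train corpus.fasta labels.tsv split.tsv --model di_sc_p \
    --out-bundle bundle --hidden-width 32 --max-epochs 60 --seed 7

# 4. score sequences
phagenn predict corpus.fasta bundle --out pred.csv
```

`pred.csv` has one row per query with the predicted class, its ensemble
score, its calibrated confidence, and all 11 per-class scores (which sum
to 10):

```
id,predicted_class,score,confidence,score_Major capsid,...
c01_f1_m1,Major capsid,2.683851743930859,,2.683851743930859,...
```

Evaluating the TEST rows of this run:

```
cutoff 0.0  retained 1.000  n 22  accuracy 0.864  weighted F1 0.84
cutoff 5.0  retained 0.409  n 9   accuracy 1.0    weighted F1 1.0
```

Read: over the 22 held-out test proteins (no family shared with
training), 86.4% are classified correctly; restricting to queries whose
top score reaches at least 5 of 10 keeps 41% of them and classifies all
of those correctly. That score-filtering trade-off — coverage for
precision — is the intended way to use the scores on real genomes.

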