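# Methods

## Model

The predictor treats drug repositioning as bipartite link prediction:
given gold-standard drug–disease treatment associations, score every
unobserved (drug, disease) pair. The score is the decision function
of a soft-margin SVM over a *pairwise Kronecker kernel*

    k((d, q), (d', q')) = K_dr(d, d') · K_di(q, q'),

the product of a drug-kernel entry and a disease-kernel entry. The
construction encodes the working assumption that a pair resembles a
known association only when the drug resembles a treating drug *and*
the disease resembles the treated disease. If both factors are
positive semidefinite, so is the pair kernel (it is a principal
submatrix of the Kronecker product), which keeps the SVM dual convex.

### Drug kernels

* **Chemical / side-effect** (`profile_similarity`): weighted cosine
  over binary profiles. Weights `wₖ = exp(−hₖ²/(d·σ²))` down-weight
  frequent features; with all features equally frequent (σ = 0) the
  measure degrades gracefully to the plain cosine. The output is a
  Gram matrix of rescaled, normalized vectors, hence PSD with unit
  diagonal and values in [0, 1] for binary input.
* **Target** (`target_set_similarity_matrix`): best-match (max)
  normalized Smith–Waterman score over the cross pairs of two drugs'
  target sets, then diagonal normalization `K_ij/√(K_ii K_jj)`. The
  max aggregator reflects "shares one very similar target"; a `mean`
  aggregator is available. Best-match aggregation is not a valid
  kernel in general, hence the explicit spectral repair downstream.
* **Comb**: unweighted arithmetic mean of the three (weights
  configurable). A convex combination of PSD matrices is PSD; the mean
  keeps all sources on their common [0, 1] scale.

### Disease kernel

A phenotype semantic-similarity matrix is consumed precomputed (the
text-mining pipeline that produces it is out of scope). It is
symmetrized on read (tolerance 1e-6, absorbing text rounding) and
spectrally repaired.

### PSD repair

`psd_repair` clips negative eigenvalues to zero and reconstructs —
the Frobenius-nearest PSD matrix. Applied by default to every drug
kernel after fusion and to the disease kernel; it is a no-op when the
smallest eigenvalue is ≥ −1e-8. The repair is configurable off for
solvers that tolerate indefinite Grams.

## Training protocol

Unlabeled pairs vastly outnumber positives, so each training set is
*balanced*: all training positives plus an equal number of pairs
drawn uniformly without replacement from (drug × disease) minus
positives minus any excluded (held-out) pairs. The penalty C is
chosen per training set by grid search over the odd powers
2⁻⁵ … 2¹⁵ with stratified 3-fold inner CV on AUC, ties toward
smaller C (flatter models). The SVM itself is libsvm
(scikit-learn `SVC`) on the precomputed pair-Gram; Gram blocks are
materialized lazily per pair list — the full Kronecker Gram over all
pairs is never built.

## Evaluation protocols

* **10-fold CV** over labeled pairs: the global labeled set
  (positives + one balanced negative draw) is split into stratified
  folds, so the test folds partition it and every labeled pair is
  tested exactly once. Training negatives are redrawn per fold
  (`resample_per_fold=True`), always excluding the held-out fold's
  pairs, so nothing scored was trained on. The CV unit is the pair:
  a drug seen in training can reappear in test with another disease —
  this protocol measures interpolation on the known network, which is
  why the complementary LODO protocol exists.
* **Leave-one-drug-out**: for each drug, every pair involving it is
  excluded from training (positives and candidate negatives alike);
  the model then ranks all of that drug's diseases. Per-drug AUCs are
  macro-averaged; a pooled micro-AUC over all held-out scores is also
  reported since the two can differ. Drugs whose positives cover
  every disease are skipped (no negatives to rank against).
* **Thresholded metrics** are reported at the F-maximizing cut over
  all unique scores, F-ties broken toward higher sensitivity (recall
  is what a repositioning screen cares about). Cuts with no predicted
  positives are skipped (precision undefined).
* **Trivial-prediction filter**: a positive (d, q) is removed when
  another positive (d', q) exists whose drug has a target with
  normalized sequence similarity ≥ 0.8 (default) to one of d's
  targets — such associations are predictable from shared targets
  alone. Removal is deterministic: an edge goes exactly when a
  conflicting positive with a lexicographically smaller drug id
  exists, so on a mutually trivial pair the smaller drug's edge
  survives and conflict chains resolve without order dependence.

## Synthetic benchmark

The generator plants the structure the method presumes: `n_classes`
latent classes over drugs and diseases; same-class drugs are
bit-flipped copies (`bit_noise`) of a class prototype fingerprint and
side-effect profile and carry point-mutated copies
(`mutation_rate`) of a class prototype protein; the phenotype matrix
is a block matrix (`pheno_within`/`pheno_between`) plus symmetric
Gaussian noise, clipped to [0, 1]; associations are Bernoulli with
`assoc_prob_within` on matching classes and `assoc_prob_between`
otherwise. Everything is a deterministic function of the seed, and
the written file bundle is byte-reproducible.

Defaults: 60 drugs, 40 diseases, 4 classes, 200 chemical + 100
side-effect features at prototype density 0.3, bit noise 0.1,
120-residue targets (1–3 per drug) at 5% mutation, associations
0.5/0.02, phenotype blocks 0.7/0.2 with 0.05 noise. Sized so that the
complete evaluation stack (four 10-fold CVs with full inner C search
plus LODO) finishes in well under a minute on one CPU while leaving
~330 positives for stable metrics.

What the benchmark does *not* emulate: real fingerprints are sparser
and feature frequencies heavy-tailed; real class structure is soft,
overlapping and hierarchical rather than 4 clean blocks; real
association networks have heavy-tailed degree distributions; real
target sets overlap across drugs. Passing tests therefore demonstrate
correct mechanics and recoverability of a planted signal, not
real-data performance.

Two properties of the default benchmark are worth knowing when
reading results:

* **AUC ceiling.** With `assoc_prob_within = 0.5`, roughly half the
  same-class pairs are unlabeled; uniformly sampled negatives include
  them, and they are statistically indistinguishable from positives.
  The Bayes-optimal AUC is ≈ 0.89, which is where well-functioning
  kernels plateau (~0.86–0.88 observed).
* **Signal saturation.** With 200/100 features per profile, moderate
  bit noise leaves class separation essentially intact (within-class
  profile correlation after flip-noise p scales as (1−2p)²), so
  single-source AUC barely moves until noise is severe, and the fused
  kernel — containing the noise-free target source — is flatter
  still. Degradation curves over bit noise are consequently shallow
  and can be non-monotone within seed noise; the benchmark is a
  correctness harness, not a sensitive noise-response instrument.

A variant generator (`generate_trivial_target_benchmark`) gives
alternating drugs per class one *shared identical* target (pairwise
target similarity exactly 1) and the rest private, heavily mutated
(40%/site) targets that stay below the 0.8 filter cutoff while
remaining class-informative — the fixture for the trivial-filter
experiment.

## Numerical choices

* Symmetry: 1e-6 tolerance on file read (averaged away), 1e-10
  internally (hard error).
* Alignment: BLOSUM50 with gap open 8 / extend 8 (a gap of length L
  costs open + (L−1)·extend); raw scores are integers, so the DP
  cross-checks in the test suite compare exactly.
* Population (not sample) standard deviation in the feature weights;
  a single feature or equal frequencies ⇒ uniform weights.
* Zero-profile drugs and empty target sets: similarity 0 off-diagonal,
  1 on the diagonal, with a warning — well-formed matrices without
  invented similarity.
* Weighted-cosine output is clipped to [0, 1] and its diagonal pinned
  to exactly 1 to absorb float round-off.
* AUC uses midrank tie handling; AUPR is the step-curve area (no
  linear PR interpolation, which is optimistic).
* All derived seeds stay below 2³¹; every stochastic step (benchmark,
  negative draws, fold shuffles) flows from one user seed.

## Known limitations

* Best-match set aggregation makes the raw target matrix potentially
  indefinite; the spectral clip changes entries slightly (Frobenius-
  minimally) and the repaired matrix no longer has exactly unit
  diagonal.
* `select_C` refits the SVM O(grid × folds) times; for much larger
  benchmarks a warm-started path solver would be preferable.
* The 10-fold protocol shares drugs between train and test folds by
  design; cold-start performance must be read from LODO.
* Disease-side profiling is phenotype-only; alternative disease
  similarities (e.g., gene-network closeness) are out of scope.
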