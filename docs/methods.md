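# Methods

## The curation problem

A structural LTR retrotransposon predictor emits candidate elements; a
reference library should contain only intact copies. Contamination takes
four forms — a nested LTR-RT from the other superfamily, a nested LTR-RT
from another lineage of the same superfamily, a total length
incompatible with the lineage's literature interval, and a Class II
(TIR transposon) insertion. The package implements both curation arms:
a deterministic rule engine, and classifiers trained to imitate it from
sequence alone.

## Rule-based filter cascade

Domain detection is exact motif matching against a configured lineage
library (forward strand by default; a both-strands switch exists). The
operation sits behind its own interface so a homology or profile-search
backend could replace it without touching the cascade. Labels are
assigned first-match-wins in the order 1 → 2 → 4 → 3: structural
contamination outranks the length symptom it causes, so a nested element
twice its host's length is reported as nested, not long. The length
filter uses a symmetric band `[min·(1−t), max·(1+t)]` with t = 0.20 by
default; a one-sided variant (fire only on length increase) is
available because the two readings of the filter are both defensible.
Elements with zero domain hits are reported as unclassifiable (`None`),
never silently as intact: forcing them into a class would hide exactly
the sequences a curator should look at.

## Synthetic data generator

The generator's contract is that the filter cascade can recover every
label exactly, while the sequence composition statistics resemble what
makes real TE classification work. Design:

* **Structure.** Element = LTR + internal + identical LTR. The internal
  region carries five domain bodies (GAG, AP, INT, RT, RH) in the
  superfamily's order, separated by intergenic background.
* **Lineages.** Each lineage has: a private 18–30 bp motif per domain
  (pairwise non-substring across the whole library, rejection-sampled
  out of all background so recovery is exact, not just overwhelmingly
  probable); an LTR length range (~150–650 bp); a total length interval
  (~4–11 kb) standing in for the literature table, which the source
  material cites but never prints; and two base compositions — an
  intergenic background (GC drawn in 0.34–0.56 with strand asymmetry)
  and a coding composition for the domain bodies. Real TE lineages have
  distinct global k-mer signatures, and their internal domains are
  kilobase-scale coding regions; without both properties, nested
  insertions are nearly invisible to frequency-normalized k-mer
  features (frequency normalization exactly cancels the count doubling
  that nesting causes when all classes share one background).
* **Contamination classes.** Nesting inserts a complete donor element
  at a uniform position strictly inside the host's internal region
  (never inside an LTR — a deliberate simplification that keeps
  LTR-boundary logic unconfounded), so `|nested| = |host| + |donor|`.
  Length anomalies pad the internal region with host-composition
  background to a length of 1.25–1.80 × the range maximum: the low end
  sits just above the 1.2 detection boundary, so the shortest anomalies
  genuinely overlap intact elements in composition space (length itself
  is invisible to frequency features) and class 3 remains the hard
  class, while the tail emulates run-on predictions and unresolved
  tandem nests. Class II insertions are a TIR motif + 300–1000 bp
  AT-rich interior (MITE-like) + the reverse-complement motif, clamped
  so the element stays inside the ±20% band and only the Class II
  filter fires.
* **Imbalance.** `imbalanced_counts(total)` apportions records at the
  reference ratio 56442 : 33874 : 4734 : 8568 : 2039 (largest
  remainder), the default study condition.
* **Determinism.** Everything flows from one `numpy` generator seeded
  by `SimConfig.seed`; identical configs give byte-identical FASTA.

What the generator does **not** emulate: evolutionary divergence between
the two LTRs or between copies, substitution noise on motifs (a
mutation knob would break exact label recovery), solo LTRs, target-site
duplications, real lineage nomenclature. Passing tests therefore show
that the pipeline is correct and learnable under clean, compositionally
realistic conditions — not that the trained weights transfer to real
genomes.

## Features

* **k-mer spectrum.** For k = 1..6, counts of all 4ᵏ A/C/G/T words by
  sliding window, windows containing N skipped; "frequency" mode (the
  default) divides each k-block by its valid-window count with 0/0 = 0,
  so each block sums to 1 or 0. The concatenated dimension is 5460.
  A raw-count mode is kept because the normalization is a choice, not a
  given.
* **One-hot.** 5 × m × n tensor, rows (A,C,G,T,N), right-padded with
  all-zero columns to the longest sequence; unknown symbols map to N
  with a logged warning.
* **Scaling and PCA.** Both are fit on the training partition only —
  fitting on all data would leak the test set into the features. The
  canonical pipeline applies PCA directly to the raw frequency spectrum
  at a 96% explained-variance target and feeds the variance-ordered
  scores to the models unscaled. Per-feature standardization before PCA
  — the conventional order — is deliberately not used: each of the 4096
  6-mer features is a frequency estimate whose multinomial sampling
  noise shrinks with sequence length, and standardizing inflates every
  such feature to unit variance, producing a noise norm that encodes
  length instead of composition and dominates distances and margins.
  `fit_scaler` (zero mean, unit variance, zero-variance columns passed
  through unchanged) remains available for score-space or classical-ML
  use. The number of retained components is a property of the data, not
  a contract; only the ≥ 96% rule is enforced.

## Models

* **Classical grid.** Candidates are enumerated exactly: KNN
  n_neighbors 1–100; SVC C ∈ {10, 100} with γ = 10⁻⁶; LR C 0.1–1 step
  0.1; LDA tol 10⁻⁴–10⁻³ step 10⁻⁴; NB var_smoothing 10⁻¹–10⁻¹⁹ by
  factor 10⁻²; MLP one hidden layer of 50–500 step 50 (lbfgs,
  α = 0.5); DT max_depth 1–10; RF n_estimators 10–100 step 10.
  Selection maximizes validation F1, ties to the smaller candidate.
  The MLP grid treats each width as a single hidden layer.
* **FNN.** Dense stack (default 256-128-64, a declared config, not a
  hard-coded architecture), each hidden block Dense → BatchNorm
  (momentum 0.99) → activation (ReLU default; sigmoid/tanh available) →
  Dropout 0.5; output softmax + categorical cross-entropy (five-label)
  or sigmoid + binary cross-entropy (two-label). Exactly 200 epochs at
  batch size 128, Adam at 10⁻³ (the optimizer is a choice; it is in the
  config). No early stopping — per-epoch validation F1 and loss are
  recorded instead and exported as CSV.
* **CNN.** Two-label only. Input is the 5 × m one-hot plane
  (N, 1, 5, m); three stages of Conv2D (64/32/32 filters, same padding,
  default kernels 5×5, 3×3, 3×3) → ReLU → SpatialDropout 0.2 →
  BatchNorm → average pooling (default 1×2), then a dense head with
  dropout 0.2. A balanced per-class subsample of the training pool is
  drawn first (default 15 000 per class, clamped to the pool).
* **Engine.** The networks run on a small seeded NumPy engine
  (`_nn.py`): im2col convolution, batch-norm with the running-average
  convention `r ← 0.99 r + 0.01 batch`, inverted dropout, Adam.
  Training is bit-reproducible for a fixed seed under single-threaded
  numerics; a same-seed-identical-weights contract is tested.
* **Prediction.** A trained model carries its preprocessing (k-mer
  config + PCA, or one-hot pad width), so raw sequences can be scored
  directly. Binary decisions threshold the positive-class probability
  at 0.5 (configurable).

## Evaluation

Stratified 80/10/10 splits (stratification chosen because of the class
imbalance), seed-deterministic, disjoint and exhaustive, largest
remainder within each class. Metrics use the standard formulas;
any 0/0 ratio is reported as 0 and flagged rather than raised. ROC and
precision-recall curves sweep the unique scores; AUC is trapezoidal and
is tested against the brute-force Mann-Whitney statistic; auPRC uses
step-wise interpolation. Displayed values follow truncation (0.9167 →
0.916; an F1 of 0.93679 prints as 93.6%); stored values keep full
precision. Multiclass reports give per-class one-vs-rest P/R/F1 with
weighted (default, matching the imbalance emphasis) and macro averages.

## Problem sizes and observed behavior

The package's own validation runs at desk scale: 3000-record corpora at
the reference imbalance, six lineages, 80/10/10 split — about 2400
training records, sequences 4–19 kb. At this scale PCA retains on the
order of 10–100 components, the two-label FNN reaches held-out F1 of
roughly 0.86–0.89 across seeds (AUC ≈ 0.95–0.97), the majority-class
baseline F1 is 0 (the majority class is "intact", so it never predicts
the positive class), and the five-label confusion matrix shows the
intact class confused almost exclusively with the length-anomaly class
— the expected structure, since those two overlap in composition space
by construction. The rule-based arm recovers 100% of ground-truth
labels on noise-free simulated data; this is an exactness contract of
the generator-filter pair, not a statement about real genomes.

## Known limitations

Exact motif matching stands in for homology search; the filter engine
is only as good as the configured lineage library. The CNN is practical
at desk scale for sequences up to a few kb (im2col memory grows with
m × batch); the FNN on k-mer features is the deployed curator, matching
its role as the best performer. Frequency features cannot see length
directly, so length anomalies just past the tolerance boundary are
intrinsically ambiguous to the ML arm — by design, the rule-based arm
is authoritative for that class.
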