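# ltrcurator

Machine-learning curation of LTR retrotransposon (LTR-RT) reference
libraries for plant genomes.

Structural LTR-RT predictors routinely emit sequences that look complete
but are contaminated: another retrotransposon nested inside the element,
a DNA (Class II) transposon insertion, or a predicted span whose length
is incompatible with the element's lineage. Using such sequences as a
reference library propagates errors into every downstream homology-based
annotation. Curating them by conventional bioinformatics (domain
homology searches plus structural filters) takes hours per genome;
`ltrcurator` reproduces that curation with trained classifiers that score
a library in seconds, and ships a rule-based filter engine and a
synthetic data generator so the whole system trains and validates
without any external database.

## What it does

**Labels.** Each predicted element gets a curation label:

| label | meaning |
|------:|---------|
| 0 | intact — keep in the reference library |
| 1 | nested LTR-RT from the other superfamily (Gypsy vs Copia) |
| 2 | nested LTR-RT from another lineage of the same superfamily |
| 3 | length outside the lineage's literature interval ± 20% |
| 4 | Class II (TIR transposon) insertion |

The two-label problem binarizes this to keep (0) vs remove (1–4).

**Rule-based arm** (`ltrcurator.filters`): scan for lineage-diagnostic
domain motifs (GAG, AP, INT, RT, RH — Copia order GAG-AP-INT-RT-RH,
Gypsy order GAG-AP-RT-RH-INT) and TIR pairs, then apply a deterministic
cascade 1 → 2 → 4 → 3 with a ±20% length tolerance.

**ML arm** (`ltrcurator.features`, `ltrcurator.models`): sequences are
represented as k-mer frequency spectra for 1 ≤ k ≤ 6 (Σ₁⁶ 4ᵏ = 5460
features) reduced by PCA at 96% explained variance, or as 5 × m one-hot
matrices (rows A,C,G,T,N). Classifiers: a classical-ML zoo (KNN, SVC,
LR, LDA, NB, MLP, DT, RF) with a fixed hyper-parameter grid selected by
validation F1; a fully-connected network (hidden stack 256-128-64, batch
normalization momentum 0.99, dropout 0.5, 200 epochs, batch size 128);
and a convolutional network (three stages of 64/32/32 filters, spatial
dropout 0.2, average pooling, dense head with dropout 0.2) trained on a
balanced per-class subsample of the two-label data. Data splits are
stratified 80/10/10 (train/validation/test), and F1 is the headline
metric because the label distribution is strongly imbalanced
(reference ratio 56442 : 33874 : 4734 : 8568 : 2039).

**Synthetic data** (`ltrcurator.sim`): generates labeled libraries whose
ground truth the filter cascade recovers exactly — lineages with private
domain motifs embedded in coding-composition domain bodies, identical
terminal repeats, per-lineage length intervals and base compositions,
plus the four contamination classes.

## Worked example

```bash
ltrcurator simulate --seed 5 --total 1500 -o data/
ltrcurator train --fasta data/dataset.fasta --labels data/labels.tsv \
    --model fnn --seed 5 -o run/
ltrcurator curate --model run/model.joblib --fasta data/dataset.fasta \
    -o curated/
ltrcurator label --fasta data/dataset.fasta --library data/library.yaml \
    -o rules/ --compare curated/scores.tsv
```

A run of the four commands above prints:

```
wrote 1500 records to data/dataset.fasta
test F1 = 0.8649 (n_test = 150)
kept 770 / removed 730 of 1500 sequences
labeled 1500 records (0 unclassifiable)
```

`test F1` is the two-label F1 of the fully-connected network on the
held-out 10% test partition. `curate` splits the library into
`kept.fasta` (predicted intact) and `removed.fasta` plus a per-sequence
score table; `label` is the conventional rule-based arm, and with
`--compare` it reports its agreement with the model's decisions
(`agreement.json`). Every command writes a manifest with its seed,
configuration and output checksums.

The same pipeline is available as a library:

```python
from ltrcurator import sim, features, models, evaluation

library = sim.make_lineage_library(3, seed=5)
config = sim.SimConfig(n_per_class=sim.imbalanced_counts(1500), seed=5)
dataset = sim.generate_dataset(config, library)
raw = features.kmer_matrix(dataset.records).X
```

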