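# transpred

Feature encoders and classifiers for predicting the substrates of
membrane transport proteins from amino-acid sequences and 3Di
structural sequences.

The package covers the full pipeline:

- **Sequence I/O** (`transpred.seq_io`) — FASTA reading/writing for AA
  and 3Di sequences, non-standard-residue filtering (B/O/U/Z/X), and
  merging of overlapping 3Di fragments of long proteins (1400-position
  windows with 1200-position overlaps).
- **k-mer features** (`transpred.kmer_features`) — overlapping k-mer
  frequency vectors (k = 1, 2, 3) over the 20-letter AA or 3Di alphabet
  (AAC, PAAC, AA-KMER3, 3Di-COMP, 3Di-KMER2, 3Di-KMER3) and their
  concatenations (COMB-KMER1/2/3).
- **PSSM features** (`transpred.pssm_features`) — ASCII PSSM parsing,
  20×20 per-residue-type conservation profiles, and the 1600-dim
  Multi-PSSM feature from {uniref50, uniref90} × {1, 3 iterations}.
- **Feature assembly** (`transpred.feature_assembly`) — mean-pooling of
  per-residue embeddings, the deterministic 1024-dim uniform-random
  DUMMY feature, and the META / META-STD fingerprints (AAC | PAAC |
  Multi-PSSM, optionally z-scored per block within each sample).
- **Dataset construction** (`transpred.go_dataset`) — OBO/GAF parsing,
  evidence-code filtering (IEA and negated qualifiers dropped), is_a
  annotation propagation, two-class label assembly with overlap
  exclusion, and greedy 70%-identity redundancy reduction.
- **Outlier screening** (`transpred.outlier_detection`) — per-feature
  z-score → PCA (≥ 95% cumulative variance) → 100-tree isolation
  forest, with an at-least-50%-of-features consensus rule. Never
  applied inside cross-validation.
- **Classifiers** (`transpred.classifiers`) — the SVM pipeline
  (zero-variance filter → ANOVA top-k ≤ 200 → z-scoring → RBF SVM with
  γ = 1/(var(X)·m) and class weights n/(K·nᵢ), C ∈ {0.1, 1, 10} chosen
  by inner stratified 5-fold search) and a NumPy feedforward network
  (512/256/128 ReLU + dropout 0.5, sigmoid output, Adam, batch 8,
  50 epochs).
- **Evaluation** (`transpred.evaluation`) — five shuffled repetitions
  of stratified 5-fold cross-validation (25 held-out scores), balanced
  accuracy, per-class F1 and macro F1, mean ± SD aggregation.
- **Synthetic fixtures** (`transpred.synthetic`) — seeded generators
  for class-biased AA/3Di sequences, PSSMs, embeddings, planted
  outliers, and a miniature OBO/GAF ontology, so the entire pipeline is
  testable offline.

## CLI

```sh
# generate a synthetic dataset folder (FASTA, PSSMs, embeddings, OBO/GAF, labels)
transpred synth --preset carriers --seed 0 --out data/

# 5x5 nested cross-validation for one feature/model
transpred evaluate --dataset data/ --feature 3Di-KMER2 --model svm --seed 0 --out results/
transpred evaluate --dataset data/ --feature DUMMY --model fnn --seed 0 --out results/

# consensus outlier report across features (dataset construction only)
transpred outliers --dataset data/ --features AAC,PAAC,3Di-COMP,3Di-KMER2 --seed 0 --out outliers.tsv
```

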