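# cellumine

Screen metagenome-assembled contigs for cellulase-like genes by translated
homology search, and classify cellulase amino-acid sequences into
optimum-temperature classes (mesophilic / thermophilic / hyper-thermophilic)
and optimum-pH classes (acidic / neutral / alkaline) with a descriptor-based
soft-voting ensemble (MLP + random forest + RBF SVM).

## What it does

**Training / prediction**

1. FASTA sequences are cleaned to the 20-letter amino-acid alphabet and
   de-redundified by greedy identity clustering (default cut-off 0.9,
   identity over the shorter sequence of an optimal global alignment).
2. Each sequence is mapped to a fixed-order, length-independent descriptor
   vector (default 973 columns: AAC, DPC, grouped AAC/DPC, CTD
   composition/transition/distribution over 7 physico-chemical attributes,
   conjoint triad, type-1 pseudo-AAC with lambda=4, atom and bond
   composition).
3. Duplicate descriptor columns are dropped, values are min-max scaled,
   features are ranked by one-way ANOVA F-test with Benjamini-Hochberg FDR
   control (`K="auto"` keeps the BH-significant count), minority classes
   are balanced with a from-scratch SMOTE, and the three base classifiers
   are fitted and combined by weighted soft voting.
4. Evaluation is repeated stratified 6-fold cross-validation with every
   state (scaler, selection, SMOTE) refitted inside each training fold.

**Screening / characterization**

Contigs are translated in six frames, stop-split peptides (>= 20 aa) are
aligned against a reference cellulase set with exact affine-gap
Smith-Waterman (BLOSUM62, gaps 11/1), raw scores become bit scores via
Karlin-Altschul constants (lambda=0.267, K=0.041), and hits with >= 50 bits
are reported. Candidates can be shortlisted by read coverage (top 25% by
nearest-rank quantile) and a stricter bit floor (>= 300). Passing peptides
are classified with trained temperature/pH bundles.

A `synthetic` module generates seeded labeled protein sets (class-biased
residue composition) and contigs with planted forward/reverse-strand genes,
so the whole pipeline is testable offline.

## CLI

```bash
# synthetic fixtures (FASTA + label TSV + contigs + truth table)
cellumine simulate --task temperature --n-per-class 60 --seed 1 --out sim/

# train a bundle
cellumine train --fasta sim/proteins.fasta --labels sim/labels.tsv \
    --task temperature --k auto --seed 1 --out run/

# cross-validated evaluation (leakage-safe, stratified 6-fold)
cellumine evaluate --fasta sim/proteins.fasta --labels sim/labels.tsv \
    --task temperature --folds 6 --iterations 100 --seed 1 --out cv/

# classify protein sequences
cellumine predict --bundle run/bundle --fasta queries.fasta --out pred/

# screen contigs against a reference protein set (+ optional shortlist)
cellumine screen --contigs contigs.fasta --refs refs.fasta \
    --bit-cutoff 50 --coverage coverage.tsv --bit-floor 300 --out hits/

# screen + classify in one step
cellumine characterize --contigs contigs.fasta --refs refs.fasta \
    --bundle-t run/bundle --out char/
```

Every command writes a `manifest.json` (config echo, seeds, input SHA-256
checksums, version) next to its outputs.

## Notes and conventions

- Class boundaries: temperature [0,50) / [50,75) / [75,inf); pH [0,5) /
  [5,8) / [8,14]. Upper classes own their lower bound.
- Smith-Waterman scores are exact local-alignment optima and will not
  numerically match BLASTx (no masking/composition adjustment); the
  bit-score thresholds keep their meaning.
- Min-max scaling maps constant training columns to 0 and does not clip
  out-of-range prediction-time values.
- All randomness is seeded; identical seeds reproduce identical bundles,
  CV reports, and synthetic datasets.
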