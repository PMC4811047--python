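# phosforest

General phosphorylation-site prediction from primary protein sequence.

Protein kinases phosphorylate serine, threonine and tyrosine residues, and
the local sequence context around a site carries much of the signal that
determines whether it is modified. `phosforest` is a library (plus a thin
command-line tool) for people who want to train, inspect and apply
*general* (kinase-agnostic) phosphosite classifiers: computational
biologists annotating candidate sites on new proteomes, and method
developers who need a transparent, feature-interpretable baseline.

## Method

Every candidate site is an odd-length window `w` (default 9) of residues
centered on an S/T/Y, padded with `X` at protein termini. Each window is
encoded into a fixed-length descriptor vector — 593 positions at `w = 9` —
built from ten families:

| block | content | length at w=9 |
|---|---|---|
| H | Shannon entropy `H = −Σ pᵢ log₂ pᵢ` of the window composition | 1 |
| RE | relative entropy `Σ pᵢ log₂(pᵢ/p₀)` against the uniform `p₀ = 1/w` | 1 |
| IG | information gain `H − RE` | 1 |
| ASA | per-residue solvent accessibility (external profile, or a built-in hydropathy fallback) | 9 |
| OP | 10 overlapping physicochemical class bits per residue (polar, positive, …, proline) | 90 |
| ACH | mean Eisenberg hydrophobicity of nested centered subwindows (3, 5, 7, 9) | 4 |
| SF | 20-bit one-hot residue identity per position | 180 |
| CTD | composition / transition / distribution over 3 groups × 7 properties | 147 |
| SOCN | sequence-order coupling numbers `τ_k = Σᵢ d²(sᵢ, sᵢ₊ₖ)`, lags 1–30, two distance matrices | 60 |
| QSO | quasi-sequence-order: normalized frequencies `fᵢ/(Σf + 0.1Στ)` plus weighted τ terms | 100 |

A random forest (100 Gini-split bootstrap trees by default) is trained per
residue type; the positive-class probability is the mean of the tree votes.
Gini feature importance ranks the descriptor columns, and an optional
two-pass mode refits on the top-k columns. Evaluation reports the full
panel — accuracy, precision, sensitivity, specificity, F1, Matthews'
correlation coefficient and ROC AUC — under stratified 10-fold cross
validation (pooled out-of-fold predictions are the headline numbers) or on
a class-balanced independent test set.

A seeded synthetic-proteome generator plants a configurable physicochemical
motif around positive sites so that the entire pipeline, including feature
importance, can be exercised and validated without external databases.

## Worked example

```bash
python examples/02_simulate_train_evaluate.py
```

```
150 proteins, 629 serine windows (326 positive)

pooled 10-fold cross-validation panel:
  accuracy     99.52 %
  precision   100.00 %
  sensitivity  99.08 %   (positives recovered)
  specificity 100.00 %   (negatives recognized)
  F1 score     99.54 %
  MCC          0.990     (1 = perfect, 0 = random)
  AUC          1.000
per-fold accuracy 99.5 +/- 1.0 %
```

The generator planted a noiseless motif (charged residues at offsets ±1,
prolines at ±2 of each positive serine), so a near-perfect panel is the
expected outcome: it demonstrates that the descriptor pipeline exposes the
local signal and the forest recovers it. `examples/03_feature_importance.py`
shows the same signal from the introspection side — the overlapping-class
and residue-identity columns at the motif offsets dominate the Gini
ranking. See `examples/01_encode_a_window.py` for the descriptor layout and
`examples/04_predict_new_proteins.py` for scoring unseen proteins.

The same pipeline is available from the shell:

```bash
phosforest simulate --out data --seed 1
phosforest extract --fasta data/proteins.fasta --annotations data/annotations.tsv \
    --asa data/asa.tsv --out-windows w.tsv --out-features f.tsv
phosforest train --features f.tsv --out model.joblib
phosforest evaluate --features f.tsv --mode cv --out report.json
phosforest predict --model model.joblib --fasta data/proteins.fasta --out calls.tsv
```

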