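# Methods

## Problem and model

`phosforest` treats general (kinase-agnostic) phosphosite prediction as
binary classification of fixed-length sequence windows. A window of odd
length `w` (default 9) is centered on a candidate serine, threonine or
tyrosine; windows overhanging a protein terminus are padded with the
placeholder `X` rather than skipped, so every annotated site is usable.
One random forest is trained per residue type, since Ser/Thr/Tyr sites
have distinct sequence preferences and real datasets differ by an order of
magnitude in size across the three.

The classifier itself is a standard bootstrap forest with Gini-impurity
splits (scikit-learn's `RandomForestClassifier`; `n_jobs=1` for
reproducibility). The default of 100 trees is the point past which
accuracy plateaus on this problem; tree depth and features-per-split
follow the library defaults and are recorded in the saved bundle. The
positive-class probability of a window is the mean of the tree votes, and
the class call is positive iff probability ≥ threshold (default 0.5, with
the tie going to positive — documented because probabilities of a
100-tree forest frequently land exactly on 0.5-adjacent grid points).

## Descriptor vector

Ten families are concatenated in a fixed order (H, RE, IG, ASA, OP, ACH,
SF, CTD, SOCN, QSO), giving 593 positions at `w = 9`. Every position has
a stable name of the form `FAMILY_globalindex` (e.g. `QSO_569`), so
importance tables are comparable across runs and window sizes are guarded
at load time.

**Placeholder rule.** `X` (terminal padding, sanitized non-standard
letters) is excluded from every probability/count denominator (H, RE, IG,
CTD), contributes 0 to scale-based sums and pairwise distances (ACH, ASA,
SOCN, QSO), and encodes as all-zero bits (OP, SF). One uniform rule keeps
terminal windows encodable without inventing chemistry for a non-residue.

**Entropy family.** `H = −Σ pᵢ log₂ pᵢ` with `pᵢ` the residue frequencies
over the effective (placeholder-free) window length; `RE = Σ pᵢ
log₂(pᵢ/p₀)` with `p₀ = 1/w` fixed by the *configured* window length and
zero-probability terms skipped. RE is deliberately implemented in this
literal form even though it is not a textbook KL divergence when the
effective length differs from `w` (padded windows): the descriptor is
defined on fixed-length windows and the literal form keeps `IG = H − RE`
an exact identity. IG can therefore be negative (e.g. −log₂ 9 for a
single-residue-type 9-window).

**ASA.** The accessibility channel takes an externally predicted
per-residue profile when one is supplied (profiles are validated against
sequence length and non-negativity). Without one, a built-in fallback is
used: the complement of the Eisenberg hydrophobicity rescaled to [0, 1]
and smoothed with a centered 5-residue moving average — a deterministic,
crude proxy for burial, sufficient to keep the pipeline runnable. Whether
the fallback was used is recorded and propagated into model metadata. Raw
(not discretized) values are used.

**OP / SF.** Ten overlapping physicochemical class bits per residue
(polar, positive, negative, charged, hydrophobic, aliphatic, aromatic,
small, tiny, proline — histidine encodes as 1101101000), and a 20-bit
one-hot identity per residue over the alphabetically ordered letters.

**ACH.** Mean Eisenberg hydrophobicity over the nested centered
subwindows of sizes 3, 5, …, w, smallest first; the subwindow size stays
the divisor when placeholders are present.

**CTD.** Residues map to three groups under seven properties
(hydrophobicity, van der Waals volume, polarity, polarizability, charge,
secondary-structure propensity, solvent accessibility; the standard
Dubchak-style tables — the hydrophobicity grouping is pinned by the
worked example MVKELRTA → 33113122). Per property: 3 composition values
`n_r/n`; 3 transition values `(n_rs + n_sr)/(N−1)` for the unordered code
pairs (1,2), (1,3), (2,3), counted on the placeholder-stripped sequence;
15 distribution values — for each group, the positions of its 1st and
⌈25 %⌉, ⌈50 %⌉, ⌈75 %⌉, 100 % occurrences (ceiling of fraction × group
count, so the 100 % entry is always the last occurrence), divided by the
effective length and ×100. A group absent from the window contributes
zeros.

**SOCN / QSO.** `τ_k = Σᵢ d²(sᵢ, sᵢ₊ₖ)` under a physicochemical distance
matrix; lags with no residue pairs are 0, and pairs involving `X`
contribute 0. Two matrices realize the fixed block lengths (60 for SOCN
at lags 1–30, 100 for QSO with τ terms at lags 1–40): (1) a hydropathy
distance, |Eisenberg difference| normalized to [0, 1]; (2) the Grantham
chemical distance computed from its published formula
`D = 50.723·√(1.833Δc² + 0.1018Δp² + 0.000399Δv²)` over side-chain
composition, polarity and volume, likewise normalized. Both matrices are
constructed in code (`_scales.py`) rather than shipped as opaque tables,
so their provenance is auditable. Since a 9-residue window has pairs only
up to lag 8, entries at higher lags are structurally zero — they are kept
so the vector length is window-size-independent within each family. QSO's
first 20 entries are `fᵢ/(Σf + 0.1·Στ)` (τ of the first matrix); entries
21–100 are `0.1·τ_k/(Σf + 0.1·Στ)` per matrix, weight 0.1.

## Window preparation

Annotations are validated on ingestion: the stated residue must be S/T/Y
and must match the sequence character at the (1-based) position; rows
failing residue checks are rejected with a report, while unknown proteins
and out-of-range positions are hard errors. Redundancy removal is a
greedy first-come single pass: an item is dropped iff its global-alignment
percent identity (Needleman–Wunsch, BLOSUM62, gap open 10.0 / extend 0.5;
identity = matches / alignment length) to any already-retained item
exceeds the threshold. The intended protocol applies a 30 % threshold at
sequence level before windowing and 20 % at window level after (per
label class); window-level "similarity" is implemented as identity, the
conservative reading. The filter is idempotent. Negative balancing draws
exactly as many negatives as positives, without replacement, from a
seeded generator.

## Evaluation

Accuracy, precision, sensitivity and specificity are percentages; F1 is
the harmonic mean of precision and sensitivity (also on the percent
scale); MCC is the usual confusion-matrix correlation. A metric whose
denominator is zero is reported as undefined (`None`/`"NA"`), never
silently zeroed. AUC is computed by trapezoidal integration of the ROC
curve and cross-checked at every call against the mid-rank Mann–Whitney
statistic; a disagreement beyond 1e-12 raises. Cross validation uses
seeded *stratified* folds (the protocol only requires random folds;
stratification keeps minority-class counts stable at Thr/Tyr dataset
sizes). Because all descriptors are window-local, features are extracted
once before folding without leakage. Both pooled out-of-fold metrics (the
headline numbers) and per-fold mean ± sd are available, since published
tables rarely say which convention they print.

## Synthetic benchmark generator

The generator emulates a curated phosphoproteome at the level this
package needs: proteins drawn i.i.d. from a background residue
distribution (uniform by default; a Swiss-Prot-like preset is included),
a seeded fraction of target residues marked positive, and flanks of
positive centers resampled from a motif expressed over the ten
overlapping classes — by default positively charged residues (K/H/R) at
offsets ±1 and proline at ±2. `noise` is the probability a positive
ignores the motif: 0 plants it everywhere, 1 yields a signal-free null in
which positives and negatives are exchangeable. Accessibility profiles
are the deterministic pseudo-accessibility of each final sequence plus
seeded Gaussian jitter (σ = 0.05), clipped at 0. Defaults (450 proteins
of 60–120 residues, positive fraction 0.5) produce ≈2000 serine windows —
large enough for stable 10-fold CV, small enough to run in seconds.

What the generator does *not* emulate: realistic class imbalance,
homology between proteins (so redundancy filtering barely fires),
kinase-family structure, long-range or structural determinants, and
disorder. Passing tests on synthetic data therefore demonstrate that the
pipeline is correct and that planted local signal of realistic form is
recoverable end-to-end — not that any particular performance level will
be attained on curated phosphoproteome benchmarks, whose difficulty is
dominated by exactly the properties the generator omits.

## Numerical and design choices

- Positions are 1-based and inclusive everywhere; window middles are
  enforced at construction.
- Importance ties are broken by lower feature index (stable sort), making
  top-k selection deterministic.
- Model bundles embed the schema version and full layout; loading a
  bundle whose schema does not match the current definition is an error,
  never a silent reindex. Prediction validates matrix width against the
  schema (full width even for top-k models; the bundle slices
  internally).
- Reproducibility: every stochastic step (generation, folding, bootstrap,
  balancing) takes an explicit seed; repeated runs are bit-identical.
- Degenerate inputs: all-placeholder windows encode to finite vectors
  (entropies 0 with a warning, frequency blocks 0); single-class training
  sets and single-class ROC inputs raise informative errors.

## Known limitations

- The two sequence-order distance matrices are this package's documented
  realization of the fixed 60/100 block lengths; other matrix/lag choices
  would produce equally valid but numerically different SOCN/QSO blocks.
- The six CTD groupings other than hydrophobicity follow the standard
  published tables; variant tables exist in the literature.
- The ASA fallback is a hydropathy heuristic, not a structure-aware
  predictor; models trained with it should not be compared against models
  trained on real accessibility profiles.
- Redundancy filtering is O(n²) pairwise alignment — fine for thousands
  of windows, slow for full proteomes.
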