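# Methods

## Model overview

`psewave` predicts the SCOP-style structural class of a protein domain
(all-α, all-β, α/β, α+β) from its primary sequence. The pipeline has four
stages: (1) two fixed-length pseudo amino acid composition (PseAAC)
representations per sequence; (2) 2-D wavelet soft-threshold denoising of
each dataset-level feature matrix; (3) fusion of the two denoised blocks by
column concatenation; (4) 1-nearest-neighbor classification evaluated by
the jackknife (leave-one-out) test with one-vs-rest sensitivity,
specificity, MCC and multiclass overall accuracy.

The working assumption is that class signal in composition features is
smooth at coarse scales of the (samples × features) matrix while sampling
noise concentrates in the fine-scale wavelet details, so shrinking detail
coefficients improves nearest-neighbor geometry.

## Feature extraction

Type 1 PseAAC augments the 20 residue frequencies with λ sequence-order
correlation factors θ_j, each the mean over the sequence of
Φ(Rᵢ, Rᵢ₊ⱼ) = ⅓[(H₁Δ)² + (H₂Δ)² + (H₃Δ)²], where H₁, H₂, H₃ are
per-residue hydrophobicity, hydrophilicity and side-chain mass scales. Type
2 (amphiphilic) PseAAC instead appends, per lag k ≤ r, the pair of mean
products ⟨H¹(Rᵢ)H¹(Rᵢ₊ₖ)⟩ and ⟨H²(Rᵢ)H²(Rᵢ₊ₖ)⟩. Both vectors are
normalized by (Σf + w Σcorrelation) so components sum to 1; type 2
components can be negative, and a strongly negative correlation block
combined with a large w can drive the normalizer non-positive — such inputs
are rejected as degenerate rather than silently sign-flipped.

Two conventions exist in the literature for the first member of the type 2
pair (H¹·H¹ versus the mixed H¹·H²). The amphiphilic construction — one
pure hydrophobicity term and one pure hydrophilicity term per lag — is the
default; the mixed product is available as `eq6_as_printed=True` so both
readings are reproducible.

The raw scale table (packaged CSV, swappable via `load_scales(path)`) is
the hydrophobicity/hydrophilicity/side-chain-mass triple conventionally
used with PseAAC. Each scale is standardized to mean 0 and *population*
(ddof=0) standard deviation 1 across the 20 residues, so the three
properties enter Φ on equal, dimensionless footing. Sequences shorter than
λ+1 (or r+1) are rejected rather than zero-padded. Nonstandard residues
(B, J, O, U, X, Z) are an error under the default `strict` policy;
`drop_unknown` removes them with a logged warning.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| λ, r | 2 | correlation tiers (type 1 / type 2); vectors are 22- and 24-dim |
| w | 0.05 | weight of the correlation block in the unit-sum normalization |
| wavelet (type 1 / type 2) | db4 / sym4 | denoising family per block |
| level | 5 | decomposition scale |
| threshold | universal, soft | t = σ̂√(2 ln m), σ̂ = MAD(finest diagonal)/0.6745 |
| K | 1 | KNN neighbors |
| strategy | 6 | denoise each block, then fuse |

These are the settings reported to perform best for this method; all are
exposed in `PipelineConfig` and on the CLI.

## Wavelet denoising

Denoising is decompose → shrink details → reconstruct, computed with
PyWavelets using symmetric boundary extension. Approximation coefficients
are never thresholded. Supported families: haar, db2/4/6, sym2/4/6,
coif1/3, bior2.2/2.4. The "default" threshold is the universal
(Donoho–Johnstone) rule with the noise scale estimated by the median
absolute value of the finest diagonal details divided by 0.6745 and m the
total detail-coefficient count; a fixed `given` threshold and a hard
threshold function are available for sensitivity analysis. With symmetric
extension, level 5 on a ~22-column matrix is well defined (and exactly
invertible) even though it exceeds the classical maximum decomposition
level; the transform emits a warning in that regime, which is expected at
the default settings.

**Row seriation.** The 2-D input to the denoiser is the dataset-level
feature matrix (rows = proteins). A wavelet transform along the sample axis
treats row adjacency as spatial continuity, yet the row order of an input
file is arbitrary — and, in distributed benchmark datasets, often grouped
by class. Denoising a class-grouped matrix smears adjacent same-class rows
together, which inflates leave-one-out accuracy through row order alone:
on a four-class dataset with *no* compositional signal, order-naive
denoising of class-sorted rows yields ~96% jackknife accuracy where chance
is 25%. To make the pipeline meaningful and order-invariant, rows are
sorted by their projection onto the leading principal component of the
block (a label-free, deterministic ordering; sign fixed, ties broken by
row index), denoised, and restored to the original order. When real class
structure exists, seriation places similar rows adjacently — recovering the
benefit the method obtains implicitly on class-sorted files — while under a
null it cannot manufacture label information.

**Transduction.** By default the full matrix (training and held-out rows)
is denoised once before the jackknife, which matches how such pipelines are
ordinarily run but shares information between folds through the threshold
and the transform itself. `denoise_per_fold=True` re-estimates the
threshold from each fold's training rows only and denoises the held-out row
jointly under that fixed threshold; residual sharing through the transform
remains and is inherent to dataset-level 2-D denoising.

A single feature vector can also be denoised through the 2-D path:
`vector_as_2d` reshapes length-n vectors row-major into the most-square
rows×cols grid with 2 ≤ rows ≤ cols ≤ 2·rows, padding the tail by symmetric
reflection when n has no acceptable factorization (22 → 4×6 with two pad
cells), and the inverse mapping strips the padding. The 1-D denoiser
(`denoise1d`) is provided for comparison.

## Classification and evaluation

KNN uses Euclidean distance with deterministic tie handling: equal
distances break to the lower training-row index; a tied majority vote
breaks to the class of the nearest neighbor among the tied classes. No
feature rescaling is applied before KNN — the vectors are already unit-sum
compositions on a common scale. The jackknife classifies each sample with
the sample removed from training, which requires at least two sequences per
class. Per-class metrics follow the standard one-vs-rest formulas; any
metric whose denominator is zero is reported as 0. Overall accuracy is the
multiclass fraction correct; the binary (TP+TN)/n form is retained
per class as `oa_binary`.

## Synthetic benchmark

The generator draws i.i.d. residues from per-class composition profiles on
the 20-simplex. Profiles are convex mixtures of the uniform composition and
four seeded Dirichlet(1) draws, mixed so the minimum pairwise
total-variation distance equals the `separation` parameter (capped by what
the draws allow); separation 0 yields four identical uniform profiles.
Defaults: 40 sequences per class, lengths uniform on 100–300, separation
0.4 — comfortably above the ~0.3 TV at which composition classes become
cleanly separable at these lengths. Records are returned in a seeded random
order so row position carries no label information (see the seriation
discussion above). An optional first-order Markov mode adds within-sequence
lag correlation so the θ/τ components also carry class signal.

What passing the synthetic benchmark shows: the full pipeline recovers
known compositional class structure almost perfectly (jackknife OA ≥ 0.9
across seeds), sits at chance on null data, and the ablation strategies
behave coherently (zero-threshold denoising collapses onto the raw
strategies; the full method is at least as accurate as raw features on the
default benchmark). What it does not show: performance on real proteins.
Real structural classes differ through secondary-structure-driven residue
*ordering* as much as composition, real datasets carry homology structure,
and the exact property-scale values and toolbox threshold conventions used
in published work are not fully specified — so published benchmark
accuracies are not reproduced here bit-for-bit.

## Numerical choices and degenerate inputs

- Population (not sample) sd in scale standardization.
- Unit-sum of extracted vectors holds to 1e-9; perfect reconstruction of
  the wavelet transforms to 1e-8.
- Universal threshold with zero-median details gives t = 0 (no-op).
- Homopolymers have θ ≡ 0, so their type 1 vectors are exactly one-hot.
- Empty classes, singleton classes, k exceeding the training size, row-id
  mismatches at fusion, and non-positive type 2 normalizers are errors,
  not warnings.
- Biorthogonal families (bior2.2/2.4) do not conserve energy; energy-based
  invariants are only asserted for the orthogonal families.

## Limitations

- Composition-only synthetic data cannot probe features that depend on
  realistic secondary-structure statistics.
- Transductive denoising means jackknife results are not a strict
  out-of-sample estimate; use `denoise_per_fold=True` for a cleaner (still
  not perfectly isolated) protocol.
- The per-fold mode recomputes two decompositions per fold and is ~n times
  slower than the transductive default.
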