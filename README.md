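# psewave

Protein structural-class prediction from primary sequence: pseudo amino
acid composition features, parallel 2-D wavelet denoising, feature fusion,
and jackknife-validated K-nearest-neighbor classification.

## The problem

A protein domain's structural class — all-α, all-β, α/β or α+β — can be
predicted from its amino-acid sequence alone, which is far cheaper than
solving the structure. Composition-based feature vectors work well when
training and test sequences are similar, but on low-identity datasets the
features carry substantial sampling noise ("redundant information") that
drags nearest-neighbor classifiers down. `psewave` implements a
denoise-and-fuse pipeline that addresses this: extract two complementary
pseudo amino acid composition (PseAAC) representations, remove fine-scale
noise from each dataset-level feature matrix with a 2-D wavelet soft
threshold, splice the cleaned blocks, and classify with KNN under the
jackknife (leave-one-out) test.

## The method

For a sequence P = R₁R₂…R_L, **type 1 PseAAC** (dimension 20+λ) combines
residue frequencies f_u with lag-j correlation factors

    θ_j = (1/(L−j)) Σᵢ Φ(Rᵢ, Rᵢ₊ⱼ),
    Φ(a,b) = ⅓ Σ_{s∈{H₁,H₂,H₃}} (s(b) − s(a))²,

where H₁/H₂/H₃ are standardized hydrophobicity, hydrophilicity and
side-chain mass scales, and normalizes so all 20+λ components sum to 1 with
the correlation block weighted by w (default 0.05). **Type 2 (amphiphilic)
PseAAC** (dimension 20+2r) instead uses paired correlation factors per lag k,
τ₂ₖ₋₁ = ⟨H¹(Rᵢ)H¹(Rᵢ₊ₖ)⟩ and τ₂ₖ = ⟨H²(Rᵢ)H²(Rᵢ₊ₖ)⟩.

Each N×d feature block is treated as a 2-D signal, decomposed to level 5
(db4 for type 1, sym4 for type 2), its detail subbands shrunk by the
universal soft threshold t = σ̂√(2 ln m) (σ̂ = MAD of the finest diagonal
details / 0.6745), and reconstructed. Rows are seriated by their leading
principal component before the transform and restored afterwards, so the
sample-axis smoothing acts on genuinely similar neighbors and the pipeline
is invariant to input row order. The two denoised blocks are fused into a
40+λ+2r-dimensional vector (46 at the default λ=r=2) and scored by
jackknife 1-NN with per-class Sens/Spec/MCC and overall accuracy. Six
strategies expose the ablations (raw blocks, denoised blocks,
fuse-then-denoise, denoise-then-fuse).

## Worked example

```python
from psewave import StructuralClassModel, SyntheticSpec, generate

seqs = generate(SyntheticSpec(n_per_class=10, length_range=(80, 150), seed=42))
model = StructuralClassModel(seqs)
res = model.fit()                      # strategy 6, published defaults
print(res.summary())
```

prints

```
Structural-class KNN (strategy 6, K=1, λ=2, r=2, w=0.05)
classifier input: 40 × 46
           class  n  Sens(%)  Spec(%)   MCC
       all_alpha 10  100.000  100.000 1.000
        all_beta 10  100.000  100.000 1.000
 alpha_plus_beta 10  100.000  100.000 1.000
alpha_slash_beta 10  100.000  100.000 1.000
OA(%): 100.00  (n=40)
```

Forty synthetic sequences (ten per class, class residue profiles separated
by 0.4 total-variation distance) are extracted into 22- and 24-dimensional
PseAAC blocks, each block is wavelet-denoised, the fused 46-dimensional
vectors are classified leave-one-out, and every protein is assigned its
correct class: sensitivity, specificity and MCC are 1 for all four classes
and the overall accuracy is 100%. On real low-identity datasets
(FASTA + a two-column id/class TSV) use
`StructuralClassModel.from_files("seqs.fasta", "labels.tsv")`, or the CLI:

```
psewave simulate --n-per-class 40 --seed 0 --out bench
psewave run --fasta bench.fasta --labels bench_labels.tsv --strategy 6 --out report.json
psewave extract --fasta bench.fasta --type 1 --out type1.csv
psewave denoise --matrix type1.csv --wavelet db4 --level 5 --out type1_dn.csv
```

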