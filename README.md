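# adtd — adaptive digital tissue deconvolution

Bulk transcriptomes are linear mixtures of the expression programs of the
cells they contain.  Classical deconvolution estimates the mixing
proportions `C` from a reference matrix `X` of cell-type profiles by
(weighted) non-negative least squares,

    Y ≈ X C,        C ⪰ 0,

but real specimens break two of its assumptions: they contain cell
populations that no column of `X` represents (e.g. cancer cells against a
healthy-tissue reference), and the cells they do contain have adapted
their expression to the tissue environment, so a static reference is
systematically off.

This package implements **adaptive digital tissue deconvolution (ADTD)**,
which addresses both at once.  With all profiles normalized to sum to one
and `G = diag(g)` a learned gene weighting, ADTD minimizes

    L(C, x, Δ) = ‖G(Y − (Δ∘X)C − x(1ₙᵀ − 1ₚᵀ(Δ∘X)C))‖²_F
               + λ₁‖C − C₀‖²_F + λ₂‖J − Δ‖²_F

subject to `C ⪰ 0`, `x ⪰ 0`, `Σⱼxⱼ = 1`, `Δ ⪰ 0` and the per-sample
budget `colsum((Δ∘X)C) ≤ 1`.  Here

* `x` is a single **hidden background profile** shared by all samples,
  with per-sample weight `cᵢ = 1 − colsum((Δ∘X)C)ᵢ` — the expression
  mass not explained by the reference cell types;
* `Δ` is a genes × cell-types matrix of multiplicative **rescaling
  factors** adapting `X` to the analyzed tissue; entries far from 1
  indicate cell-type-specific gene regulation (`Δⱼₖ = 2` reads as
  "gene j is twice as active in cell type k as the reference claims");
* `C₀` is the plain weighted-NNLS composition, anchoring the solution
  (`λ₁ → ∞` recovers the naive pipeline with EPIC-style hidden
  proportions `max(0, 1 − Σₖ Cₖᵢ)`; `λ₂ → ∞` freezes `Δ` at 1).

The objective is minimized by block-coordinate descent: exact per-sample
quadratic programs for `C`, an exact water-filling solution on the gene
simplex for `x`, and exact non-negative row updates for `Δ` that respect
the budget coupling.  The gene weights `g` are learned beforehand from
mixtures of known composition (DTD, loss-function learning): `g`
maximizes the summed per-cell-type Pearson correlation between known and
re-estimated compositions.

The package also ships a synthetic single-cell/pseudo-bulk generator (so
the whole stack is testable without downloads), evaluation metrics
(per-type recovery correlations, hidden proportion/profile recovery,
regulation-detection AUC, gene ranking by `maxₖ|Δⱼₖ−1|`), and a CLI.

## Worked example

```python
from adtd import (ADTDModel, DTDModel, recovery_correlations,
                  hidden_recovery, profile_recovery, regulation_auc)
from adtd.io import RunConfig
from adtd.pipeline import simulate_dataset

# synthetic study: 4 reference cell types + a hidden population (~15%),
# 200 genes, 200 mixtures of 100 cells, 60 genes with spiked regulation
config = RunConfig(p=200, q=4, n=200, n_train=300, seed=3)
data = simulate_dataset(config)

dtd = DTDModel(data["X"].to_numpy(), data["Y_train"].to_numpy(),
               data["truth_train"].C_true).fit()
model = ADTDModel(data["Y_val"], data["X"], gene_weights=dtd.gene_weights,
                  lambda1=0.1, lambda2=1e-8)
result = model.fit()
print(result.summary())
```

prints

```
Adaptive digital tissue deconvolution
==============================================
genes: 200   cell types: 4   samples: 200
lambda1 = 0.1   lambda2 = 1e-08
converged: True after 42 iterations
final loss: 2.189574e-04
mean hidden weight: 0.0656
top |Delta - 1| genes: g00096 (2.764), g00019 (2.575), g00010 (2.566), g00090 (2.526), g00140 (2.512)
```

`result.C` holds the compositions, `result.x` the hidden profile,
`result.hidden_weights` the per-sample background weights and
`result.Delta` the rescaling factors.  Scoring against the generator's
ground truth,

```python
truth = data["truth_val"]
_, mean_r = recovery_correlations(truth.C_true, result.C)
hidden_r  = hidden_recovery(truth.hidden_true, result.hidden_weights)
profile_r = profile_recovery(truth.x_true, result.x)
auc       = regulation_auc(result.Delta, truth.regulation)
```

gives, for this seed: mean per-type Pearson r = 0.988, hidden-proportion
r = 0.911, hidden-profile r = 0.963 and regulation AUC = 0.903 — the
known cell types are recovered almost perfectly, the unseen population's
abundance and profile are reconstructed, and the spiked regulation
events rank clearly above unspiked (gene, cell type) pairs.

## Command line

```bash
adtd simulate --seed 1 --out-dir sim/
adtd train-weights --reference sim/X.tsv --bulks sim/Y_train.tsv \
    --compositions sim/C_train.tsv --out g.tsv
adtd deconvolve --reference sim/X.tsv --bulks sim/Y.tsv --weights g.tsv \
    --lambda1 0.1 --lambda2 1e-8 --out-dir fit/
adtd evaluate --truth-dir sim/ --estimate-dir fit/ --out report.json
adtd grid --lambda1-list 0.1,inf --lambda2-list 1e-8,inf --out grid.tsv
adtd run --seed 1 --out-dir run/          # all of the above end-to-end
```

All matrices are TSV with gene ids in the first column; `inf` is accepted
for either penalty and activates the corresponding exact limit.

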