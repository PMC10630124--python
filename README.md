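# gsfa — guided sparse factor analysis for single-cell CRISPR screens

Pooled CRISPR screens with single-cell RNA-seq readout (CROP-seq,
Perturb-seq) measure, for each cell, a transcriptome and the guide RNAs the
cell carries.  The analysis question is: which genes does each perturbation
affect?  Gene-by-gene differential expression tests are noisy at the
per-cell level and ignore the fact that perturbations act through
transcriptional programs.  `gsfa` addresses this with a two-layer Bayesian
factor model in which perturbations act on a small number of latent gene
modules (factors), and the factors determine gene expression:

```
Y = Z Wᵀ + E,        E_ij ~ N(0, ψ_j)          (sparse factor analysis)
Z = G β + Φ,         φ_ik ~ N(0, 1)            (perturbations guide the factors)
```

with `Y` the N×P (cells × genes) expression matrix, `Z` the N×K factor
matrix, `W` the P×K gene loadings, `G` the N×M binary perturbation matrix
and `β` the M×K perturbation-to-factor effects.  Sparsity is imposed by a
spike-and-slab prior on β, `β_mk ~ p_m N(0, d_m²) + (1−p_m) δ₀`, and a
normal-mixture prior on W, `W_jk ~ π_k N(0, σ_k²) + (1−π_k) N(0, σ_k² c_k²)`
with `0 < c_k < 1` (a point-mass spike-and-slab variant is available).
Inference is by Gibbs sampling; all conditionals are conjugate.

From the posterior draws the package reports:

- **PIP(β_mk) = Pr(γ_mk = 1 | data)** and **PIP(W_jk) = Pr(F_jk = 1 | data)** —
  posterior inclusion probabilities of effects and loadings;
- the **total effect** of perturbation m on gene j per draw,
  `θ_mj⁽ᵗ⁾ = Σ_k β_mk⁽ᵗ⁾ W_jk⁽ᵗ⁾ F_jk⁽ᵗ⁾`;
- the **local false sign rate**,
  `LFSR(θ_mj) = min{Pr(θ ≥ 0 | data), Pr(θ ≤ 0 | data)}`, and DEG lists at
  `LFSR < 0.05`;
- negative-control adjustment `β′_mk = β_mk − β₀k` for nonspecific guide
  effects, and a two-group mode with group-specific β.

Raw UMI counts are prepared for the model by a binomial deviance-residual
transform (a variance-stabilized, z-score-like quantity), deviance-based
feature selection, optional covariate regression, and per-gene scaling to
unit variance.  A simulation module generates data from the same generative
process (with a Poisson count layer) and an evaluation module scores
inference against ground truth and runs the comparison baselines
(Welch t-test, two-step clustering, two-step factor analysis) and
permutation calibration.

Intended users: computational biologists analyzing low-MOI single-cell
CRISPR screens, and methodologists benchmarking perturbation-effect
inference.

## Worked example

```python
import numpy as np
from gsfa import (SimConfig, simulate_counts, preprocess_counts,
                  GuidedSparseFactorModel)

# simulate a screen: 800 cells, 1000 genes, 6 perturbations hitting one
# factor each with effects 0.1..0.6, Poisson count layer
cfg = SimConfig(n_cells=800, n_genes=1000, factor_density=0.1, seed=11)
counts, guides, truth = simulate_counts(cfg)

Y = preprocess_counts(counts)            # deviance residuals, unit variance
model = GuidedSparseFactorModel(Y.Y, guides, n_factors=10,
                                gene_ids=list(Y.gene_ids))
results = model.fit(n_iter=1200, n_use=400, seed=0)
print(results.summary())
```

```
Guided sparse factor model fit
==================================
cells x genes:      800 x 1000
factors (K):        10
perturbations:      6
loading prior:      normal_mixture
iterations:         1200 (last 400 used)
seed:               0
variance explained: 16.1%

perturbation        factors PIP>0.95  DEGs (LFSR<0.05)
perturbation_0      -                 0
perturbation_1      -                 0
perturbation_2      -                 0
perturbation_3      -                 0
perturbation_4      -                 0
perturbation_5      5                 57
```

The strongest perturbation (true effect 0.6 on one factor) is confidently
assigned to a single inferred factor and yields 57 genes at LFSR < 0.05;
the weaker effects (0.1–0.5) do not clear the stringent PIP > 0.95 bar at
this reduced sample size — selection stays sparse rather than returning
false positives.  Matching true to inferred factors by absolute Pearson
correlation of the factor scores:

```python
from gsfa.evaluate import match_factors
fmap = match_factors(truth.Z, results.z_mean)
print(np.round([r for _, r in fmap.values()], 3))
# [0.953 0.923 0.958 0.959 0.96  0.952 0.962 0.131 0.957 0.948]
```

Nine of ten true factors are recovered with |r| ≈ 0.95.  Gene-level effects,
uncertainty and calls come from `results.pip_beta`, `results.mean_beta`,
`results.pip_w`, `results.lfsr()` and `results.call_degs(threshold=0.05)`;
`results.save("fit.h5")` round-trips the whole fit.

A command-line interface mirrors the library:

```bash
gsfa simulate --scenario count --cells 800 --genes 1000 --seed 1 --out sim/
gsfa transform --counts sim/counts --format mtx_dir --out tr/
gsfa fit --residuals tr/residuals.tsv --guides sim/guides.tsv --k 10 \
         --iters 1200 --use-last 400 --out fit/
gsfa summarize --fit fit/fit.h5 --out summary/
```

plus `select-k` (explained-variance elbow diagnostics), `calibrate`
(permutation null) and `evaluate` (the full simulation benchmark).

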