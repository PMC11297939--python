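# mrdcscreen

Marginal feature screening for ultrahigh-dimensional, heavy-tailed,
multi-platform omics data, based on **multivariate ranks** (optimal
transport onto low-discrepancy grids) and the **distance-correlation
V-statistic**, with the max-ratio gap criterion for threshold-free
selection. SIS (absolute Pearson correlation) and DC-SIS (raw distance
correlation) baselines, synthetic benchmark generators with full truth
bookkeeping, and the standard screening metrics (minimum model size S,
per-truth and simultaneous success rates) are included.

## Who this is for

Statisticians and computational biologists who need to rank tens of
thousands of candidate predictors (copy-number segments, methylation
probes, miRNA, protein arrays — possibly several platforms per gene)
against a high-dimensional response (e.g. a gene-expression matrix) when
the data are far from Gaussian: extremely long tails, outliers, nonlinear
and non-monotone associations, and a response that is mostly noise.

## The method

For a sample X¹,…,Xⁿ in ℝᵈ, fix a "uniform-like" reference set
𝓗 = {h₁,…,hₙ} ⊂ (0,1]ᵈ — the lattice {i/n} for d = 1, the first n points of
the unscrambled Sobol' sequence for d > 1 — and define the empirical
multivariate rank by the optimal assignment

    σ̂ = argmax_σ Σᵢ ⟨Xⁱ, h_σ(i)⟩,    R̂(Xⁱ) = h_σ̂(i),

solved exactly with the Hungarian algorithm. Dependence between a
response block **Y** and a predictor vector **Xⱼ** is the distance
correlation computed on the rank vectors:

    MrDcov²(X, Y) = S₁ + S₂ − 2S₃             (the usual V-statistic sums)
    MrDc(X, Y)    = MrDcov(X, Y) / √(MrDcov(X, X) · MrDcov(Y, Y))

Because the ranks are always a permutation of the fixed grid, MrDc is
distribution-free under independence and invariant to monotone marginal
transforms — a single 10⁶-fold outlier cannot move it. Screening computes
ω̂ⱼ = MrDc(Xⱼ, Y-block) for every predictor and every small response
subgroup (default 5 columns), then selects at the largest consecutive
ratio ω̂₍ⱼ₎/ω̂₍ⱼ₊₁₎ of the sorted scores. Two summaries of the
subgroup-by-predictor score table separate strong single associations
(one global cut) from pleiotropy — weak association with many response
components — via per-subgroup selection counts.

## Worked example

```python
import numpy as np
from mrdcscreen import (SimulationConfig, gen_study3, screen,
                        select_scenario1, min_model_size, cutoff_s)

cfg = SimulationConfig(study="study3", n=200, p=1000, q=100, seed=7)
ds = gen_study3(cfg)                  # 3 platforms: t2, t1, t3 margins
table = screen(ds.Y, ds.X, method="mrdc", group_size=5)
print(table.scores.shape)             # (20, 1000): 20 subgroups x 1000 predictors
print(ds.truth_positions(5))          # [2, 4, 1002, 1004, 2002, 2004]
print(min_model_size(table, ds.truth_positions(5)))   # 8
print(cutoff_s(200))                  # 37
print(select_scenario1(table).scenario1_positions)
# [4, 2, 2004, 1004, 1003, 3, 2002, 1002, 2003, 5, 1005, 2005]
```

All six true (subgroup, predictor) scores rank inside the top 8 of the
20,000 scores — well within the conventional cutoff s₁ = ⌊n/log n⌋ = 37.
The global max-ratio cut selects 12 pairs: the six truth positions plus the
immediate AR(1) neighbours of predictors 2 and 4 (columns 3 and 5), which
are correlated 0.8 with the truth and genuinely carry signal.

The same pipeline is available from the shell:

```bash
mrdc-screen simulate --study study3 --n 200 --p 1000 --q 100 --seed 7 --out-dir data/
mrdc-screen screen --response data/Y.tsv \
    --predictors data/X_df2.tsv --predictors data/X_df1.tsv --predictors data/X_df3.tsv \
    --method mrdc --group-size 5 --out scores.tsv --selection-out sel
mrdc-screen evaluate --scores scores.tsv --truth data/truth.json --n 200 --out report.tsv
```

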