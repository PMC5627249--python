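# grabld

Gradient boosted, LD adjusted (GraBLD) polygenic risk scores from GWAS
summary statistics.

## The problem

Polygenic risk scores (PRS) predict a complex trait as a weighted sum of SNP
dosages, `g(x_i) = Σ_j x_ij · w_j`, usually seeded with univariate effect
sizes `β_ext` published by large external meta-analyses. Two things limit the
naive score: the external effects are not calibrated to the target
population, and correlated SNPs (linkage disequilibrium, LD) are counted
multiple times. `grabld` implements a two-step heuristic addressing both:

1. **Boosted weight tuning.** The signed deviation of the target-cohort
   univariate coefficient from the external one,
   `d_j = (β_obs,j − β_ext,j) · sign(β_ext,j)`,
   is regressed on `|β_ext,j|` with gradient boosted regression trees.
   SNPs are split into K contiguous genome blocks (default 5); the deviation
   of every SNP in a block is predicted by a model trained on the other
   blocks, so a SNP's own observed coefficient never influences its own
   weight — a leakage-free, LD-spillover-safe partition. Tuned weights are
   `ŵ_j = sign(β_ext,j) · (|β_ext,j| + d̂_j)`.
2. **Windowed LD correction.** Each weight is divided by
   `η_j = Σ_{k=j−W..j+W} r²_jk` (default W = 100 SNPs per side, self term
   included), the sum of squared genotype correlations with neighbouring
   scored SNPs. Five SNPs in perfect mutual LD each get η = 5, so together
   they contribute exactly like one uncorrected SNP.

The final score uses `w̃_j = ŵ_j / η_j`. For quantitative traits the score
is judged by the prediction R² = Cov(g,y)²/(Var(g)Var(y)); for binary traits
by the ROC AUC; calibration by linear recalibration, decile tables and the
Hosmer–Lemeshow test.

The package also ships a simulation suite that verifies the theory of the
LD correction on synthetic block-LD genomes: Cov(g,y) is an unbiased
estimator of the true regional genetic variance, Var(g) exceeds it, and
under realistic partial LD the prediction R² recovers ≈88% of the true
genetic variance.

## Worked example

```python
import numpy as np
from grabld import (read_genotypes, read_summary_stats, harmonize,
                    GraBLD, BoostConfig, SimConfig)
from grabld.simulate import write_cohort_fixture

# simulate a small cohort + external summary statistics (or read your own)
paths, _ = write_cohort_fixture("demo", SimConfig(
    m_snps=200, n_target=1500, n_external=20000, pool_haplotypes=10000, seed=7))
panel = read_genotypes(str(paths["plink"]) + ".bed")
stats = read_summary_stats(paths["summary"])
import pandas as pd
pheno = pd.read_csv(paths["phenotype"], sep="\t").set_index("sample_id") \
          .reindex(panel.sample_ids)["trait"].to_numpy()

study = harmonize(panel, stats, phenotype=pheno)
res = GraBLD(study, boost=BoostConfig(n_trees=300, shrinkage=0.01, seed=7)).fit()
print(res.summary())
report = res.evaluate(study.genotypes_std, study.phenotype)
print(f"prediction R2: {report.r2:.3f}")
```

prints (abridged):

```
       GraBLD polygenic score fit
========================================
                 No. SNPs            200
No. samples (calibration)           1500
       Folds (contiguous)              5
Trees / depth / shrinkage 300 / 5 / 0.01
 Bag fraction / selection      0.5 / oob
         LD window (SNPs)            100
        Weight convention        adapted
    corr(beta_ext, w_hat)         0.9925
                 mean eta         2.0230
             mean |d_hat|       0.005703
----------------------------------------
prediction R2: 0.286
```

`corr(beta_ext, w_hat)` near 1 says the trees made only gentle adjustments
(the external study here is well calibrated); `mean eta ≈ 2.0` reflects the
block-LD structure of the simulated region; the prediction R² on the
calibration cohort is close to the simulated regional heritability (0.3),
the in-sample ceiling for a 200-SNP score. The same pipeline is available stage-by-stage from
the shell: `grabld harmonize | beta-obs | boost | ld-adjust | score |
evaluate | simulate | end-to-end` (see `grabld --help`).

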