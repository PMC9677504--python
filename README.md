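# omicsmr

Multi-omics Mendelian randomization (MR) with dependence-aware P-value
combination.

## The problem

When QTL summary statistics are available for several omics biomarkers of one
gene — expression (eQTL), protein (pQTL), metabolite (metQTL), methylation
(meQTL) — each biomarker can be tested for a causal/pleiotropic effect on a
disease outcome by two-sample MR against GWAS summary statistics. That yields
m P-values per gene, and they are *dependent*: the biomarkers share cis-SNP
instruments in linkage disequilibrium (LD) and often share biology. `omicsmr`
provides the per-exposure MR engines, combination tests that stay valid under
that dependence, and a simulation benchmark that measures type I error and
power of every engine × combiner pair.

## Methods at the core

**Engines** (per exposure k, SNPs j = 1…p with exposure effects β̂_Xkj, outcome
effects β̂_Yj, outcome standard errors σ̂_Yj, unsquared LD matrix R):

- **IVW** — θ̂ = Σ β̂_Xj β̂_Yj σ̂_Yj⁻² / Σ β̂_Xj² σ̂_Yj⁻², var(θ̂) = (Σ β̂_Xj² σ̂_Yj⁻²)⁻¹
  (uncorrelated instruments).
- **GLS** — θ̂ = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹ β̂_Xᵀ Ω⁻¹ β̂_Y with Ω = diag(σ̂_Y) R diag(σ̂_Y);
  accounts for LD, reduces to IVW at R = I.
- **SMR** — single-SNP T = z_Y² z_X² / (z_Y² + z_X²) ~ χ²(1), in `singleSNP`
  (strongest QTL per exposure) and `allSNPs` variants.
- **GSMR** — per-SNP Wald ratios pooled by GLS against their second-order
  covariance under LD, with instrument filters r² < 0.95 and z_X² > 10.
- **Multivariable MR** — joint m-df Wald test of all exposures' direct effects
  in the weighted regression β̂_Y ~ Σ_k θ_k β̂_Xk.

**Combiners** for the m per-exposure P-values p_k:

- **Cauchy (ACAT)** — T = Σ w_k tan{(0.5 − p_k)π}; valid under arbitrary
  dependence.
- **HMP** — harmonic mean Σw / Σ(w/p), calibrated against the one-sided stable
  (Landau) law with tail index λ = β = 1.
- **MinP** — min p_k taken as the P-value (no correction; benchmark control).
- **Fisher χ²** — −2Σ ln p_k vs χ²(2m) (exact only under independence).
- **Fisher gamma** — the same statistic against a moment-matched gamma null
  whose variance 4m + 2Σ_{i<j} c(ρ_ij) uses the Brown/Kost polynomial in the
  correlations ρ_ij of the exposures' GLS z-statistics, which are computed
  from the LD matrix alone (`gls_z_correlation`). Only available with the
  GLS engine.

**Simulator** — individual-level genotypes (Binomial(2, 0.3) dosages with
equicorrelated pairwise LD via a Gaussian copula), three omics exposures under
vertical (serial) or horizontal (parallel) pleiotropy with a shared
confounder, continuous or case/control outcomes, and configurable subject
overlap between the QTL and GWAS studies; summary statistics are produced by
per-SNP OLS/logistic regressions exactly as a study would.

## Worked example

Simulate one gene-scale study and analyze it with GLS + Fisher-gamma:

```bash
omicsmr simulate --seed 42 --out-dir sim
omicsmr mr --qtl X1=sim/qtl_X1.tsv --qtl X2=sim/qtl_X2.tsv --qtl X3=sim/qtl_X3.tsv \
           --gwas sim/gwas.tsv --ld sim/ld.tsv --engine gls --combiner fisher_gamma
```

```
exposure    snps                           theta      se        z        pval      method
X1          snp1,snp2,snp3,snp4,snp5       0.1249     0.1217    1.026    0.3048    gls
X2          snp1,snp2,snp3,snp4,snp5       0.0619     0.0622    0.996    0.3191    gls
X3          snp1,snp2,snp3,snp4,snp5      -0.1388     0.1223   -1.135    0.2564    gls
(combined)                                                       0.2924   fisher_gamma

gene-level P = 0.2924 (not significant at 0.05)
```

Each row is one biomarker's GLS causal-effect estimate against the outcome
(here a null simulation — no effect, and none is found); the combined row is
the gene-level P-value after correcting for the correlation between the three
tests (the simulated exposures are nearly collinear, so the effective number
of independent tests is close to 1).

The same analysis is available as a library:

```python
import omicsmr as om
cfg = om.SimulationConfig(beta_x=0.1, alpha=2.0)           # a power setting
rep = om.simulate_replicate(cfg, rng)
qtls, gwas, ld = om.compute_summary(rep, cfg)
res = om.analyze_gene(qtls, gwas, ld, engine="gls", combiner="fisher_gamma")
print(res.pval)
```

and `omicsmr benchmark` replays settings × methods over many replicates and
tabulates empirical rejection rates with Monte-Carlo standard errors.

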