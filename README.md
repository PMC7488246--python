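# pigsnp

Discovery and evaluation of small SNP panels that predict ordinal **eye and
hair color** in genetically structured populations — the forensic-DNA-
phenotyping setting where reference panels such as HIrisPlex-S, trained on
West Europeans, underperform on cohorts with different ancestry (e.g. North
Eurasian populations spanning the Caucasus, European Russia, West Siberia and
North Asia).

## What it does

Given a multi-sample VCF over candidate pigmentation regions and a phenotype
table (population, region, 5-grade eye darkness, 5-grade hair darkness with
grade 0 = red), the pipeline:

1. **QC** — keeps variants with QUAL > 40 and read depth DP > 5, drops
   samples with a genotyping rate below 90%;
2. **encodes** genotypes additively (`0/0 → 0`, `0/1 → 1`, `1/1 → 2`) and
   mean-imputes residual missing calls from training samples only;
3. **filters populations** that do not span at least 4 of the 5 phenotype
   grades (to balance phenotypic classes across the structured cohort);
4. **splits** each dataset 60:40 into training and test, stratified by
   phenotype class × region;
5. **scores every SNP** on the training split with three feature-selection
   methods, treating the 5-grade scale as a continuous pigment concentration:
   - the univariate regression F test,
     `F = r²/(1−r²)·(n−2)` with `p` from `F(1, n−2)`, gated at `p < 0.01`;
   - a k-nearest-neighbor **mutual information** estimate (nats);
   - the **Lasso**, `min_w ‖Xw − y‖²/(2n) + α‖w‖₁`, over the penalty grid
     α ∈ {0.7, 0.5, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005}, on the raw
     0/1/2 scale (no standardization — the coefficient thresholds below are
     meaningful only on that scale);
6. **assigns rule-based scores 0–3** per dataset (pooled cohort and each
   region; score 3 exists only for the pooled dataset), e.g. for pooled eye
   color: 3 for top-5 F, |coef| ≥ 0.1 at α = 0.2 or non-zero at α = 0.5;
   2 for top-10 F/MI or non-zero at α = 0.2; 1 for |coef| ≥ 0.1 at α = 0.005;
7. **ranks SNPs by total score** (sum over datasets) and cuts a *minimal*
   set (top total-score tier) and an *optimal* set (all pooled-supported
   SNPs);
8. **fits a linear regression** of the ordinal grade on the selected SNP
   codes, converts the continuous prediction to the nearest class
   (eye: blue / intermediate / brown; hair: red / blond / brown / dark, plus
   a merged blond+brown 3-class scale), and reports per-class one-vs-rest
   AUC, precision, recall, overall accuracy and r² on the held-out split,
   with N/A for classes below a minimum test count.

A first-class **synthetic cohort generator** emulates the data this analysis
assumes: Balding–Nichols regional allele-frequency divergence, LD blocks from
shared latent haplotypes, a few strong-effect causal SNPs driving an additive
liability cut at ordered thresholds into the 5-grade scales, a recessive
red-hair locus, genotype missingness, and synthetic QUAL/DP fields so the QC
stage is exercised.

## Worked example

```python
import pigsnp as pg

# simulate a 300-sample, 3-region cohort with 5 causal eye-color SNPs
cfg = pg.SimulationConfig(
    n_samples_per_region=100,
    regions=("Caucasus", "EuropeanRussia", "WestSiberia"),
    n_snps=5000, populations_per_region=1, seed=7,
)
genotypes, phenotypes, truth = pg.simulate_cohort(cfg)
paths = pg.write_dataset(genotypes, phenotypes, truth, "cohort/")

config = pg.PipelineConfig(vcf=str(paths["vcf"]),
                           phenotypes=str(paths["phenotypes"]), trait="eye")
result = pg.run_full_pipeline(config, seed=7)

print({k: len(v) for k, v in result["snp_sets"].items()})
print(result["ledger"].head(3))
rep = result["reports"]["minimal_eye3"]
print(rep.per_class.round(3), "accuracy", round(rep.accuracy, 3))
```

prints (numbers from this exact seed):

```
{'minimal': 8, 'optimal': 54}
              pooled  Caucasus  EuropeanRussia  WestSiberia  total  n_datasets
snp_id
1:110300_T_G       3         0               0            2      5           2
1:160200_G_T       3         0               2            0      5           2
1:10200_G_C        3         0               0            0      3           1
               n    auc  precision  recall
class
blue          40  0.921      0.875   0.700
intermediate   4    NaN        NaN     NaN
brown         77  0.939      0.981   0.675
accuracy 0.678
```

The minimal set contains the five planted causal SNPs (or members of their
LD blocks); the two top-ranked SNPs also carry regional support, mirroring
how the strongest pigmentation SNPs replicate across regions.  The 4-sample
intermediate class is reported N/A (below the 10-sample minimum), and the
held-out one-vs-rest AUCs for the extreme classes are ≈ 0.92–0.94 (hard-class
accuracy is lower because shrunken regression predictions concentrate near
the class boundaries).

The same flow is available from the shell:

```bash
pigsnp simulate --config sim.yaml --out cohort/ --seed 7
pigsnp run --vcf cohort/cohort.vcf --pheno cohort/phenotypes.tsv \
           --trait eye --seed 7 --out results/
pigsnp evaluate --pred external_predictions.csv --pheno cohort/phenotypes.tsv
```

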