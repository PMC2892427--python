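# famstage

Staged genome-wide association testing for **quantitative traits in family
data**, with the simulation machinery to study its type I error and power.

Cohorts built from pedigrees (trios, sibships, multi-generation families)
break the two workhorse assumptions of population-based GWAS: phenotypes are
correlated within families, and hidden population stratification can fake
genotype–trait associations.  `famstage` implements the three association
engines a family-GWAS needs and chains them into a screening pipeline that is
fast, calibrated, and robust to admixture:

1. **LM** — ordinary least squares of trait on allele count (two-sided t
   test).  Fast but anti-conservative under familial correlation; used only
   as a liberal screen (p < 0.1 by default).
2. **LME** — a kinship linear mixed model,
   `Y ~ N(β₀ + βX, σ²_g·2Φ + σ²_e·I)` with `Φ` the block-diagonal kinship
   matrix, fitted by maximum likelihood and tested by a 1-df Wald chi-square
   on β.  Calibrated under familial correlation; applied only to SNPs that
   pass the screen, with a genome-wide cut-off (10⁻⁶ by default).
3. **FBAT** — the quantitative family-based association test
   `Z = S/√V`, `S = Σ Tᵢⱼ(Xᵢⱼ − E[X|Pᵢ])`, which compares offspring
   genotypes with their Mendelian expectation conditional on parental
   genotypes and is therefore immune to stratification.  Run only on
   genome-wide-significant SNPs; the final p-value is the FBAT p-value
   Bonferroni-corrected **only for the n SNPs that reached stage 3**
   (`min(1, n·p)` against a familywise 0.05).

The package also contains the full simulation stack used to validate this
design: pedigree generation, recursive kinship, Mendelian gene dropping,
two-locus haplotype dropping at a target LD r², Balding–Nichols
subpopulation allele frequencies with a trait-mean offset, and
variance-component trait simulation (QTL + polygenic + residual, with
non-normal marginal transforms).  See `docs/methods.md` for the models and
their assumptions.

## Worked example

```python
import numpy as np
import famstage as fs
from famstage.simstudy import default_panel

ped  = default_panel(200)                    # 840 individuals, 200 families
kin  = fs.compute_kinship(ped)
fams = fs.extract_nuclear_families(ped)
rng  = np.random.default_rng(11)

# 20 SNPs; the first is a causal QTL explaining 8% of trait variance
cols  = [fs.drop_genotypes(ped, 0.2, rng).counts[:, 0] for _ in range(20)]
genos = fs.GenotypeMatrix(np.column_stack(cols),
                          [f"snp{j}" for j in range(20)], ped.ids)
model = fs.TraitModel(q2=0.08, polygenic_h2=0.3, qtl_allele_freq=0.2)
y     = fs.simulate_trait(ped, kin, model, rng, qtl=genos.counts[:, 0])

res = fs.run_three_stage(y, genos, kin, fams,
                         fs.StageConfig(alpha1=0.1, alpha2=1e-4))
print("n_stage3 =", res.n_stage3)
print(res.table[res.table.stage_reached >= 2])
```

prints

```
n_stage3 = 1
snp_id  stage_reached    lm_pvalue   lme_pvalue  fbat_pvalue  adjusted_pvalue  significant
  snp0              3 7.122874e-20 1.592368e-17     0.000362         0.000362         True
```

The causal SNP survives the LM screen (p ≈ 7·10⁻²⁰), reaches genome-wide
significance in the mixed model (p ≈ 2·10⁻¹⁷), and is confirmed by FBAT
(p ≈ 3.6·10⁻⁴); with a single stage-3 SNP the Bonferroni-adjusted final
p-value equals the FBAT p-value and falls under the 0.05 familywise level.
The 19 null SNPs stop at stage 1 or 2 and are reported not associated.

A command-line interface mirrors the library:

```sh
famstage simulate --n-families 200 --n-snps 20 --q2 0.08 --seed 11 --out-dir run/
famstage staged --ped run/pedigree.ped --geno run/genotypes.tsv \
                --pheno run/phenotypes.tsv --alpha2 1e-4 --out run/staged.tsv
famstage simstudy --experiment table1 --n-reps 1000 --seed 1 --out run/sim/
```

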