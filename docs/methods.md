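# Methods

`famstage` implements a staged association-testing strategy for quantitative
traits measured on families, together with the simulation machinery needed to
study its operating characteristics.  This note records the statistical
models, the simulation design, the numerical choices, and the limits of what
the package's own validation can show.

## The three engines

**Least squares (LM).**  For trait $Y_{ij}$ (person $j$ in family $i$) and
additive genotype coding $X_{ij} \in \{0,1,2\}$ (minor-allele count),

$$Y_{ij} = \beta_0 + \beta X_{ij} + \varepsilon_{ij}, \qquad
\varepsilon_{ij} \sim \text{iid } N(0, \sigma^2),$$

tested with the classical two-sided t test ($n-2$ df).  LM ignores the
phenotypic correlation among relatives, so under a polygenic trait its type I
error is inflated — the inflation grows with heritability.  It is kept as a
cheap screen, not as an inference tool.

**Kinship linear mixed model (LME).**  The polygenic background is modelled
as a random effect whose correlation between two members of a family is twice
their kinship coefficient $\varphi$:

$$Y \sim N(\beta_0 + \beta X,\; \sigma_g^2 \, 2\Phi + \sigma_e^2 I),$$

with $2\Phi$ block diagonal over families.  The fit is maximum likelihood.
We reparameterise the covariance as $\sigma^2[(1-h)I + h\,2\Phi]$ with
heritability ratio $h = \sigma_g^2/(\sigma_g^2+\sigma_e^2) \in [0,1)$;
$(\beta_0,\beta,\sigma^2)$ are profiled out in closed form via GLS in the
eigenbasis of $2\Phi$ (computed once per family block and cached), leaving a
one-dimensional bounded search over $h$ (tolerance $10^{-8}$, at most 200
iterations, with the $h=0$ boundary checked explicitly and accepted without
p-value adjustment — the Wald test on $\beta$ is unaffected by a boundary
variance estimate).  The genotype effect is tested by the Wald chi-square
$W = (\hat\beta/\text{SE})^2$ against the upper tail of $\chi^2_1$, which is
numerically identical to a two-sided Z test on $\hat\beta/\text{SE}$; a
chi-square statistic has only one usable tail, which is how we read the
"one-sided Wald chi-square" convention of the mixed-model GWAS literature.

**Quantitative FBAT.**  Conditional on parental genotypes $P_i$, offspring
transmissions are Mendelian under the null of no linkage and no association,
regardless of population structure.  With $T_{ij} = Y_{ij} - \mu$,

$$S = \sum_{ij} T_{ij}\,(X_{ij} - E[X_{ij}\mid P_i]), \qquad
V = \sum_{ij} T_{ij}^2\, \text{Var}(X_{ij}\mid P_i),$$

where $E[X\mid P] = (x_f + x_m)/2$ and
$\text{Var}(X\mid P) = (\mathbb{1}[x_f{=}1] + \mathbb{1}[x_m{=}1])/4$ for
additive coding, $Z = S/\sqrt V$ is referred to a standard normal
(two-sided).  Offspring transmissions are treated as independent given
parents, which is exact under the no-linkage, no-association null.  The
offset $\mu$ defaults to the sample mean of the tested offspring phenotypes —
the standard variance-reducing choice for quantitative FBAT — and is
configurable (e.g. 0).  Parental phenotypes never enter the statistic; that
parents nevertheless contribute to LM/LME is precisely the power argument for
combining the engines.  Only nuclear families with BOTH parents genotyped are
used; extended pedigrees are decomposed into (father, mother, offspring)
units, so one person may be offspring in one unit and parent in another.
Sufficient-statistic reconstruction of missing parents is deliberately out of
scope.

## The staged pipelines

Stage 1 screens every SNP with LM at a liberal cut-off $\alpha_1$ (default
0.1).  Stage 2 runs the LME only on survivors and applies the genome-wide
cut-off $\alpha_2$ (default $10^{-6}$).  Stage 3 runs FBAT on stage-2 hits
and reports, as the final p-value, the FBAT p-value Bonferroni-corrected only
for the $n_3$ SNPs that entered stage 3: $\min(1, n_3 p)$, compared against
the familywise level $\alpha_3$ (default 0.05).  SNPs that never reach
stage 3 are deemed not associated.  The adjustment is applied to
full-precision p-values; arithmetic done on rounded, printed p-values can
differ in the last digit.  A SNP that enters stage 3 but is FBAT-
non-informative still counts toward $n_3$ (conservative) and is reported
untested.  An optional top-SNP restriction keeps only the smallest-LME-p SNP
per externally supplied locus, with $n_3$ becoming the number of loci (ties
break to the lowest SNP id); LD-based clumping is not implemented.

## Simulation framework

**Pedigrees.**  The default study panel is 500 families — 40% parent–child
trios, 40% two-child nuclear families, 20% seven-member three-generation
families (≈ 2,100 individuals, ≈ 700 FBAT-usable offspring).  It stands in
for a large family cohort at desk scale: big enough for stable rate
estimates, small enough that a 10,000-replicate study runs in well under a
minute per engine.  Panel construction is deterministic (largest-remainder
apportionment of templates, interleaved across family order).

**Kinship** is computed by the tabular recursion
$\varphi_{kk} = (1+\varphi_{f_k m_k})/2$,
$\varphi_{kj} = (\varphi_{f_k j}+\varphi_{m_k j})/2$ with parents processed
before children; the recursion handles inbreeding loops without special
casing.  It is validated against a Monte-Carlo gene-drop IBD oracle in the
tests.

**Genotypes.**  Founders draw alleles under HWE at the design frequency;
offspring receive one uniformly chosen allele per parent (gene dropping), so
Mendelian consistency is exact.  QTL/marker pairs at a target $r^2$ are
dropped as two-locus haplotypes with
$D = +\sqrt{r^2 p_A(1-p_A) p_B(1-p_B)}$ (the sign of $D$ affects neither
$r^2$ nor two-sided tests) and no recombination within the pair, so founder
LD is preserved through the pedigree.  Subpopulation allele frequencies for
stratification studies follow the Balding–Nichols Beta model (mean $p$,
variance $p(1-p)F_{ST}$); whole families are assigned to the two
subpopulations alternately in family order, giving near-equal sizes (the
assignment rule is this package's choice — splitting a family would break
the founder-frequency model).  No genotyping error or missingness is
simulated; missing-data handling lives in the engines (listwise deletion for
LM/LME, per-offspring exclusion for FBAT).

**Traits.**  $Y = a(X_{qtl} - 2p) + g + e$ on a standardised scale
(mean 0, total variance 1 by default): $a = \sqrt{q^2/(2p(1-p))}$ so the QTL
explains fraction $q^2$ among HWE founders (the design frequency is used, so
realised QTL variance fluctuates across replicates); $g \sim
N(0, h^2\,2\Phi)$ per family block; $e$ iid.  Non-normal marginals
(absolute normal, $\chi^2_1$, lognormal) are produced by transforming the
multivariate-normal draw element-wise, which preserves familial dependence —
the conventional way simulated variance-component traits are made
non-normal.  The stratification offset $\delta$ (default 0.25, trait-SD
units) is added to subpopulation 2 last, after any transform.

**Replication.**  Replicate $i$ of a study seeded with $s$ uses generator
seed $s+i$, making runs reproducible and resumable; every reported rate
carries its binomial standard error.

## Choices where the design was open

- The unlinked-QTL type I error design leaves the QTL's own frequency free;
  we use MAF 0.3, comparable to the frequencies of the worked power and
  admixture designs (0.31 and 0.3).
- Genome-panel experiments evaluate "by replicate": the event is any
  rejection among the panel's SNPs in that replicate.
- Admixture orderings are evaluated at panel-scaled significance levels
  (per-SNP 0.05 pooled over SNPs, and a genome-wide $0.05/n_{\text{SNPs}}$
  cut-off for the by-replicate rates).  At a cohort of ≈ 2,100 individuals
  the confounding shift in a test statistic scales with $\sqrt n$, so at
  $10^{-6}$ every method's rate is indistinguishable from zero and the
  inflation ordering would be invisible; the drivers keep the significance
  level configurable.

## Known limitations

- With a small simulated genome and a correspondingly liberal genome-wide
  cut-off, the three-stage by-replicate false-positive rate under admixture
  shows a small excess over the familywise level (≈ 0.08 vs 0.05 in our
  studies) because FBAT and LME statistics are positively correlated among
  the SNPs selected into stage 3 — sequential use of the two statistics does
  not admit an exact analytic level.  The rate remains several-fold below
  the population-based methods' inflation, which is the property the
  three-stage design is built on.
- The ML (not REML) mixed model is very slightly anti-conservative at a few
  hundred families; rates in our studies sit within Monte-Carlo error of the
  nominal level at 500 families.
- The synthetic panel cannot reproduce magnitudes that depend on a specific
  cohort's pedigree structure or on real LD patterns (e.g. exact LM
  inflation factors or statistic correlations); those are validated as
  orderings, not values.
- Only biallelic SNPs, additive coding, and a single fixed intercept are
  supported; dichotomous traits, covariates, X-linked kinship and weighted
  multi-stage FBAT generalisations are out of scope.
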