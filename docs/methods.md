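# Methods

`famlipid` studies the genetic architecture of familial combined
hyperlipidemia (FCH): how much of the familial aggregation of high total
cholesterol (TC) and/or triglycerides (TG) is carried by common
lipid-associated SNPs acting in aggregate (polygenic scores), how much by
rare high-impact Mendelian genotypes (APOE ε2ε2, APOA5 rs3135506
homozygosity), and whether lipid-raising alleles are systematically
over-represented in affected family members relative to the general
population.  Because the family and cohort data such a study needs are not
public, the package pairs every analysis stage with a synthetic-data
generator whose structure matches the assumptions the statistics rely on.

## The synthetic study

**Population cohort.** `n = 18,715` unrelated individuals by default.
Genotypes at panel SNPs are independent Hardy–Weinberg draws,
`dosage ~ Binomial(2, MAF)`.  Ages are uniform on 25–75 years; sex is
balanced.

**Variant panel.** 212 SNPs by default: 106 assigned to the LDL-C score
and 106 to the TG score (disjoint sets), 44 OMIM-flagged.  MAFs are
log-uniform on (0.002, 0.5], populating the rare, low-frequency and common
classes (rare: MAF ≤ 0.5%; low-frequency: 0.5% < MAF ≤ 5%; common:
MAF > 5%).  Signed effects are drawn with equal expected per-SNP variance
contribution and rescaled so the panel jointly explains a fixed share of
trait variance (`h2_ldl = h2_tg = 0.15` by default — a simulator
convention, chosen as an upper-middle value for a curated lipid panel; no
published decomposition is being asserted).  Three named variants occupy
fixed slots with literature-typical Finnish frequencies and effects:
rs429358 (APOE ε4 tag, MAF 0.18, +0.15 mmol/l LDL-C per allele), rs7412
(APOE ε2 tag, MAF 0.041, −0.45 mmol/l), and APOA5 rs3135506 (MAF 0.062,
+0.25 log-TG per allele).

**Families.** Three-generation pedigrees: a founder couple, a sibship of
mean ≈ 3.2, spouses marrying in with probability 0.7, and grandchild
sibships of mean ≈ 2.5 — mean family size ≈ 13–14.  One second-generation
member is the designated index case.  Genotypes descend by gene dropping:
founders are Hardy–Weinberg draws, each meiosis transmits one uniformly
chosen allele per parent.  The APOE locus segregates as a single
three-allele haplotype (ε2/ε3/ε4) and is expanded to the two SNP dosages
afterwards, so rs429358/rs7412 combinations can never imply an ε1-like
haplotype.

**Phenotypes.** LDL-C is additive on the natural scale:
baseline 3.3 mmol/l + age and sex terms + Σ dosage×β + shared-family
effect + Gaussian residual, with total SD 0.9 mmol/l.  TG is additive on
the log scale and exponentiated (log-normal, matching the right skew of
serum TG), total log-scale SD 0.5.  HDL-C is log-normal with a sex shift;
TC closes over the Friedewald relation in reverse, TC = LDL-C + HDL-C +
0.45·TG — a simulator convention (the emulated study measured TC
directly).  The shared-family variance fraction is 0.15 per trait
(convention; it controls familial aggregation beyond the panel).
Residual variance absorbs the remainder so population and family totals
match.  Exclusion conditions (diabetes 5%, cancer 3%, lipid-lowering or
estrogen medication 5%) are independent draws.

**Affection and ascertainment.** Sex- and 5-year-age-band 90th percentiles
of TC and TG are estimated from the (exclusion-filtered) population cohort
by linear-interpolation quantiles; ages outside the covered range clamp to
the nearest band.  Affected ⇔ not excluded and TC ≥ threshold or TG ≥
threshold (inclusive), subtyped TC-only / TG-only / both.  A candidate
family enters the study iff the index case is affected, at least one of
their first-degree relatives is affected, and at least one affected member
has elevated TG.  Candidates are generated until 53 families pass.  The
index criterion replaces the premature-CHD clinic ascertainment of real
FCH studies (CHD is not modelled; it never enters the statistics).

**What the generator does not emulate:** linkage disequilibrium between
panel SNPs, recombination maps, X-linked inheritance, assortative mating,
non-additive effects (including the recessive TG effect of ε2ε2),
age-by-genotype interactions, and shared-environment structure beyond a
single family-level effect.  Tests passing on these simulations therefore
certify the statistical machinery and its calibration under the stated
model, not distributional details of real Finnish lipid data.

## Polygenic scores

Per-SNP weights are the coefficients of one multiple linear regression per
trait — all score-member SNP dosages simultaneously, plus age and sex —
fitted in the exclusion-filtered population cohort (never in the
families).  TG is regressed on the log scale, the scale on which the
simulator is additive; this is a package convention, stated here because
the analogous published analyses do not document the transform.  SNPs with
fewer than two effect-allele copies among fitted individuals are dropped
and listed.  The score is Σ weight × effect-allele dosage with missing
dosages mean-imputed at 2×MAF (frequency estimation, by contrast, uses
complete observations only, keeping frequencies unbiased while scores stay
defined).  "High" means ≥ the empirical 90th percentile of the population
score distribution.

## Enrichment against a MAF-binned empirical null

For each panel SNP the effect allele is the population minor allele
(effect/other are stored explicitly and folded once, here).  The
enrichment ratio is the affected-family allele frequency over the
population frequency; relatedness among the affected individuals is
deliberately kept, because the null is built under the same family
structure: 200,000 effect-free background variants are gene-dropped
through the same pedigrees, their population frequencies drawn as
`Binomial(2N, MAF)/2N` (the exact sampling law of an HWE frequency
estimate), variants within 50 kb of a panel locus or below MAF 0.001
excluded, and each surviving ratio assigned to one of 15 minor-allele
frequency bins ([0.1%,0.5%), [0.5%,1%), …, [45%,50%)).  Per-bin empirical
2.5%/97.5% quantiles give the 95% credible band; per-SNP one-sided p is
the add-one tail probability in the direction of the observed ratio
(upper tail for ratios ≥ 1).  Because case allele counts are discrete the
tail p has atoms; calibration diagnostics therefore use the randomized
tail probability, which is exactly uniform when panel and null ratios are
exchangeable.  The direction-concordance sign test is the exact one-sided
binomial upper tail on the count of SNPs whose enrichment direction
matches their effect sign (elevating ∧ ratio > 1, or lowering ∧ ratio <
1; zero-beta SNPs, carrier-free SNPs and exact ties are uninformative and
dropped).

## APOE calling and Mendelian carriers

The isoform pair is a deterministic function of the unphased rs429358 and
rs7412 genotypes for every combination with rs429358-C count + rs7412-T
count ≤ 2; other combinations imply an ε1-like haplotype and are flagged
inconsistent rather than guessed.  rs429358 carries a simulated
imputation posterior (Beta-distributed around 1 − error, default mean
error 3%); the isoform is determined only when the posterior exceeds 0.9.
Per-isoform concordance is reported as 100 × (n imputed as the isoform) /
(n observed with it), so values can exceed 100 when miscalls flow into an
isoform.  High-impact Mendelian carriers are APOE ε2ε2 individuals and
APOA5 rs3135506 homozygotes; missing data never creates a carrier.

## Relatedness-aware statistics

The GRM is `K[i,j] = (1/m) Σ_k (x_ik − 2p_k)(x_jk − 2p_k) / (2p_k(1−p_k))`
over polymorphic variants, with allele frequencies estimated from the
supplied sample by default (configurable; note the classic −1/(n−1)
off-diagonal shrinkage when frequencies come from a small related sample —
tests supply generator frequencies where that matters).  Trait contrasts
between affected and unaffected members use `y = Xβ + g + e`,
`g ~ N(0, σ_g²K)`, `e ~ N(0, σ_e²I)`, fitted by REML: one
eigendecomposition of K turns every likelihood evaluation into diagonal
algebra; the mixing fraction h = σ_g²/(σ_g²+σ_e²) is profiled on a grid
and refined by bounded scalar minimisation (xatol 1e−8); total variance is
profiled analytically on n − p degrees of freedom.  At K = I the fit
reduces exactly to OLS.  The Wald statistic on the group coefficient is
referred to the standard normal; binary affection is fitted with the same
linear model (matching standard mixed-model association practice).
Eigenvalues more negative than −1e−8·max are an error; small negatives are
clipped to zero.

Prediction uses PPV = P(affected | flag) and NPV = P(unaffected | no
flag).  Family summaries count affected members "explained" (either score
high or Mendelian carrier); "over half" is strict inequality, "all"
requires every affected member explained with ≥ 1 affected.  The
genetic-correlation check averages off-diagonal GRM entries over all
affected pairs per family (≥ 2 affected members) and regresses that mean
on the family's explained-count rank by simple linear regression.

## Problem sizes and numerical choices

The default study is simulated at full design scale (population 18,715;
53 families; 212 SNPs; 200,000 null variants).  Test simulations scale
down where a property does not need the full size: weight-recovery
coverage uses 30-SNP panels in cohorts of 600 over 200 replicates;
sign-test power uses populations of 4,000 with 40 families over an
8-replicate, 3-point TG-effect grid; mixed-model type-I uses 60
four-sib families over 300 replicates.  Quantiles are linear-interpolation
throughout.  All randomness flows through `numpy.random.default_rng`
seeded from the configuration, so identical configurations reproduce
bit-identical studies.

## Known limitations

Sign-test power at the 53-family scale is modest and seed-dependent (the
TG test rejects in most but not all replicates), mirroring the intrinsic
noisiness of per-SNP frequency ratios measured on ~240 related cases.
The REML Wald p is asymptotic; with few family clusters it is mildly
anti-conservative, which is why the calibration check uses 60 families.
Real-data mode (VCF/PED/TSV readers, user-supplied percentile tables and
weights) exercises the same code paths but has only been validated on
simulated data written through the package's own writers.
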