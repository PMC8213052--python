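# condgwas

Conditional and unconditional **full-genetic-model GWAS** for a continuous
trait in a multi-ethnic cohort. The package implements the complete analysis
chain used to dissect body surface area (BSA) in a four-group US cohort
(European-, Chinese-, African-, and Hispanic-American): quality control,
additive/dominance/epistasis coding, mixed-model association testing with
Henderson Method III F-statistics, permutation experiment-wise thresholds,
Gibbs-sampling effect estimation, component heritability decomposition, and
lifestyle-cofactor-conditional model comparison. Because the original
cohort's genotypes are controlled-access, a first-class synthetic-data
module generates multi-ethnic cohorts with planted architectures so every
stage is testable end to end.

## The model

For subject *k* in ethnic group *h*, the phenotype is modelled as

```
y_hk = μ + s_hk + c_hk
     + Σ_i a_i xA_ik + Σ_i d_i xD_ik
     + Σ_{i<j} aa_ij xAA_ijk + ad_ij xAD_ijk + da_ij xDA_ijk + dd_ij xDD_ijk
     + e_h
     + Σ_i ae_ih u^AE_ihk + de_ih u^DE_ihk
     + Σ_{i<j} aae_ijh u^AAE_ijhk + ade_ijh u^ADE_ijhk
              + dae_ijh u^DAE_ijhk + dde_ijh u^DDE_ijhk
     + ε_hk
```

where `s` is a sex block effect, `c` an optional lifestyle cofactor (walk,
exercise, read, smoke, transportation), `xA ∈ {1, 0, −1}` for QQ/Qq/qq and
`xD ∈ {0, 1, 0}` are the additive and dominance codes, the digenic epistasis
codes are their elementwise products, and `u^·` are the group-specific
incidence columns of each genetic coding. SNP effects (a, d, aa, ad, da, dd)
are fixed; ethnicity (e) and all gene-by-ethnicity interactions
(ae, de, aae, ade, dae, dde) are random.

Association tests are reduction-in-sums-of-squares F-statistics (Henderson
Method III construction), referred to the permutation null of the
genome-wide maximum F (phenotype shuffled within sex × ethnicity strata;
2,000 permutations by default) to control the experiment-wise type I error
at 0.05. Effects of the selected multi-locus model are estimated by Gibbs
sampling (20,000 iterations by default), and heritability is decomposed as

```
V_P = (V_A + V_D + V_AA + V_AD + V_DA + V_DD)
    + (V_AE + V_DE + V_AAE + V_ADE + V_DAE + V_DDE) + V_ε
```

with `h²_T` the sum of the 12 component heritabilities, `h²_D+` the
dominance-related sum, and `h²_GE` the gene-by-ethnicity sum.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (2,000 subjects, 60 SNPs, planted architecture proportioned like the
published decomposition):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_base_model_scan.py
python analysis/04_conditional_models.py
python analysis/05_report_tables.py
```

which prints, step by step:

```
simulated 2000 subjects x 60 SNPs; realized total heritability 76.5% (9 single loci, 10 pairs planted)
QC kept 60/60 SNPs and 1927/2000 subjects (IQR fence dropped 71, residual filter dropped 2)
base model: 18 loci and 2 epistatic pairs selected (critical F 3.29); estimated total heritability 58.5%
BSA|trans: 19 loci selected; verdicts {'not_affected': 20, 'suppressed': 3, 'caused_by': 1}
BSA|smoke: 19 loci selected; verdicts {'not_affected': 20, 'suppressed': 3, 'caused_by': 1}
```

Reading: the generator planted a 76.5%-heritability architecture; after QC
(the quartile fence removes ~3.5% of subjects, the 3-standardized-residual
rule a handful more), the base model recovers most planted loci at the
permutation critical F of 3.29 and attributes 58.5% of phenotypic variance
to them (smaller planted terms stay undetected at n = 2,000). Conditioning
on the transportation cofactor leaves most effects unchanged (`×`),
uncovers three suppressed effects (`√` gained), and absorbs one
cofactor-mediated effect (`√` lost). Tables land under `results/`
(`scan.tsv`, `effects.tsv`, `heritability_all_models.tsv`,
`cofactor_comparison.tsv`, `carrier_percentages.tsv`, `architecture.png`).

A `condgwas` CLI wraps the same steps
(`condgwas {simulate,qc,scan,estimate,compare,report} --help`).

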