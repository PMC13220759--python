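# epiburden

Burden testing for **gene–gene interactions between rare variants** in
case-control sequencing studies — for statistical geneticists who want to
find epistatic gene pairs that SNP×SNP interaction tests (contingency-table
or kernel methods) are underpowered to detect at rare allele frequencies.

Instead of contrasting cases against controls, `epiburden` contrasts the
interaction burden observed in cases against a **baseline expectation
estimated from genomic features**:

1. **Rare-variant interaction burden (RVIB).** For gene pair (i, j) over
   K cases,

       Y_ij = Σ_{k=1..K} max { w_{i,p} g_{i,p,k} · w_{j,q} g_{j,q,k} : p ∈ V_i, q ∈ V_j }

   where g ∈ {0,1,2} are minor-allele copy numbers and w = ⌈s/b⌉ integer
   weights from per-variant pathogenicity scores s ∈ [0,1] at bin length b.
   Only simultaneously mutated cases contribute.

2. **Truncated negative-binomial baseline.** Background pairs follow
   Y_ij ~ TNB(μ_ij, θ, t), a negative binomial truncated at t ∈ {0,1,2}
   (the excess of barely co-mutated pairs is outside the support), with

       ln μ_ij = β0 + Σ_{l=1..6} β_l X_{l,i} X_{l,j} + β7 X7_ij

   on products of per-gene features (CDS length, accumulated rare-variant
   MAF, their product, missense/LoF constraint, GC content) plus the pair's
   control burden X7. Coefficients and θ are fitted by maximum likelihood;
   the background is **recursively purified** (fit → BH-FDR → drop q ≤ 0.1
   → refit) so disease pairs do not contaminate the baseline, and the
   (b, t) combination is chosen on a grid by balancing background
   calibration (MLFC) against the number of significant pairs.

3. **Testing.** Each pair's standardized deviance residual d′ yields a
   one-sided p-value 1 − Φ(d′) and BH-FDR q-value.

The package also ships a **two-locus epistasis simulator** (threshold,
multiplicative, and classic epistasis odds models, with α and θ solved from
prevalence, MAF, and genotype OR) that generates complete synthetic cohorts
(VCF + annotation/feature/pair TSVs) and runs the type-I-error and power
experiments with exact Clopper–Pearson intervals.

## Worked example

Simulate a cohort of 2000 samples with one causal pair planted under the
threshold model (genotype OR 20, causal MAF 2%, prevalence 1%), then test:

```bash
epiburden simulate --n-samples 2000 --n-genes 100 --n-pairs 800 --seed 7 \
    --model threshold --or 20 --maf 0.02 --out demo
epiburden run --vcf demo.vcf --anno demo.anno.tsv --features demo.features.tsv \
    --pairs demo.pairs.tsv --cases demo.cases.txt --out demo_run \
    --b-grid 0.1,0.2 --t-grid 0 --min-background 200
```

which prints the stage log

```
[qc] 297 sites retained
[rare] 297 rare non-synonymous sites
[pairs] 801 candidate pairs
[burden] computed at 2 bin lengths; X7 included
[grid] chose b=0.1 t=0 (MLFC=0.0641, 0 significant)
wrote demo_run.pairs.tsv, demo_run.grid.tsv
```

`demo_run.pairs.tsv` holds one row per tested pair, sorted by p-value:
gene ids, prediction score, unweighted and weighted burdens, the seven
predictors, fitted baseline `mu_hat`, standardized residual `d_std`,
`p_value`, `q_value`, and whether the pair sat in the purified background.
The planted pair stands out as the cohort's largest burden against a small
baseline:

```
gene_i    gene_j    y_basic  Y_weighted  x7_control  mu_hat  p_value
TARGET_A  TARGET_B  27       2187        243         686.4   0.032
```

(27 cases are simultaneously mutated at the two causal variants; the
weighted burden 2187 is 3× its baseline — at this toy size, an 800-pair
candidate list, that is nominally significant but not study-wide; the power
experiments below use realistic 40000-pair candidate lists, where this
setting is detected in every replicate.)

Experiments from the command line:

```bash
epiburden type1 --n 1000 --reps 50 --seed 1          # null calibration
epiburden power --model classic --or 20 --maf 0.005 --n 4000 --reps 50 --seed 1
```

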