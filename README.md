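# sidefx

A tested, reusable pipeline for studying the aetiology of antidepressant side
effects: descriptive epidemiology of per-medication side-effect reports,
tetrachoric-correlation clustering of side-effect co-occurrence, bifactor
liability-threshold structural modelling of common versus drug-class factors,
and polygenic-risk-score (PRS) construction with association testing.

Because the cohort data this kind of analysis targets is access-restricted,
the package ships a first-class synthetic-data module that generates cohorts,
block-LD genotypes and GWAS summary statistics with exactly the statistical
structure the downstream stages assume, so every stage is testable end to end
offline.

## Pipeline stages

| stage          | what it does |
|----------------|--------------|
| `simulate`     | liability-threshold bifactor cohort + block-LD genotype dosages + marginal GWAS summary statistics + `truth.json` with all latent parameters |
| `descriptives` | per-medication side-effect prevalence with Wilson 95% CIs, pooled-variance two-sample Z proportion tests (male vs female), two-sample t-tests (endorsed vs not, by age), single-antidepressant sensitivity subset |
| `cooccurrence` | pairwise-complete tetrachoric correlation matrix over medication x side-effect columns, `d = 1 - rho` distance transform, Ward minimum-variance clustering, within/across co-occurrence medians |
| `sem`          | per side effect: bifactor liability model (general + SSRI + SNRI factors) and its three reductions, fitted by marginal ML with Gauss-Hermite quadrature; AIC and LRT comparisons |
| `prs`          | QC (imputation r2 >= 0.6, strand-ambiguous A/T & C/G removal), allele harmonisation, greedy LD clumping (p1=1, p2=1, r2=0.1, 10,000 kb), the eight-threshold C+T ladder, dosage-weighted scoring, genetic PCs |
| `assoc`        | logistic regression of each side effect (per medication and pooled) on each PRS with sex, age and 20 PCs; Wald ORs/CIs, likelihood-ratio pseudo-R2, Bonferroni families; amitriptyline-for-insomnia sensitivity adjustment |

## CLI

All stages are subcommands of a single entry point:

```bash
sidefx run --config configs/demo.yaml --out-dir out/          # end to end
sidefx simulate --config configs/demo.yaml --out-dir out/sim
sidefx descriptives --pheno out/sim/phenotypes.tsv --stratify-sex --out-dir out
sidefx cooccurrence --pheno out/sim/phenotypes.tsv --min-pair-n 30 --out-dir out
sidefx sem --pheno out/sim/phenotypes.tsv --side-effect nausea --out-dir out
sidefx prs --sumstats out/sim/sumstats_bmi.tsv \
           --genotypes out/sim/dosages.tsv --sidecar out/sim/variants.tsv \
           --trait bmi --out-dir out
sidefx assoc --pheno out/sim/phenotypes.tsv --prs out/prs.tsv --pcs out/pcs.tsv \
             --family per_drug_10 --out out/assoc.tsv
```

Exit codes: 0 success, 1 user/input error, 2 internal error.  `sidefx run`
writes `manifest.json` with the seed, all parameter blocks, package versions
and a sha256 per output; reruns with the same config are byte-identical
(`tests/data/expected_demo/` holds the packaged expected outputs for
`configs/demo.yaml`).

## File formats

* **Phenotypes** — TSV: `participant_id`, `sex` (male/female), `age`,
  `taken_<drug>` (0/1) for the ten medications, and `se_<drug>_<effect>` for
  the 10 x 25 endorsement cells (0/1 when the medication was taken, `NA`
  otherwise).  The 25 effects are the 23-item checklist plus
  `other_side_effects` and `no_side_effects`.
* **Genotypes** — either a dosage matrix TSV (`participant_id` + one column
  per variant) with a variant sidecar TSV
  (`variant_id chrom pos ref alt imputation_r2`), or a VCF with a `DS`
  FORMAT field and an `R2` INFO key.  Dosages count the alternate allele and
  must lie in [0, 2]; positions are 1-based.
* **Summary statistics** — whitespace/tab-delimited with a header.  Column
  aliases (case-insensitive): `SNP/ID/RSID -> variant_id`, `CHR -> chrom`,
  `BP/POS -> pos`, `A1/EA -> effect_allele`, `A2/OA/NEA -> other_allele`,
  `FRQ/EAF/FREQ/MAF -> freq`, `B/BETA/EFFECT -> beta`, `SE -> se`,
  `P/PVAL/PVALUE -> pval`, `N -> n`.  Pre-computed weight files (e.g. from a
  Bayesian shrinkage method) can be supplied in the same shape and scored
  with thresholding bypassed.

## Method notes

* Tetrachoric correlations use the two-step estimator (thresholds from the
  marginal normal quantiles, then rho by bivariate-normal ML) with a 0.5
  continuity correction on zero cells; pairs are evaluated on participants
  exposed to both medications.
* The distance transform is `1 - rho` (recorded in output metadata);
  undefined pairs are imputed to the median distance with a logged count.
* The bifactor models are estimated by marginal maximum likelihood: the
  factor vector is integrated out per participant over the manifests that
  participant observed, with the class-factor blocks handled by nested
  one-dimensional Gauss-Hermite quadratures.  Residual variances are fixed
  by the unit-liability-variance constraint; multi-start optimisation runs in
  an unconstrained probit slope/intercept parametrisation.
* PRS p-value thresholds and the imputation-quality cutoff use strict `<`
  comparisons (below 0.6 excluded); LD is computed in the target panel.
* Pooled outcomes collapse to participant level: endorsed for at least one
  medication taken.  Variance explained uses the likelihood-ratio pseudo-R2
  rescaling with the null model dropping only the PRS term.
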