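# aileqtl

Genetical-genomics analysis for advanced intercross lines (AILs):
expression-QTL interval mapping by Haley–Knott regression, tiered
permutation significance thresholds, cis/trans classification, trans-eQTL
hotspot detection, colocalization of eQTL with organismal-trait QTL, and
SEM-based causal edge orienting (leo.nb scores) — plus a forward simulator
of AIL genotypes, expression and traits with known ground truth.

The package targets crosses such as the wild × domestic chicken intercross
(Red junglefowl × White Leghorn): a small F8 cohort genotyped at a few
hundred SNPs on an expanded genetic map, transcriptome-profiled in a tissue
of interest, with the goal of mapping the loci that regulate transcript
abundance and asking which transcripts causally drive organismal traits
(e.g. brain-region masses or body mass). It is written for quantitative
geneticists who would otherwise juggle several R packages for these steps
and have no offline way to validate the whole chain.

## The model

Genotype states {RR, RW, WW} follow a Markov chain along each chromosome
with F2-type transitions built from the Haldane map function; a
forward–backward pass over typed markers (with a genotyping-error emission
model and support for partially informative calls `R-`/`W-`) yields
conditional genotype probabilities on a cM grid. Haley–Knott regression
scans each transcript y:

    LOD(x) = (n/2) · log10( RSS0 / RSS1(x) )

with RSS0 from y ~ intercept + sex + batch and RSS1 adding the additive
score a = P(WW) − P(RR) and dominance score d = P(RW) at position x (and
a·sex, d·sex for the sex-interactive model). Suggestive and significant
thresholds are the 80th/95th percentiles of permuted genome-wide maximum
LODs (separate cis tier over the gene's marker-extended ±50 cM window);
confidence intervals use a 1.8-LOD drop expanded to the flanking markers.
Hotspots are regions where more eQTL CIs overlap than the 95th percentile
of a random-interval-placement null. Colocalized transcript–trait pairs
are oriented by comparing ML path models (causal M→A→B vs reactive,
confounded, collider) through leo.nb = log10 p(causal)/p(next best).

## Worked example

```python
from aileqtl import (SimConfig, simulate_cross, PipelineConfig,
                     run_pipeline, TraitQtl, detectable_effect_pct)

cfg = SimConfig(seed=2, n_individuals=59, n_probesets=80, n_chromosomes=5,
                n_cis=8, hotspot_targets=15)
cross, truth = simulate_cross(cfg)

pc = PipelineConfig(output_dir="example", n_perm=200, n_probesets=40,
                    iterations=2, seed=3, step_cm=2.0)
c0 = truth.cis[0]   # anchor a trait QTL at the first planted cis locus
trait_qtls = [TraitQtl("mass_causal", [(c0["chrom"], c0["pos_cm"] - 30,
                                        c0["pos_cm"] + 30, c0["pos_cm"])])]
result = run_pipeline(cross, pc, trait_qtls)
print(result["summary"])
```

prints

```
{'n_eqtl': 55, 'n_cis': 21, 'n_trans': 34, 'n_rjf': 31, 'n_wl': 24,
 'n_sex': 17, 'n_nonsex': 38, 'n_probesets': 41, 'n_genes': 32}
```

— 55 eQTL called at the suggestive tier across 41 of the 80 probesets,
split into cis/trans, by which founder allele raises expression (RJF vs
WL), and by whether the sex-interactive model was selected. The same run
reports its permutation tiers (here trans suggestive/significant ≈
3.02/3.80 for the plain model, 4.28/5.18 with sex interaction), one
hotspot — `chr1 112–144 cM, 16 members (threshold 11), 10 RJF / 6 WL`,
the planted master regulator — and the edge-orienting result for the
planted causal transcript:

```
LEO: mass_causal ~ ps0001  leo.nb=1.24  leo.nb.oca=0.40  edge=probeset->trait
```

leo.nb ≥ 1 means the causal model's fit p-value beats every alternative
model ten-fold, so the transcript is called causal for the trait. Finally,

```python
detectable_effect_pct(n=59, power=0.80)   # -> 27.3
```

is the smallest QTL effect (% variance explained) a 59-individual scan
detects with 80% power — the reason small-effect eQTL are expected to be
missed at this design.

Real data enter through four plain-text files (genotypes CSV in transposed
qtl-cross layout, phenotype/covariate CSV, expression TSV, annotation TSV;
see `aileqtl/io.py` for the exact dialect) via `aileqtl.read_cross`, or
from the shell:

```sh
aileqtl simulate --outdir sim --seed 1
aileqtl run --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv \
            --expression sim/expression.tsv --annotation sim/annotation.tsv \
            --outdir results --seed 1
```

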