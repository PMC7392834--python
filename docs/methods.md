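# Methods

`aileqtl` implements a genetical-genomics analysis for an advanced
intercross line (AIL) between two founder populations — here a Red
junglefowl × White Leghorn chicken cross — covering expression QTL
interval mapping, permutation-based significance tiers, cis/trans
classification, trans-eQTL hotspot detection, colocalization with
organismal-trait QTL, and SEM-based causal edge orienting. A forward
simulator with known ground truth makes every stage testable offline.

## Genotype probabilities and the scan model

The F8 AIL is scanned with F2-type machinery on its own expanded genetic
map. Genotype states {RR, RW, WW} (R = junglefowl-origin allele, W =
Leghorn-origin) form a Markov chain along each chromosome; the one-step
transition matrix at recombination fraction *r* is the standard intercross
matrix (two independent meioses). Distances convert to *r* through the
Haldane map function (no interference), `r = (1 − e^(−2d/100))/2`; Kosambi
is available as an option. Because the AIL map is an expanded map estimated
on the cross itself, no AIL-specific transition correction is applied — the
map expansion is already in the cM coordinates.

Conditional genotype probabilities at every marker and at pseudomarkers
(default step 1 cM; tests and examples mostly use 2–4 cM for speed) come
from a scaled forward–backward pass. The emission model absorbs genotyping
error (default 1e-4) and partial informativeness: `R-` means "carries R,
homolog unknown" (not WW) and `W-` the mirror image, with emissions 1−e/2
for the compatible states and e for the excluded one; missing genotypes are
uninformative. On chromosomes with at most a handful of markers the HMM is
verified against exhaustive enumeration of all joint genotype paths
(agreement to 1e-10).

Haley–Knott regression uses the regressors `a = P(WW) − P(RR)` and
`d = P(RW)`. At each grid position

    LOD = (n/2) · log10(RSS0 / RSS1)

where RSS0 is the phenotype regressed on intercept, sex and batch dummies,
and RSS1 adds `a` and `d` (plus `a·sex`, `d·sex` for the sex-interactive
model). Missing expression values (from outlier removal) are handled by
per-probeset case-wise deletion; probesets with fewer than 10 usable birds
are skipped. A positive additive coefficient means the Leghorn allele
increases the trait (`direction = WL`).

Numerical choices: designs are solved by batched QR; positions whose
design is rank-deficient (e.g. monomorphic regions collinear with the
intercept) fall back to an SVD projection so they cannot inflate LOD, and
non-finite ratios are mapped to LOD 0. The interactive curve is clipped to
be ≥ the additive curve (they are nested; only numerical dust is removed).

## Expression preprocessing

Per probeset, the single most extreme value is tested with the one-outlier
chi-square statistic `X² = (x − mean)²/var` (sample variance, p from the
χ²(1) upper tail) and blanked while p < 1e-6, at most twice, recomputing
moments after each removal. Zero-variance probesets are left unchanged. The
operation is idempotent. Gene cM positions are interpolated linearly in bp
between flanking markers (gene = bp midpoint of its annotated span),
clamped at terminal markers; genes on chromosomes with fewer than two
bp-anchored markers stay unplaced and are treated as trans-only.

## Permutation significance tiers

Thresholds are population-level, computed once per data set: per iteration
a random probeset subsample is drawn (defaults: 1000 probesets, 10
iterations, 1000 permutations); per permutation the individual labels of
(expression, covariates) are shuffled **jointly** against the genotypes, so
only the genotype–phenotype link is broken while the phenotype–covariate
association is preserved. The genome-wide maximum LOD is recorded
separately for the plain and sex-interactive models; the pooled maxima give
the suggestive (80th percentile) and significant (95th) tiers. The cis tier
repeats the scheme with each probeset's maxima restricted to its own cis
window. Under a fixed seed the procedure is bit-reproducible.

## Peak calling, cis windows and support intervals

The cis window is the gene position ±50 cM with each bound extended
outward to the closest flanking marker at least 50 cM away (clamped at
terminal markers); an eQTL inside the window is "cis" (strictly "local"),
anything else — including every eQTL of an unplaced EST — is trans.

Per probeset and chromosome at most one peak is reported: the maximum-LOD
position, kept when it clears the applicable suggestive threshold (cis tier
inside the window, trans outside; tiers are labelled suggestive/significant
accordingly, with values at a threshold counting as cleared). The
sex-interactive model is selected when its LOD clears the sex-tier
suggestive threshold *and* the interactive-minus-additive difference
exceeds the sex/nonsex threshold gap — a deterministic stand-in for the
model choice, since the interactive model dominates the additive one by
construction.

Support intervals use a 1.8-LOD drop: the contiguous region around the
peak with LOD ≥ peak − 1.8, each endpoint then expanded outward to the
nearest marker (which yields chromosome-end clamping for free). Effects
(additive, dominance, and their sex interactions under the interactive
model) are the peak-position HK coefficients;
`pct_var = 100·(1 − 10^(−2·LOD/n))`.

## Trans-eQTL hotspots

Per autosome with at least 10 called eQTL, the closed confidence intervals
are overlapped; the coverage profile is computed by an endpoint sweep
(verified against pointwise counting) and intervals touching at a single
point count as overlapping. The null distribution places the same number of
intervals, each of the chromosome's mean CI length, uniformly at random on
the chromosome, 1000 times; the threshold is the 95th percentile of the
per-replicate maximum overlap (rounded up). Hotspots are the maximal
regions at/above threshold; sub-threshold gaps split regions into distinct
hotspots. Members are all eQTL whose CI intersects the hotspot, with an
allelic-direction tally. Both an all-eQTL mode (default) and a trans-only
mode are provided, since either reading of "the eQTL found on the
chromosome" is defensible.

## Trait-QTL overlap and edge orienting

eQTL CIs are intersected with the CIs of externally supplied (or
pipeline-scanned) phenotypic QTL loci. Each overlapping pair is tested by
OLS of the trait on the probeset's expression with sex and batch as
covariates (two-sided p and t for the expression coefficient, adjusted R²).
Within each trait-QTL interval the p-values are Bonferroni-corrected by the
number of *uncorrelated* transcripts: probesets are single-linkage
clustered at |r| ≥ 0.7 (the cutoff is a package choice; single linkage for
determinism) and the cluster count is the effective test number. "Nominal"
means raw p < 0.05, "significant" means adjusted p < 0.05.

Pairs passing the nominal level proceed to local edge orienting. Four
recursive path models are fitted on the covariance of (marker score M,
expression A, trait B): causal M→A→B, reactive M→B→A, confounded A←M→B
(A ⊥ B | M) and collider M→A←B (M ⊥ B). Because each model is a DAG with
independent residuals, the Gaussian likelihood factorizes over nodes and
the ML solution is exact per-node least squares on the covariance matrix —
the fitter needs no iterative optimization (this is asserted against a
numeric minimizer in the tests). Model fit is
`F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p`, `χ² = (n−1)F` with
`df = p(p+1)/2 − #free`; saturated models return p = 1 flagged.

The leo.nb score is `log10 p(causal) − log10 max p(alternatives)` with a
p-floor of 1e-300 for numerical stability. A single-anchor edge
probeset→trait is called at leo.nb ≥ 1.0 (a ten-fold better p); the
reactive orientation is called symmetrically. Multi-anchor scores:
`leo.nb.oca` uses orthogonal anchors (transcript anchors drive A, trait
anchors drive B; the A–B edge orientation — forward, reverse, absent — is
compared) with threshold 0.3; `leo.nb.cpa` uses shared pleiotropic anchors.
Anchor–anchor covariances are free parameters so linkage between anchors is
not penalized. Anchors enter as additive scores, either the HK expectation
at the peak grid position (default) or the hard genotype at the nearest
marker; heterozygote dominance is ignored inside the SEM, which needs one
number per anchor. When a trait has several loci (epistatic QTL), all of
them are used as trait-side anchors even if only one overlaps the eQTL
(the "distal" convention).

## Scan power

The scan test is 2-df (additive + dominance); the statistic `2 ln(10)·LOD`
is approximately noncentral chi-square with `λ = n·h²/(1 − h²)` for a QTL
explaining a fraction h² of variance. Power at a LOD threshold T is
`P(χ²₂(λ) > 2 ln(10)·T)`, inverted numerically to get the minimum
detectable effect. The default threshold, 3.44, is the suggestive
(calling) tier of the 59-bird study design this package mirrors; at that
design the minimum detectable effect at 80% power is ≈27% of variance.

## The synthetic generator

`simulate_ail` breeds the cross forward: founders fixed for R and W
haplotypes, an F1 of ~41, intermediate generations at a census of ~100,
and a final cohort of 59 (26 F / 33 M) by default. Gametes are formed by
switching between the parental homologs with probability `haldane_r(d)`
per marker interval — exact for a no-interference model at marker
resolution; obligate chiasmata are not modelled. Recombinations accumulate
over generations, so realized adjacent-marker recombination at F8 exceeds
the single-meiosis fraction (map expansion), which the tests verify. A
configurable fraction of markers (default 10%, matching 61/612) is made
partially informative by collapsing one homozygote with the heterozygote
into the corresponding partial code.

Expression is baseline noise (SD 1) plus planted additive/dominance cis
effects at the probeset's own marker (additive effect sized as
`a = √(2σ²f/(1−f))` so a fraction f of variance is explained at intercross
genotype frequencies; default 25%), one master regulator driving a block of
target transcripts in trans (default 30 targets, allelic directions skewed
4:1 toward one founder line as hotspots in real data tend to be), and
per-probeset sex and batch effects (SD 0.3). Traits are wired to planted
probesets as causal (trait = β·expr + ε), reactive (trait genetically
driven, expression rewritten from the trait), confounded (both driven by
the same marker) and collider (expression receives marker and trait), with
path coefficient 0.6 by default.

What the generator does **not** emulate: array-level intensity artifacts,
probe-level summarization, correlated co-expression modules beyond the
planted hotspot, selection or inbreeding during breeding, and sex
chromosomes (autosomes only, as scanned). Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to microarray-specific noise.

## Problem sizes and runtime choices

The permutation protocol defaults to the full published-scale parameters
(1000 × 1000 × 10); the test suite and examples run the same code with
reduced permutation counts, subsample sizes and pseudomarker steps (e.g.
120–250 permutations, 2-cM grids, 50–200 probesets) — chosen so each check
retains power for what it asserts while the whole suite stays fast.
Threshold-calibration checks use ≥ 600 independent null scans; orientation
recovery uses 200 replicates at n = 200.

## Known limitations

- One eQTL per probeset per chromosome; linked multi-peak architecture on
  a chromosome is merged into the chromosome-wide maximum.
- The sex-interaction call rule is a deterministic package convention; no
  canonical rule exists for choosing between nested scan models.
- The SEM model catalogue is the four named structures; the original NEO
  software's larger model list is not reproduced verbatim, so leo scores
  here are comparable in spirit but not bit-identical to NEO's.
- The cis tier applies a single window half-width (50 cM) everywhere;
  chromosomes shorter than the window are effectively all-cis for genes
  they carry.
- Hotspot thresholds use the chromosome-mean CI length; strong CI-length
  heterogeneity within a chromosome makes the null conservative for short
  CIs and liberal for long ones.
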