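# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions that were genuinely open.

## Study design being modelled

The pipeline reproduces a two-cohort mQTL study design: methylation
β-values (methylated / total intensity, in [0, 1]) at CpG probes and
dosage-coded genotypes in two independent cohorts, each serving in turn as
discovery and replication. Downstream, the replicated mQTL SNP set is
related to complex-trait GWAS summary statistics through stratified
LD-score regression with resampling-based inference.

## Normalisation

β-values are normalised per probe against technical and biological
covariates (chip, chip position, sex, age, age², sex×age interactions,
optionally blood cell counts) before association. The model is a
quasi-binomial GLM with a logistic link — appropriate for a response that
is a bounded intensity ratio rather than a binomial count — and the
normalised phenotype is the link-scale residual, subsequently projected
onto the orthogonal complement of the covariate design. The projection
step makes the residuals exactly uncorrelated with every covariate column
(machine precision), which the downstream OLS association assumes; without
it, GLM link residuals retain small covariate correlations from the
mean–variance reweighting. For an intercept-only design the whole
procedure collapses to centred logit(β), which is also implemented as a
fast path. β exactly 0 or 1 is clipped to [1e-6, 1−1e-6] with a logged
count.

Outliers are handled by the 5-IQR rule: a measurement more than five
interquartile ranges from its nearest quartile (quartiles by linear
interpolation, type 7 — the rule is only reproducible once a quartile
method is fixed) is either set missing (discovery-cohort convention) or
leaves the probe restricted to SNPs with MAF > 0.05 (replication-cohort
convention), since outliers colliding with rare genotype classes are the
main false-positive mechanism.

## Association scan

Association is simple linear regression of the normalised phenotype on the
additive dosage; slope, SE, two-sided t-test and r² are computed in closed
form, vectorised over SNP blocks with pairwise missing-data handling.
Family structure is deliberately not modelled: the synthetic cohorts are
unrelated, and a mixed model can be slotted behind the same
``assoc_test`` contract later.

Scan geometry: cis is the window ±2 Mbp around the target CpG; trans is
everything outside that 4 Mbp window — a different chromosome or a
same-chromosome distance > 2 Mbp, so cis and trans partition the genome
exactly. The trans scan is two-stage to mirror the computational design it
models: stage 1 uses genotyped SNPs only, and a probe × chromosome pair
advancing at p < 10⁻⁷ is re-analysed on all SNPs of that chromosome
(restricted to the triggering chromosome, not genome-wide). Thresholds
default to the design's published Bonferroni logic (cis discovery 10⁻¹¹,
trans discovery 10⁻¹³, replication 10⁻⁶/10⁻⁵ with same direction of
effect). Ties in p are broken toward the smaller (chromosome, position).
When both scan directions replicate a probe at different SNPs, the SNP
with the larger Fisher statistic −2(ln p_disc + ln p_rep) is kept.

Effects are reported per alt-allele dose on the normalised (logit-residual)
phenotype scale. Allele alignment at replication flips the effect sign when
the other cohort encodes the swapped ref/alt pair.

## Synthetic data

The generator defines the conditions everything is tested under.

*Genotypes* use a mosaic-of-founders model: 24 founder haplotypes per
panel, each individual's haplotype switching founder identity along the
chromosome with probability 1 − exp(−d/λ) over a gap of d bp
(λ = ``ld_decay_bp``, default 50 kb). The founder panel itself carries LD:
a latent AR(1) Gaussian with coefficient exp(−d/λ) is rank-thresholded per
locus so that exactly round(K·p) founders carry the alt allele. This keeps
population allele frequencies pinned at the target (cohorts differ only by
sampling), produces blocky local r² with occasional near-duplicate pairs
(needed by the pruning and two-stage-scan tests), and decays to
independence at large distance. The realized r² decay is faster than the
nominal λ because three attenuations compound (latent correlation,
rank-thresholding, founder switching); the tests therefore assert the
decay shape, not the literal scale. With λ → 0 every locus draws an
independent founder and the mean off-diagonal r² sits at the 1/(2N)
sampling floor. About 30% of panel SNPs are flagged imputed for the
two-stage trans scan.

*Methylation* is generated on the logit scale: probe baseline
N(0, 1.5²) + planted standardised-dosage effects + covariate structure +
N(0, σ²) noise, mapped through the inverse logit so β stays strictly
inside (0, 1). Default residual variance σ² = 1 and covariate effect sizes
(chip 0.3, sex 0.2, age 0.2 SD on the logit scale) are of the order of
realistic array batch and demographic effects. Planted effect sizes are
solved so each pair's share of total logit-scale variance equals its
requested fraction exactly in expectation; grids default to fractions
between 0.15 and 0.5, the range where single-cohort discovery at 10⁻¹¹ is
realistic at n ≈ 600.

*GWAS summary statistics* are simulated at the χ² level only:
χ²_j = E_j · Z² with E_j = α + N·τ_mQTL·L_j,mQTL + N·τ_G·L_j,G, i.e. a
scaled-central-χ²₁ draw with the stratified LD-score expectation. No
individual-level liability model is simulated; this is sufficient to
exercise the regression and the resampling null, but it means the
simulated statistics have exactly the assumed mean structure — passing
recovery tests demonstrates correctness of the estimator, not robustness
to model misspecification (confounding, uncorrected stratification,
in-sample LD mismatch), which real data would add.

*Gene models* are laid out in disjoint slots per chromosome with 3–8 exons,
UTR5/UTR3 flanks around the CDS for coding transcripts, and multi-exon
ncRNA otherwise, so every annotation category is realisable on a toy
genome.

What the generator does not emulate: family structure, sex chromosomes,
genotyping/imputation error, probe cross-hybridisation beyond an explicit
blacklist, cell-composition variation beyond given covariates, and real
human LD (haplotype blocks are statistically, not demographically,
shaped).

## LD scores and partition

LD scores use the windowed, bias-corrected estimator
L_j = 1 + Σ r² − n/N over the 1 Mbp window centred on SNP j, with n
EXCLUDING the target SNP — the leading 1 is the self-term, which makes an
isolated SNP score exactly 1 and is the only reading under which the
formula's structure is self-consistent. The stratified components subtract
their own n_c/N, so the two components add to the total identically. r² is
computed from dosages (composite LD), not phased haplotypes; a SNP exactly
at the half-window boundary is inside the window. The windowed r² band is
held as a sparse matrix so that re-stratifying for a new SNP membership —
the inner loop of the resampling null — costs two sparse mat-vecs.

The partition fit is unweighted OLS of χ² on (1, L_mQTL, L_G) with a free
intercept, and h²_c = β_c·M_c/N_GWAS with M_c the component SNP counts.
No heteroskedasticity weights and no block-jackknife SEs are used:
inference for the quantity of interest comes from the resampling null, not
from the regression's own standard errors (which are reported for
orientation only). This is a deliberate divergence from canonical LDSC
practice, matching the plain regression the partition is defined by. With
an empty mQTL component the model collapses to single-column LD-score
regression with β_mQTL pinned at zero. Negative h² estimates are reported
untruncated with a warning, and the proportion is undefined (error) only
when both components are non-positive. An optional region mask excludes,
e.g., the HLA block before fitting.

## Resampling null

The target mQTL set is first LD-pruned greedily in ascending-p order so no
retained pair within 1 Mbp has r² > 0.8 (distal pairs are assumed
unlinked); this makes its LD structure comparable to a random MAF-matched
draw. Null sets reproduce the target's per-stratum counts exactly — MAF
bins [0, .05), …, [.45, .5] (null #1), jointly crossed with the annotation
category for null #2 (joint matching is the stricter reading; marginal
matching is available via the flag). Sampling is without replacement
within a set and independent across sets, deterministic under the seed.
B defaults to 199 (99 in the faster examples); the empirical p
(r+1)/(B+1) is reported alongside the one-sided upper-tail normal
approximation z = (obs − mean)/SD, the latter suppressed below B = 20.
The null SD (not the SD of the mean) is the "S.E."-style dispersion used
in the z — the reading consistent with published tables of this test.

## Genome distribution

The subtelomeric fraction counts 1 Mbp at both ends of every autosome
(GRCh37 lengths bundled as constants; 2·22 Mbp / 2881.03 Mbp = 1.53%), and
the enrichment test is an exact one-sided binomial against that fraction.
Per-chromosome expected trans-SNP counts are proportional to gene counts
(uniform-by-length available as an alternative), with Pearson residuals
and a χ² goodness-of-fit; the gene-count/SNP-count correlation can exclude
flagged outlier chromosomes.

Probe–SNP overlap flags are pure interval geometry (default binding region:
50 bp ending at the CpG, configurable — array chemistry offsets differ and
the interval is input metadata), computed from a variant list that may be
denser than the analysis SNPs. Flagged mQTL are reported but never removed
downstream; the attributable fraction is max(0, cis% − background%) with
background taken over probes with no mQTL.

## Problem sizes in the shipped tests

The test suite and acceptance script run at desk scale chosen to keep the
statistical assertions sharp: cohorts of 500–1400 samples, panels of
600–20,000 SNPs, 40–150 probes, B = 99 null sets with 500 calibration
replicates, and 50-seed power runs for the cis pipeline at a planted
variance fraction of 0.3 and n = 600 (per-SNP F-statistics of order 250,
so discovery at 10⁻¹¹ has power near 1 and the 48/50 acceptance bound is
conservative). Headline counts from the real study (tens of thousands of
cis mQTL) are functions of the real cohorts and are not reproduced at this
scale.

## Known limitations

- OLS association only; related samples would inflate test statistics.
- The χ²-level GWAS simulation cannot probe LDSC's robustness properties.
- Greedy LD pruning checks pairs within 1 Mbp; long-range LD (e.g. across
  the MHC) would survive pruning.
- Annotation is positional only (no splice/codon-level effects) and
  assumes transcripts fit in memory as flat rows.
- The per-probe GLM normalisation is the slowest stage at scale; the
  projection fast path applies only to intercept-only designs.
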