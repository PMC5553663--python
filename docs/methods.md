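# Methods

## Classification model

A haplotype here is an allele vector over an ordered panel of tag
variants; the packaged panel holds the four SNPs rs3834466 (HincII site
5' of *HBE1*; an indel, alleles G/GT), rs28440105 (HindIII, G-gamma),
rs10128556 (HindIII, 3' of *HBG1*) and rs968857 (HincII, 5' of *HBD*).
The five named haplotypes (BEN, CAR, SEN, CAM, AI) occupy 5 of the 16
possible biallelic vectors; the remaining 11 are UNKNOWN. Classification
of a phased chromosome is exact string lookup — no scoring, no nearest
match — because the table rows are the definition of the haplotypes, not
estimates. Matching is literal uppercase string equality against the
configured alleles, which handles the G/GT indel without any
normalization logic; the cost is that the panel config must match the
VCF's allele dialect, which is why the panel is data, not code.

Diplotypes are order-normalized with the fixed precedence
BEN < CAR < SEN < CAM < AI < UNKNOWN (most common first in
African-American sickle-cell cohorts, UNKNOWN last) so outputs are
diffable regardless of which parental chromosome came first.

**Missing data.** The strict default maps any chromosome with a missing
site to UNKNOWN with a `missing_site` flag — conservative, because a
salvage rule is a modeling choice. The optional lenient mode returns a
`partial` call when the observed alleles are consistent with exactly one
table row. Alleles outside a site's configured set flag
`unrecognized_allele` and force UNKNOWN rather than guessing.

**Phase.** Extraction takes the left GT index as haplotype A and the
right as haplotype B. A heterozygous genotype with a `/` separator
invalidates per-chromosome assignment, so the sample is excluded with a
warning by default; unphased *homozygous* genotypes are accepted because
phase carries no information there. Half-calls (`.|1`) are treated as a
missing site. The optional `enumerate` policy routes unphased samples
through the same consistency enumeration used for RFLP data, reporting a
diplotype only when the unordered allele counts decode uniquely.

## RFLP model

The legacy assay observes, per site, how many of the two chromosomes cut
(0/1/2). The ± pattern per haplotype is derived from the allele table
through a per-site allele→{+,−} map shipped as config; which allele
destroys the recognition site only relabels the symbols per column and
cannot change which diplotypes are distinguishable, but users comparing
against historical ± tables should set the orientation from their assay.
Enumeration is brute force over the C(6,2)=15 unordered pairs of the
five haplotypes: a pair is consistent if its error-free signature
matches every typed site; untyped sites impose no constraint, so masking
can only enlarge the consistent set (a tested invariant). A call is
`unique` with one consistent pair, `ambiguous` with several, `atypical`
with none. For the default four-site panel all 15 pair signatures are
distinct, so error-free unphased data is uniquely decodable *for this
panel*; the ambiguity the phased method escapes in practice comes from
other historical site sets, missing assays and flip errors, which the
simulator reproduces. An optional wildcard extension pairs one known
haplotype with an unconstrained chromosome to mirror partial calls like
BEN/UNKNOWN.

## Concordance and rescue

Labels compare as unordered token multisets; `UNK` and `UNKNOWN` are
input synonyms normalized to `UNK` in reports. Per-class rows group by
the canonicalized *reference* labeling (the legacy assignment), with
ratios kept at full float precision and a rounded-percent summary line.
The rescue rate counts, among samples whose reference label contains at
least one UNK token, those whose test label contains none; with no such
samples the result is flagged undefined rather than raised. No
agreement statistics beyond counts (no kappa) are computed.

## Phenotype summaries

HbF (percent of total hemoglobin, non-negative) is summarized per
canonical diplotype as n, arithmetic mean, and the sample (n−1) standard
deviation, omitted for singletons; no outlier exclusion is applied.
Within-class values are sorted before reduction so results are
bit-identical under input permutation. A quartile table (min, Q1,
median, mean, Q3, max) replaces boxplot rendering, which is out of
scope.

## Synthetic cohorts

The generator emulates the study's data-generating process: true
diplotypes drawn from explicit class frequencies (or by Hardy-Weinberg
random mating over haplotype frequencies — cohorts need not be at HWE,
so explicit frequencies take precedence), phased allele vectors copied
from the table rows, HbF drawn from a per-diplotype Normal truncated
below at 0 (HbF is a percentage; the published summaries give only
mean/sd), and an RFLP readout in which each chromosome's ± state flips
independently per site with probability ε. The default class
frequencies and (mean, sd) parameters are the packaged cohort summaries
(n-weighted), with AI/AI at mean 18.03%, sd 5.39% from the
Eastern-Province cohort where that diplotype occurs; a `default` entry
(7%, 5%) covers classes without a published estimate. A single RNG
stream per cohort is consumed in a fixed order — (1) diplotypes,
(2) HbF per class in sorted class order, (3) the genotype missing
mask — so cohorts are reproducible bit-for-bit from (config, seed). The
RFLP assay takes its own seed since it models a separate measurement
process. When the panel carries no coordinates, emitted VCFs use
placeholder positions on chromosome 11 (5,200,000 + 10,000·i); real
coordinates must be supplied by the user and verified against dbSNP.

The generator does **not** simulate imputation dosage uncertainty,
phasing switch errors, or linked genome-wide background variation; the
flip-error channel is a generic per-site model, not a calibrated
imputation error model. Passing round-trip tests therefore demonstrate
the correctness of the classification logic, not the accuracy of any
upstream phasing pipeline on real data.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 30–10,000 samples (100,000 for
the law-of-large-numbers check on HbF means), sizes at which binomial
4σ bounds and 3σ/√n mean bounds give comfortably stable assertions
under fixed seeds. Frequency vectors must sum to 1 within 1e-9.
Concordance ratios are exact rational counts evaluated in double
precision. Class rows sort by count descending then label; ties in
canonical pair ordering cannot occur because precedence is a total
order.

## Known limitations

- Only the five major haplotypes are modeled; sub-haplotypes (e.g. AI
  subtypes) and rarer backgrounds fall into UNKNOWN.
- No indel left-alignment or allele normalization: the panel config must
  match the VCF dialect.
- The shipped RFLP cut-map orientation is a declared convention, not a
  transcription of any specific wet-lab assay.
- BCF and liftover are unsupported; coordinates are 1-based VCF.
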