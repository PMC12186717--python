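# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions a careful user should know.

## Four-taxon introgression model

All gene-flow statistics assume the species arrangement (((P1, P2), P3), O):
P1 and P2 are sisters, P3 is the candidate donor, and O carries the
ancestral state (in practice a reconstructed ancestral sequence added to
the VCF as an extra sample). Under incomplete lineage sorting alone the two
discordant site patterns ABBA and BABA are equally likely; gene flow
between P3 and P2 inflates ABBA, between P3 and P1 inflates BABA. All
pattern counts are frequency-weighted sums over sites (see README for the
formulas), so partially sorted polymorphism contributes fractional weight
and sites fixed identically in all four taxa contribute nothing.

**Patterson's D and significance.** D is the normalised ABBA−BABA
imbalance. Significance comes from an m-block delete-one jackknife over
contiguous, equal-SNP-count genome blocks (default m = 20): Z = D/SE with
SE the standard delete-one jackknife standard error, and a two-sided normal
p-value. Equal-count contiguous blocks are robust to linkage as long as
blocks are much longer than the correlation scale; with too few informative
sites per block the normal approximation degrades, which is why the trio
driver keeps whole-genome site lists rather than per-chromosome ones at
desk scale. On null simulations (200 replicates, 6,000 unlinked sites) the
measured type-I rate at α = 0.05 is ≈ 0.055 and the Z distribution is
standard normal to within a few percent.

**f4-ratio.** The admixture fraction is estimated as
Σ(p1−p2)(p3a−p4) / Σ(p1−p3b)(p3a−p4), where the P3 chromosome pool is
split per site into halves a and b by a seeded hypergeometric draw — the
standard device when phased haplotypes are not tracked. The estimate is 0
when P2 is indistinguishable from P1 and 1 on complete replacement; two
independent random splits differ by far less than the sampling error.

**Trio enumeration.** Orientation is fixed either by declared role sets
(so the sign of D keeps a consistent reading across trios) or by a rooted
guide topology (every species triple whose sister pair matches the tree).
Bonferroni filtering divides α = 0.05 by the number of tested trios.

## Windowed fdM scan

fdM is computed in non-overlapping windows of 50 *informative* SNPs —
polarized biallelic sites where p1, p2, p3 are not all equal and all four
frequencies are defined; each chromosome's trailing partial window is
dropped. The numerator is the window's ABBA−BABA sum; the denominator
substitutes, per site, the larger derived frequency of the tested donor
pair for both of its members ({P2,P3} when the numerator is non-negative,
{P1,P3} otherwise, with a sign flip), bounding fdM in [−1, 1] and making it
symmetric between P2–P3 (positive) and P1–P3 (negative) sharing.

Because windows are SNP-count-defined, sparse regions produce huge spans
dominated by inaccessible sequence; windows spanning more than 20 kb
(strict inequality) are removed. Candidate windows are those with fdM
strictly above |q-quantile| of the empirical fdM distribution at q = 0.005
(linear interpolation between order statistics). The quantile is exposed as
a flag; 0.005 is the documented default of the analysis this reproduces.
If the q-quantile is non-negative the threshold degenerates to 0 and a
warning is raised.

The KS diagnostic standardises fdM values by their sample mean/SD before
the one-sample test against the standard normal. Estimating the reference
parameters from the data makes the test mildly anticonservative; this is
documented rather than corrected because the diagnostic is used as an
effect gauge, not an inferential test.

**Adjacency enrichment.** Under independent placement of k candidates among
N genome-ordered windows, the expected number of candidates adjacent to
another candidate is E = (N−1)·(k/N)²·2 (each of the N−1 neighbour pairs
contributes two chances at rate (k/N)²); this matches a permutation null to
Monte-Carlo precision. The run-length spectrum counts maximal candidate
runs of each length ≥ 2 within chromosomes (never across chromosome ends),
and the observed adjacent count equals Σ length×count over the spectrum.
The deviation column is observed/expected.

## Net-divergence split times

For diploid samples i, j the per-site divergence contribution is
(gᵢ(2−gⱼ) + (2−gᵢ)gⱼ)/4 — the probability that one allele drawn from each
genotype differs — summed over sites and divided by the accessible genome
length L. By default every pair shares one global L (sites where either
member is missing simply contribute zero); a per-pair-L correction is
available as an option. Heterozygosity is the per-sample count of
heterozygous sites over L.

D_A = median cross-group d_xy − mean(median het of group x, median het of
group y). Uncertainty comes from deleting one chromosome at a time and
recomputing D_A; bounds are mean ± 3 SD with SD the standard delete-one
jackknife standard error √((n−1)/n·Σ(θᵢ−θ̄)²), n = 22 chromosomes by
default. These ±3 SD intervals are deliberately conservative — they are
meant to absorb process variation, not just estimation noise — and cover a
simulated truth in ≈ 99% of replicates. A narrower alternative reading
(plain divisor-n SD of the delete-one values, `scale="sample"`) is exposed
for comparison but undercovers badly (~50% in the same experiment) and is
not used by the estimators. Split times in years are t = D_A·g/(2μ) with
g = 3 years and μ = 3.5×10⁻⁹ per generation by default; no mutation-rate
or generation-time uncertainty is propagated, so ratios between lineage
pairs are more meaningful than absolute dates.

## NJ consensus tree

Distances are plain dosage differences |gᵢ−gⱼ| summed per fixed 100 kb
coordinate window (unlike the SNP-count windows of the fdM scan; each
convention is used where its analysis needs it). The genome-wide tree is
canonical neighbour joining — Q-criterion agglomeration with ties broken on
the lowest (row, column) index pair, standard limb-length and distance
updates — on the summed matrix, rooted at the midpoint of the outgroup's
terminal edge. NJ is exact on additive inputs; all-equal (star) inputs
resolve deterministically with zero-length internal branches. Bootstrap
supports resample windows with replacement, rebuild the tree, and score
each consensus clade (leaf bipartitions evaluated after outgroup rooting)
as present/absent; supports are presence fractions under a fixed seed.

## Synthetic data

**Unlinked mode.** Each SNP gets an independent msprime genealogy of the
(((P1,P2),P3),O) demography (optional mass-migration pulse P3→P2).
Genealogies are accepted with probability proportional to total branch
length (cap maintained adaptively from a warm-up batch), and one mutation
is placed on a branch chosen proportionally to its length, so emitted
patterns follow the exact distribution of a randomly chosen segregating
site on an infinite unlinked genome. The implied accessible length
L = n_sites/(μ·mean total branch length) is recorded in the truth object;
dividing counts by it calibrates heterozygosity (≈ 4Neμ) and d_xy
(≈ 2μT + 4N_anc μ) to the mutation rate, which is what makes the
split-time recovery experiments possible. Sites are spread evenly over
n_chrom chromosomes to support the chromosome jackknife.

**Tract mode.** For the window scan, donor ancestry is planted explicitly:
per recipient haplotype and chromosome, tract counts are Poisson with mean
f·L/mean_tract (f from the pulse fraction, mean_tract default 50 kb) and
lengths exponential, so the expected donor span per haplotype is f·L with
variance 2·f·L·mean_tract (slightly less after clipping and merging). At
sites inside a tract the recipient haplotype's allele is copied from a
dedicated auxiliary P3 haplotype simulated without the pulse — the site
genealogy is then exactly a no-gene-flow genealogy in which the recipient
lineage is sampled from the donor population, i.e. consistent with the
local ancestry. SNP positions are uniform draws at a configurable density
(default 4,000 per 500 kb chromosome, ≈ 8 SNPs/kb, so 50-SNP windows span
≈ 13 kb and survive the 20 kb filter).

**Annotations and planted failures.** Simulated annotations are clean
(MQ 60, no MQ0, neutral bias p-values, Poisson(20) per-genotype depths with
balanced het allele depths); `plant_filter_failures` then makes chosen
sites violate exactly one named rule each, recording them in the truth.

**Default demography.** Population sizes are Ne = 1.43×10⁵ so that
4Neμ ≈ 0.002 matches haplochromine heterozygosity. Split times default to
3×10⁵, 6×10⁵ and 2×10⁶ generations — 1–2 coalescent units between the
ingroup splits, so incomplete lineage sorting (the raw material of the
statistics) is common, with the outgroup far outside the ingroup
coalescences. Real cichlid radiations have deeper inter-lineage splits;
at those depths discordant patterns are so rare that validating the
statistics would need the ~10⁸-SNP genome of the real study rather than
the 10⁴–10⁵ sites used here. All experiment sizes in the test suite
(6,000-site null replicates, 10⁵-site recovery runs, 50-replicate
coverage studies) were chosen as the smallest designs at which the
asymptotics the statistics rely on are comfortably valid.

**What passing tests do not show.** The generator has no recombination map
(unlinked sites or planted tracts only), no selection, no sequencing-error
or genotype-caller error model beyond the planted annotations, and no
missing-data structure (missingness appears only where planted). Passing
the suite therefore validates the estimators and their calibration under
the model's assumptions — not robustness to the full messiness of real
short-read callsets.

## Numerical conventions and degenerate inputs

* Coordinates are 1-based inclusive throughout; BED input is converted
  unless a flag declares the intervals already 1-based.
* Dosage −1 is missing; frequencies over all-missing member sets are NaN
  and NaN sites are skipped by every accumulator.
* The depth filter's data-driven cutoff (mean + 1.5 SD, population SD) is
  estimated once per call from the input table and recorded in the filter
  log; re-filtering with the recorded explicit cutoff reproduces the same
  decisions, which is the sense in which filtering is idempotent.
* The heterozygote allele-balance PHRED uses the exact symmetric two-sided
  binomial tail 2·cdf(min(r,a); r+a, ½), clipped at 1. A site fails if any
  het genotype exceeds PHRED 20 ("majority" aggregation is available).
* The 10 bp proximity rule runs once over the originally failing sites
  (non-transitive).
* Zero denominators (D, f4-ratio, fdM, deviation) yield NaN flags, never
  exceptions; SE = 0 in the jackknife yields ±∞ Z with p = 0.
* All randomness flows through seeded numpy generators; seeds are recorded
  in truth objects and output headers, and identical seeds give
  byte-identical outputs.
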