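# Methods

This note records the models, conventions and design choices behind
`exomesieve`, in the order the pipeline applies them.

## Coordinates and allele normalization

Variants follow the VCF convention (1-based, indels anchored on the base
before the event); intervals follow BED (0-based, half-open). All
conversions happen in `exomesieve.io`; no analysis code mixes the two.

`left_normalize` produces the unique minimal left-most representation of a
sequence edit: shared trailing bases are stripped (extending leftward
through the reference when an allele would empty), then shared leading
bases are stripped while both alleles remain longer than one base. The
operation is idempotent, and any two paddings of the same edit normalize to
the same `NormalizedVariant`; this is what makes call-set comparison by
(chrom, pos, ref, alt) key well defined. Multiallelic sites are decomposed
into one biallelic record per alternate allele before normalization;
per-sample alternate-allele counts are conserved across the decomposition.
Symbolic alleles (`<DEL>`, breakends, `*`) are rejected explicitly —
structural variation enters through the dedicated indel module instead.

## Founder-cohort rarity

The unaffected parents of all families serve as the allele-frequency
control; for each proband their own parents are excluded, leaving the
chromosomes of the remaining couples. Per chromosome class a founder
contributes 2 (autosomal), 2/1 for female/male (X) or 1/0 (Y) chromosomes;
with 53 couples this yields 212 autosomal, 159 X and 53 Y chromosomes.
Absence of a call is counted as homozygous reference — in a jointly
genotyped cohort a founder without the alternate allele carries the
reference — and explicitly missing genotypes (`./.`) are treated the same
way by default; a `strict_missing` mode drops them from the denominator
instead, since a missing call is evidence of nothing.

The frequency estimate is p̂ = k/n with a 95 % Wilson score interval,
computed in closed form with z = Φ⁻¹(0.975) (not hard-coded 1.96; the
printed third/fourth-decimal values reproduce under either). The interval is
exactly the inversion of the binomial score test, and the test suite checks
it against both an independent numeric root-finding inversion and
`statsmodels` to 1e-9. At k = 0 and k = n the bounds are set to their exact
analytic values 0 and 1.

Rarity is classified per chromosome class. The default rule is the count
cutoff {autosomal ≥ 6, X ≥ 5, Y ≥ 2 alt alleles ⇒ common}; k = 0 is
*absent*, anything between is *rare*. The pure interval rule (Wilson lower
bound > 1 % ⇒ common) is available by disabling the cutoffs, but the two
disagree at one edge: at k = 5, n = 212 the lower bound is 0.0101, a hair
above 1 %, so the interval rule says common where the cutoff keeps it rare.
The cutoffs are the default because they state the intended rule exactly.
Two published allele totals are internally inconsistent at the margin (an X
MAF of 0.0316 implies 158 counted X chromosomes, not 159; a stated Y total
of 54 against 53 fathers); the implementation always derives n from the
pedigree rather than fixing either number.

## Segregation models

A variant (or pair) is a candidate when it passes the transcript-effect
gate, is absent/rare in the founders, and is consistent with at least one
model over the *included* members. Constraints on excluded members are
vacuous — this is what makes a singleton analysis a superset of a trio
analysis. Model semantics, for included members:

- **homozygous recessive** — proband homozygous alt; each parent
  heterozygous; affected siblings homozygous alt; unaffected members not
  homozygous alt.
- ***de novo* dominant** — proband heterozygous (a homozygous-alt proband
  would need two independent mutations and is rejected); parents carry no
  alt allele; unaffected siblings carry none; affected siblings carry ≥ 1.
- **X-linked** — X variants only. Male proband hemizygous alt, mother
  heterozygous, father non-carrier, unaffected brothers non-carriers,
  unaffected sisters not homozygous. A homozygous-alt female proband is also
  accepted (carrier mother, hemizygous-carrier father) since nothing
  restricts the model to males.
- **compound heterozygous** — two distinct heterozygous variants in one
  gene in the proband; no included unaffected member carries both; included
  affected siblings carry both; and when both parents are included there
  must exist an assignment of the two variants to two *different* carrier
  parents. Without parents no phase constraint exists, so any two rare
  heterozygous variants in a gene qualify — the main driver of the
  singleton excess.

Affected siblings are required to share the causal genotype; a relaxation
for reduced penetrance is deliberately not a default. A missing genotype in
an included member fails that member's constraint under the default
conservative policy (`permissive` treats it as vacuous). The family-size
ablation runs a nested ladder of configurations and reports candidate
counts as distinct variants (a compound-het pair contributes two); counts
are provably non-increasing along a nested ladder.

## Coverage

Depth tracks are sparse (chromosome, 1-based position, depth); absent
positions are depth 0 by contract. Per-position summaries report mean,
median and the fraction of bases at ≥ 10 and ≥ 20 reads over merged
regions. Per-exon analysis uses the *minimum* depth in the exon, binned as:
all bases zero ("no coverage"), some but not all zero ("partially no
coverage"), minimum 1–9, 10–19, ≥ 20 — the only reading under which the
five categories are disjoint. Cumulative low-coverage proportions are
min < 10 (first three bins) and min < 20 (plus the fourth). Gene rollups
take the minimum over the gene's exons; first-exon analysis re-bins the
first-exon subset. A gene counts as low at a known-disease-position
threshold when at least one of its listed positions is below it. An exon is
*consistently low* when its minimum depth is below 10 in every sample; a
gene is flagged when strictly more than 25 % of its exons are consistently
low. An exon counts as on-target when it overlaps a capture target by at
least one base (a full-containment mode exists); unpadded exon intervals
are the default.

## Non-exonic variants

Distance to the nearest exon is measured in whole bases from the variant's
1-based anchor position to the nearest exon base: 0 inside an exon (such
variants are excluded from the non-exonic set), 1 when immediately
adjacent. The distance profile reports a histogram, a log10-count series
and the fraction within 500 bases — the expected footprint of off-target
coverage given a ~280 bp sequencing insert. Score tiers: negative raw score
⇒ benign regardless of the Phred value; otherwise the highest of the
inclusive Phred thresholds 10/15/20 (inclusive by choice; the difference is
immaterial beyond exact ties). The funnel applies, in order: all non-exonic
variants → rarity ∈ {absent, rare} → raw ≥ 0 → Phred ≥ 10 → ≥ 15 → ≥ 20.
Frequency is deliberately applied before score, and each stage equals the
intersection of the individual rule filters (asserted in tests). Variants
are keyed at allele level, not position level.

## Medium-sized indels

Split-read deletion/insertion calls carry a signed size (negative =
deletion) and, when available, the inserted sequence; inversions,
duplications and breakends are out of scope. A call is on-target when its
affected span (deletion span; insertion anchor base) overlaps a capture
target expanded by 50 bases. Matching against the genotype caller's indels
is by exact equality of left-normalized alleles when sequences are
available — deletions take their sequence from the reference, insertions
from the call — with a positional fallback (same type, |Δpos| ≤ 10, size
ratio ≥ 0.8) for insertions lacking sequence. Phasing marks a proband call
`one_parent`/`both_parents`/`unassigned` by matching against each parent's
call set; every supported call is treated as one heterozygous allele, so a
matched parental call contributes one alt allele to the founder count and n
follows the founder chromosome arithmetic above. The funnel: all calls →
unique to the split-read caller → rare/absent in founders → on-target.
Phase distributions are reported for all calls and for the unique-and-rare
subset; founder-shared common events drop out of the latter, shifting it
away from `both_parents`.

## Synthetic data

The generator emulates the study conditions, not real human sequence:

- **Cohort** — nuclear families of a male affected proband, two unaffected
  parents and unaffected siblings (default 6 families of 6; the
  `paper_shape` preset scales to 54 families, the study's cohort size).
- **Genome** — non-overlapping genes (default 30, ~15 % on X, 10 %
  single-exon) of fixed-length exons and introns on a uniformly random
  reference; capture targets cover 90 % of exons with 10 bp padding.
- **Genotypes** — per-site founder alleles drawn in Hardy–Weinberg
  proportions from a spectrum of 55 % common sites (MAF uniform on
  0.05–0.5) and a rare tail at MAF 0.01; children receive Mendelian
  transmissions (X-aware: sons are hemizygous for a maternal allele); 5 %
  of sites are triallelic. One causal variant (or compound-het pair with
  opposite parental origins) per model is planted into the first four
  families with genotypes exactly satisfying the model and absent from all
  other founders.
- **Depth** — on-target Poisson depth at mean 80 reads; first exons scaled
  by 0.35 (the empirical first-exon capture shortfall); 5 % of exons are
  systematic capture failures shared by every sample (×0.05); 3 %
  per-sample random exon dropout; a 2×10⁻⁴ per-base hole rate producing
  partially-uncovered exons; off-target flanking depth decays as
  exp(−d/280), the insert-size scale.
- **Non-exonic variants** — positions drawn at exponentially decaying
  distance (scale 180 bp) from exon boundaries plus an 8 % far tail; 47 %
  of scores have a negative raw value (the benign fraction), the rest an
  exponential Phred tail.
- **Structural variants** — a population pool of deletion/insertion events
  with log-uniform sizes up to 16 kb, carried by parents per event
  frequency and transmitted heterozygously, plus rare de novo events per
  proband; the probability that the genotype caller also reports a call
  steps down with size (deletions: 0.72 ≤ 10 b … 0.05 > 100 b; insertions
  decline faster), reproducing the redundancy fall-off.

One `SeedSequence` with fixed per-stage spawn keys drives everything:
identical config + seed give byte-identical outputs, and adding a stage
never perturbs earlier ones. What the generator does *not* model: real
sequence context (mappability, GC bias, segmental duplications), genotyping
error, population structure or relatedness, and allele-frequency
correlation between nearby sites. Passing tests therefore demonstrate the
correctness of the filtration logic under the stated statistical structure,
not performance on real reads.

## Problem sizes and numerics

The default synthetic scale (6 families × ~1,500 sites) runs the full suite
in well under a minute; the 54-family preset used for the ablation and the
acceptance measurements runs in minutes. Cohort-scale published magnitudes
(per-proband variant totals in the 10⁵ range) are intentionally not
reproduced — the generator preserves the *shape* of each analysis (ordering
of funnel stages, direction of the singleton→trio drop, size-dependence of
redundancy), not absolute counts. Proportion arithmetic uses exact
comparisons where the quantities are exact (bin proportions sum to 1 within
1e-12); Wilson bounds are clamped to their analytic boundary values at
k ∈ {0, n}. Ties: Phred thresholds inclusive, the 25 % gene fraction and
the 1 % MAF threshold strict, as stated above.
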