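# Methods

## Problem and data model

`mitokit` recovers haploid mitogenome consensus sequences from short-read
multi-sample VCFs and analyses maternal diversity in cattle-style cohorts.
Short-read callers genotype the mitochondrial contig diploid-style, so a
position where an animal shows two alleles — from genuinely mixed
mitogenome copies or from nuclear copies of mitochondrial DNA (NUMTs)
misaligned to MT — appears as a heteroplasmic call such as `0/1` with
split allele depths (AD). Semen-derived samples carry few mitochondria,
so NUMT reads there produce more balanced allelic-depth ratios and many
more apparent heteroplasmic sites than somatic tissues; the QC stage
exploits exactly this contrast.

The central container (`table.MitoVariantTable`) is an animals × sites
matrix of allele-index pairs with AD/DP, plus per-site POS/REF/ALT/QUAL/MQ.
All coordinates are 1-based and the circular mitogenome is treated as a
linear sequence.

## Quality control

Filters run in a fixed, logged order because removal counts depend on it:

1. **Site filters** — QUAL ≥ 30, MQ ≥ 30, minor-allele count ≥ 2, and a
   depth cap: per-site mean DP across animals must not exceed the grand
   mean of those per-site means + 3 SDs. The cap statistic is taken at
   the site level because the filter acts per site; since it is
   re-estimated from whatever table it is given, it is the one filter
   that is not formally idempotent (the others are, and are tested so).
   Minor-allele counting treats each genotype as carrying each of its
   distinct alleles once (a heteroplasmic call counts once for both
   alleles). ALT alleles individually below the count threshold are
   removed and genotypes referencing them set missing; the site survives
   only if the second-most-frequent remaining allele reaches the
   threshold.
2. **INDEL + missing removal** — any site whose alleles differ in length,
   or with ≥ 1 missing genotype, is dropped; downstream stages may assume
   SNPs only, zero missing.
3. **Animal depth** — animals with mean DP < 10 over retained sites drop.
4. **Semen heteroplasmy cap** — Semen-group animals (males sampled from
   semen or from unknown tissue) with > 150 heteroplasmic sites drop;
   Non-semen animals (all females, and males from known non-semen
   tissue) are never removed by this rule.

## Consensus calling

Homoplasmic genotypes pass their allele through; heteroplasmic genotypes
take the allele with the higher read depth; a REF/ALT depth tie resolves
to ALT, avoiding reference bias. An ALT/ALT tie has no established
convention, so the higher allele index is chosen — the same
anti-reference preference extended — and logged as a warning. Sequences
come in two forms: variant-positions-only strings (one base per retained
site, shared position list) and full-length records (default 16,340 bp,
the ARS-UCD1.2 mitochondrial contig length; configurable) with N at
non-variant positions, as required by haplogrouping tools.

## Reference liftover

The packaged map relates the classical bovine reference (BRS, V00654,
16,338 bp) to ARS-UCD1.2_M (16,340 bp): two bases present only in the
newer reference (target coordinates 222 and 589) and twelve substitution
differences. Positions below the first insertion are unchanged, those
between the two shift by +1, later ones by +2; the exact boundary is
defined so that lift and inverse-lift form a bijection between source
coordinates and non-inserted target coordinates (the inserted positions
invert to "deleted"). Lifting a defining-variant set drops any variant
whose allele equals the target reference base at the lifted position —
it is no longer a variant there; with the packaged map this removes
exactly five of the classical haplogroup-defining variants. The map
format is generic (TSV of deletions and substitutions), so other
reference pairs can be supplied.

## Haplogroup assignment

Haplogroups are sets of diagnostic (position, allele) variants. A query
is scored per group as matched / (matched + mismatched) over its
non-missing defining sites — a match *fraction* rather than a raw count,
so small subgroup definitions are not penalized. N bases count as
missing; a group with no informative site is excluded; if the best
fraction is 0 the query is unassignable. Exact ties are reported as
unresolved together with the deepest common name prefix (a T1/T3 tie
resolves to level "T"), mirroring how restricted-region haplogrouping
degrades: scoring only a short region (e.g. the D-loop; shipped default
interval (15792–16340) ∪ (1–363), a configuration value, not a claim
about the true control-region boundaries) leaves groups whose
informative sites lie outside the region unable to separate.

Private variants are non-N query bases that differ from the reference at
positions defining no group at all (defining positions of *any* group are
"known" and excluded). Within a haplogroup, private variants carried by
an identical animal subset of ≥ `min_group_size` members — and by nobody
else in the haplogroup — flag a putative subgroup; the detector groups
variants by exact carrier set, so a planted subgroup is recovered exactly.

## Diversity and structure

* Pairwise differences: Hamming distance with pairwise deletion of
  positions where either sequence has N (the filtered pipeline output has
  none).
* k = mean pairwise differences over unordered pairs; π = k / L with L
  the sequence length by default (pass the genome length to express π per
  genomic site).
* Haplotypes are exact-sequence-equality classes. Hd = n(1 − Σp²)/(n−1);
  its SD uses Nei's (1987) large-sample sampling variance
  V = 2/(n(n−1)) [2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²].
* Hierarchical clustering uses average linkage; at cut height 0 the
  partition equals the zero-distance connected components, so the linkage
  choice is provably irrelevant there (unit-tested) and the h = 0 clusters
  coincide exactly with haplotype classes for N-free sequences.
* AMOVA is the one-level Excoffier–Smouse–Quattro decomposition of
  squared pairwise distances; σ²_among uses the unequal-group-size
  coefficient n̄ = (N − Σn²/N)/(k−1), and Φ_ST = σ²_among/σ²_total. A
  negative among-group component (possible under the moment estimator) is
  reported as-is with a warning so permutation nulls stay unbiased; the
  permutation p-value shuffles labels.
* The haploid GRM standardizes one 0/1 indicator per non-majority allele
  per polymorphic site, z = (x − p)/√(p(1−p)), GRM = ZZᵀ/M. The majority
  allele is the baseline (for biallelic sites the choice does not affect
  the GRM); `collapse_multiallelic=True` switches to a single
  majority-vs-rest indicator. PCA is the GRM eigendecomposition with
  coordinates scaled by √eigenvalue.

## Imputation harness

A cross-validation of sporadic-missing-genotype imputation: per
replicate, ⌊20% × N⌋ animals (Group I) have ⌊10% × S⌋ sites masked —
drawn independently per animal — and the remaining animals form the
reference panel (Group II). The built-in imputer copies the k = 5
nearest panel haplotypes (Hamming distance on the animal's unmasked
consensus bases; ties to the lowest panel index): GT is the best
haplotype's allele as a phased homoplasmic pair, and DS/GP are the
normalized inverse-distance-weighted allele votes. It is deliberately
simple — it exists to exercise the evaluation machinery and the
GT:DS:GP interface, not to match a production imputer's accuracy; being
homoplasmic-only, it structurally cannot recover heteroplasmic truth
genotypes, which is why their per-class concordance sits far below the
homoplasmic classes.

Imputed heteroplasmy resolves to a base by: REF/ALT genotype → REF if
DS < 1, else ALT (values in (1,2) fall to ALT by monotonicity); ALT/ALT
genotype → "N" when the two alleles carry equal GP mass (the balanced
DS = 2 case), otherwise the allele with the larger mass summed over GP
entries containing it; homoplasmic → its allele. Concordance is scored
over masked cells as unordered genotype pairs, keyed by the original
genotype class; haplogroup agreement compares re-predicted haplogroups
(ties as sets) against calls from the complete data. Replicate r seeds
its mask with master_seed + r.

## Synthetic cohort generator

The generator produces the inputs the pipeline assumes, with exact truth:
a uniform-random reference; disjoint defining-variant sets per haplogroup
(names T1…Tk) and founders = reference + defining alleles; animals =
founder + Poisson(rate) private substitutions drawn *outside* all
defining positions so truth labels stay exact; metadata with breed,
country, sex and tissue. Genotypes add per-site Normal(depth_mean,
depth_sd) depths (floor 1), tissue-dependent heteroplasmy (per-site
Bernoulli; semen-like rate ≥ somatic rate), missing genotypes and spiked
insertion records at otherwise invariant positions. At a heteroplasmic
genotype the major-allele fraction is Beta-distributed with mean
1 − numt_allele_fraction(tissue) and concentration 30 — the real
allelic-ratio distribution shape is not established, so these are free
configuration — and the truth allele is kept the *strict* depth majority
so that majority-rule consensus provably recovers truth. Substitutions
pick a uniform random different base; transitions are not privileged
(real mitogenome data is transition-dominated; irrelevant to what the
tests probe). All randomness flows from one master seed (stages use
seed, seed+1, seed+2), and identical configs yield byte-identical output
files.

Defaults model a desk-scale cohort: 200 animals, 4 haplogroups × 25
defining variants, ~0.5% heteroplasmic sites per somatic animal vs 5%
for semen-like samples, mean depth 30×, 1% missing genotypes. What the
generator does **not** emulate: read-level error, alignment artefacts
beyond the heteroplasmy model, correlated missingness across sites
within an animal, transition bias, recombination (absent in mtDNA) and
selection. Passing tests therefore demonstrate the correctness of the
pipeline's logic under the assumed statistical structure, not calling
accuracy on real sequence data. One visible consequence of independent
per-genotype missingness: with hundreds of animals most sites have at
least one missing genotype, so the missing-site filter is the dominant
site sink in the demo analysis — as it is, less extremely, in real
cohorts.

## Numerical choices and limitations

* Depth-cap statistics use population SD (ddof 0) over per-site means.
* Hd variance is clipped at 0 before the square root.
* GRM standardization excludes indicators with p ∈ {0, 1}; PCA clips
  negative eigenvalues to 0 when scaling coordinates.
* The liftover boundary between the +1 and +2 offset regions is fixed by
  bijectivity (see above); all twelve tabulated substitution pairs and
  both endpoints are unit-tested.
* `find_shared_private_variants` requires carrier sets strictly smaller
  than the haplogroup, so variants shared by *every* member (which would
  redefine the group itself) are not reported as subgroups.
* The analysis drivers run at sizes chosen to keep the full demo in
  seconds-to-minutes on one CPU: 200 animals, 4 haplogroups, 50
  imputation replicates.
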