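# Methods

## Problem setting

A rare pathogenic allele found in several apparently unrelated pedigrees
can be either a recurrent mutation or a founder allele inherited from a
common ancestor.  The two hypotheses separate on haplotype structure:
descendants of a founder share, around the allele, a chromosomal segment
that recombination shortens by an expected factor `1/g` Morgan per side
after `g` meioses, while recurrent mutations arise on unrelated
haplotypes.  `foundertrace` measures that structure from phased
genotypes: the carrier consensus haplotype and its minimal shared core,
the core's frequency among background haplotypes, and the carrier
enrichment of rare variants in linkage with the focal allele.

## Shared-core detection

Inputs are a phased biallelic haplotype matrix (2N haplotypes × M sites,
entries 0/1/missing) and the focal variant.  Stages:

1. **Carrier resolution.**  Samples with exactly one focal alt allele are
   carriers; the phase of that allele selects the focal haplotype.
   Homozygous-alt samples are rejected: the dominant founder model
   assumes heterozygotes, and a homozygote almost certainly signals a
   genotyping artefact at a variant this rare.
2. **Site filtering.**  Common-variant analysis uses biallelic SNVs with
   minor allele frequency strictly above 5% and missingness strictly
   below 1% (both thresholds configurable and deliberately strict
   inequalities); the focal site is always retained.  Rare-variant
   tagging reloads sites unfiltered.
3. **Consensus.**  Per-site majority allele across carrier focal
   haplotypes.  Ties are broken toward the first carrier in sample-ID
   sort order, falling through missing alleles, so reruns are exactly
   reproducible.
4. **Extents.**  From the focal site outward, each direction tolerates at
   most `tolerance` mismatches (default 0) and stops before the next
   one; the reported boundary is the outermost *matched* site, so
   tolerated mismatches at the run's edge are trimmed.  A per-direction
   rather than pooled budget keeps the extent deterministic and
   symmetric without search.  Missing alleles never match the consensus
   (conservative: missing data can only shrink evidence of sharing).
5. **Core and background frequency.**  The core is the intersection of
   all extents (it contains the focal site by construction).  Background
   frequency counts non-carrier haplotypes matching the core alleles at
   every core site, reported as "1 in ⌊total/matches⌋".  Exclusion of
   relatives beyond the carrier set is the caller's responsibility.

Because extents end at genotyped sites, all core statements are at *site
resolution*: the core is guaranteed to cover every genotyped site inside
the region where all carriers still carry the founder haplotype, but its
bp endpoints can sit inside the flanking inter-site gaps.  Note also
that only the intersection of all carriers' true segments is protected:
outside it the majority consensus can drift away from the founder
haplotype (once most carriers' segments have ended), so a single
carrier's extent need not cover that carrier's own full segment.

## Exact 2×2 test

Fisher's exact test is computed from the hypergeometric pmf in log space
(`gammaln` factorials), which is exact to float precision at cohort sizes
of 10⁵–10⁶ where factorial ratios overflow.  The one-sided (enrichment)
p-value is the upper tail P(A ≥ a); the two-sided p-value sums all tables
with the observed margins whose probability does not exceed the observed
table's, with a relative tie tolerance of 1e-7 guarding float round-off.
All tables sharing margins reuse one pmf evaluation
(`fisher_exact_class`), which makes exhaustive enumeration checks and
power sweeps cheap.  Sidedness convention: the two-sided rule above is
the common "no more probable than observed" convention; it reproduces
published carrier-enrichment tables from their printed counts.

Discreteness: the exact test's null p-value distribution is
super-uniform, so uniformity diagnostics use the randomized p-value
P(A > a) + U·P(A = a) (U ~ Uniform(0,1)), which is exactly uniform under
the null.  `ContingencyResult.randomized_p` exposes it.

The rare-site selection threshold (default: alt frequency strictly below
0.005 in a 1 Mb window centred on the focal variant) is evaluated
against *background* (non-carrier) allele frequencies: in small cohorts
the carriers' own copies would otherwise push a genuinely rare tag over
the threshold.  An alternative convention of "rarer than 1 in 250
individuals" (0.004 allele frequency if roughly one copy per carrier)
appears in the literature; both are exposed, 0.005 is the default.
Carrier tagging is genotype-level (alt present on either haplotype),
matching how per-individual counts are published; no multiple-testing
correction is applied to the primary p-values, a Bonferroni column is
emitted for convenience.

## Variant normalization and equivalence

Canonical form: trim the shared allele suffix, left-shift through repeat
context while the trailing bases agree (pulling in the preceding
reference base), then trim the shared prefix, always keeping at least
one base per allele — standard VCF left alignment, so
`chrom:pos:ref:alt` identifiers from common tooling round-trip.  Two
records are equivalent iff they edit the same reference window to the
same product string; this is the strongest checkable criterion for
"several call representations of one underlying delins" and is evaluated
over a user-supplied window (±50 bp default in the CLI).  Equivalence
classes are reported by the normalized representative of their first
member; since normalization preserves the edited product, all members of
a class share it.

## Clinical statistics

* "Independent t-test" is implemented as **Welch's** unequal-variance
  test, computable directly from published group summaries
  (mean, SD, n).  With a small carrier group against a population-scale
  background the Welch df collapse to n₁−1 and the result depends only
  on the carrier summary — the regime in which such cohort tables are
  read.  Pooled-variance t does not reproduce the published p-values
  from the printed summaries; Welch does.
* χ² on 2×2 tables uses the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
  continuity correction off by default (flag-controlled).
* CKD-EPI 2009 eGFR uses the published κ/α coefficients; the 2009
  ethnicity coefficient is retained for fidelity to the cited equation
  and is flag-controlled (off by default).  KDIGO staging: G by eGFR
  cut-points 90/60/45/30/15, A by ACR < 3 / 3–30 / > 30 mg/mmol; the CKD
  flag is eGFR < 60 or ≥ A2 (the 3-month duration criterion is the
  caller's).
* Kaplan–Meier and the two-group log-rank test are backed by
  `lifelines`; the median is the first time with S(t) ≤ 0.5 (undefined
  if the curve never reaches 0.5).

## Simulator

`simulate_founder_cohort` emulates the statistical structure a founder
event leaves in population data:

* **Genealogy.**  Each carrier's ancestral segment is drawn
  independently — a star-shaped genealogy from the founder.  This is the
  simplest model consistent with "apparently unrelated pedigrees"; it
  ignores shared internal branches, which in real data would correlate
  carrier extents and make the shared core slightly longer than
  independence predicts.
* **Recombination.**  Haldane model: one-sided segment lengths are
  Exponential(g) in Morgans, converted to bp by a uniform map (default
  1 cM/Mb), truncated at the region edges.  The truth record keeps both
  the truncated bp segments and the raw Morgan draws.
* **Background.**  Sites are independent Bernoulli draws at their allele
  frequencies (common sites Uniform(0.05, 0.5); defaults: 400 sites on a
  90 Mb chromosome-16-like region, focal at 20.36 Mb, 9 carriers, 2,500
  background samples, founder depth g = 10).  An optional pool-mosaic
  mode (haplotypes stitched from a 50-member pool) provides crude LD.
  Independent sites make the background core frequency *lower* than in
  real data with LD, so the "1 in K" statistic on simulated data is not
  comparable to published cohort values and is not used as a target.
* **Rare tags.**  Four tag variants at 0.3% background frequency inside
  the 1 Mb window, riding the founder haplotype with probability 1 by
  default.
* **Phenotypes.**  `simulate_clinical` draws carrier kidney-failure ages
  from Normal(52, 10) truncated to [30, 80] years against a low constant
  background hazard, uniform censoring ages in [40, 85], blood-pressure
  and creatinine shifts for carriers, no carrier gout excess, and
  sex-neutral survival.  `carrier_effect=0` reduces carriers to the
  background model exactly (null for type-I-error checks).

A fixed seed yields byte-identical VCF/JSON/TSV outputs.

What passing tests on these simulations do **not** show: robustness to
real LD structure, phasing/genotyping error (available via
`genotype_error_rate` but off by default), population stratification, or
cryptic relatedness in the background pool.

## Validation problem sizes and numerical choices

The validation suite uses: 200 replicates × 9 carriers per founder depth
g ∈ {5, 10, 20, 50} on a wide 600 Mb synthetic region (so exponential
segment truncation is negligible: the edge tail at g = 5 is
e⁻¹⁵ ≈ 3·10⁻⁷) for the Haldane calibration; 100 default cohorts for
end-to-end core recovery; 100 five-carrier cohorts for planted-tag
power plus 300 null tables for the randomized-p uniformity check; 1,000
two-group exponential null replicates (n = 200) for the log-rank type-I
rate; and exhaustive enumeration of all ~6.3·10⁵ non-degenerate 2×2
tables with total ≤ 60 against an exact integer oracle (probabilities
within a margin class share the denominator C(n, c₁), so comparisons are
exact; the two-sided tie rule is applied in integer arithmetic).

Degenerate inputs: an empty carrier row or background row makes the
exact test undefined and raises; zero-variance groups with unequal means
make Welch's t infinite and raise; a core containing a missing-consensus
site can match no background haplotype (missing never matches).

## Known limitations

* Phasing is assumed given; statistical phasing and its switch errors
  are out of scope (homozygous unphased genotypes can be accepted via a
  flag since they carry no phase ambiguity).
* Multi-allelic records are skipped rather than decomposed.
* Genetic distances are bp-uniform (configurable rate); no recombination
  map support.
* No haplotype-based allele-age estimation; the simulator's g is an
  input, not an estimate, and the observed 7–30 Mb scale of real shared
  extents constrains but does not identify it.
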