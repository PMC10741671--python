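# Methods

`kindredscan` implements a pedigree-based strategy for finding inherited
predisposition variants for a rare, severe phenotype — operationally,
*recurrent breast cancer* — in a population resource that links a deep
genealogy with cancer-registry and death-certificate records.  This note
describes the statistical model, the tunable parameters, what the synthetic
population emulates (and does not), and the numerical and design choices
that were genuinely open.

## Phenotype definition

Cancer registries record independent primary tumours, not recurrences.  The
operational case definition is therefore indirect: a female with a registry
diagnosis of primary breast cancer whose linked death certificate lists
breast cancer as a cause of death at least `min_lag_years` (default 10)
years after the earliest primary diagnosis.  Only calendar years are
modelled; the lag rule is `death_year − diagnosis_year ≥ 10`, strictly.
Cause-of-death codes are abstract tokens (`C50` stands in for the
breast-cancer ICD family); revision-specific ICD mapping is out of scope.
Male breast cancer exists in the data and in the assay phenotype pool, but
males are excluded from the *recurrent* case definition.

## Cohort rates and the excess test

Every individual with a linked death certificate is assigned to a cohort
`(sex, 5-year birth bin, born in-state)`; the cohort rate is the number of
recurrent cases in the cohort divided by its death-certified count.  This
is an internal-cohort rate, not an age-standardized incidence: cases are
defined through death certificates, so the denominator must be too.

A *cluster* is the strict-descendant set of an ancestor (or ancestral
couple) containing at least `min_cases` (default 2) sampled cases.  All
ancestors are scanned; clusters with identical member-case sets are
deduplicated by keeping the most recent common ancestor couple, and
overlapping clusters with distinct member sets are all retained (one case
can belong to several pedigrees through different ancestors).

For a cluster, `expected = Σ` over death-certified descendants of their
cohort rate, and `observed` counts **all** qualifying cases among the
descendants, not only the sampled members that seeded the cluster.
Significance is the exact one-sided Poisson upper tail

    p = P(X ≥ observed),  X ~ Poisson(expected)

and a cluster with `p < alpha` (default 0.05) is *high-risk*.  The exact
tail was chosen because it reproduces all seven published worked-example
p-values for a large founder pedigree (83 obs / 60.1 exp → 0.003, 44/29.3
→ 0.0067, 23/13.2 → 0.009, 54/41.9 → 0.041, 14/7.3 → 0.018, 24/15.8 →
0.033, 78/53.0 → 7.7×10⁻⁴) at their printed precision; the one apparent
one-ulp discrepancy (0.0067 vs a printed 0.006) is within the rounding of
the published expected count itself.

Two structural properties are worth stating:

* **Conservation.**  When the test is applied to the entire population the
  rates were estimated from, `expected = Σ n_k·(c_k/n_k) = Σ c_k =
  observed` — exactly, up to floating-point round-off.  The implementation
  groups descendants by cohort before multiplying so this identity holds at
  machine precision; it is asserted in the test suite.
* **Discreteness.**  An exact tail test is conservative: its attained size
  at α = 0.05 oscillates below 0.05 and approaches it only as the expected
  count grows.  Analytic computation (binomial observed, Poisson critical
  values) gives an attained size near 0.030–0.045 for expected counts of
  10–30 and ≈ 0.043 on average for expected counts of 40–110.  The
  calibration experiment therefore uses large founder lines at a
  common-cancer-site rate (3% of death-certified females, giving expected
  counts of roughly 40–110 per line, the regime of the published per-site
  excess tests).  Small clusters would show *lower* rejection rates — a
  property of exact tests, not an implementation artefact.

The expected count for calibration and power experiments uses the
generator's true (configured) cohort rates rather than rates re-estimated
per replicate; re-estimation couples each cluster to its own expectation
and adds conservatism beyond the discreteness effect, obscuring the
property being measured.  The pipeline itself always re-estimates rates
from the input data.

No multiple-testing correction is applied across clusters for the
high-risk designation, mirroring the method's screening role.

## Kinship, relationships and sharing

The kinship coefficient φ uses the standard recursion (founders unrelated
and non-inbred; recurse on the individual farther from the founders), so
parent–offspring = 1/4, first cousins = 1/16.  Relationship labels derive
from minimal meiosis paths through the nearest common ancestors; collateral
labels (sibling, avuncular, cousin…) require a full relationship — a shared
ancestral *couple* — and half-relationships fall into `other-related`.
Ties between equally-minimal connections resolve toward the closer label.

The affected-pair design rests on remoteness: first cousins share on
average only 1/8 of their genomes (2φ), so a rare variant carried by both
members of an affected cousin pair in a high-risk pedigree is a strong
candidate.  The pipeline picks, per high-risk pedigree, the related sampled
pair with the *smallest* kinship, and sequences the pair plus up to
`max_sequenced_per_pedigree − 2` (default 2) further sampled cases closest
to the pair.

## Variant filtering and co-segregation tiers

The filter cascade keeps records with population AF strictly below
`maf_max` (default 0.005; missing AF is kept and counted — an allele absent
from the reference panel is rare by construction), any consequence class
except `synonymous`, and at least one confident carrier after masking
genotypes with GQ < 20 or DP < 10 (conventional short-read thresholds; the
published coverage statement — ~95% of targets above 10× — motivates the
depth cut).  The three stages commute; the suite asserts
order-invariance.  A carrier is any genotype with ≥ 1 alternate allele
(dominant model); whether the pair shares an identical genotype is not
required, only joint carriage.

Downstream, assay genotypes of additional breast-cancer-affected relatives
feed a per-variant `SegregationSummary`:

* **Obligate carriers.**  An untyped individual is inferred to carry iff,
  for every ancestor that could be the variant's single within-pedigree
  source, the individual lies on *every* transmission path from that source
  to at least one typed carrier (typed non-carriers cannot transmit).  The
  inference can never contradict a typed non-carrier, and in gene-drop
  simulations the inferred set is always a subset of the true carriers.
* **Counting.**  Additional *recurrent* carriers are carriers with the
  recurrent phenotype other than the index pair (the other sequenced cases
  count here); additional *breast-cancer* carriers are carriers with a
  non-recurrent breast-cancer phenotype, including inferred ones.
* **Tiers.**  `assay_failed` (every assay failed, nothing else typed),
  `full_cosegregation` (every sequenced case carries and at least one
  sequenced case beyond the pair exists), `unrelated_carriers` (additional
  carriers exist but are not genealogically connected to the pair),
  otherwise `no_additional` / `one_additional` / `multi_additional` by
  count.  Relatedness means kinship > 0 with at least one index member —
  any documented genealogical connection.

Case–control association is reduced to its statistical core: a 2×2 table
of carrier counts with odds ratio ad/bc (infinite on an empty control cell,
optional Haldane–Anscombe correction) and a two-sided Fisher exact p-value
(minimum-likelihood convention).  Control matching, imputation and
quality-score filtering belong to the upstream biobank pipeline and are out
of scope; the module consumes pre-matched counts.

## The synthetic population

The generator emulates the *structure* of a statewide genealogy resource,
not Utah demography:

* Founder couples (born 1780–1820 by default) head independent lines;
  every non-terminal child pairs with a newly drawn founder spouse, so
  blood-descendant sets of distinct founder lines never overlap and each
  line is a clean cluster.
* Offspring per couple ~ Poisson(`mean_offspring`); the default of 6
  reflects the large pioneer-era sibships needed for a founder line to
  reach resource scale (the anchor pedigree of the worked examples has
  over 11,600 descendants) within the generations that are deceased today.
  Only individuals dead by the present (lifespan ~ N(72, 15), cut at the
  present year) can carry a death certificate (coverage 0.85), which is
  why founder birth years, not generation counts, bound the usable cohort.
* Recurrent-case risk for an eligible female (death-certified, lived to at
  least 40) is `baseline_rate` (default 0.008 ≈ published case and
  death-certificate totals) times `relative_risk` if she carries the risk
  allele, capped at 1.  The default `relative_risk` of 60 expresses a
  BRCA-like carrier penetrance of ≈ 0.5 rather than a literal relative
  risk; the power experiment uses the reference effect size RR = 20.
* The risk allele enters heterozygous in one founder and is transmitted by
  gene drop (probability 1/2 per meiosis, independent loci, no
  recombination map).  Background variants are unlinked, with log-uniform
  rare allele frequencies, a common-variant admixture and a synonymous
  fraction, written to an uncompressed multi-sample VCF with GENE /
  CSQCLASS / AF annotations and GT:GQ:DP genotypes.
* Sampled cases (DNA stored) are drawn at `sampling_fraction` (default
  0.8, reflecting dense biorepository sampling within studied high-risk
  pedigrees); sporadic non-recurrent breast cancers provide the assay
  phenotype pool; simulated assays read the true carrier sets with a 5%
  failure rate.

What passing tests on this population do **not** show: realistic age/sex
incidence structure, linkage disequilibrium or haplotype sharing,
genealogy errors (non-paternity, adoption), differential registry coverage,
or ascertainment bias in who gets sampled.  Conclusions about those belong
to real-data studies.

End-to-end recovery of the planted variant (filters → pair sharing →
`full_cosegregation`) succeeds in roughly three quarters of demo seeds
(30/40 measured); the remaining seeds are populations in which the risk
line, by branching-process chance, produced too few sampled carrier cases
to seat an affected pair, or a sporadic non-carrier case entered the pair —
outcomes a real study would share.

## Numerical choices and degenerate inputs

* Poisson tail via `scipy.stats.poisson.sf(obs − 1, λ)`; `observed = 0`
  returns exactly 1, `expected = 0` with `observed > 0` returns exactly 0.
* Fisher p via `scipy.stats.fisher_exact`; the test suite cross-checks it
  against exact `Fraction`-arithmetic enumeration of all tables with the
  observed margins.
* Kinship memoized per genealogy; depth ordering guarantees the recursion
  terminates on any DAG.
* Cluster dedup tie-breaks: most recent root = smallest descendant set,
  then lexicographic id; deterministic across runs.
* All simulation randomness flows from one integer seed through a single
  `numpy.random.Generator` in documented order; iteration is always over
  sorted ids or topological order, so outputs are byte-identical across
  processes and hash seeds.
* Problem sizes used by the experiment helpers: calibration pools ≥ 2000
  (default experiments use 12000) per-cohort-binomial replicates over 12
  founder lines of one ~25,000-person population; power pools 200 gene-drop
  replicates over 10 single-line populations; IBD sharing uses 10⁵ unlinked
  loci.  These sizes were chosen so each Monte-Carlo standard error is
  small against the quantity measured.

## Known limitations

* Kinship only (no inbreeding-adjusted identity coefficients, no X-linked
  kinship); inbred fixtures would need condensed identity states.
* The obligate-carrier rule assumes a single origin of the variant within
  the pedigree; recurrent mutation or two married-in carriers would defeat
  it (it then simply infers less, never wrongly under its assumption).
* The dedup rule for overlapping ancestor clusters (keep the most recent
  couple per maximal member set) is a documented choice; other resources
  may enumerate pedigrees differently.
* `pop_af` is trusted as annotated; no re-estimation from the cohort.
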