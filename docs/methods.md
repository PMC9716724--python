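# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic data can and cannot establish.

## The synthetic population model

`simdata.simulate_pedigree` grows a closed study area over
`n_generations` discrete generations from `n_founders` unrelated founders
(half male, half female). Each generation:

* every resident female of breeding age mates with **one** resident adult
  male chosen uniformly (a promiscuous mating system with no active mate
  choice — inbreeding avoidance arises only passively, through dispersal)
  and bears a Poisson(`mean_offspring_per_female`) number of offspring;
* each son remains resident with `male_philopatry_prob` (default 0.9);
  each daughter emigrates with `female_emigration_prob` (default 0.9).
  Emigrants stay in the pedigree — they matter for kinship bookkeeping —
  but never breed locally and never appear in surveys;
* `immigrant_females_per_gen` unrelated adult females (default 4) join the
  resident pool, the counterpart of emigration in an open population.

Females breed at pedigree age 1–3 generations; males breed from age 1
with no upper bound. Age classes at the end of the simulation are
assigned from generations-since-birth: 0 → sub-adult (optionally cub with
probability `cub_fraction`), ≥ 4 → elderly, otherwise adult. Immigrants
arrive as adults. There is no explicit mortality; generation depth plays
that role. These choices are the package's own — the field system gives no
published generation structure — and they are deliberately simple: the
only property downstream analyses rely on is that male kin accumulate in
the resident pool while resident females are mostly immigrants.

`Pedigree.kinship` implements Malecot's recursive path-counting kinship,
so every simulation carries an exact oracle for expected relatedness
(2 × kinship for non-inbred pairs).

### Genotypes and genotyping error

Genotypes come from Mendelian gene dropping over the pedigree on a panel
of 15 microsatellite loci with 8 equifrequent alleles (the panel size of
the fecal-genotyping protocol this emulates; per-locus frequencies are
unpublished, so a uniform default is used and is overridable per locus).

Each fecal sample yields `n_replicates` (default 3, max 5) independent
replicate calls. Per replicate and locus:

* **allelic dropout** — each allele of a true heterozygote fails
  independently with `dropout_rate` (default 0.05). If one allele
  survives, the call is homozygous for it; if both fail, a trace product
  of one of the two alleles (uniform) is still scored. The apparent-
  homozygote probability for a heterozygote is therefore 1 − (1 − d)²
  per replicate (0.36 at d = 0.2), which unit tests verify;
* **false alleles** — with `false_allele_rate` (default 0.02) one of the
  two observed allele copies is replaced by a uniformly drawn different
  allele;
* optionally, whole-locus amplification failure with
  `locus_failure_rate` (default 0).

### Surveys, fragments and sexing

Each of `n_surveys` (default 6, monthly) occasions detects every resident
independently with `detection_prob`, one fecal sample per detection. The
default detection probability is 0.4: with six occasions that yields an
expected pairwise co-detection probability 1 − (1 − p²)⁶ ≈ 0.65, matching
the sparse association networks observed in this system (connectance
~0.64) rather than a near-complete graph. The tradeoff is a smaller
sample count than a real season would produce; network density, not
sample volume, is the property downstream inference is sensitive to.

Fragment measurements (40 per sample) are drawn from per-age-class normal
distributions of bamboo-leaf fragment length/width in mm — sub-adults
21 ± 2, adults 28 ± 4, elderly 38 ± 4 long — anchored to the scale of
published per-individual fragment means; cubs produce none. Sexing-PCR
replicates are correct with probability 1 − `sexing_error`; the error
mode for males is dropout of the 210 bp Y-band, for females whole-
reaction failure.

## Consensus, matching, sexing, ageing

**Consensus** follows the multi-tube rule: heterozygote accepted iff each
allele appears in ≥ 2 replicates; homozygote iff the identical homozygous
call appears in ≥ 3; otherwise the locus is unresolved and up to two more
replicates may be consulted; after five replicates it is missing. When
both rules fire simultaneously the heterozygote wins — dropout (which
manufactures homozygotes) is far more common than a twice-replicated
false allele. Thresholds are exposed as arguments.

**Matching** clusters samples by single linkage on "differ at ≤
`max_mismatch_loci` (default 2) of jointly resolved loci", requiring ≥
`min_shared_loci` (default 9) jointly resolved; a reconciliation pass then
merges clusters whose per-locus-majority consensuses agree exactly.
Samples with too few resolved loci are excluded and logged, never
force-assigned. The published protocol states neither threshold; 2/9 are
conservative defaults and both are parameters.

**Sexing** per sample: male iff ≥ 2 replicates show both bands, female
iff the Y-band never appears and ≥ 2 replicates show the 130 bp band,
else unknown. Per individual, conflicting sample-level sexes give
unknown. **Ageing** pools all fragments of an individual's samples and
classifies the (mean length, mean width) point by nearest centroid in
per-axis-standardized space against a calibration table of known-class
animals (a built-in default ships with the package); a mean length above
`elderly_factor` (1.3) × the adult calibration mean flags elderly.
Fewer than 40 fragments → unknown unless overridden; no fragments → cub
if flagged unweaned, else unknown.

## Relatedness

Allele frequencies are counted over the identified individuals (one
genotype per individual, never per sample). The focal pair is **not**
excluded from the frequencies — the reference analysis computed
frequencies "from all individuals identified" — which induces a small
negative bias of order −1/(n−1) for unrelated pairs at sample size n;
this is documented rather than corrected.

The estimator is Queller & Goodnight (1989), symmetrized: per-locus
numerators/denominators pooled over shared loci in each direction, then
averaged. Masked pairs (no shared loci, zero pooled denominator) are NaN
throughout and excluded pairwise from every downstream computation.
Estimates slightly outside [−1, 1] are possible with estimated
frequencies and are reported as-is, flagged in the pair table, as are
pairs sharing < 6 loci (low confidence). Kin classes use midpoint bins
between the canonical values: unrelated < 0.125 ≤ third < 0.1875 ≤
second < 0.375 ≤ first; only 0.125 is stated by the reference protocol,
the interior edges are the natural interpolation and are parameters.

`relatedness_matrix` is a per-locus vectorized implementation; the
readable scalar `qg_relatedness` is the reference, and the test suite
cross-checks the two against each other to 1e-12.

## Networks

The social network uses raw co-detection counts as weights (the reference
protocol's binary per-survey association, summed over occasions), not a
rate index such as SRI; the genetic network has an edge wherever
R ≥ 0.125 with weight R (kin-class rank weighting 3/2/1 is available as
an option since the published figure's exact mapping is unstated).
Individuals lacking genotypes (cubs) never enter either network. Metrics:
degree, strength = weighted degree, normalized degree centrality,
connectance = edges / C(n, 2), mean ± SD degree. Node order in all
outputs is sorted by id for byte-stable files.

## Inference

* **Node permutation**: statistic = difference in mean node metric
  between attribute levels (level 1 − level 0), optionally on the
  z-scored metric (`std_coef`) to report standardized effect sizes — the
  p-value is identical for a binary attribute. Labels are shuffled over
  the labeled nodes only; the network is never rewired. Data-stream
  permutations of the detection records are deliberately out of scope.
* **Mantel**: Spearman correlation of strict lower triangles, null by
  simultaneous row/column permutation of the second matrix (direction
  is irrelevant to the p-value); requires ≥ 4 nodes.
* **Wilcoxon rank-sum**: W = mid-rank sum of sample 1. Exact by
  enumeration over all C(N, n1) rank assignments when N ≤ 12 without
  ties; otherwise normal approximation with tie correction and a 0.5
  continuity correction. Two-tailed p = 2·min(P≤, P≥), capped at 1.

All permutation p-values follow the (b + 1)/(n_perm + 1) convention, so
p is never exactly 0 and identical seeds reproduce identical null
distributions. Per-stage RNG streams are derived from the master seed
with fixed offsets, making every pipeline product byte-identical under
re-runs (the run manifest's timing fields excepted).

## Problem sizes used in the shipped checks

The whole-artifact test suite simulates at the scale of the study system
or modestly above it: 500 dyads per kin class for estimator calibration
(binomial SE of the mean ≈ 0.006, well inside the ±0.05 band), 30
individuals / 200 samples for zero-error identification recovery, 500
replicates × 200 permutations for type-I-error calibration of both
permutation tests, and 200 replicate populations for the dispersal
signature (resident MM mean R > FF mean R in ≥ 90% of replicates).

## What the simulator does not emulate

No spatial structure (home ranges, transect geometry, distance-dependent
association), no bamboo phenology or seasonal migration, no PCR artifacts
beyond dropout/false alleles (null alleles, stutter, contamination), no
mortality or overlapping-litter age structure, and fragment sizes are
independent normals rather than correlated within individuals. Passing
tests therefore demonstrate that the analysis chain recovers structure
*under its own assumptions*; they do not validate the field protocol
itself. Probability-of-identity computations and likelihood-based kinship
hypothesis testing are logged as future work.
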