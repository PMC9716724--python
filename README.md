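# pandanet

**From non-invasive genetic samples to the social structure of a solitary
mammal.**

Solitary species such as the giant panda rarely meet, yet they maintain
community structure through indirect interactions — scent marks, shared
foraging grounds, overlapping ranges. `pandanet` implements, as a tested
and reusable pipeline, the analysis chain that turns fecal-DNA field
surveys into that structure:

1. **Consensus genotyping** — replicate ("multi-tube") microsatellite PCR
   calls per fecal sample are combined into reliable multilocus genotypes:
   a heterozygote needs each allele observed in ≥ 2 replicates, a
   homozygote needs the identical call in ≥ 3; unresolved loci can be
   rescued by up to two extra replicates.
2. **Individual, sex and age identification** — samples are clustered into
   individuals by single-linkage genotype matching; sex comes from
   replicate sexing-PCR band patterns (male: 210 bp + 130 bp bands in ≥ 2
   replicates; female: 130 bp only); age class (sub-adult / adult /
   elderly) comes from bamboo-leaf fragment sizes in feces via
   nearest-centroid classification against known-age calibration animals.
3. **Pairwise relatedness** — the symmetrized Queller & Goodnight (1989)
   moment estimator. For focal alleles (a, b) against partner alleles
   (c, d) at one locus,

   ```
   num = ½(I_ac + I_ad + I_bc + I_bd) − p_a − p_b
   den = 1 + I_ab − p_a − p_b
   ```

   with allele-identity indicators I and population frequencies p;
   numerators and denominators are pooled over shared loci, the ratio
   taken in each direction, and the two averaged. Pairs are binned into
   kin classes around the canonical pedigree values (first 0.5, second
   0.25, third 0.125; R < 0.125 = unrelated).
4. **Networks** — a social network by the *gambit of the group*: all
   individuals detected on the same survey occasion are associated, edge
   weight = number of co-detections; and a genetic network with an edge
   wherever R ≥ 0.125, weighted by R.
5. **Inference** — node-permutation tests for sex/age effects on strength
   (weighted degree), a Mantel test (Spearman) for social–genetic
   congruence, and a Wilcoxon rank-sum comparison of MM vs FF relatedness.
   All permutation p-values are two-tailed with the observed statistic
   included: p = (b + 1)/(n_perm + 1).

Because raw field data of this kind are rarely public, the package ships a
first-class simulator (`pandanet.simdata`) generating multigenerational
populations with **male philopatry and female-biased dispersal**,
Mendelian gene dropping over a 15-locus microsatellite panel, allelic
dropout and false alleles in replicate calls, monthly survey detections,
fragment-size distributions by age class, and sexing-PCR errors — so every
stage of the chain can be tested against ground truth.

## Worked example

```python
from pandanet import SimConfig, run_pipeline

manifest, report = run_pipeline(SimConfig(seed=1), "demo/", n_perm=1000)
```

With the default configuration and seed 1 this simulates a population,
identifies individuals from the noisy replicate calls, and prints the
report (excerpt):

```
identified: 58 of 59 residents; 157 samples
social:  58 nodes, 1241 edges, connectance 0.751, mean degree 42.793 (SD 9.959)
genetic: 58 nodes,  198 edges, connectance 0.120, mean degree 6.828
MM: n=595  mean R=-0.005  prop relatives=0.173
MF: n=805  mean R=-0.021  prop relatives=0.097
FF: n=253  mean R=-0.036  prop relatives=0.067
genetic_sex_strength:      stat=1.141  p=0.001
mantel_social_genetic:     r=-0.015    p=0.525
ranksum_mm_vs_ff_adults:   W=60426.0   p=0.5468
```

Reading this: identification recovered 58 of the 59 resident animals from
157 fecal samples. Male–male pairs are the most related group (17.3% of MM
pairs are relatives at R ≥ 0.125, versus 6.7% of FF pairs) — the signature
of female-biased dispersal, which removes related females from the study
area while philopatric males accumulate into patrilines — and sex has a
strong effect on strength in the genetic network (males more connected,
p = 0.001).

The same stages are available from a shell:

```sh
pandanet simulate --seed 1 --outdir sim/
pandanet identify --calls sim/replicate_calls.csv --sexing sim/sexing.csv \
                  --fragments sim/fragments.csv --out ind/
pandanet relatedness --genotypes ind/consensus_genotypes.csv \
                     --individuals ind/individuals.csv --out rel/
pandanet networks --detections sim/detections.csv \
                  --relatedness rel/relatedness.csv \
                  --individuals ind/individuals.csv --out nets/
pandanet run --seed 1 --outdir results/     # everything end to end
```

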