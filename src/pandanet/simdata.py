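"""Synthetic populations with male philopatry and female-biased dispersal.

This module generates every input the downstream analysis chain consumes:

* a multigenerational :class:`Pedigree` in which sons tend to stay resident
  and daughters tend to emigrate, with unrelated immigrant females arriving
  each generation (the dispersal regime reported for wild giant pandas);
* true multilocus microsatellite genotypes by Mendelian gene dropping;
* fecal-sample data: per-survey detections, replicate genotype calls with
  allelic dropout and false alleles, bamboo-fragment measurements drawn from
  age-class-specific distributions, and sexing-PCR band patterns.

Pedigree-based kinship (path counting) is included so simulations carry
their own oracle for relatedness-recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .config import ConfigError, Locus, SimConfig, default_loci
from .genotyping import (
    BandPattern,
    FragmentMeasurementSet,
    MultilocusGenotype,
    ReplicateCallSet,
    SexReplicateSet,
)

__all__ = [
    "Individual",
    "Pedigree",
    "TrueGenotypeTable",
    "SurveyDetection",
    "ReplicateCallSet",
    "FragmentMeasurementSet",
    "SexReplicateSet",
    "BandPattern",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_samples",
    "simulate_dyads",
    "simulate_identification_dataset",
    "corrupt_call",
]

MALE = "male"
FEMALE = "female"


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str
    birth_gen: int
    mother: str | None
    father: str | None
    resident: bool
    age_class: str


class Pedigree:
    """Ordered collection of individuals; parents always precede offspring."""

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals = list(individuals)
        self._by_id = {ind.id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise ValueError("duplicate individual ids in pedigree")
        self._kinship_cache: dict[tuple[str, str], float] = {}

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def residents(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.resident]

    def kinship(self, a: str, b: str) -> float:
        """Malecot kinship coefficient f(a, b) by recursive path counting."""
        if a == b:
            ind = self._by_id[a]
            if ind.mother is None or ind.father is None:
                return 0.5
            return 0.5 * (1.0 + self.kinship(ind.mother, ind.father))
        key = (a, b) if a < b else (b, a)
        if key in self._kinship_cache:
            return self._kinship_cache[key]
        ia, ib = self._by_id[a], self._by_id[b]
        # recurse on the younger individual; founders/immigrants are unrelated
        if ia.birth_gen < ib.birth_gen:
            ia, ib = ib, ia
        if ia.mother is None and ia.father is None:
            if ib.mother is None and ib.father is None:
                f = 0.0
            else:
                f = 0.5 * (
                    self.kinship(ib.mother, ia.id) + self.kinship(ib.father, ia.id)
                )
        else:
            f = 0.5 * (
                self.kinship(ia.mother, ib.id) + self.kinship(ia.father, ib.id)
            )
        self._kinship_cache[key] = f
        return f

    def relatedness(self, a: str, b: str) -> float:
        """Expected pedigree relatedness, 2 x kinship (0.5 for parent-offspring)."""
        return 2.0 * self.kinship(a, b)

    def to_records(self) -> list[dict]:
        return [
            {
                "id": i.id,
                "sex": i.sex,
                "birth_gen": i.birth_gen,
                "mother": i.mother or "",
                "father": i.father or "",
                "resident": i.resident,
                "age_class": i.age_class,
            }
            for i in self.individuals
        ]


def _age_class(birth_gen: int, n_generations: int, immigrant: bool) -> str:
    age = n_generations - birth_gen
    if age >= 4:
        return "elderly"
    if age == 0 and not immigrant:
        return "sub-adult"
    return "adult"


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Simulate a multigenerational pedigree under female-biased dispersal.

    Each generation, every resident female of breeding age (1..3 generations
    old) mates with one uniformly chosen resident adult male and bears a
    Poisson number of offspring. Sons stay resident with
    ``male_philopatry_prob``; daughters emigrate with
    ``female_emigration_prob`` (they remain in the pedigree for kinship
    bookkeeping but never breed locally or appear in surveys). Unrelated
    immigrant adult females arrive each generation. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    ng = config.n_generations
    individuals: list[Individual] = []

    n_f = config.n_founders // 2
    n_m = config.n_founders - n_f
    for k in range(config.n_founders):
        sex = MALE if k < n_m else FEMALE
        individuals.append(
            Individual(
                id=f"FND{k:02d}",
                sex=sex,
                birth_gen=0,
                mother=None,
                father=None,
                resident=True,
                age_class=_age_class(0, ng, immigrant=False),
            )
        )

    for g in range(1, ng + 1):
        mothers = [
            i
            for i in individuals
            if i.sex == FEMALE and i.resident and 1 <= g - i.birth_gen <= 3
        ]
        fathers = [
            i
            for i in individuals
            if i.sex == MALE and i.resident and g - i.birth_gen >= 1
        ]
        births: list[Individual] = []
        if fathers:
            for mom in mothers:
                dad = fathers[rng.integers(len(fathers))]
                for _ in range(rng.poisson(config.mean_offspring_per_female)):
                    sex = MALE if rng.random() < 0.5 else FEMALE
                    if sex == MALE:
                        resident = rng.random() < config.male_philopatry_prob
                    else:
                        resident = rng.random() >= config.female_emigration_prob
                    cls = _age_class(g, ng, immigrant=False)
                    if cls == "sub-adult" and rng.random() < config.cub_fraction:
                        cls = "cub"
                    births.append(
                        Individual(
                            id=f"G{g}N{len(births):03d}",
                            sex=sex,
                            birth_gen=g,
                            mother=mom.id,
                            father=dad.id,
                            resident=resident,
                            age_class=cls,
                        )
                    )
        for k in range(config.immigrant_females_per_gen):
            births.append(
                Individual(
                    id=f"IMM{g}N{k:02d}",
                    sex=FEMALE,
                    birth_gen=g,
                    mother=None,
                    father=None,
                    resident=True,
                    age_class=_age_class(g, ng, immigrant=True),
                )
            )
        individuals.extend(births)

    ped = Pedigree(individuals)
    if not ped.residents():
        raise ConfigError("degenerate scenario: no residents at end of simulation")
    return ped


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


class TrueGenotypeTable:
    """Ground-truth multilocus genotypes, one complete genotype per individual."""

    def __init__(self, loci: Sequence[Locus], genotypes: dict[str, MultilocusGenotype]):
        self.loci = tuple(loci)
        self.genotypes = dict(genotypes)

    def __getitem__(self, ind_id: str) -> MultilocusGenotype:
        return self.genotypes[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.genotypes

    def __len__(self) -> int:
        return len(self.genotypes)

    def items(self):
        return self.genotypes.items()


def _draw_founder_genotype(loci: Sequence[Locus], rng: np.random.Generator) -> MultilocusGenotype:
    calls = {}
    for locus in loci:
        a, b = rng.choice(locus.alleles, size=2, p=locus.frequencies)
        calls[locus.name] = (min(a, b), max(a, b))
    return MultilocusGenotype(calls)


def _mendelian_child(
    mother: MultilocusGenotype,
    father: MultilocusGenotype,
    loci: Sequence[Locus],
    rng: np.random.Generator,
) -> MultilocusGenotype:
    calls = {}
    for locus in loci:
        a = mother[locus.name][rng.integers(2)]
        b = father[locus.name][rng.integers(2)]
        calls[locus.name] = (min(a, b), max(a, b))
    return MultilocusGenotype(calls)


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> TrueGenotypeTable:
    """Mendelian gene dropping over the pedigree.

    Founders and immigrants draw both alleles from the configured locus
    frequencies; every offspring inherits one uniformly chosen allele from
    each parent at each locus. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    genotypes: dict[str, MultilocusGenotype] = {}
    for ind in pedigree.individuals:
        if ind.mother is None or ind.father is None:
            genotypes[ind.id] = _draw_founder_genotype(config.loci, rng)
        else:
            genotypes[ind.id] = _mendelian_child(
                genotypes[ind.mother], genotypes[ind.father], config.loci, rng
            )
    return TrueGenotypeTable(config.loci, genotypes)


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyDetection:
    """One individual detected (via a fecal sample) on one survey occasion."""

    survey_id: str
    individual_id: str
    sample_id: str


def corrupt_call(
    genotype: MultilocusGenotype,
    loci: Sequence[Locus],
    rng: np.random.Generator,
    dropout_rate: float,
    false_allele_rate: float,
    locus_failure_rate: float = 0.0,
) -> dict[str, tuple[str, str]]:
    """One replicate PCR call with allelic dropout and false alleles.

    Dropout acts per allele of a true heterozygote: each of the two alleles
    fails to amplify independently with ``dropout_rate``. If one survives,
    the call is homozygous for the survivor; if both fail, trace product of
    one of the two alleles (chosen uniformly) is still scored, so the locus
    again appears homozygous. Hence the apparent-homozygote probability for
    a heterozygote is 1 - (1 - d)^2 per replicate. A false allele replaces
    one observed allele copy with a uniformly drawn different allele with
    ``false_allele_rate`` per locus per replicate.
    """
    call: dict[str, tuple[str, str]] = {}
    for locus in loci:
        if locus_failure_rate and rng.random() < locus_failure_rate:
            continue
        a, b = genotype[locus.name]
        if a != b:
            drop_a = rng.random() < dropout_rate
            drop_b = rng.random() < dropout_rate
            if drop_a and drop_b:
                a = b = (a, b)[rng.integers(2)]
            elif drop_a:
                a = b
            elif drop_b:
                b = a
        if false_allele_rate and rng.random() < false_allele_rate:
            pos = rng.integers(2)
            current = (a, b)[pos]
            others = [x for x in locus.alleles if x != current]
            wrong = others[rng.integers(len(others))]
            a, b = (wrong, b) if pos == 0 else (a, wrong)
        call[locus.name] = (min(a, b), max(a, b))
    return call


def _sex_patterns(
    sex: str, n: int, error: float, rng: np.random.Generator
) -> tuple[BandPattern, ...]:
    pats = []
    for _ in range(n):
        fail = rng.random() < error
        if sex == MALE:
            # error mode: dropout of the 210 bp Y-band
            pats.append(BandPattern(band_210=not fail, band_130=True))
        else:
            # error mode: whole-reaction failure (no bands)
            pats.append(BandPattern(band_210=False, band_130=not fail))
    return tuple(pats)


def simulate_samples(
    pedigree: Pedigree, truth: TrueGenotypeTable, config: SimConfig
) -> tuple[
    list[SurveyDetection],
    list[ReplicateCallSet],
    list[FragmentMeasurementSet],
    list[SexReplicateSet],
]:
    """Simulate monthly surveys and the fecal samples they yield.

    Each resident is detected on each survey occasion with
    ``detection_prob``; every detection produces one fecal sample carrying
    ``n_replicates`` genotype calls (with dropout/false alleles),
    ``n_fragments`` bamboo-fragment measurements drawn from the
    individual's age-class distribution (none for cubs), and
    ``n_sex_replicates`` sexing band patterns. Deterministic given seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    residents = pedigree.residents()
    if not residents:
        raise ConfigError("no residents to sample")

    detections: list[SurveyDetection] = []
    callsets: list[ReplicateCallSet] = []
    fragmentsets: list[FragmentMeasurementSet] = []
    sexsets: list[SexReplicateSet] = []

    for s in range(1, config.n_surveys + 1):
        survey_id = f"M{s:02d}"
        for ind in residents:
            if rng.random() >= config.detection_prob:
                continue
            sample_id = f"{survey_id}_{ind.id}"
            detections.append(SurveyDetection(survey_id, ind.id, sample_id))

            reps = [
                corrupt_call(
                    truth[ind.id],
                    config.loci,
                    rng,
                    config.dropout_rate,
                    config.false_allele_rate,
                    config.locus_failure_rate,
                )
                for _ in range(config.n_replicates)
            ]
            callsets.append(ReplicateCallSet(sample_id, reps))

            if ind.age_class != "cub":
                dist = config.fragment_params[ind.age_class]
                lengths = np.maximum(
                    rng.normal(dist.length_mean, dist.length_sd, config.n_fragments),
                    0.1,
                )
                widths = np.maximum(
                    rng.normal(dist.width_mean, dist.width_sd, config.n_fragments),
                    0.1,
                )
                fragmentsets.append(
                    FragmentMeasurementSet(
                        sample_id,
                        tuple(zip(lengths.tolist(), widths.tolist())),
                    )
                )

            sexsets.append(
                SexReplicateSet(
                    sample_id,
                    _sex_patterns(
                        ind.sex, config.n_sex_replicates, config.sexing_error, rng
                    ),
                )
            )

    return detections, callsets, fragmentsets, sexsets


# ---------------------------------------------------------------------------
# focused dyad and identification harnesses
# ---------------------------------------------------------------------------

Relationship = Literal[
    "parent-offspring", "full-sib", "half-sib", "first-cousin", "unrelated"
]


def simulate_dyads(
    relationship: Relationship,
    n_dyads: int,
    loci: Sequence[Locus] | None = None,
    seed: int = 0,
) -> list[tuple[MultilocusGenotype, MultilocusGenotype]]:
    """Simulate genotype pairs with a known pedigree relationship.

    Founder genotypes come from the locus frequencies; descent is
    Mendelian. Supported relationships and their expected relatedness:
    parent-offspring and full sibs (0.5), half sibs sharing one parent
    (0.25), first cousins via a full-sib parental pair (0.125), and
    unrelated pairs (0).
    """
    loci = tuple(loci) if loci is not None else default_loci()
    rng = np.random.default_rng([seed, 7])
    draw = lambda: _draw_founder_genotype(loci, rng)  # noqa: E731
    child = lambda m, f: _mendelian_child(m, f, loci, rng)  # noqa: E731

    dyads = []
    for _ in range(n_dyads):
        if relationship == "parent-offspring":
            p1, p2 = draw(), draw()
            dyads.append((p1, child(p1, p2)))
        elif relationship == "full-sib":
            p1, p2 = draw(), draw()
            dyads.append((child(p1, p2), child(p1, p2)))
        elif relationship == "half-sib":
            shared, f1, f2 = draw(), draw(), draw()
            dyads.append((child(shared, f1), child(shared, f2)))
        elif relationship == "first-cousin":
            g1, g2 = draw(), draw()
            sib1, sib2 = child(g1, g2), child(g1, g2)
            dyads.append((child(sib1, draw()), child(sib2, draw())))
        elif relationship == "unrelated":
            dyads.append((draw(), draw()))
        else:
            raise ValueError(f"unknown relationship {relationship!r}")
    return dyads


def simulate_identification_dataset(
    n_individuals: int,
    n_samples: int,
    config: SimConfig | None = None,
    seed: int = 0,
) -> tuple[
    dict[str, MultilocusGenotype],
    dict[str, str],
    dict[str, str],
    list[ReplicateCallSet],
    list[SexReplicateSet],
]:
    """Unrelated individuals, each sampled at least once, for identification tests.

    Returns ``(true_genotypes, true_sexes, sample_to_individual, callsets,
    sexsets)``. The first ``n_individuals`` samples cover every individual
    once; remaining samples are assigned uniformly at random.
    """
    if n_samples < n_individuals:
        raise ValueError("need at least one sample per individual")
    config = (config or SimConfig()).validate()
    rng = np.random.default_rng([seed, 11])
    ids = [f"T{k:03d}" for k in range(n_individuals)]
    truth = {i: _draw_founder_genotype(config.loci, rng) for i in ids}
    sexes = {i: (MALE if rng.random() < 0.5 else FEMALE) for i in ids}

    owners = list(range(n_individuals)) + list(
        rng.integers(n_individuals, size=n_samples - n_individuals)
    )
    callsets, sexsets = [], []
    sample_to_individual = {}
    for s, owner in enumerate(owners):
        ind = ids[int(owner)]
        sample_id = f"S{s:04d}"
        sample_to_individual[sample_id] = ind
        reps = [
            corrupt_call(
                truth[ind],
                config.loci,
                rng,
                config.dropout_rate,
                config.false_allele_rate,
                config.locus_failure_rate,
            )
            for _ in range(config.n_replicates)
        ]
        callsets.append(ReplicateCallSet(sample_id, reps))
        sexsets.append(
            SexReplicateSet(
                sample_id,
                _sex_patterns(
                    sexes[ind], config.n_sex_replicates, config.sexing_error, rng
                ),
            )
        )
    return truth, sexes, sample_to_individual, callsets, sexsets
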