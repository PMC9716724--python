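"""Pedigree, gene-dropping and sampling-process simulator tests."""

import numpy as np
import pytest

from pandanet.config import ConfigError, Locus, SimConfig, default_loci
from pandanet.genotyping import MultilocusGenotype
from pandanet.simdata import (
    Pedigree,
    corrupt_call,
    simulate_genotypes,
    simulate_identification_dataset,
    simulate_pedigree,
    simulate_samples,
)
from pandanet.simdata import _mendelian_child  # white-box Mendelian oracle check


def test_forced_emigration_leaves_no_resident_daughters(small_config):
    """With emigration probability 1, every locally-born female leaves."""
    cfg = small_config.replace(
        female_emigration_prob=1.0, n_generations=3, immigrant_females_per_gen=3
    )
    ped = simulate_pedigree(cfg)
    for ind in ped.residents():
        if ind.sex == "female" and ind.mother is not None:
            pytest.fail(f"resident locally-born female {ind.id}")


def test_full_philopatry_full_emigration_structure(small_config):
    """All sons stay, all daughters leave: resident mother-daughter pairs absent."""
    cfg = small_config.replace(
        male_philopatry_prob=1.0, female_emigration_prob=1.0, n_generations=3
    )
    ped = simulate_pedigree(cfg)
    resident_ids = {i.id for i in ped.residents()}
    for ind in ped.residents():
        if ind.sex == "male" and ind.mother is not None:
            assert ind.resident  # forced by philopatry prob 1
        if ind.sex == "female" and ind.mother is not None:
            assert ind.mother not in resident_ids or not ind.resident


def test_pedigree_rejects_degenerate_configs():
    with pytest.raises(ConfigError):
        simulate_pedigree(SimConfig(n_founders=1))
    with pytest.raises(ConfigError):
        SimConfig(dropout_rate=1.5).validate()
    with pytest.raises(ConfigError):
        SimConfig(loci=(Locus("L1", (0.6, 0.3)),)).validate()
    with pytest.raises(ConfigError):
        SimConfig(n_replicates=2).validate()


def test_pedigree_kinship_canonical_values():
    """Path-counting kinship reproduces textbook relatedness on a hand pedigree."""
    from pandanet.simdata import Individual

    mk = lambda i, sex, g, m, f: Individual(i, sex, g, m, f, True, "adult")
    ped = Pedigree(
        [
            mk("gm", "female", 0, None, None),
            mk("gf", "male", 0, None, None),
            mk("u1", "male", 0, None, None),
            mk("u2", "male", 0, None, None),
            mk("s1", "female", 1, "gm", "gf"),
            mk("s2", "female", 1, "gm", "gf"),
            mk("h1", "female", 1, "gm", "u1"),
            mk("c1", "male", 2, "s1", "u1"),
            mk("c2", "male", 2, "s2", "u2"),
        ]
    )
    assert ped.relatedness("gm", "s1") == pytest.approx(0.5)  # parent-offspring
    assert ped.relatedness("s1", "s2") == pytest.approx(0.5)  # full sibs
    assert ped.relatedness("s1", "h1") == pytest.approx(0.25)  # half sibs
    assert ped.relatedness("gm", "c1") == pytest.approx(0.25)  # grandmother
    assert ped.relatedness("c1", "c2") == pytest.approx(0.125)  # first cousins
    assert ped.relatedness("u1", "u2") == 0.0


def test_mendelian_consistency_of_simulated_genotypes(small_config):
    ped = simulate_pedigree(small_config)
    truth = simulate_genotypes(ped, small_config)
    for ind in ped.individuals:
        if ind.mother is None:
            continue
        gm, gf, gc = truth[ind.mother], truth[ind.father], truth[ind.id]
        for locus in small_config.loci:
            a, b = gc[locus.name]
            mom, dad = set(gm[locus.name]), set(gf[locus.name])
            assert (a in mom and b in dad) or (a in dad and b in mom), (
                f"{ind.id} at {locus.name}: {a}/{b} not derivable from "
                f"{mom} x {dad}"
            )


def test_single_allele_locus_is_monomorphic():
    cfg = SimConfig(
        n_founders=6,
        n_generations=2,
        loci=(Locus("L1", (1.0 - 1e-12, 1e-12)),),
    )
    ped = simulate_pedigree(cfg)
    truth = simulate_genotypes(ped, cfg)
    assert all(g["L1"] == ("01", "01") for _, g in truth.items())


def test_offspring_allele_combinations_equifrequent(rng):
    """A/B x C/D children hit each of the four combinations ~1/4 of the time."""
    loci = (Locus("L1", (0.25,) * 4),)
    mom = MultilocusGenotype({"L1": ("01", "02")})
    dad = MultilocusGenotype({"L1": ("03", "04")})
    counts = {}
    n = 10_000
    for _ in range(n):
        pair = _mendelian_child(mom, dad, loci, rng)["L1"]
        counts[pair] = counts.get(pair, 0) + 1
    assert set(counts) == {("01", "03"), ("01", "04"), ("02", "03"), ("02", "04")}
    for pair, c in counts.items():
        assert abs(c / n - 0.25) < 0.02, (pair, c)


def test_dropout_apparent_homozygote_rate_closed_form(rng):
    """P(heterozygote scored homozygous) = 1 - (1-d)^2 = 0.36 at d = 0.2."""
    loci = (Locus("L1", (0.125,) * 8),)
    g = MultilocusGenotype({"L1": ("01", "02")})
    n = 100_000
    hom = 0
    for _ in range(n):
        a, b = corrupt_call(g, loci, rng, dropout_rate=0.2, false_allele_rate=0.0)["L1"]
        hom += a == b
    assert abs(hom / n - 0.36) < 0.01


def test_zero_error_replicates_equal_truth(small_config):
    cfg = small_config.replace(
        dropout_rate=0.0, false_allele_rate=0.0, locus_failure_rate=0.0
    )
    ped = simulate_pedigree(cfg)
    truth = simulate_genotypes(ped, cfg)
    _, callsets, _, _ = simulate_samples(ped, truth, cfg)
    for cs in callsets:
        ind_id = cs.sample_id.split("_", 1)[1]
        expected = truth[ind_id].calls
        for rep in cs.replicates:
            assert rep == dict(expected)


def test_full_detection_probability(small_config):
    cfg = small_config.replace(detection_prob=1.0, n_surveys=6)
    ped = simulate_pedigree(cfg)
    truth = simulate_genotypes(ped, cfg)
    detections, _, _, _ = simulate_samples(ped, truth, cfg)
    per_ind = {}
    for d in detections:
        per_ind.setdefault(d.individual_id, set()).add(d.survey_id)
    assert set(per_ind) == {i.id for i in ped.residents()}
    assert all(len(s) == 6 for s in per_ind.values())


def test_seed_determinism(small_config):
    def run():
        ped = simulate_pedigree(small_config)
        truth = simulate_genotypes(ped, small_config)
        samples = simulate_samples(ped, truth, small_config)
        return ped.to_records(), dict(truth.items()), samples

    r1, r2 = run(), run()
    assert r1[0] == r2[0]
    assert r1[1] == r2[1]
    assert r1[2] == r2[2]


def test_resident_mm_relatedness_exceeds_ff_by_pedigree_oracle():
    """Male philopatry + female dispersal concentrates kin among resident
    males: pedigree-kinship mean of MM dyads >= FF dyads (sign test over
    100 replicate pedigrees)."""
    import itertools

    wins = ties = 0
    n_rep = 100
    for rep in range(n_rep):
        cfg = SimConfig(
            n_founders=8, n_generations=3, immigrant_females_per_gen=3, seed=1000 + rep
        )
        ped = simulate_pedigree(cfg)
        males = [i.id for i in ped.residents() if i.sex == "male"]
        females = [i.id for i in ped.residents() if i.sex == "female"]
        if len(males) < 2 or len(females) < 2:
            ties += 1
            continue
        mm = np.mean(
            [ped.relatedness(a, b) for a, b in itertools.combinations(males, 2)]
        )
        ff = np.mean(
            [ped.relatedness(a, b) for a, b in itertools.combinations(females, 2)]
        )
        wins += mm > ff
        ties += mm == ff
    assert wins / (n_rep - ties) > 0.9


def test_fragment_means_match_configured_distributions(small_config):
    cfg = small_config.replace(detection_prob=1.0)
    ped = simulate_pedigree(cfg)
    truth = simulate_genotypes(ped, cfg)
    _, _, fragmentsets, _ = simulate_samples(ped, truth, cfg)
    by_ind = {i.id: i for i in ped.individuals}
    for fs in fragmentsets:
        assert len(fs.measurements) == cfg.n_fragments >= 40
    # the 3-4 SE bound is checked on the pooled per-class aggregate, not on
    # every individual sample (a few 40-draw samples will exceed 3 SE)
    pooled = {}
    for fs in fragmentsets:
        cls = by_ind[fs.sample_id.split("_", 1)[1]].age_class
        pooled.setdefault(cls, []).extend(m[0] for m in fs.measurements)
    for cls, lengths in pooled.items():
        dist = cfg.fragment_params[cls]
        se = dist.length_sd / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - dist.length_mean) < 4 * se


def test_cubs_produce_no_fragments():
    cfg = SimConfig(
        n_founders=6, n_generations=2, cub_fraction=1.0, detection_prob=1.0, seed=5
    )
    ped = simulate_pedigree(cfg)
    cubs = {i.id for i in ped.residents() if i.age_class == "cub"}
    assert cubs, "expected forced cubs in the final generation"
    truth = simulate_genotypes(ped, cfg)
    detections, _, fragmentsets, _ = simulate_samples(ped, truth, cfg)
    with_fragments = {fs.sample_id for fs in fragmentsets}
    for d in detections:
        if d.individual_id in cubs:
            assert d.sample_id not in with_fragments


def test_identification_dataset_covers_every_individual():
    truth, sexes, mapping, callsets, sexsets = simulate_identification_dataset(
        12, 40, SimConfig(), seed=3
    )
    assert len(truth) == 12 and len(callsets) == 40 == len(sexsets)
    assert set(mapping.values()) == set(truth)
    with pytest.raises(ValueError):
        simulate_identification_dataset(10, 5)
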