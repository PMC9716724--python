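"""Consensus genotyping, individual matching, sexing and ageing tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pandanet.config import Locus, SimConfig
from pandanet.genotyping import (
    BandPattern,
    FragmentMeasurementSet,
    MultilocusGenotype,
    ReplicateCallSet,
    SexReplicateSet,
    classify_age,
    consensus_genotype,
    consensus_with_retries,
    determine_sex,
    match_individuals,
)
from pandanet.simdata import corrupt_call


def _calls(*reps):
    return ReplicateCallSet("S1", [dict(r) for r in reps])


AB = {"L1": ("A", "B")}
AA = {"L1": ("A", "A")}


class TestConsensus:
    @pytest.mark.parametrize(
        "reps, expected",
        [
            ([AB, AB, AB], ("A", "B")),  # unanimity
            ([AA, AB, AB], ("A", "B")),  # A seen 3x, B seen 2x -> heterozygote
            ([AA, AA, AA], ("A", "A")),  # homozygote seen 3x
            ([AA, AA, AA, AB, AB], ("A", "B")),  # confirmed allele beats hom rule
            ([AB, AA, {"L1": ("B", "B")}], ("A", "B")),  # A and B each seen twice
        ],
    )
    def test_resolved_loci(self, reps, expected):
        result = consensus_genotype(_calls(*reps))
        assert result.genotype["L1"] == expected
        assert not result.unresolved

    @pytest.mark.parametrize(
        "reps",
        [
            [AA, AA, {}],  # homozygote seen only twice
            [AA, AB, {"L1": ("A", "C")}],  # B and C seen once each, A not 3x hom
            [{"L1": ("A", "C")}, {"L1": ("B", "C")}, {"L1": ("A", "B")}],  # 3 alleles
        ],
    )
    def test_unresolved_loci(self, reps):
        result = consensus_genotype(_calls(*reps))
        assert "L1" in result.unresolved
        assert "L1" not in result.genotype

    def test_retry_protocol(self):
        """Two homozygous calls resolve only after extra replicates arrive."""
        three = _calls(AA, AA, {})
        assert "L1" in consensus_genotype(three).unresolved
        five = _calls(AA, AA, {}, AA, AA)
        assert consensus_with_retries(five)["L1"] == ("A", "A")

    def test_requires_three_replicates(self):
        with pytest.raises(ValueError, match="3 replicates"):
            consensus_genotype(_calls(AB, AB))

    def test_replicate_order_invariance(self):
        reps = [AA, AB, {"L1": ("B", "B")}, AB, {}]
        results = {
            (
                tuple(sorted(consensus_genotype(_calls(*p)).genotype.calls.items())),
                tuple(sorted(consensus_genotype(_calls(*p)).unresolved)),
            )
            for p in itertools.permutations(reps)
        }
        assert len(results) == 1

    @settings(max_examples=60, derandomize=True)
    @given(
        reps=st.lists(
            st.dictionaries(
                st.just("L1"),
                st.tuples(st.sampled_from("ABC"), st.sampled_from("ABC")).map(
                    lambda p: (min(p), max(p))
                ),
                max_size=1,
            ),
            min_size=3,
            max_size=5,
        ),
        perm_seed=st.integers(0, 1000),
    )
    def test_permutation_invariance_property(self, reps, perm_seed):
        """Consensus never depends on the order replicates arrive in."""
        base = consensus_genotype(_calls(*reps))
        shuffled = list(reps)
        np.random.default_rng(perm_seed).shuffle(shuffled)
        other = consensus_genotype(_calls(*shuffled))
        assert base.genotype.calls == other.genotype.calls
        assert base.unresolved == other.unresolved

    def test_error_rate_under_heavy_dropout(self):
        """Five replicates at dropout 0.2: wrong consensus calls < 1% of loci."""
        rng = np.random.default_rng(77)
        loci = tuple(Locus(f"L{i:05d}", (0.125,) * 8) for i in range(10_000))
        calls = {}
        for locus in loci:
            a, b = rng.choice(locus.alleles, size=2, p=locus.frequencies)
            calls[locus.name] = (min(a, b), max(a, b))
        truth = MultilocusGenotype(calls)
        reps = [
            corrupt_call(truth, loci, rng, dropout_rate=0.2, false_allele_rate=0.0)
            for _ in range(5)
        ]
        result = consensus_genotype(ReplicateCallSet("S", reps))
        wrong = sum(
            1
            for locus in result.genotype.loci
            if result.genotype[locus] != truth[locus]
        )
        assert wrong / len(loci) < 0.01


def _geno(seed, n_loci=15, n_alleles=8):
    rng = np.random.default_rng(seed)
    return MultilocusGenotype(
        {
            f"L{i:02d}": tuple(
                sorted(f"{a + 1:02d}" for a in rng.integers(n_alleles, size=2))
            )
            for i in range(n_loci)
        }
    )


def _mutate(g, loci_to_change):
    calls = dict(g.calls)
    for locus in loci_to_change:
        a, b = calls[locus]
        calls[locus] = ("99", "99")
    return MultilocusGenotype(calls)


class TestMatching:
    def test_identical_samples_merge(self):
        g = _geno(1)
        recs = match_individuals([("s1", g), ("s2", g)])
        assert len(recs) == 1
        assert recs[0].sample_ids == ["s1", "s2"]

    def test_zero_threshold_splits_single_locus_difference(self):
        g = _geno(2)
        g2 = _mutate(g, ["L00"])
        assert len(match_individuals([("s1", g), ("s2", g2)], max_mismatch_loci=0)) == 2
        assert len(match_individuals([("s1", g), ("s2", g2)], max_mismatch_loci=1)) == 1

    def test_cluster_count_monotone_in_mismatch_threshold(self):
        rng = np.random.default_rng(9)
        samples = []
        for k in range(12):
            base = _geno(100 + k // 3)  # 4 true individuals, 3 samples each
            noisy = _mutate(
                base, [f"L{i:02d}" for i in rng.choice(15, size=rng.integers(3), replace=False)]
            )
            samples.append((f"s{k:02d}", noisy))
        counts = [
            len(match_individuals(samples, max_mismatch_loci=t, reconcile=False))
            for t in range(5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_low_coverage_samples_excluded(self, caplog):
        g = _geno(3)
        sparse = MultilocusGenotype({l: g[l] for l in sorted(g.loci)[:4]})
        recs = match_individuals([("s1", g), ("s2", sparse)], min_shared_loci=9)
        assert len(recs) == 1
        assert recs[0].sample_ids == ["s1"]

    def test_consensus_is_per_locus_majority(self):
        g = _geno(4)
        g_err = _mutate(g, ["L01"])
        recs = match_individuals([("s1", g), ("s2", g), ("s3", g_err)])
        assert len(recs) == 1
        assert recs[0].genotype["L01"] == g["L01"]


BOTH = BandPattern(True, True)
F130 = BandPattern(False, True)
NONE = BandPattern(False, False)


class TestSexing:
    @pytest.mark.parametrize(
        "patterns, expected",
        [
            ((BOTH, BOTH, F130), "male"),
            ((BOTH, BOTH, BOTH), "male"),
            ((F130, F130, F130), "female"),
            ((F130, F130, NONE), "female"),
            ((BOTH, F130, F130), "unknown"),  # one Y-band sighting: ambiguous
            ((NONE, NONE, NONE), "unknown"),
            ((BOTH, NONE, NONE), "unknown"),
        ],
    )
    def test_band_rule(self, patterns, expected):
        assert determine_sex(SexReplicateSet("S1", patterns)) == expected

    def test_requires_three_replicates(self):
        with pytest.raises(ValueError):
            determine_sex(SexReplicateSet("S1", (BOTH, BOTH)))


def _fragments(mean_length, mean_width, n=40, seed=0):
    rng = np.random.default_rng(seed)
    return FragmentMeasurementSet(
        "S1",
        tuple(
            (float(max(l, 0.1)), float(max(w, 0.1)))
            for l, w in zip(
                rng.normal(mean_length, 0.5, n), rng.normal(mean_width, 0.2, n)
            )
        ),
    )


class TestAgeClassification:
    @pytest.mark.parametrize(
        "length, width, expected",
        [
            (33.2, 8.2, "adult"),
            (18.7, 6.1, "sub-adult"),
            (28.0, 8.0, "adult"),
            (21.0, 7.3, "sub-adult"),
            (40.0, 10.0, "elderly"),  # > 1.3x the adult-centroid length
        ],
    )
    def test_reference_calibration(self, length, width, expected):
        assert classify_age(_fragments(length, width)) == expected

    def test_no_fragments(self):
        assert classify_age(None, unweaned=True) == "cub"
        assert classify_age(None) == "unknown"

    def test_too_few_fragments(self):
        fs = _fragments(30.0, 8.0, n=10)
        assert classify_age(fs) == "unknown"
        assert classify_age(fs, allow_few_fragments=True) == "adult"

    def test_positive_measurement_invariant(self):
        with pytest.raises(ValueError):
            FragmentMeasurementSet("S1", ((10.0, -1.0),))
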