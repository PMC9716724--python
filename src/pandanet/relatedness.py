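"""Pairwise genetic relatedness from multilocus microsatellite genotypes.

Implements the symmetrized Queller & Goodnight (1989) moment estimator of
pairwise relatedness R, population allele-frequency estimation from the
identified individuals, kin-class binning against the canonical pedigree
values (first 0.5, second 0.25, third 0.125; R < 0.125 = unrelated), and
the MM/MF/FF pair-group summaries used to describe sex structure in
relatedness.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Locus
from .genotyping import IndividualRecord, MultilocusGenotype

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleFrequencyTable",
    "RelatednessMatrix",
    "KinClass",
    "KIN_CLASSES",
    "allele_frequencies",
    "qg_relatedness",
    "relatedness_matrix",
    "classify_kin",
    "pair_group_summary",
    "PairGroupSummary",
]

KIN_CLASSES = ("first", "second", "third", "unrelated")

#: Canonical expected relatedness of the three kin classes and the cutoff
#: below which a pair is treated as unrelated.
FIRST_CLASS_R = 0.5
SECOND_CLASS_R = 0.25
THIRD_CLASS_R = 0.125
UNRELATED_CUTOFF = 0.125

# midpoint bin edges between the canonical class values (config-exposed
# through classify_kin arguments)
_FIRST_EDGE = 0.375
_SECOND_EDGE = 0.1875


class AlleleFrequencyTable:
    """Per-locus allele -> frequency maps."""

    def __init__(self, freqs: Mapping[str, Mapping[str, float]]):
        self.freqs = {locus: dict(f) for locus, f in freqs.items()}
        for locus, f in self.freqs.items():
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"locus {locus}: frequencies sum to {total!r}, not 1"
                )

    def __getitem__(self, locus: str) -> dict[str, float]:
        return self.freqs[locus]

    def __contains__(self, locus: str) -> bool:
        return locus in self.freqs

    @property
    def loci(self) -> list[str]:
        return sorted(self.freqs)

    @classmethod
    def from_loci(cls, loci: Sequence[Locus]) -> "AlleleFrequencyTable":
        """The configured (true) frequencies of a simulated locus panel."""
        return cls(
            {l.name: dict(zip(l.alleles, l.frequencies)) for l in loci}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": locus, "allele": a, "frequency": f}
            for locus in self.loci
            for a, f in sorted(self.freqs[locus].items())
        ]
        return pd.DataFrame(rows)


def allele_frequencies(
    individuals: Sequence[IndividualRecord | MultilocusGenotype],
) -> AlleleFrequencyTable:
    """Estimate allele frequencies by direct counting over individuals.

    One genotype per identified individual (never per sample) contributes
    two allele copies at each resolved locus; missing loci contribute
    nothing. Loci resolved in no individual are dropped with a warning.
    """
    genotypes = [
        ind.genotype if isinstance(ind, IndividualRecord) else ind
        for ind in individuals
    ]
    if sum(1 for g in genotypes if g.n_resolved > 0) < 2:
        raise ValueError("need >= 2 individuals with resolved genotypes")
    loci = sorted({l for g in genotypes for l in g.loci})
    freqs: dict[str, dict[str, float]] = {}
    for locus in loci:
        counts: dict[str, int] = {}
        for g in genotypes:
            if locus in g:
                a, b = g[locus]
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        if total == 0:
            logger.warning("locus %s resolved in zero individuals; dropped", locus)
            continue
        freqs[locus] = {a: n / total for a, n in counts.items()}
    return AlleleFrequencyTable(freqs)


# ---------------------------------------------------------------------------
# Queller & Goodnight estimator
# ---------------------------------------------------------------------------


def _qg_directional(
    x: MultilocusGenotype,
    y: MultilocusGenotype,
    freqs: AlleleFrequencyTable,
    shared: Iterable[str],
) -> tuple[float, float]:
    """Pooled numerator and denominator with x as the focal individual."""
    num = den = 0.0
    for locus in shared:
        a, b = x[locus]
        c, d = y[locus]
        p = freqs[locus]
        pa = p.get(a, 0.0)
        pb = p.get(b, 0.0)
        ident = (
            0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
        )
        num += ident - pa - pb
        den += 1.0 + (a == b) - pa - pb
    return num, den


def qg_relatedness(
    x: MultilocusGenotype,
    y: MultilocusGenotype,
    freqs: AlleleFrequencyTable,
) -> float:
    """Symmetrized Queller & Goodnight pairwise relatedness.

    Per locus, with focal alleles (a, b) and partner alleles (c, d):
    numerator 0.5*(I_ac + I_ad + I_bc + I_bd) - p_a - p_b and denominator
    1 + I_ab - p_a - p_b, where I is the allele-identity indicator and p
    the population frequency. Numerators and denominators are pooled over
    jointly resolved loci, the ratio is formed in each direction, and the
    two directional estimates are averaged. Returns NaN (masked) when the
    pair shares no resolved locus present in the frequency table or when a
    pooled denominator is zero.
    """
    shared = sorted(l for l in x.shared_loci(y) if l in freqs)
    if not shared:
        logger.warning("pair shares no resolved loci; relatedness masked")
        return float("nan")
    num_x, den_x = _qg_directional(x, y, freqs, shared)
    num_y, den_y = _qg_directional(y, x, freqs, shared)
    if den_x == 0.0 or den_y == 0.0:
        logger.warning("zero pooled denominator; relatedness masked")
        return float("nan")
    return 0.5 * (num_x / den_x + num_y / den_y)


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise R over identified individuals; diagonal masked.

    ``values[i, j]`` is NaN for the diagonal and for masked pairs (no
    shared loci / degenerate denominator).
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        finite = ~np.isnan(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T]
        ):
            raise ValueError("relatedness matrix must be symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        """All unordered pairs with their R (NaN for masked pairs)."""
        for i, j in itertools.combinations(range(len(self.ids)), 2):
            yield self.ids[i], self.ids[j], float(self.values[i, j])

    def n_defined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.sum(~np.isnan(self.values[iu])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def relatedness_matrix(
    individuals: Sequence[IndividualRecord],
    freqs: AlleleFrequencyTable,
) -> RelatednessMatrix:
    """Queller-Goodnight R for every unordered pair of individuals.

    Vectorized per locus over all pairs (allele-identity indicator
    matrices), which matters when this runs inside replicate simulations;
    tests cross-check it against the scalar :func:`qg_relatedness`.
    """
    ids = [ind.individual_id for ind in individuals]
    n = len(ids)
    loci = [l for l in freqs.loci]
    # integer-encode genotypes: -1 = missing
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    any_locus = np.zeros((n, n), dtype=bool)
    for locus in loci:
        alleles = sorted(freqs[locus])
        index = {a: k for k, a in enumerate(alleles)}
        p = np.array([freqs[locus][a] for a in alleles])
        a1 = np.full(n, -1)
        a2 = np.full(n, -1)
        for i, ind in enumerate(individuals):
            if locus in ind.genotype:
                x, y = ind.genotype[locus]
                if x in index and y in index:
                    a1[i], a2[i] = index[x], index[y]
        present = a1 >= 0
        if not present.any():
            continue
        ident = 0.5 * (
            (a1[:, None] == a1[None, :]).astype(float)
            + (a1[:, None] == a2[None, :]).astype(float)
            + (a2[:, None] == a1[None, :]).astype(float)
            + (a2[:, None] == a2[None, :]).astype(float)
        )
        psum = np.where(present, p[np.clip(a1, 0, None)] + p[np.clip(a2, 0, None)], 0.0)
        hom = (a1 == a2).astype(float)
        pair_ok = present[:, None] & present[None, :]
        num += np.where(pair_ok, ident - psum[:, None], 0.0)
        den += np.where(pair_ok, 1.0 + hom[:, None] - psum[:, None], 0.0)
        any_locus |= pair_ok

    with np.errstate(divide="ignore", invalid="ignore"):
        r_dir = num / den
    r = 0.5 * (r_dir + r_dir.T)
    r[~(any_locus & (den != 0.0) & (den.T != 0.0))] = np.nan
    np.fill_diagonal(r, np.nan)
    n_masked = (
        np.sum(np.isnan(r[np.triu_indices(n, k=1)])) if n > 1 else 0
    )
    if n_masked:
        logger.info("relatedness matrix: %d masked pairs", int(n_masked))
    return RelatednessMatrix(ids, r)


# ---------------------------------------------------------------------------
# kin classes
# ---------------------------------------------------------------------------

KinClass = str


def classify_kin(
    r: float,
    unrelated_cutoff: float = UNRELATED_CUTOFF,
    second_edge: float = _SECOND_EDGE,
    first_edge: float = _FIRST_EDGE,
) -> KinClass:
    """Bin an R value into first/second/third-class relative or unrelated.

    R below the 0.125 cutoff means no relatedness; above it, midpoint bins
    between the canonical class values assign third (< 0.1875), second
    (< 0.375) and first (>= 0.375) class.
    """
    if not np.isfinite(r):
        raise ValueError("cannot classify a masked (non-finite) R value")
    if r < unrelated_cutoff:
        return "unrelated"
    if r < second_edge:
        return "third"
    if r < first_edge:
        return "second"
    return "first"


# ---------------------------------------------------------------------------
# MM / MF / FF summaries
# ---------------------------------------------------------------------------


@dataclass
class PairGroupSummary:
    """Relatedness structure of one sex-pair group (MM, MF or FF)."""

    group: str
    n_pairs: int
    n_defined: int
    values: np.ndarray
    mean_r: float
    prop_related: float
    class_counts: dict[str, int]
    class_props: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_pairs": self.n_pairs,
            "n_defined": self.n_defined,
            "mean_r": self.mean_r,
            "prop_related": self.prop_related,
            "class_counts": self.class_counts,
            "class_props": self.class_props,
        }


def pair_group_summary(
    matrix: RelatednessMatrix,
    individuals: Sequence[IndividualRecord],
    unrelated_cutoff: float = UNRELATED_CUTOFF,
) -> dict[str, PairGroupSummary]:
    """Partition all pairs into MM / MF / FF and summarize relatedness.

    Individuals of unknown sex are excluded (and logged). Each group
    reports its pair count, defined-R count, mean R, the proportion of
    relatives (R >= cutoff), and per-kin-class counts and proportions —
    proportions use the defined-pair denominator, and raw counts are also
    reported so alternative bookkeepings can be compared.
    """
    sex = {ind.individual_id: ind.sex for ind in individuals}
    excluded = [i for i in matrix.ids if sex.get(i) not in ("male", "female")]
    if excluded:
        logger.warning("excluding %d unknown-sex individuals: %s", len(excluded), excluded)

    groups: dict[str, list[float]] = {"MM": [], "MF": [], "FF": []}
    totals: dict[str, int] = {"MM": 0, "MF": 0, "FF": 0}
    for a, b, r in matrix.pairs():
        if a in excluded or b in excluded:
            continue
        key = "".join(sorted(sex[a][0].upper() + sex[b][0].upper()))
        key = {"MM": "MM", "FM": "MF", "FF": "FF"}[key]
        totals[key] += 1
        if np.isfinite(r):
            groups[key].append(r)

    out: dict[str, PairGroupSummary] = {}
    for key in ("MM", "MF", "FF"):
        vals = np.array(groups[key])
        if vals.size == 0:
            out[key] = PairGroupSummary(
                key, totals[key], 0, vals, float("nan"), float("nan"), {}, {}
            )
            continue
        classes = [classify_kin(r, unrelated_cutoff=unrelated_cutoff) for r in vals]
        counts = {c: classes.count(c) for c in KIN_CLASSES}
        props = {c: counts[c] / vals.size for c in KIN_CLASSES}
        out[key] = PairGroupSummary(
            group=key,
            n_pairs=totals[key],
            n_defined=int(vals.size),
            values=vals,
            mean_r=float(vals.mean()),
            prop_related=float(np.mean(vals >= unrelated_cutoff)),
            class_counts=counts,
            class_props=props,
        )
    return out
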