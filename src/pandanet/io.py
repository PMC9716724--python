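"""File formats: plain CSV tables for every stage, plus GenePop genotypes.

All tabular interchange goes through pandas CSVs with fixed column names.
Consensus genotypes are additionally written in GenePop format (title
line, locus list, "Pop", ``id ,  diploid codes``) for interoperability
with population-genetics tooling; reading GenePop delegates to
Bio.PopGen.GenePop. Because GenePop codes cap at 2-3 digits, a lossless
long-format CSV dialect (individual, locus, allele1, allele2) is the
primary on-disk representation.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.PopGen import GenePop as _genepop

from .genotyping import (
    BandPattern,
    FragmentMeasurementSet,
    IndividualRecord,
    MultilocusGenotype,
    ReplicateCallSet,
    SexReplicateSet,
)
from .relatedness import RelatednessMatrix
from .simdata import Pedigree, SurveyDetection, TrueGenotypeTable

__all__ = [
    "write_detections", "read_detections",
    "write_replicate_calls", "read_replicate_calls",
    "write_fragments", "read_fragments",
    "write_sexing", "read_sexing",
    "write_pedigree",
    "write_individuals", "read_individuals",
    "write_genotypes_csv", "read_genotypes_csv",
    "write_genepop", "read_genepop",
    "write_relatedness", "read_relatedness",
    "write_pair_table",
]

MISSING = ""


# -- detections -------------------------------------------------------------

def write_detections(detections: Sequence[SurveyDetection], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"survey_id": d.survey_id, "individual_id": d.individual_id,
             "sample_id": d.sample_id}
            for d in detections
        ]
    ).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[SurveyDetection]:
    df = pd.read_csv(path, dtype=str)
    return [
        SurveyDetection(r.survey_id, r.individual_id, r.sample_id)
        for r in df.itertuples()
    ]


# -- replicate genotype calls ------------------------------------------------

def write_replicate_calls(callsets: Sequence[ReplicateCallSet], path: str | Path) -> None:
    rows = []
    for cs in callsets:
        for rep_idx, rep in enumerate(cs.replicates, start=1):
            for locus, (a, b) in sorted(rep.items()):
                rows.append(
                    {"sample_id": cs.sample_id, "replicate": rep_idx,
                     "locus": locus, "allele1": a, "allele2": b}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_replicate_calls(path: str | Path) -> list[ReplicateCallSet]:
    df = pd.read_csv(path, dtype={"sample_id": str, "locus": str,
                                  "allele1": str, "allele2": str})
    out: dict[str, dict[int, dict[str, tuple[str, str]]]] = {}
    for r in df.itertuples():
        out.setdefault(r.sample_id, {}).setdefault(int(r.replicate), {})[r.locus] = (
            r.allele1, r.allele2,
        )
    return [
        ReplicateCallSet(sid, [reps[k] for k in sorted(reps)])
        for sid, reps in out.items()
    ]


# -- fragments ---------------------------------------------------------------

def write_fragments(fragmentsets: Sequence[FragmentMeasurementSet], path: str | Path) -> None:
    rows = [
        {"sample_id": fs.sample_id, "fragment_index": i,
         "length_mm": length, "width_mm": width}
        for fs in fragmentsets
        for i, (length, width) in enumerate(fs.measurements)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fragments(path: str | Path) -> list[FragmentMeasurementSet]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return [
        FragmentMeasurementSet(
            sid, tuple(zip(g["length_mm"].tolist(), g["width_mm"].tolist()))
        )
        for sid, g in df.groupby("sample_id", sort=True)
    ]


# -- sexing ------------------------------------------------------------------

def write_sexing(sexsets: Sequence[SexReplicateSet], path: str | Path) -> None:
    rows = [
        {"sample_id": ss.sample_id, "replicate": i,
         "band_210bp": int(p.band_210), "band_130bp": int(p.band_130)}
        for ss in sexsets
        for i, p in enumerate(ss.patterns, start=1)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sexing(path: str | Path) -> list[SexReplicateSet]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    out: dict[str, dict[int, BandPattern]] = {}
    for r in df.itertuples():
        out.setdefault(r.sample_id, {})[int(r.replicate)] = BandPattern(
            bool(r.band_210bp), bool(r.band_130bp)
        )
    return [
        SexReplicateSet(sid, tuple(pats[k] for k in sorted(pats)))
        for sid, pats in out.items()
    ]


# -- pedigree / individuals --------------------------------------------------

def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pd.DataFrame(pedigree.to_records()).to_csv(path, index=False)


def write_individuals(individuals: Sequence[IndividualRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": ind.individual_id,
                "sex": ind.sex,
                "age_class": ind.age_class,
                "n_samples": len(ind.sample_ids),
                "sample_ids": ";".join(ind.sample_ids),
                "n_loci": ind.genotype.n_resolved,
            }
            for ind in individuals
        ]
    ).to_csv(path, index=False)


def read_individuals(path: str | Path, genotypes: dict[str, MultilocusGenotype] | None = None) -> list[IndividualRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for r in df.itertuples():
        g = (genotypes or {}).get(r.individual_id, MultilocusGenotype({}))
        records.append(
            IndividualRecord(
                individual_id=r.individual_id,
                genotype=g,
                sex=r.sex,
                age_class=r.age_class,
                sample_ids=[s for s in r.sample_ids.split(";") if s],
            )
        )
    return records


# -- genotype tables ---------------------------------------------------------

def write_genotypes_csv(
    genotypes: dict[str, MultilocusGenotype] | TrueGenotypeTable, path: str | Path
) -> None:
    """Lossless long-format genotype CSV (works for any allele labels)."""
    items = genotypes.items()
    rows = [
        {"individual_id": ind, "locus": locus, "allele1": a, "allele2": b}
        for ind, g in sorted(items)
        for locus, (a, b) in sorted(g.calls.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotypes_csv(path: str | Path) -> dict[str, MultilocusGenotype]:
    df = pd.read_csv(path, dtype=str)
    calls: dict[str, dict[str, tuple[str, str]]] = {}
    for r in df.itertuples():
        calls.setdefault(r.individual_id, {})[r.locus] = (r.allele1, r.allele2)
    return {ind: MultilocusGenotype(c) for ind, c in calls.items()}


def write_genepop(
    genotypes: dict[str, MultilocusGenotype] | TrueGenotypeTable,
    path: str | Path,
    title: str = "pandanet consensus genotypes",
) -> None:
    """GenePop export: per-locus allele labels are mapped (by sorted label
    order) to 2-digit codes, 3-digit when a locus has more than 99 alleles;
    missing loci are all-zero codes."""
    items = sorted(genotypes.items())
    loci = sorted({l for _, g in items for l in g.loci})
    codes: dict[str, dict[str, str]] = {}
    width: dict[str, int] = {}
    for locus in loci:
        alleles = sorted({a for _, g in items if locus in g for a in g[locus]})
        numeric = all(a.isdigit() and 0 < int(a) <= 999 for a in alleles)
        if numeric:
            # keep numeric labels as their own codes so the file round-trips
            w = 2 if max(int(a) for a in alleles) <= 99 else 3
            codes[locus] = {a: f"{int(a):0{w}d}" for a in alleles}
        else:
            w = 2 if len(alleles) <= 99 else 3
            codes[locus] = {a: f"{i + 1:0{w}d}" for i, a in enumerate(alleles)}
        width[locus] = w

    lines = [title]
    lines.extend(loci)
    lines.append("Pop")
    for ind, g in items:
        parts = []
        for locus in loci:
            if locus in g:
                a, b = g[locus]
                parts.append(codes[locus][a] + codes[locus][b])
            else:
                parts.append("0" * (2 * width[locus]))
        lines.append(f"{ind} ,  " + " ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> dict[str, MultilocusGenotype]:
    """Read a GenePop file (via Bio.PopGen.GenePop); codes become labels.

    Allele codes are kept as zero-padded strings, so a file written by
    :func:`write_genepop` from label-sorted codes round-trips exactly.
    """
    with open(path) as fh:
        record = _genepop.read(fh)
    out: dict[str, MultilocusGenotype] = {}
    for pop in record.populations:
        for name, markers in pop:
            calls = {}
            for locus, alleles in zip(record.loci_list, markers):
                if alleles is None or any(a in (None, 0) for a in alleles):
                    continue
                w = 2 if max(alleles) <= 99 else 3
                a, b = (f"{x:0{w}d}" for x in alleles)
                calls[locus] = (min(a, b), max(a, b))
            out[name.strip()] = MultilocusGenotype(calls)
    return out


# -- relatedness -------------------------------------------------------------

def write_relatedness(matrix: RelatednessMatrix, path: str | Path) -> None:
    """Square CSV; masked cells (and the diagonal) are empty."""
    matrix.to_frame().to_csv(path, na_rep=MISSING)


def read_relatedness(path: str | Path) -> RelatednessMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelatednessMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_pair_table(
    matrix: RelatednessMatrix,
    individuals: Sequence[IndividualRecord],
    path: str | Path,
    low_confidence_loci: int = 6,
) -> None:
    """Long-format pair table: id1, id2, n shared loci, R, kin class, sex pair.

    Pairs sharing fewer than ``low_confidence_loci`` resolved loci are
    flagged, as are estimates outside the theoretical [-1, 1] range.
    """
    from .relatedness import classify_kin  # local import avoids cycle at startup

    by_id = {ind.individual_id: ind for ind in individuals}
    rows = []
    for a, b, r in matrix.pairs():
        ga, gb = by_id[a].genotype, by_id[b].genotype
        shared = len(ga.shared_loci(gb))
        sexes = "".join(
            sorted(by_id[a].sex[:1].upper() + by_id[b].sex[:1].upper())
        )
        sex_pair = {"MM": "MM", "FM": "MF", "FF": "FF"}.get(sexes, "??")
        defined = np.isfinite(r)
        rows.append(
            {
                "id1": a,
                "id2": b,
                "n_loci": shared,
                "r": r if defined else np.nan,
                "kin_class": classify_kin(r) if defined else "",
                "sex_pair": sex_pair,
                "low_confidence": shared < low_confidence_loci,
                "out_of_range": bool(defined and (r < -1 or r > 1)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, na_rep=MISSING)
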