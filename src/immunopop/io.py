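"""Readers and writers for the package's plain-text formats.

All tabular formats are tab-separated UTF-8.  Missing genotype alleles are
encoded as ``.`` and missing matrix entries as ``NA`` so that every format
round-trips exactly through its matching reader/writer pair.

Also houses the clone-to-genotype validation filter: an allele sequence is
accepted only when it was isolated from at least two independent PCR
reactions (from the same individual or from different individuals), and an
individual showing more than ``max_alleles`` accepted alleles is rejected as
possible contamination or gene duplication.
"""

from __future__ import annotations

import math
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO

from .model import (
    AlleleCatalog,
    CloneObservation,
    CloneTable,
    DistanceMatrixLabeled,
    GenotypeRecord,
    PopulationGenotypes,
    SelectionRow,
    SiteSelectionTable,
)

PathLike = Union[str, Path]

GENOTYPE_COLUMNS = ["sample", "population", "locus", "allele_a", "allele_b"]
CLONE_COLUMNS = ["sample", "pcr_replicate", "clone_sequence_id"]
SELECTION_COLUMNS = [
    "site",
    "model",
    "statistic_name",
    "statistic_value",
    "evidence_kind",
    "evidence_value",
]


def read_allele_fasta(
    path: PathLike, locus_name: str = "DAB", codon_mode: bool = False
) -> AlleleCatalog:
    """Read an aligned allele FASTA into an :class:`AlleleCatalog`."""
    alleles: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in alleles:
            raise ValueError(f"duplicate allele id {record.id!r}")
        alleles[record.id] = str(record.seq).upper()
    if not alleles:
        raise ValueError(f"no sequences found in {path}")
    return AlleleCatalog(locus_name=locus_name, alleles=alleles, codon_mode=codon_mode)


def write_allele_fasta(catalog: AlleleCatalog, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for allele_id, seq in catalog.alleles.items():
            fh.write(f">{allele_id}\n{seq}\n")


def read_genotype_table(
    path: PathLike, catalog: Optional[AlleleCatalog] = None
) -> PopulationGenotypes:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"genotype table missing columns {sorted(missing_cols)}")
    records = [
        GenotypeRecord(
            sample_id=row["sample"],
            population=row["population"],
            locus=row["locus"],
            allele_a=None if row["allele_a"] == "." else row["allele_a"],
            allele_b=None if row["allele_b"] == "." else row["allele_b"],
        )
        for row in df.to_dict("records")
    ]
    genotypes = PopulationGenotypes(records)
    if catalog is not None:
        genotypes.validate_against(catalog)
    return genotypes


def write_genotype_table(genotypes: PopulationGenotypes, path: PathLike) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "population": r.population,
            "locus": r.locus,
            "allele_a": "." if r.allele_a is None else r.allele_a,
            "allele_b": "." if r.allele_b is None else r.allele_b,
        }
        for r in genotypes.records
    ]
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clone_table(path: PathLike) -> CloneTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(CLONE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"clone table missing columns {sorted(missing_cols)}")
    observations = [
        CloneObservation(
            sample_id=row["sample"],
            pcr_replicate=int(row["pcr_replicate"]),
            clone_sequence_id=row["clone_sequence_id"],
        )
        for row in df.to_dict("records")
    ]
    return CloneTable(observations)


def write_clone_table(clones: CloneTable, path: PathLike) -> None:
    rows = [
        {
            "sample": o.sample_id,
            "pcr_replicate": o.pcr_replicate,
            "clone_sequence_id": o.clone_sequence_id,
        }
        for o in clones.observations
    ]
    pd.DataFrame(rows, columns=CLONE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_selection_table(path: PathLike) -> SiteSelectionTable:
    df = pd.read_csv(path, sep="\t")
    missing_cols = set(SELECTION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"selection table missing columns {sorted(missing_cols)}")
    rows = [
        SelectionRow(
            site=int(row["site"]),
            model=str(row["model"]),
            statistic_name=str(row["statistic_name"]),
            statistic_value=float(row["statistic_value"]),
            evidence_kind=str(row["evidence_kind"]),
            evidence_value=float(row["evidence_value"]),
        )
        for row in df.to_dict("records")
    ]
    return SiteSelectionTable(rows)


def write_selection_table(table: SiteSelectionTable, path: PathLike) -> None:
    rows = [
        {
            "site": r.site,
            "model": r.model,
            "statistic_name": r.statistic_name,
            "statistic_value": r.statistic_value,
            "evidence_kind": r.evidence_kind,
            "evidence_value": r.evidence_value,
        }
        for r in table.rows
    ]
    pd.DataFrame(rows, columns=SELECTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matrix(path: PathLike) -> DistanceMatrixLabeled:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError("matrix row labels must equal column labels")
    return DistanceMatrixLabeled(labels, df.to_numpy(dtype=float))


def write_matrix(matrix: DistanceMatrixLabeled, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            cells = ["NA" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(label + "\t" + "\t".join(cells) + "\n")


def validate_clone_genotypes(
    clones: CloneTable,
    max_alleles: int = 2,
    populations: Optional[Mapping[str, str]] = None,
    locus: str = "DAB",
) -> tuple[PopulationGenotypes, list[str], set[str]]:
    """Derive verified genotypes from clone observations.

    An allele is accepted iff it appears in >= 2 distinct (sample, replicate)
    PCR reactions.  A sample is genotyped homozygous from one accepted allele,
    heterozygous from two; samples showing more than ``max_alleles`` accepted
    alleles are rejected and listed; samples with no accepted allele are
    untyped and silently excluded.

    Returns ``(genotypes, rejected_samples, accepted_alleles)``.
    """
    reactions_per_allele: dict[str, set[tuple[str, int]]] = defaultdict(set)
    alleles_per_sample: dict[str, set[str]] = defaultdict(set)
    for obs in clones.observations:
        reactions_per_allele[obs.clone_sequence_id].add(
            (obs.sample_id, obs.pcr_replicate)
        )
        alleles_per_sample[obs.sample_id].add(obs.clone_sequence_id)

    accepted = {
        allele
        for allele, reactions in reactions_per_allele.items()
        if len(reactions) >= 2
    }

    records: list[GenotypeRecord] = []
    rejected: list[str] = []
    for sample_id in sorted(alleles_per_sample):
        sample_alleles = sorted(alleles_per_sample[sample_id] & accepted)
        if not sample_alleles:
            continue  # untyped
        if len(sample_alleles) > max_alleles:
            rejected.append(sample_id)
            continue
        if len(sample_alleles) == 1:
            pair = (sample_alleles[0], sample_alleles[0])
        else:
            pair = (sample_alleles[0], sample_alleles[1])
        population = populations.get(sample_id, "unknown") if populations else "unknown"
        records.append(
            GenotypeRecord(
                sample_id=sample_id,
                population=population,
                locus=locus,
                allele_a=pair[0],
                allele_b=pair[1],
            )
        )
    return PopulationGenotypes(records), rejected, accepted
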