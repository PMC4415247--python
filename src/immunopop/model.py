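"""Core domain types shared across the package.

The analysis revolves around a single hyperpolymorphic locus (an MHC class II
beta exon-2 fragment, "DAB") genotyped in several populations, alongside a
panel of neutral microsatellite loci.  Types here hold aligned allele
sequences, diploid genotype calls, clone observations from PCR/cloning
verification, per-site selection-model statistics, and labeled distance
matrices, with their structural invariants enforced at construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

NUCLEOTIDES = set("ACGTN-")

__all__ = [
    "AlleleCatalog",
    "GenotypeRecord",
    "PopulationGenotypes",
    "CloneObservation",
    "CloneTable",
    "SelectionRow",
    "SiteSelectionTable",
    "DistanceMatrixLabeled",
]


@dataclass(frozen=True)
class AlleleCatalog:
    """Named, aligned nucleotide allele sequences for one locus.

    Sequences use the alphabet {A,C,G,T,N,-}; ``N`` is treated as missing by
    site statistics and ``-`` as an alignment gap.  In ``codon_mode`` the
    alignment length must be a multiple of three and every gap run must span
    whole codons, so each sequence translates to an amino-acid string with a
    gap residue where a codon is deleted.
    """

    locus_name: str
    alleles: dict[str, str]
    codon_mode: bool = False

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("catalog must contain at least one allele")
        lengths = {len(s) for s in self.alleles.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"unequal sequence lengths {sorted(lengths)}; input must be aligned"
            )
        for allele_id, seq in self.alleles.items():
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise ValueError(f"allele {allele_id!r}: invalid symbols {sorted(bad)}")
        if self.codon_mode:
            (length,) = lengths
            if length % 3 != 0:
                raise ValueError(
                    f"codon mode requires length divisible by 3, got {length}"
                )
            for allele_id, seq in self.alleles.items():
                for codon_start in range(0, length, 3):
                    codon = seq[codon_start : codon_start + 3]
                    if "-" in codon and codon != "---":
                        raise ValueError(
                            f"allele {allele_id!r}: gap not aligned to codon "
                            f"boundaries at position {codon_start + 1}"
                        )

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.alleles.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)

    def sequence(self, allele_id: str) -> str:
        return self.alleles[allele_id]

    def codons(self, allele_id: str) -> list[str]:
        if not self.codon_mode:
            raise ValueError("codons() requires a codon-mode catalog")
        seq = self.alleles[allele_id]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def translate(self) -> dict[str, str]:
        """Translate each allele; '---' codons become '-' residues."""
        from Bio.Seq import Seq

        if not self.codon_mode:
            raise ValueError("translation requires a codon-mode catalog")
        out: dict[str, str] = {}
        for allele_id, seq in self.alleles.items():
            residues = []
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if codon == "---":
                    residues.append("-")
                elif "N" in codon:
                    residues.append("X")
                else:
                    residues.append(str(Seq(codon).translate()))
            out[allele_id] = "".join(residues)
        return out


@dataclass(frozen=True)
class GenotypeRecord:
    sample_id: str
    population: str
    locus: str
    allele_a: Optional[str]  # None encodes a missing call (".")
    allele_b: Optional[str]

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None or self.allele_b is None

    @property
    def is_heterozygous(self) -> bool:
        if self.is_missing:
            raise ValueError("heterozygosity undefined for missing genotype")
        return self.allele_a != self.allele_b


class PopulationGenotypes:
    """Per-sample diploid allele calls grouped by population and locus."""

    def __init__(
        self,
        records: Iterable[GenotypeRecord],
        populations: Optional[Sequence[str]] = None,
    ) -> None:
        self.records: list[GenotypeRecord] = list(records)
        seen = set()
        for rec in self.records:
            key = (rec.sample_id, rec.locus)
            if key in seen:
                raise ValueError(f"duplicate genotype for sample/locus {key}")
            seen.add(key)
        if populations is None:
            populations = list(dict.fromkeys(r.population for r in self.records))
        self.populations: list[str] = list(populations)

    def __len__(self) -> int:
        return len(self.records)

    def loci(self) -> list[str]:
        return list(dict.fromkeys(r.locus for r in self.records))

    def subset(self, population: str, locus: str) -> list[GenotypeRecord]:
        return [
            r
            for r in self.records
            if r.population == population and r.locus == locus
        ]

    def typed(self, population: str, locus: str) -> list[GenotypeRecord]:
        return [r for r in self.subset(population, locus) if not r.is_missing]

    def sample_size(self, population: str, locus: str) -> int:
        """Diploid N: number of genotype records for the population/locus."""
        return len(self.subset(population, locus))

    def allele_counts(self, population: str, locus: str) -> Counter:
        """Gene-copy counts, excluding missing genotypes."""
        counts: Counter = Counter()
        for rec in self.typed(population, locus):
            counts[rec.allele_a] += 1
            counts[rec.allele_b] += 1
        return counts

    def genotype_pairs(self, population: str, locus: str) -> list[tuple[str, str]]:
        return [
            tuple(sorted((r.allele_a, r.allele_b)))
            for r in self.typed(population, locus)
        ]

    def validate_against(self, catalog: AlleleCatalog) -> None:
        known = set(catalog.alleles)
        for rec in self.records:
            if rec.locus != catalog.locus_name:
                continue
            for allele in (rec.allele_a, rec.allele_b):
                if allele is not None and allele not in known:
                    raise ValueError(
                        f"unknown allele {allele!r} for sample {rec.sample_id!r}"
                    )


@dataclass(frozen=True)
class CloneObservation:
    sample_id: str
    pcr_replicate: int
    clone_sequence_id: str

    def __post_init__(self) -> None:
        if self.pcr_replicate < 1:
            raise ValueError("pcr_replicate must be >= 1")


@dataclass
class CloneTable:
    """Clone sequencing observations used to verify allele calls."""

    observations: list[CloneObservation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class SelectionRow:
    site: int
    model: str  # SLAC | REL | MEME
    statistic_name: str
    statistic_value: float
    evidence_kind: str  # p_value | bayes_factor
    evidence_value: float

    def __post_init__(self) -> None:
        if self.model not in {"SLAC", "REL", "MEME"}:
            raise ValueError(f"unknown model {self.model!r}")
        if self.evidence_kind not in {"p_value", "bayes_factor"}:
            raise ValueError(f"unknown evidence kind {self.evidence_kind!r}")
        if self.site < 1:
            raise ValueError("site positions are 1-based")
        if self.evidence_kind == "p_value" and not 0.0 <= self.evidence_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.evidence_kind == "bayes_factor" and self.evidence_value < 0:
            raise ValueError("Bayes factor must be non-negative")


@dataclass
class SiteSelectionTable:
    """Per-residue statistics from one or more codon selection models."""

    rows: list[SelectionRow] = field(default_factory=list)

    def models(self) -> set[str]:
        return {r.model for r in self.rows}

    def for_model(self, model: str) -> list[SelectionRow]:
        return [r for r in self.rows if r.model == model]


class DistanceMatrixLabeled:
    """Square symmetric matrix with population labels; NaN encodes missing."""

    def __init__(self, labels: Sequence[str], values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count must match matrix dimension")
        finite = np.isfinite(values)
        if not np.allclose(
            np.where(finite & finite.T, values, 0.0),
            np.where(finite & finite.T, values.T, 0.0),
            rtol=0,
            atol=0,
        ):
            raise ValueError("matrix must be symmetric")
        if not np.all(np.diag(values) == 0.0):
            raise ValueError("diagonal must be zero")
        self.labels = list(labels)
        self.values = values

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrixLabeled):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.values, other.values, equal_nan=True
        )

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def upper_triangle(self) -> np.ndarray:
        idx = np.triu_indices(len(self.labels), k=1)
        return self.values[idx]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrixLabeled":
        perm = [self.labels.index(l) for l in labels]
        return DistanceMatrixLabeled(list(labels), self.values[np.ix_(perm, perm)])
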