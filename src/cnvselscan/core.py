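"""Core domain types shared by every pipeline stage.

The pipeline operates on biallelic structural variants (in the study system,
deletion CNVs) genotyped across a two-group cohort of diploid individuals:
a high-litter-size (HL) and a low-litter-size (LL) group. Genotypes are
stored as small integer codes so that whole-cohort operations vectorise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np

SVTYPES = ("DEL", "INS", "INV", "DUP")

GROUP_HL = "HL"
GROUP_LL = "LL"


class Genotype(IntEnum):
    """Diploid biallelic genotype codes (alt-allele dosage; -1 = missing)."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass
class SVRecord:
    """One biallelic structural variant with per-sample genotypes.

    Coordinates are 1-based inclusive (VCF native): ``pos`` is the VCF POS,
    ``end`` the INFO/END. ``svlen`` is signed (negative for deletions).
    ``genotypes`` is an int8 array in panel sample order using
    :class:`Genotype` codes.
    """

    id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svtype in ("DEL", "INV", "DUP") and self.pos > self.end:
            raise ValueError(f"{self.id}: pos {self.pos} > end {self.end}")

    @property
    def span(self) -> int:
        """Reference footprint in bp (1-based inclusive interval length)."""
        return self.end - self.pos + 1

    def genotype_counts(self) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) over non-missing samples."""
        g = self.genotypes
        return (
            int(np.sum(g == Genotype.HOM_REF)),
            int(np.sum(g == Genotype.HET)),
            int(np.sum(g == Genotype.HOM_ALT)),
        )

    def copy(self) -> "SVRecord":
        return SVRecord(
            self.id, self.chrom, self.pos, self.end, self.svtype, self.svlen,
            self.genotypes.copy(),
        )


@dataclass
class SamplePanel:
    """Ordered sample ids and their HL/LL group assignment.

    Groups must be disjoint (a mapping enforces this), cover every sample,
    and each be non-empty.
    """

    samples: list[str]
    group: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in panel")
        missing = [s for s in self.samples if s not in self.group]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        bad = {g for g in self.group.values() if g not in (GROUP_HL, GROUP_LL)}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for label in (GROUP_HL, GROUP_LL):
            if not any(self.group[s] == label for s in self.samples):
                raise ValueError(f"group {label} is empty")

    @property
    def n(self) -> int:
        return len(self.samples)

    def indices(self, label: str) -> np.ndarray:
        """Integer indices (panel order) of the samples in ``label``."""
        return np.array(
            [i for i, s in enumerate(self.samples) if self.group[s] == label],
            dtype=int,
        )

    @property
    def hl_indices(self) -> np.ndarray:
        return self.indices(GROUP_HL)

    @property
    def ll_indices(self) -> np.ndarray:
        return self.indices(GROUP_LL)


@dataclass(frozen=True)
class GeneFeature:
    """One annotation interval, 1-based inclusive.

    ``feature_kind`` follows the flattened vocabulary used throughout:
    gene, exon, CDS, five_prime_UTR, three_prime_UTR, ncRNA_gene, ncRNA_exon.
    Sub-features carry the gene_id of their parent gene.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    feature_kind: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


def genotype_matrix(records: Sequence[SVRecord]) -> np.ndarray:
    """Stack record genotypes into an (n_variants, n_samples) int8 matrix."""
    if not records:
        return np.zeros((0, 0), dtype=np.int8)
    return np.vstack([r.genotypes for r in records])
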