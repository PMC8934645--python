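"""Core genomic data model.

Coordinates are 1-based, fully closed intervals throughout (GenBank/GFF3
convention); conversions happen only at parse/write boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised when a record or annotation violates its invariants."""


@dataclass(frozen=True)
class GeneRecord:
    """A single protein-coding gene on a replicon.

    Parameters
    ----------
    replicon_id, gene_id : str
        Replicon and unique gene identifiers.
    start, end : int
        1-based inclusive nucleotide coordinates, ``end >= start``.
    strand : {"+", "-"}
    protein_length : int
        Length of the encoded protein in amino acids (>= 1).
    product : str
        Free-text product description.
    protein_seq : str, optional
        Amino-acid sequence; when present its length must equal
        ``protein_length``.
    """

    replicon_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    protein_length: int
    product: str = ""
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise AnnotationError(
                f"{self.gene_id}: end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.protein_length < 1:
            raise AnnotationError(f"{self.gene_id}: protein_length < 1")
        if self.protein_seq is not None and len(self.protein_seq) != self.protein_length:
            raise AnnotationError(
                f"{self.gene_id}: protein_seq length {len(self.protein_seq)} "
                f"!= protein_length {self.protein_length}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenomeAnnotation:
    """Ordered, stranded gene models of one replicon.

    ``genes`` are kept sorted by start coordinate; gene ids must be unique.
    """

    replicon_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    source_label: str = ""
    length_bp: Optional[int] = None

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(
                f"{self.replicon_id}: duplicated gene ids {dupes}")
        for g in self.genes:
            if g.replicon_id != self.replicon_id:
                raise AnnotationError(
                    f"gene {g.gene_id} replicon {g.replicon_id!r} != "
                    f"{self.replicon_id!r}")
        if self.length_bp is None and self.genes:
            self.length_bp = self.genes[-1].end + 100

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def index_of(self, gene_id: str) -> int:
        for i, g in enumerate(self.genes):
            if g.gene_id == gene_id:
                return i
        raise KeyError(gene_id)

    def reverse_complement(self) -> "GenomeAnnotation":
        """Flip all strands and mirror coordinates (for symmetry checks)."""
        L = self.length_bp or (self.genes[-1].end if self.genes else 0)
        flipped = [
            GeneRecord(
                replicon_id=g.replicon_id,
                gene_id=g.gene_id,
                start=L - g.end + 1,
                end=L - g.start + 1,
                strand="-" if g.strand == "+" else "+",
                protein_length=g.protein_length,
                product=g.product,
                protein_seq=g.protein_seq,
            )
            for g in self.genes
        ]
        return GenomeAnnotation(self.replicon_id, flipped, self.source_label, L)


@dataclass(frozen=True)
class HomologyHit:
    """One homology-search hit mapping a marker family onto a gene.

    ``query_coverage`` is stored as a fraction in [0, 1] (query-relative).
    ``subject_start``/``subject_end`` are 1-based inclusive amino-acid
    positions on the subject protein.
    """

    query_family: str
    subject_gene_id: str
    percent_identity: float
    evalue: float
    query_coverage: float
    subject_start: int
    subject_end: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.query_coverage <= 1.0):
            raise AnnotationError(
                f"hit {self.query_family}->{self.subject_gene_id}: "
                f"coverage {self.query_coverage} outside [0, 1]")
        if self.evalue < 0:
            raise AnnotationError("negative E-value")
        if self.subject_end < self.subject_start:
            raise AnnotationError(
                f"hit {self.query_family}->{self.subject_gene_id}: "
                "subject_end < subject_start")


@dataclass(frozen=True)
class DomainAnnotation:
    """A predicted DNA-binding (or other) domain on a protein."""

    gene_id: str
    domain_label: str  # HTH | AP2 | other
    probability: float
    region_start: int
    region_end: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise AnnotationError(
                f"domain on {self.gene_id}: probability outside [0, 1]")
        if self.region_end < self.region_start or self.region_start < 1:
            raise AnnotationError(f"domain on {self.gene_id}: bad region")

    @property
    def is_dna_binding(self) -> bool:
        return self.domain_label in ("HTH", "AP2")


def validate_residues(seq: str) -> None:
    """Raise if ``seq`` contains characters outside the 20 amino acids."""
    bad = sorted(set(seq) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(f"invalid amino-acid characters: {bad}")


def genes_by_id(genomes: Iterable[GenomeAnnotation]) -> dict[str, GeneRecord]:
    out: dict[str, GeneRecord] = {}
    for genome in genomes:
        for g in genome:
            out[g.gene_id] = g
    return out
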