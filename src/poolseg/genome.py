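"""Scaled-down genome and gene models for simulated suppressor screens.

The simulated genome stands in for a small budding-yeast-like reference:
a handful of chromosomes named with the roman-numeral ``chrI``..``chrXVI``
convention, each carrying non-overlapping single-interval protein-coding
genes with explicit CDS sequences. Coordinates are 1-based inclusive
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

__all__ = ["GeneModel", "GenomeSpec", "build_genome", "roman"]

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
#: the 61 sense codons of the standard nuclear code
SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    """Roman-numeral rendering used for chromosome names (1 -> 'I')."""
    if n < 1:
        raise ValueError("roman() requires a positive integer")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


class GeneModelError(ValueError):
    """A gene model violates a CDS invariant."""


@dataclass(frozen=True)
class GeneModel:
    """Single-interval protein-coding gene.

    ``cds_sequence`` is stored in coding orientation (starts with ATG);
    for minus-strand genes it is the reverse complement of the genomic
    slice ``[cds_start, cds_end]``.
    """

    gene_id: str
    chromosome: str
    cds_start: int
    cds_end: int
    strand: str
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.cds_start < 1 or self.cds_end < self.cds_start:
            raise GeneModelError(f"{self.gene_id}: bad CDS interval")
        n = len(self.cds_sequence)
        if n != self.cds_end - self.cds_start + 1:
            raise GeneModelError(
                f"{self.gene_id}: CDS sequence length {n} does not match "
                f"interval {self.cds_start}-{self.cds_end}"
            )
        if n % 3 != 0:
            raise GeneModelError(f"{self.gene_id}: CDS length {n} not divisible by 3")
        if not self.cds_sequence.startswith("ATG"):
            raise GeneModelError(f"{self.gene_id}: CDS does not start with ATG")
        internal = [
            self.cds_sequence[i : i + 3] for i in range(0, n - 3, 3)
        ]
        if any(c in STOP_CODONS for c in internal):
            raise GeneModelError(f"{self.gene_id}: internal stop codon in CDS")

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    @property
    def protein(self) -> str:
        """Translation of the CDS (standard nuclear code), including any stop."""
        return str(Seq(self.cds_sequence).translate())

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.cds_start <= position <= self.cds_end
        )

    def genomic_base(self, position: int) -> str:
        """Reference base on the *genome* (plus) strand at ``position``."""
        if not self.contains(self.chromosome, position):
            raise ValueError(f"position {position} outside {self.gene_id} CDS")
        if self.strand == "+":
            return self.cds_sequence[position - self.cds_start]
        return str(Seq(self.cds_sequence[self.cds_end - position]).complement())


@dataclass
class GenomeSpec:
    """Chromosome sizes plus the gene models they carry."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        sizes = dict(self.chromosomes)
        if any(length <= 0 for length in sizes.values()):
            raise ValueError("chromosome lengths must be > 0")
        for gene in self.genes:
            if gene.chromosome not in sizes:
                raise ValueError(f"{gene.gene_id}: unknown chromosome {gene.chromosome}")
            if gene.cds_end > sizes[gene.chromosome]:
                raise ValueError(f"{gene.gene_id}: CDS extends past chromosome end")

    @property
    def chromosome_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def gene_at(self, chromosome: str, position: int) -> GeneModel | None:
        hits = [g for g in self.genes if g.contains(chromosome, position)]
        if len(hits) > 1:  # build_genome never produces overlaps
            raise ValueError(f"overlapping genes at {chromosome}:{position}")
        return hits[0] if hits else None


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + terminal stop; no internal stops."""
    if n_codons < 2:
        raise ValueError("CDS needs at least a start and a stop codon")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def build_genome(
    n_chromosomes: int,
    genes_per_chromosome: int,
    cds_codons: int,
    seed: int,
    intergenic_gap: int = 500,
) -> GenomeSpec:
    """Build a deterministic random genome with invariant-passing genes.

    Parameters
    ----------
    n_chromosomes, genes_per_chromosome
        Layout counts; must be >= 1.
    cds_codons
        Codons per gene including the initiator ATG and terminal stop, so
        each CDS spans ``3 * cds_codons`` nucleotides.
    seed
        Seed for the CDS sequences, strands and spacing; the same seed
        reproduces the genome byte for byte.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1 or cds_codons < 2:
        raise ValueError(
            "n_chromosomes and genes_per_chromosome must be >= 1 and "
            "cds_codons >= 2"
        )
    rng = np.random.default_rng(seed)
    cds_len = 3 * cds_codons
    chromosomes: list[tuple[str, int]] = []
    genes: list[GeneModel] = []
    for ci in range(1, n_chromosomes + 1):
        chrom = f"chr{roman(ci)}"
        cursor = 1
        for gi in range(1, genes_per_chromosome + 1):
            cursor += int(rng.integers(intergenic_gap // 2, intergenic_gap + 1))
            start, end = cursor, cursor + cds_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _random_cds(rng, cds_codons)
            genes.append(
                GeneModel(
                    gene_id=f"G{ci:02d}{gi:03d}",
                    chromosome=chrom,
                    cds_start=start,
                    cds_end=end,
                    strand=strand,
                    cds_sequence=cds,
                )
            )
            cursor = end + 1
        chromosomes.append((chrom, cursor + intergenic_gap))
    return GenomeSpec(chromosomes=chromosomes, genes=genes)
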