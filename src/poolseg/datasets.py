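"""Bundled worked-example data for the suppressor-mapping pipeline.

Two pooled-segregant frequency tables from a published spontaneous
suppressor screen in budding yeast (two revertant pools, 6 segregants
each, with the shared CLN2 frameshift at fixation in both) ship with the
package as TSV. The matching gene models are *synthetic*: plus-strand
fixture CDSs engineered so that the coding-effect annotator reproduces
each printed annotation string at the printed genomic coordinate — real
reference gene structures are not bundled.
"""

from __future__ import annotations

from importlib import resources

from .genome import GeneModel
from .variants import PoolFrequencyTable, read_pool_tsv

__all__ = [
    "revertant_pool_tables",
    "revertant_screen_genes",
    "frameshift_worked_example",
]

_FILLER = "GCT"  # alanine; contains no stop in frame


def revertant_pool_tables() -> tuple[PoolFrequencyTable, PoolFrequencyTable]:
    """The bundled revertant pool A and pool B frequency tables."""
    tables = []
    for name, pool_id in (
        ("revertant_pool_a.tsv", "pool_A"),
        ("revertant_pool_b.tsv", "pool_B"),
    ):
        ref = resources.files("poolseg.data").joinpath(name)
        with resources.as_file(ref) as path:
            tables.append(read_pool_tsv(path, pool_id=pool_id))
    return tables[0], tables[1]


def _engineered_gene(
    gene_id: str,
    chromosome: str,
    variant_position: int,
    codon_index: int,
    codon_pos: int,
    ref_codon: str,
    next_codon: str | None = None,
    tail_codons: int = 6,
) -> GeneModel:
    """Plus-strand fixture gene placing ``ref_codon`` at ``codon_index``
    such that the variant position falls on base ``codon_pos`` of it."""
    offset = 3 * (codon_index - 1) + codon_pos  # 1-based CDS offset
    cds_start = variant_position - offset + 1
    if cds_start < 1:
        raise ValueError(f"{gene_id}: variant too close to chromosome start")
    n_codons = codon_index + tail_codons
    codons = ["ATG"] + [_FILLER] * (n_codons - 2) + ["TAA"]
    codons[codon_index - 1] = ref_codon
    if next_codon is not None:
        codons[codon_index] = next_codon
    cds = "".join(codons)
    return GeneModel(
        gene_id=gene_id,
        chromosome=chromosome,
        cds_start=cds_start,
        cds_end=cds_start + len(cds) - 1,
        strand="+",
        cds_sequence=cds,
    )


def revertant_screen_genes() -> list[GeneModel]:
    """Synthetic fixture gene models for every bundled pool variant.

    Each gene is engineered so ``annotate`` yields the bundled table's
    annotation string: e.g. the AAA lysine codon at position 407 of the
    SMC2 fixture turns into GAA (E) under the printed A>G change, and the
    CLN2 fixture carries ACT-T at CDS bases 664-667 so the printed ACTT
    deletion is a frameshift at threonine 222.
    """
    return [
        # pool A (CLN2 and RPL31A are shared with / mirrored in pool B)
        _engineered_gene("CLN2", "chrXVI", 65946, 222, 1, "ACT",
                         next_codon="TGG", tail_codons=80),
        _engineered_gene("SMC2", "chrVI", 218888, 407, 1, "AAA"),
        _engineered_gene("GIT1", "chrIII", 297908, 233, 2, "AGT"),
        _engineered_gene("CAF40", "chrXIV", 90717, 139, 1, "GTG"),
        _engineered_gene("SEF1", "chrII", 98352, 588, 3, "TTG"),
        _engineered_gene("PTH1", "chrVIII", 484285, 87, 1, "TAT"),
        _engineered_gene("AIM44", "chrXVI", 252349, 654, 3, "GAA"),
        _engineered_gene("MSH5", "chrIV", 178744, 137, 3, "TGG"),
        _engineered_gene("RPL31A", "chrIV", 322263, 13, 2, "ACC"),
        # pool B only
        _engineered_gene("EAF1", "chrIV", 1193539, 449, 2, "ATA"),
        _engineered_gene("FLC1", "chrXVI", 133275, 78, 2, "GCC"),
        _engineered_gene("AFG3", "chrV", 191025, 255, 2, "GCA"),
    ]


def frameshift_worked_example() -> tuple[GeneModel, "object"]:
    """The 297-codon frameshift worked example.

    A synthetic 297-codon gene carries ACT (threonine) at the codon
    spanning CDS nucleotides 664-666 (codon 222) followed by TGG; a
    4-base ACTT deletion starting at CDS nucleotide 664 shifts the frame
    at codon 222, leaving residues 1-221 intact. Returns (gene, variant).
    """
    from .variants import VariantRecord

    n_codons = 297
    codons = ["ATG"] + [_FILLER] * (n_codons - 1)
    codons[221] = "ACT"   # codon 222
    codons[222] = "TGG"   # codon 223 starts with T -> deleted run is ACTT
    codons[223] = "CAA"   # keeps the shifted frame divergent and stop-free
    gene = GeneModel(
        gene_id="FS297",
        chromosome="chrXVI",
        cds_start=1001,
        cds_end=1000 + 3 * n_codons,
        strand="+",
        cds_sequence="".join(codons),
    )
    variant = VariantRecord(
        chromosome="chrXVI",
        position=gene.cds_start + 663,  # CDS nucleotide 664
        ref_allele="ACTT",
        alt_allele="",
    )
    assert gene.cds_sequence[663:667] == "ACTT"
    return gene, variant
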