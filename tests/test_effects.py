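"""Coding-effect annotation: worked examples and brute-force translation
properties."""

import math

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from poolseg import GeneModel, VariantRecord, annotate, annotate_table
from poolseg.datasets import (
    frameshift_worked_example,
    revertant_pool_tables,
    revertant_screen_genes,
)
from poolseg.effects import AmbiguousAnnotationError
from poolseg.genome import SENSE_CODONS


def _gene_from_codons(codons, chrom="chrI", start=101, strand="+"):
    cds = "".join(codons)
    if strand == "-":
        genomic_len = len(cds)
        return GeneModel("g", chrom, start, start + genomic_len - 1, "-", cds)
    return GeneModel("g", chrom, start, start + len(cds) - 1, "+", cds)


def _mutant_cds(gene: GeneModel, variant: VariantRecord) -> str:
    """Brute-force oracle: apply the variant to the CDS in coding space."""
    if gene.strand == "+":
        off = variant.position - gene.cds_start  # 0-based
        if variant.is_snv:
            return (
                gene.cds_sequence[:off]
                + variant.alt_allele
                + gene.cds_sequence[off + 1 :]
            )
        if variant.is_deletion:
            return (
                gene.cds_sequence[:off]
                + gene.cds_sequence[off + len(variant.ref_allele) :]
            )
        return (
            gene.cds_sequence[:off] + variant.alt_allele + gene.cds_sequence[off:]
        )
    # minus strand: translate the genomic event into coding coordinates
    if variant.is_snv:
        off = gene.cds_end - variant.position
        alt = str(Seq(variant.alt_allele).complement())
        return gene.cds_sequence[:off] + alt + gene.cds_sequence[off + 1 :]
    if variant.is_deletion:
        last = variant.position + len(variant.ref_allele) - 1
        off = gene.cds_end - last
        return (
            gene.cds_sequence[:off]
            + gene.cds_sequence[off + len(variant.ref_allele) :]
        )
    raise NotImplementedError


def _translate(cds: str) -> str:
    """Translate, dropping any trailing partial codon (frameshifted CDS)."""
    return str(Seq(cds[: len(cds) // 3 * 3]).translate())


def _first_divergence(wt_protein: str, mut_protein: str) -> int:
    """1-based index of the first differing residue (oracle)."""
    for i, (a, b) in enumerate(zip(wt_protein, mut_protein), start=1):
        if a != b:
            return i
    return min(len(wt_protein), len(mut_protein)) + 1


def test_missense_worked_example_k407e():
    # codon 407 is AAA (K); A>G at its first base gives GAA (E)
    codons = ["ATG"] + ["GCT"] * 410
    codons[406] = "AAA"
    gene = _gene_from_codons(codons)
    pos = gene.cds_start + 3 * 406  # first base of codon 407
    eff = annotate(VariantRecord("chrI", pos, "A", "G"), gene)
    assert eff.effect_class == "missense"
    assert eff.label == "K407E"


def test_frameshift_worked_example_y87fs():
    codons = ["ATG"] + ["GCT"] * 90
    codons[86] = "TAT"  # tyrosine codon 87
    gene = _gene_from_codons(codons)
    pos = gene.cds_start + 3 * 86  # first base of codon 87 is T
    eff = annotate(VariantRecord("chrI", pos, "T", ""), gene)
    assert eff.effect_class == "frameshift"
    assert eff.label == "Y87fs"


def test_frameshift_long_label_style():
    gene, variant = frameshift_worked_example()
    eff = annotate(variant, gene, long_frameshift_style=True)
    assert eff.label == "Frameshift at T222"


def test_four_base_deletion_at_cds_664_hits_codon_222():
    # ceil(664 / 3) = 222; residues 1-221 remain intact
    gene, variant = frameshift_worked_example()
    eff = annotate(variant, gene)
    assert eff.effect_class == "frameshift"
    assert eff.codon_index == 222 == math.ceil(664 / 3)
    assert eff.preserved_residues == 221
    # brute-force translation agrees
    wt = gene.protein
    mut = _translate(_mutant_cds(gene, variant))
    assert _first_divergence(wt, mut) == 222
    assert wt[:221] == mut[:221]


def test_in_frame_deletion_is_not_frameshift():
    codons = ["ATG"] + ["GCT"] * 30
    gene = _gene_from_codons(codons)
    pos = gene.cds_start + 9
    ref = gene.cds_sequence[9:12]
    eff = annotate(VariantRecord("chrI", pos, ref, ""), gene)
    assert eff.effect_class == "in_frame_indel"
    assert "fs" not in eff.label


def test_synonymous_and_nonsense_calls():
    codons = ["ATG", "TTA", "TGG", "GCT"]
    gene = _gene_from_codons(codons)
    # TTA -> TTG both leucine
    eff = annotate(VariantRecord("chrI", gene.cds_start + 5, "A", "G"), gene)
    assert eff.effect_class == "synonymous"
    # TGG -> TGA stop
    eff = annotate(VariantRecord("chrI", gene.cds_start + 8, "G", "A"), gene)
    assert eff.effect_class == "nonsense"
    assert eff.label == "W3*"


def test_minus_strand_snv_annotated_in_coding_orientation():
    codons = ["ATG", "AAA", "GCT"]
    gene = _gene_from_codons(codons, strand="-")
    # coding AAA codon 2; genomic slice is revcomp so its bases sit at
    # genomic positions cds_end-3 .. cds_end-5 (T on the plus strand)
    # coding offset 4 (codon 2 base 1) is genomic position cds_end - 3
    pos = gene.cds_end - 3
    # plus-strand base there is complement(A) = T; T>C on genome = A>G coding
    eff = annotate(VariantRecord("chrI", pos, "T", "C"), gene)
    assert eff.effect_class == "missense"
    assert eff.label == "K2E"


def test_intergenic_and_chromosome_mismatch():
    gene = _gene_from_codons(["ATG", "GCT", "TGG"])
    eff = annotate(VariantRecord("chrI", gene.cds_end + 50, "A", "G"), gene)
    assert eff.effect_class == "intergenic"
    with pytest.raises(ValueError, match="chrII"):
        annotate(VariantRecord("chrII", gene.cds_start, "A", "G"), gene)


def test_bundled_pool_annotations_reproduce_printed_labels():
    pool_a, pool_b = revertant_pool_tables()
    genes = revertant_screen_genes()
    labels_a = [r.annotation.label for r in annotate_table(pool_a, genes)]
    assert labels_a == [
        "T222fs", "K407E", "S233T", "V139L", "L588F",
        "Y87fs", "E654D", "W137C", "T13I",
    ]
    labels_b = [r.annotation.label for r in annotate_table(pool_b, genes)]
    assert labels_b == ["T222fs", "T13I", "I449T", "A78G", "A255V"]


def test_annotate_table_flags_ambiguous_overlap():
    g1 = _gene_from_codons(["ATG", "GCT", "TGG"], start=101)
    g2 = _gene_from_codons(["ATG", "GCT", "TGG"], start=104)
    from poolseg import PoolFrequencyRecord, PoolFrequencyTable

    table = PoolFrequencyTable(
        "p", [PoolFrequencyRecord(VariantRecord("chrI", 105, "C", "T"), 0.5)]
    )
    with pytest.raises(AmbiguousAnnotationError):
        annotate_table(table, [g1, g2])


def test_annotate_table_empty_and_intergenic():
    from poolseg import PoolFrequencyRecord, PoolFrequencyTable

    gene = _gene_from_codons(["ATG", "GCT", "TGG"])
    empty = annotate_table(PoolFrequencyTable("p", []), [gene])
    assert len(empty) == 0
    table = PoolFrequencyTable(
        "p", [PoolFrequencyRecord(VariantRecord("chrI", 1, "A", "G"), 0.1)]
    )
    out = annotate_table(table, [gene])
    assert out.records[0].annotation.effect_class == "intergenic"


# ---------------------------------------------------------------------------
# brute-force translation properties over random fixtures
# ---------------------------------------------------------------------------

_codon_strategy = st.sampled_from(SENSE_CODONS)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    codons=st.lists(_codon_strategy, min_size=4, max_size=40),
    data=st.data(),
)
def test_snv_annotation_agrees_with_full_translation(codons, data):
    """Translating the whole mutant CDS and diffing proteins recovers the
    annotator's (ref, codon, alt) triple for every coding SNV."""
    codons = ["ATG"] + codons
    gene = _gene_from_codons(codons)
    off = data.draw(
        st.integers(min_value=3, max_value=len(gene.cds_sequence) - 1),
        label="cds_offset0",
    )
    ref = gene.cds_sequence[off]
    alt = data.draw(
        st.sampled_from([b for b in "ACGT" if b != ref]), label="alt"
    )
    variant = VariantRecord("chrI", gene.cds_start + off, ref, alt)
    eff = annotate(variant, gene)
    wt = gene.protein
    mut = _translate(_mutant_cds(gene, variant))
    if eff.effect_class == "synonymous":
        assert wt == mut
    else:
        idx = _first_divergence(wt, mut)
        assert idx == eff.codon_index
        assert wt[idx - 1] == eff.ref_residue
        assert mut[idx - 1] == eff.alt_residue


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    codons=st.lists(_codon_strategy, min_size=6, max_size=40),
    data=st.data(),
)
def test_frameshift_codon_matches_first_protein_divergence(codons, data):
    """The annotated frameshift codon equals the first divergent residue
    under brute-force translation whenever the shifted codon actually
    changes the residue (it can coincide by chance, in which case the
    divergence can only come later)."""
    codons = ["ATG"] + codons
    gene = _gene_from_codons(codons)
    max_start = len(gene.cds_sequence) - 6
    off = data.draw(st.integers(min_value=3, max_value=max_start), label="off0")
    length = data.draw(st.sampled_from([1, 2, 4, 5]), label="del_len")
    ref = gene.cds_sequence[off : off + length]
    variant = VariantRecord("chrI", gene.cds_start + off, ref, "")
    eff = annotate(variant, gene)
    assert eff.effect_class == "frameshift"
    wt = gene.protein
    mut = _translate(_mutant_cds(gene, variant))
    idx = _first_divergence(wt, mut)
    ci = eff.codon_index
    assert idx >= ci
    if len(mut) >= ci and wt[ci - 1] != mut[ci - 1]:
        assert idx == ci
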