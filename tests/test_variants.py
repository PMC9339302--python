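"""Variant record semantics and VCF / summary-TSV / gene-model I/O."""

import pytest

from poolseg import (
    PoolFrequencyRecord,
    PoolFrequencyTable,
    VariantRecord,
    read_gene_models,
    read_pool_tsv,
    read_vcf,
    write_pool_tsv,
    write_vcf,
)
from poolseg.genome import GeneModelError
from poolseg.variants import VariantFormatError


def test_change_labels_round_trip_with_alleles():
    snv = VariantRecord("chrI", 10, "A", "G")
    assert snv.change_label == "A > G" and snv.is_snv
    dele = VariantRecord("chrXVI", 65946, "ACTT", "")
    assert dele.change_label == "delACTT" and dele.is_deletion
    ins = VariantRecord("chrII", 5, "", "GA")
    assert ins.change_label == "insGA" and ins.is_insertion
    with pytest.raises(VariantFormatError, match="round-trip"):
        VariantRecord("chrI", 10, "A", "G", change_label="delA")


def test_change_token_parsing_dialects():
    v = VariantRecord.from_change_token("chrVI", 218888, "A > G")
    assert (v.ref_allele, v.alt_allele) == ("A", "G")
    d = VariantRecord.from_change_token("chrXVI", 65946, "delACTT")
    assert d.ref_allele == "ACTT" and d.alt_allele == ""
    with pytest.raises(VariantFormatError, match="dupACT"):
        VariantRecord.from_change_token("chrI", 1, "dupACT")


def test_pool_table_rejects_duplicate_sites():
    v = VariantRecord("chrI", 10, "A", "G")
    with pytest.raises(VariantFormatError, match="duplicate"):
        PoolFrequencyTable(
            "p", [PoolFrequencyRecord(v, 0.5), PoolFrequencyRecord(v, 0.6)]
        )


def test_frequency_bounds_enforced():
    v = VariantRecord("chrI", 10, "A", "G")
    with pytest.raises(VariantFormatError):
        PoolFrequencyRecord(v, 1.5)


def test_vcf_round_trip_is_lossless(tmp_path):
    table = PoolFrequencyTable(
        "p1",
        [
            PoolFrequencyRecord(VariantRecord("chrI", 100, "A", "G"), 0.5, depth=80),
            PoolFrequencyRecord(
                VariantRecord("chrXVI", 65947, "ACTT", "", anchor_base="T"),
                1.0,
                depth=120,
            ),
            PoolFrequencyRecord(
                VariantRecord("chrII", 50, "", "GA", anchor_base="C"), 0.25, depth=60
            ),
        ],
    )
    path = tmp_path / "p1.vcf"
    write_vcf(table, path)
    back = read_vcf(path)
    original = sorted(
        table.records, key=lambda r: (r.variant.chromosome, r.variant.position)
    )
    for a, b in zip(original, back.records):
        assert a.variant == b.variant
        assert a.frequency == pytest.approx(b.frequency)
        assert a.depth == b.depth


def test_vcf_deletion_anchoring_matches_convention(tmp_path):
    # a VCF row REF=TACTT ALT=T at 65946 is the ACTT deletion whose first
    # deleted base is 65947
    vcf = tmp_path / "x.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
        "##contig=<ID=chrXVI>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrXVI\t65946\t.\tTACTT\tT\t.\t.\tAF=1.0\n"
    )
    table = read_vcf(vcf)
    (rec,) = table.records
    assert rec.variant.change_label == "delACTT"
    assert rec.variant.position == 65947
    assert rec.variant.anchor_base == "T"
    assert rec.frequency == 1.0


def test_vcf_multiallelic_sites_are_split(tmp_path):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
        "##contig=<ID=chrI>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrI\t20\t.\tA\tG,T\t.\t.\tAF=0.5,0.25\n"
    )
    table = read_vcf(vcf)
    assert [(r.variant.alt_allele, r.frequency) for r in table.records] == [
        ("G", 0.5),
        ("T", 0.25),
    ]


def test_vcf_missing_af_names_the_line(tmp_path):
    vcf = tmp_path / "bad.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
        "##contig=<ID=chrI>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrI\t20\t.\tA\tG\t.\t.\tDP=10\n"
    )
    with pytest.raises(VariantFormatError, match="line 1"):
        read_vcf(vcf)


def test_empty_vcf_gives_empty_table(tmp_path):
    vcf = tmp_path / "empty.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
        "##contig=<ID=chrI>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    assert len(read_vcf(vcf)) == 0


def test_pool_tsv_parses_bundled_dialect(pool_tables):
    pool_a, pool_b = pool_tables
    assert len(pool_a) == 9 and len(pool_b) == 5
    smc2 = next(r for r in pool_a if r.variant.gene_id == "SMC2")
    assert smc2.variant.chromosome == "chrVI"
    assert smc2.variant.position == 218888
    assert smc2.variant.change_label == "A > G"
    assert smc2.frequency == 1.00
    rpl = next(r for r in pool_a if r.variant.gene_id == "RPL31A")
    assert rpl.frequency == 0.25
    assert rpl.variant.change_label == "C > T"


def test_pool_tsv_header_only_gives_empty_table(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text(
        "chromosome_position\tdna_change\tannotation\tgene\tdescription\tfrequency\n"
    )
    assert len(read_pool_tsv(p)) == 0


def test_pool_tsv_round_trip(tmp_path, pool_tables):
    pool_a, _ = pool_tables
    out = tmp_path / "a.tsv"
    write_pool_tsv(pool_a, out)
    back = read_pool_tsv(out, pool_id=pool_a.pool_id)
    assert [r.variant for r in back.records] == [r.variant for r in pool_a.records]
    assert [r.frequency for r in back.records] == [
        pytest.approx(r.frequency) for r in pool_a.records
    ]


def test_cross_format_readers_agree(tmp_path):
    """Equivalent VCF and TSV content produce identical in-memory records."""
    tsv = tmp_path / "p.tsv"
    tsv.write_text(
        "chromosome_position\tdna_change\tannotation\tgene\tdescription\tfrequency\n"
        "chrI_100\tA > G\t\t\t\t0.5\n"
        "chrII_201\tdelCT\t\t\t\t1.0\n"
    )
    vcf = tmp_path / "p.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
        "##contig=<ID=chrI>\n##contig=<ID=chrII>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrI\t100\t.\tA\tG\t.\t.\tAF=0.5\n"
        "chrII\t200\t.\tGCT\tG\t.\t.\tAF=1.0\n"
    )
    from_tsv = read_pool_tsv(tsv, pool_id="p")
    from_vcf = read_vcf(vcf, pool_id="p")
    for a, b in zip(from_tsv.records, from_vcf.records):
        assert a.variant.key() == b.variant.key()
        assert a.variant.change_label == b.variant.change_label
        assert a.frequency == pytest.approx(b.frequency)


def _write_fasta(path, chrom, seq):
    path.write_text(f">{chrom}\n{seq}\n")


def test_gene_models_plus_strand_bed(tmp_path):
    seq = "N" * 10 + "ATGGCTTGGTAA" + "N" * 8
    fasta = tmp_path / "g.fa"
    _write_fasta(fasta, "chrI", seq)
    bed = tmp_path / "g.bed"
    bed.write_text("chrI\t10\t22\tGENE1\t0\t+\n")
    (gene,) = read_gene_models(bed, fasta)
    assert gene.cds_sequence == "ATGGCTTGGTAA"
    assert (gene.cds_start, gene.cds_end) == (11, 22)


def test_gene_models_minus_strand_reverse_complemented(tmp_path):
    # independent oracle: hand reverse-complement of the genomic slice
    cds = "ATGGCTTGGTAA"
    genomic = "TTACCAAGCCAT"  # revcomp(cds)
    seq = "N" * 5 + genomic + "N" * 5
    fasta = tmp_path / "g.fa"
    _write_fasta(fasta, "chrII", seq)
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chrII\tsrc\tCDS\t6\t17\t.\t-\t0\tID=GENE2\n"
    )
    (gene,) = read_gene_models(gff, fasta)
    assert gene.strand == "-"
    assert gene.cds_sequence == cds


def test_gene_models_reject_bad_cds_length(tmp_path):
    seq = "N" * 5 + "ATGGCTTGGT" + "N" * 5
    fasta = tmp_path / "g.fa"
    _write_fasta(fasta, "chrI", seq)
    bed = tmp_path / "g.bed"
    bed.write_text("chrI\t5\t15\tBADGENE\t0\t+\n")
    with pytest.raises(GeneModelError, match="BADGENE"):
        read_gene_models(bed, fasta)
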