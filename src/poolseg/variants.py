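"""Variant records, pooled allele-frequency tables, and their file formats.

Three on-disk representations are supported:

* VCF v4.2 with pooled allele frequency in INFO/AF and depth in INFO/DP
  (one file per segregant pool) — the output shape of a pooled-continuous
  variant caller. Read/written through :mod:`pysam`.
* a pooled-variant summary TSV dialect with columns
  ``chromosome_position`` (e.g. ``chrXVI_65946``), ``dna_change``
  (``A > G`` / ``delACTT`` / ``insGA``), ``annotation``, ``gene``,
  ``description`` and ``frequency`` — the shape of a published revertant
  screen summary table.
* gene models as BED12 (single block) or a single-interval GFF3 subset,
  with CDS sequences pulled from a FASTA.

Canonical in-memory coordinates: SNVs sit at their own position; for
indels ``position`` is the first deleted/inserted base, with the VCF
anchor-base convention translated on the way in and out (VCF anchor =
``position - 1``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

from .genome import GeneModel, GeneModelError

__all__ = [
    "VariantRecord",
    "PoolFrequencyRecord",
    "PoolFrequencyTable",
    "read_vcf",
    "write_vcf",
    "read_pool_tsv",
    "write_pool_tsv",
    "read_gene_models",
    "VariantFormatError",
]


class VariantFormatError(ValueError):
    """Malformed variant content in a file or token."""


_SNV_RE = re.compile(r"^([ACGTN])\s*>\s*([ACGTN])$")
_DEL_RE = re.compile(r"^del([ACGTN]+)$")
_INS_RE = re.compile(r"^ins([ACGTN]+)$")


@dataclass(frozen=True)
class VariantRecord:
    """One mutation: locus, allele change and (optionally) the gene hit.

    Exactly one of three shapes holds: SNV (``len(ref) == len(alt) == 1``),
    deletion (``alt == ""``, ``ref`` = deleted bases) or insertion
    (``ref == ""``, ``alt`` = inserted bases). ``change_label`` always
    round-trips with the alleles. ``anchor_base`` carries the VCF anchor
    when known; "N" otherwise.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    change_label: str = ""
    gene_id: Optional[str] = None
    anchor_base: str = "N"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantFormatError("position must be >= 1")
        if not (self.is_snv or self.is_deletion or self.is_insertion):
            raise VariantFormatError(
                f"alleles {self.ref_allele!r}>{self.alt_allele!r} are not a "
                "supported SNV/deletion/insertion"
            )
        expected = self._render_label()
        if not self.change_label:
            object.__setattr__(self, "change_label", expected)
        elif self.change_label != expected:
            raise VariantFormatError(
                f"change_label {self.change_label!r} does not round-trip "
                f"with alleles (expected {expected!r})"
            )

    # -- shape predicates -------------------------------------------------
    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_deletion(self) -> bool:
        return len(self.ref_allele) >= 1 and self.alt_allele == ""

    @property
    def is_insertion(self) -> bool:
        return self.ref_allele == "" and len(self.alt_allele) >= 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    def _render_label(self) -> str:
        if self.is_snv:
            return f"{self.ref_allele} > {self.alt_allele}"
        if self.is_deletion:
            return f"del{self.ref_allele}"
        return f"ins{self.alt_allele}"

    def key(self) -> tuple[str, int, str]:
        """Cross-pool matching key: chromosome, position, alt allele."""
        return (self.chromosome, self.position, self.alt_allele)

    @classmethod
    def from_change_token(
        cls, chromosome: str, position: int, token: str, gene_id: str | None = None
    ) -> "VariantRecord":
        """Parse a ``A > G`` / ``delACTT`` / ``insGA`` change token."""
        token = token.strip()
        if m := _SNV_RE.match(token):
            return cls(chromosome, position, m.group(1), m.group(2), gene_id=gene_id)
        if m := _DEL_RE.match(token):
            return cls(chromosome, position, m.group(1), "", gene_id=gene_id)
        if m := _INS_RE.match(token):
            return cls(chromosome, position, "", m.group(1), gene_id=gene_id)
        raise VariantFormatError(f"unparseable DNA change token {token!r}")


@dataclass
class PoolFrequencyRecord:
    """A variant with its pooled allele frequency in one segregant pool."""

    variant: VariantRecord
    frequency: float
    depth: Optional[int] = None
    pool_id: str = ""
    annotation: object = None  # str from TSV, EffectAnnotation once annotated

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise VariantFormatError(
                f"frequency {self.frequency} outside [0, 1] at "
                f"{self.variant.chromosome}:{self.variant.position}"
            )


@dataclass
class PoolFrequencyTable:
    """All variant frequencies observed in one pool of segregants."""

    pool_id: str
    records: list[PoolFrequencyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.variant.key() for r in self.records]
        if len(set(keys)) != len(keys):
            raise VariantFormatError(
                f"duplicate (chromosome, position, alt) in pool {self.pool_id!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _record_from_vcf_alleles(
    chrom: str, vcf_pos: int, ref: str, alt: str
) -> VariantRecord:
    if len(ref) == 1 and len(alt) == 1:
        return VariantRecord(chrom, vcf_pos, ref, alt)
    if len(ref) > len(alt) == 1 and ref.startswith(alt):
        # anchored deletion: canonical position is the first deleted base
        return VariantRecord(chrom, vcf_pos + 1, ref[1:], "", anchor_base=alt)
    if len(alt) > len(ref) == 1 and alt.startswith(ref):
        return VariantRecord(chrom, vcf_pos + 1, "", alt[1:], anchor_base=ref)
    raise VariantFormatError(
        f"unsupported allele pair {ref}>{alt} at {chrom}:{vcf_pos} "
        "(only SNVs and anchored indels)"
    )


def read_vcf(path: str | Path, pool_id: str | None = None) -> PoolFrequencyTable:
    """Read a pooled VCF (INFO/AF required, INFO/DP optional).

    Multi-allelic sites are split into one biallelic record per ALT, each
    with its own AF entry. A record without AF raises
    :class:`VariantFormatError` naming the offending line.
    """
    path = Path(path)
    if pool_id is None:
        pool_id = path.stem
    records: list[PoolFrequencyRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        has_dp = "DP" in vcf.header.info
        has_eff = "EFF" in vcf.header.info
        for i, rec in enumerate(vcf, start=1):
            if "AF" not in rec.info:
                raise VariantFormatError(
                    f"{path.name} data line {i} ({rec.chrom}:{rec.pos}): "
                    "missing INFO/AF"
                )
            afs = rec.info["AF"]
            if not isinstance(afs, tuple):
                afs = (afs,)
            depth = rec.info.get("DP") if has_dp else None
            alts = rec.alts or ()
            if len(afs) not in (1, len(alts)):
                raise VariantFormatError(
                    f"{path.name} data line {i}: AF count does not match ALTs"
                )
            for j, alt in enumerate(alts):
                af = float(afs[j if len(afs) == len(alts) else 0])
                variant = _record_from_vcf_alleles(rec.chrom, rec.pos, rec.ref, alt)
                eff = rec.info.get("EFF") if has_eff else None
                records.append(
                    PoolFrequencyRecord(
                        variant=variant,
                        frequency=af,
                        depth=int(depth) if depth is not None else None,
                        pool_id=pool_id,
                        annotation=eff if eff else None,
                    )
                )
    return PoolFrequencyTable(pool_id=pool_id, records=records)


def write_vcf(table: PoolFrequencyTable, path: str | Path) -> None:
    """Write a pool table as VCF v4.2 with AF/DP (and EFF when annotated).

    Indels are emitted left-aligned with an anchor base at
    ``position - 1``; if the anchor is unknown (records that came from the
    summary-TSV dialect, which has no reference sequence) an ``N`` anchor
    is written.
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "poolseg")
    for chrom in dict.fromkeys(r.variant.chromosome for r in table.records):
        header.contigs.add(chrom)
    header.info.add("AF", "A", "Float", "Pooled alternate allele frequency")
    header.info.add("DP", 1, "Integer", "Read depth at the site")
    header.info.add("EFF", 1, "String", "Coding effect label")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(
            table.records, key=lambda r: (r.variant.chromosome, r.variant.position)
        ):
            v = rec.variant
            if v.is_snv:
                pos0, alleles = v.position - 1, (v.ref_allele, v.alt_allele)
            else:
                anchor = v.anchor_base or "N"
                if v.is_deletion:
                    pos0, alleles = v.position - 2, (anchor + v.ref_allele, anchor)
                else:
                    pos0, alleles = v.position - 2, (anchor, anchor + v.alt_allele)
            line = out.new_record(
                contig=v.chromosome, start=pos0, alleles=alleles
            )
            line.info["AF"] = (rec.frequency,)
            if rec.depth is not None:
                line.info["DP"] = rec.depth
            label = getattr(rec.annotation, "label", rec.annotation)
            if isinstance(label, str) and label:
                line.info["EFF"] = label.replace(" ", "_")
            out.write(line)


# ---------------------------------------------------------------------------
# Pooled-variant summary TSV dialect
# ---------------------------------------------------------------------------

def _norm_col(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


def _split_locus(token: str) -> tuple[str, int]:
    chrom, _, pos = token.strip().rpartition("_")
    if not chrom or not pos.isdigit():
        raise VariantFormatError(f"unparseable chromosome_position {token!r}")
    return chrom, int(pos)


def _gene_symbol(cell: object) -> str | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).replace("*", "").strip()
    return text.split()[0] if text else None


def read_pool_tsv(path: str | Path, pool_id: str | None = None) -> PoolFrequencyTable:
    """Read the pooled-variant summary TSV dialect.

    Expected (case-insensitive) columns: ``chromosome_position``,
    ``dna_change``, ``annotation``, ``gene``, ``description``,
    ``frequency``. Positions of indels are the first altered base.
    """
    path = Path(path)
    if pool_id is None:
        pool_id = path.stem
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [_norm_col(c) for c in df.columns]
    required = {"chromosome_position", "dna_change", "frequency"}
    if missing := required - set(df.columns):
        raise VariantFormatError(f"{path.name}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        chrom, pos = _split_locus(row.chromosome_position)
        variant = VariantRecord.from_change_token(
            chrom, pos, row.dna_change, gene_id=_gene_symbol(getattr(row, "gene", None))
        )
        annotation = getattr(row, "annotation", None)
        if isinstance(annotation, float) and pd.isna(annotation):
            annotation = None
        records.append(
            PoolFrequencyRecord(
                variant=variant,
                frequency=float(row.frequency),
                pool_id=pool_id,
                annotation=annotation,
            )
        )
    return PoolFrequencyTable(pool_id=pool_id, records=records)


def write_pool_tsv(table: PoolFrequencyTable, path: str | Path) -> None:
    """Write a pool table in the summary TSV dialect."""
    rows = []
    for rec in table.records:
        v = rec.variant
        label = getattr(rec.annotation, "label", rec.annotation)
        rows.append(
            {
                "chromosome_position": f"{v.chromosome}_{v.position}",
                "dna_change": v.change_label,
                "annotation": label if label is not None else "",
                "gene": v.gene_id or "",
                "description": "",
                "frequency": f"{rec.frequency:.4g}",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chromosome_position", "dna_change", "annotation",
            "gene", "description", "frequency",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (BED12 / GFF3 subset + FASTA)
# ---------------------------------------------------------------------------

def _fasta_index(fasta_path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def _gene_from_interval(
    gene_id: str, chrom: str, start1: int, end1: int, strand: str,
    sequences: dict[str, str],
) -> GeneModel:
    if chrom not in sequences:
        raise VariantFormatError(f"{gene_id}: chromosome {chrom} not in FASTA")
    genomic = sequences[chrom][start1 - 1 : end1]
    if len(genomic) != end1 - start1 + 1:
        raise VariantFormatError(f"{gene_id}: CDS interval exceeds FASTA sequence")
    cds = genomic if strand == "+" else str(Seq(genomic).reverse_complement())
    return GeneModel(
        gene_id=gene_id, chromosome=chrom,
        cds_start=start1, cds_end=end1, strand=strand, cds_sequence=cds,
    )


def read_gene_models(path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Read single-interval CDS gene models from BED12 or GFF3 + FASTA.

    Minus-strand CDSs are reverse-complemented into coding orientation.
    CDS invariant violations (length % 3, missing ATG, internal stop)
    raise :class:`~poolseg.genome.GeneModelError` naming the gene.
    """
    path = Path(path)
    sequences = _fasta_index(fasta_path)
    genes: list[GeneModel] = []
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        for row in df.itertuples(index=False):
            fields = list(row)
            chrom, start0, end1 = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start0}"
            strand = fields[5] if len(fields) > 5 else "+"
            if len(fields) >= 10 and int(fields[9]) != 1:
                raise VariantFormatError(
                    f"{name}: multi-block BED12 records are not supported"
                )
            genes.append(
                _gene_from_interval(name, chrom, start0 + 1, end1, strand, sequences)
            )
    elif path.suffix.lower() in (".gff", ".gff3"):
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True,
            merge_strategy="create_unique", keep_order=True,
        )
        for feat in db.features_of_type("CDS"):
            name = (
                feat.attributes.get("ID", [None])[0]
                or feat.attributes.get("gene_id", [None])[0]
                or feat.attributes.get("Parent", [None])[0]
                or f"{feat.seqid}:{feat.start}"
            )
            genes.append(
                _gene_from_interval(
                    name, feat.seqid, feat.start, feat.end, feat.strand, sequences
                )
            )
    else:
        raise VariantFormatError(f"unrecognised gene-model format: {path.name}")
    return genes
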