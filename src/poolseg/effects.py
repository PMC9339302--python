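"""Coding-effect annotation: missense/nonsense/synonymous calls and
frameshift naming in the compact ``K407E`` / ``Y87fs`` convention.

Codon numbering is 1-based from the initiator ATG. For indels the
reported codon is the one containing the leftmost altered base in coding
orientation; a frameshift at codon *n* therefore leaves the first
``n - 1`` residues intact, matching the usual truncation-allele
shorthand (a frameshift at T222 preserves residues 1-221).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

from Bio.Seq import Seq

from .genome import GeneModel
from .variants import PoolFrequencyRecord, PoolFrequencyTable, VariantRecord

__all__ = [
    "EffectAnnotation",
    "annotate",
    "annotate_table",
    "AmbiguousAnnotationError",
]

EffectClass = Literal[
    "missense", "synonymous", "nonsense", "frameshift",
    "in_frame_indel", "intergenic", "noncoding",
]


class AmbiguousAnnotationError(ValueError):
    """A variant overlaps more than one gene model."""


@dataclass(frozen=True)
class EffectAnnotation:
    """Consequence call for one variant against one gene model."""

    effect_class: EffectClass
    ref_residue: Optional[str] = None
    codon_index: Optional[int] = None
    alt_residue: Optional[str] = None
    long_frameshift_style: bool = False

    def __post_init__(self) -> None:
        if self.codon_index is not None and self.codon_index < 1:
            raise ValueError("codon_index must be >= 1")

    @property
    def label(self) -> str:
        """Render the annotation string; regenerates deterministically."""
        c = self.effect_class
        if c == "missense":
            return f"{self.ref_residue}{self.codon_index}{self.alt_residue}"
        if c == "synonymous":
            return f"{self.ref_residue}{self.codon_index}{self.ref_residue}"
        if c == "nonsense":
            return f"{self.ref_residue}{self.codon_index}*"
        if c == "frameshift":
            if self.long_frameshift_style:
                return f"Frameshift at {self.ref_residue}{self.codon_index}"
            return f"{self.ref_residue}{self.codon_index}fs"
        if c == "in_frame_indel":
            return f"{self.ref_residue}{self.codon_index}inframe"
        return c

    @property
    def preserved_residues(self) -> Optional[int]:
        """Complete upstream codons unaffected by the variant (coding only)."""
        if self.codon_index is None:
            return None
        return self.codon_index - 1

    @property
    def is_truncating(self) -> bool:
        return self.effect_class in ("frameshift", "nonsense")


def _coding_offset(variant: VariantRecord, gene: GeneModel) -> Optional[int]:
    """1-based CDS offset of the first altered base in coding orientation.

    Returns None when the altered interval lies entirely outside the CDS.
    Indels that straddle a CDS edge are clamped to the CDS.
    """
    if variant.is_deletion:
        first, last = variant.position, variant.position + len(variant.ref_allele) - 1
    else:
        first = last = variant.position
    if last < gene.cds_start or first > gene.cds_end:
        return None
    first, last = max(first, gene.cds_start), min(last, gene.cds_end)
    if gene.strand == "+":
        return first - gene.cds_start + 1
    return gene.cds_end - last + 1


def annotate(
    variant: VariantRecord,
    gene: GeneModel,
    long_frameshift_style: bool = False,
) -> EffectAnnotation:
    """Classify a variant's coding consequence against one gene model.

    SNVs inside the CDS are translated on the coding strand and classified
    missense / synonymous / nonsense at codon ``ceil(offset / 3)``; indels
    are frameshifts when ``length % 3 != 0`` (at the codon containing the
    first altered base) and in-frame otherwise. Anything outside the CDS
    is intergenic.
    """
    if variant.chromosome != gene.chromosome:
        raise ValueError(
            f"variant on {variant.chromosome} annotated against gene "
            f"{gene.gene_id} on {gene.chromosome}"
        )
    offset = _coding_offset(variant, gene)
    if offset is None:
        return EffectAnnotation(effect_class="intergenic")
    codon_index = math.ceil(offset / 3)
    cds = gene.cds_sequence
    codon_start = 3 * (codon_index - 1)
    ref_codon = cds[codon_start : codon_start + 3]
    ref_aa = str(Seq(ref_codon).translate())

    if variant.is_snv:
        alt_base = (
            variant.alt_allele
            if gene.strand == "+"
            else str(Seq(variant.alt_allele).complement())
        )
        within = (offset - 1) % 3
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == ref_aa:
            cls: EffectClass = "synonymous"
        elif alt_aa == "*":
            cls = "nonsense"
        else:
            cls = "missense"
        return EffectAnnotation(
            effect_class=cls, ref_residue=ref_aa,
            codon_index=codon_index, alt_residue=alt_aa,
            long_frameshift_style=long_frameshift_style,
        )

    if variant.indel_length % 3 != 0:
        return EffectAnnotation(
            effect_class="frameshift", ref_residue=ref_aa,
            codon_index=codon_index,
            long_frameshift_style=long_frameshift_style,
        )
    return EffectAnnotation(
        effect_class="in_frame_indel", ref_residue=ref_aa,
        codon_index=codon_index,
        long_frameshift_style=long_frameshift_style,
    )


def annotate_table(
    table: PoolFrequencyTable,
    genes: list[GeneModel],
    long_frameshift_style: bool = False,
) -> PoolFrequencyTable:
    """Annotate every record against its single overlapping gene.

    Variants overlapping no gene get an intergenic annotation; overlapping
    two or more genes raises :class:`AmbiguousAnnotationError` naming them.
    The input table is left unmodified.
    """
    out: list[PoolFrequencyRecord] = []
    for rec in table.records:
        v = rec.variant
        if v.is_deletion:
            span = range(v.position, v.position + len(v.ref_allele))
        else:
            span = range(v.position, v.position + 1)
        hits = [
            g for g in genes
            if g.chromosome == v.chromosome
            and not (span.stop - 1 < g.cds_start or span.start > g.cds_end)
        ]
        if len(hits) > 1:
            names = ", ".join(g.gene_id for g in hits)
            raise AmbiguousAnnotationError(
                f"{v.chromosome}:{v.position} overlaps multiple genes: {names}"
            )
        if not hits:
            ann = EffectAnnotation(effect_class="intergenic")
            out.append(replace_record(rec, annotation=ann))
        else:
            ann = annotate(v, hits[0], long_frameshift_style=long_frameshift_style)
            new = replace_record(rec, annotation=ann)
            if new.variant.gene_id is None:
                new.variant = replace(new.variant, gene_id=hits[0].gene_id)
            out.append(new)
    return PoolFrequencyTable(pool_id=table.pool_id, records=out)


def replace_record(rec: PoolFrequencyRecord, **changes) -> PoolFrequencyRecord:
    """Shallow-copy a pool record with field overrides."""
    return PoolFrequencyRecord(
        variant=changes.get("variant", rec.variant),
        frequency=changes.get("frequency", rec.frequency),
        depth=changes.get("depth", rec.depth),
        pool_id=changes.get("pool_id", rec.pool_id),
        annotation=changes.get("annotation", rec.annotation),
    )
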