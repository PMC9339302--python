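"""Annotate coding variants: missense naming and frameshift arithmetic.

Builds the 297-codon worked-example gene in which a 4-base ACTT deletion
starts at CDS nucleotide 664, and shows how the annotator names coding
changes (K407E-style missense; T222fs / "Frameshift at T222" styles).
"""

from poolseg import GeneModel, VariantRecord, annotate
from poolseg.datasets import frameshift_worked_example

gene, deletion = frameshift_worked_example()
eff = annotate(deletion, gene)
long = annotate(deletion, gene, long_frameshift_style=True)
print(f"gene: {gene.gene_id}, {gene.n_codons} codons on {gene.chromosome}")
print(f"variant: {deletion.change_label} at CDS nucleotide "
      f"{deletion.position - gene.cds_start + 1}")
print(f"effect: {eff.effect_class} -> {eff.label} (long style: {long.label})")
print(f"codon index {eff.codon_index}: ceil(664/3); "
      f"preserved upstream residues: {eff.preserved_residues}")

# a missense example: codon 12 is AAA (lysine), A>G makes it GAA (glutamate)
codons = ["ATG"] + ["GCT"] * 19
codons[11] = "AAA"
gene2 = GeneModel("DEMO", "chrI", 101, 100 + 3 * len(codons), "+",
                  "".join(codons))
snv = VariantRecord("chrI", gene2.cds_start + 3 * 11, "A", "G")
print(f"missense demo: {annotate(snv, gene2).label}")
# The frameshifted protein keeps residues 1-221 intact, the same count a
# truncation allele retaining 221 residues would preserve.
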