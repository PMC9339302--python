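# Methods

## Suppressor-screen model

The simulated screen mirrors the standard pooled-segregant design for a
spontaneous suppressor in a haploid yeast-like organism.

**Genome.** A scaled-down genome of `n_chromosomes` chromosomes (named
`chrI`… in roman numerals), each carrying non-overlapping single-interval
genes with explicit CDS sequences (initiator ATG, sense codons, terminal
stop, no internal stop). Coordinates are 1-based inclusive everywhere,
matching the `chrXVI_65946` locus notation used in screen summary
tables. Defaults (4 chromosomes × 5 genes × 300 codons) keep simulations
fast while exercising all coordinate logic; the genome is a stand-in for
a real reference, not a model of one.

**Founder.** The revertant founder carries one suppressor — a 1-bp
coding deletion in a random gene, i.e. a loss-of-function allele, the
class such screens usually recover — plus `m` passenger SNVs at random
distinct positions (chromosomes weighted by length). All variants are
heterozygous in the backcross diploid.

**Backcrosses and segregation.** `n_backcrosses` (default 2) rounds of
crossing to wildtype: each intermediate round carries forward a single
revertant-phenotype spore, and the final cross is sporulated to yield
the pooled segregants. Phenotype selection conditions every spore on the
suppressor allele. Two recombination models exist:

- `unlinked` (default): every passenger is an independent fair coin per
  spore. The screen's own logic treats passengers as segregating
  randomly, and most passengers are on other chromosomes.
- `haldane`: within each chromosome, haplotype inheritance is a Markov
  walk across loci ordered by position with recombination probability
  r = (1 − e^(−2d/100))/2 between neighbours at map distance
  d = |Δbp|/1000 · `map_cM_per_kb` (default 0.35 cM/kb, the usual
  budding-yeast average). On the suppressor's chromosome the walk is
  anchored at the suppressor when selection is on. This is the knob that
  produces intermediate fixed-adjacent frequencies for linked
  passengers; pairwise interference is not modelled.

A consequence of carrying one spore per intermediate round is that each
unlinked passenger *survives* a round with probability 1/2; a passenger
lost in round 1 sits at frequency 0 in every pool. Among passengers
still segregating in the final cross, the per-segregant expectation is
exactly 1/2 — this conditional 0.5, which is what a summary table of
observed mutations reflects, is the property the test suite checks.

**Pools and sequencing noise.** A pool of `k` segregants (default 6) has
true allele frequency = carriers/k at every founder locus; the
suppressor is exactly 1.0 whenever selection is on. Sequencing is
modelled per locus as depth ~ Poisson(depth) and alt reads ~
Binomial(depth, f(1−e) + (1−f)e) with per-read error e; the observed
frequency is the alt-read ratio. Defaults depth = 100 and e = 0.001 are
this package's choices of a realistic short-read pooled design (the
depth of any given study is rarely critical here; at 100× the fixation
filter at 0.95 is separated from the noise floor by many standard
deviations). A locus that draws zero reads is recorded with depth 0 and
frequency 0 and is removed by the depth gate downstream. No read-level
simulation, base qualities, alignment or mapping bias are modelled.

## Inference

`filter_fixed` keeps records with frequency ≥ `min_frequency` (default
0.95 — observed frequencies are finite-depth read ratios, so demanding
exactly 1.0 would be brittle; when filtering an exactly printed summary
table, pin it to 1.0) and depth ≥ `min_depth` when depth is recorded,
minus an `exclude_genes` list (the in-silico stand-in for discarding
candidates already explained by complementation). `intersect_pools`
matches fixed variants across pools by (chromosome, position, alt);
gene-level matching is a flag, because independent alleles of one gene
in different revertants implicate the gene even when the variants
differ. `expected_false_fixed(m, k, n_pools) = m·(2^−k)^n_pools` is the
chance expectation for unlinked passengers; it ignores linkage and the
survival attrition of intermediate backcrosses, so it is an upper bound
for the simulated design. `rank_candidates` orders
frameshift/nonsense > missense > other, then mean frequency, then
coordinate.

## Variant I/O conventions

Canonical in-memory indel coordinates use the *first altered base*; the
VCF representation is left-aligned with an anchor base at position − 1
(so a VCF row `REF=TACTT ALT=T` at 65946 is the ACTT deletion whose
first deleted base is 65947). When a record originates from the
summary-TSV dialect there is no reference sequence to supply the anchor,
and `write_vcf` emits `N`; records read from VCF keep their real anchor
and round-trip losslessly. Whether a printed summary table's deletion
position denotes the first deleted base or the VCF anchor is not
decidable from the table itself; this package adopts the first-deleted-
base reading and documents it here. Multi-allelic VCF sites are split
into biallelic records, one AF each.

## Coding-effect annotation

Codons are numbered 1-based from the initiator ATG. SNVs are translated
on the coding strand (minus-strand genes handled in coding orientation)
and classified missense/synonymous/nonsense at codon ⌈offset/3⌉. Indels
with length ≢ 0 (mod 3) are frameshifts, reported at the codon
containing the leftmost altered base in coding orientation — so a 4-base
deletion starting at CDS nucleotide 664 is a frameshift at codon 222
that preserves residues 1–221, the same count a truncation allele
retaining 221 residues keeps. In-frame indels are labelled but not
interpreted further. Only the standard nuclear code is supported; splice
sites, UTRs and regulatory effects are out of scope. The bundled
worked-example gene models are synthetic fixtures engineered so the
annotator reproduces each printed annotation string at the printed
genomic coordinate; real reference gene structures are not bundled.

A brute-force oracle (apply the edit to the whole CDS, translate both,
diff the proteins) backs the test suite. One subtlety: after a
frameshift the shifted codon can by chance encode the wildtype residue,
in which case the first protein divergence falls *after* the annotated
codon; the property tests assert equality exactly when the shifted
residue differs and ≥ otherwise.

## Condensation scoring

**Rendering.** Each nucleus is an isotropic 2-D Gaussian whose full
width at the segmentation threshold equals θ·D, with D the wildtype mass
diameter (default 62 px) and θ ∈ (0,1] the compaction parameter; θ = 1
reproduces a wildtype-sized mass and smaller θ emulates
hypercondensation. Optional thin bright protrusions (width 3 px, length
20 px by default) attach to the mass perimeter to emulate rDNA loops.
Additive Gaussian noise completes the field. Rendering is geometry, not
chromatin texture: the classifier only consumes area and boundary
geometry, so blobs suffice. Images are written as 16-bit TIFF with a
JSON ground-truth sidecar.

**Scoring.** Masses are 8-connected components above an Otsu or fixed
threshold, ≥ `min_area_px` (50). A mass whose footprint dilated by 4 px
touches another mass is omitted from all percentages (boundaries
obscured). Protrusions thinner than 7 px are removed by morphological
opening with a disk of radius ⌊7/2⌋ before scoring; a mass that is thin
everywhere has no core and is unscorable. The ROI template — read as a
*diameter* 62 px circle, since a 62 px radius would dwarf a yeast
nucleus at typical magnification — is centred on the core centroid
(template placement is otherwise unspecified in manual scoring; centroid
placement is the neutral choice). A mass matches when covered template
area ≥ `fill_fraction` (0.90; exact 1.0 would fail on pixelated edges)
**or** when ≥ `edge_fraction` (0.75) of the template boundary lies
within `edge_tolerance_px` (2) of the mass. The boundary test samples
the exact circle densely and reads an interpolated Euclidean distance
transform, minus half a pixel because the EDT measures to foreground
pixel *centres*; this keeps the criterion stable at sub-pixel margins.
The "filled or contacted most of the edges" wording of manual template
scoring is inherently ambiguous between the two criteria, so both are
implemented with OR semantics.

On noiseless rendered blobs the classifier is provably equivalent to the
analytic rule "matched iff θ² ≥ 0.90 or (D/2)(1−θ) ≤ 2 px", and the
mean matched percentage is non-increasing in compaction — these are the
properties the acceptance tests check. Because the physical pixel scale
of any particular microscope/camera setup is unrecoverable, validation
is relative and synthetic only; percentages measured on real micrographs
from other rigs are not reproduction targets. Passing these tests shows
the scoring operators are correct on clean geometry; it does not show
robustness to focus drift, uneven staining, or textured chromatin, which
the generator does not emulate.

## Statistics

`chi_square_gof` (Σ(O−E)²/E, df = c−1) and `chi_square_independence`
(E_ij = row·col/N, df = (r−1)(c−1), no Yates correction — the plain
test-of-independence formula) take their upper-tail p-values from the
regularized incomplete gamma function Q(df/2, x/2). `t_two_sample` is
the two-tailed Student test on per-field percentages (pooled variance,
df = n_a+n_b−2), with Welch as an option; both zero-variance samples
degenerate to p = 1 (equal means) or a flagged p = 0. scipy's
distribution functions serve as independent oracles in the tests, never
as the statistic implementation. The printed p-values of any specific
published condensation experiment are not reconstruction targets: the
exact observed/expected table underlying a chi-square on matched-mass
counts is not recoverable from percentages and totals alone, so the
package exposes both a goodness-of-fit against wildtype-derived
proportions and a 2×2 independence test and leaves the choice to the
analyst.

## Reproducibility and problem sizes

Seeds are explicit arguments everywhere; there is no global RNG state.
`RunConfig` fans one global seed out to named per-stage streams, and CLI
runs write a manifest (config, hash, seed, version). The test suite uses
deliberately small problem sizes — 10,000-pool Monte Carlo checks for
the 2^−k fixation law, 500 simulated screens for end-to-end recovery,
a handful of 512×512 fields per compaction level — chosen so the
binomial standard errors quoted in each test make the checks sharp.

## Known limitations

- Passenger SNVs are uniform over the genome; no mutational spectrum.
- Haldane linkage ignores crossover interference and models pairwise
  distances along the locus order only.
- The condensation generator renders non-overlapping, in-focus,
  isotropic masses; overlap handling is exercised with constructed
  images rather than rendered fields.
- `expected_false_fixed` assumes unlinked passengers and no attrition
  from intermediate backcrosses (a conservative upper bound).
- VCF support covers SNVs and anchored indels with INFO AF/DP only; no
  genotype columns, structural variants or BAM/CRAM.
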