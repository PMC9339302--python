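# poolseg

Pooled-segregant suppressor mapping and chromosome-condensation ROI
scoring for budding-yeast genetics, with a synthetic-data generator that
makes every stage verifiable against known ground truth.

## The problem

A spontaneous suppressor screen isolates revertants — strains in which a
second-site mutation rescues a conditional growth defect. Each revertant
carries the causal suppressor plus unrelated passenger mutations. After
backcrossing the revertant to wildtype and pooling *k* phenotype-selected
haploid segregants (by default *k* = 6), pooled whole-genome sequencing
shows the suppressor at allele frequency 1.0 (every selected segregant
carries it), while each unlinked passenger segregates as a fair coin and
lands at a multiple of 1/*k*. The inference is therefore:

1. keep the (near-)fixed variants in each pool
   (frequency ≥ 1 − ε; ε accommodates finite sequencing depth),
2. intersect the fixed sets across independent pools,
3. annotate coding consequences and rank protein-truncating alleles first.

The expected number of passengers fixed in all pools by chance is

    E[false fixed] = m · (2^−k)^n_pools

so with m = 8 passengers, pools of 6, and 2 pools: 8/4096 ≈ 0.002 — the
intersection is essentially noise-free.

A second component quantifies chromosome condensation the way manual
template scoring of DAPI-stained nuclei does: segment DNA masses,
discard masses whose boundaries are obscured by a neighbour, prune thin
rDNA-loop-like protrusions by morphological opening, centre a fixed
circular ROI (62 px diameter) on each mass, and call the mass *matched*
when it fills ≥ 90% of the template area **or** contacts ≥ 75% of the
template boundary within 2 px. Hypercondensed masses fail both criteria;
the readout is the per-field matched percentage, compared across strains
by chi-square and two-tailed t-tests.

## Worked example

`examples/02_bundled_revertant_pools.py` runs the full inference on the
bundled pooled-variant tables of two revertant segregant pools:

```
pool_A: 9 variants, fixed at 1.00: CLN2, SMC2
pool_B: 5 variants, fixed at 1.00: CLN2, RPL31A
shared across pools: CLN2 chrXVI_65946 delACTT (A=1.00, B=1.00)
pool_A coding effects: T222fs, K407E, S233T, V139L, L588F, Y87fs, E654D, W137C, T13I
```

Each pool contains exactly two fixed variants, but only the CLN2
frameshift (a 4-base ACTT deletion that shifts the frame at threonine
222, truncating the protein after residue 221) is fixed in *both* pools
— the signature of the causal suppressor arising independently in two
revertants. The other examples simulate a screen end to end
(`01_simulate_and_map_suppressor.py`), score synthetic DAPI fields and
compare conditions with a t-test (`03_condensation_scoring.py`), and
walk through the frameshift codon arithmetic
(`04_annotate_frameshift.py`).

A thin CLI wraps the same library calls:

```bash
poolseg simulate-screen --seed 7 --m 10 --out run/
poolseg call-suppressors run/pool_A.vcf run/pool_B.vcf --min-frequency 0.95
poolseg simulate-fields --theta 0.8 --n-fields 5 --out fields/
poolseg score-condensation fields/*.tif --out scores/
poolseg stats --chi-gof counts.csv --proportions 0.5,0.5
```

## Layout

- `src/poolseg/genome.py`, `screen.py`, `imaging.py` — synthetic data:
  genomes/gene models, backcross + pooling + sequencing-noise simulation,
  DAPI-like field rendering with ground truth
- `src/poolseg/variants.py` — VCF (AF/DP), summary-TSV dialect, BED12/GFF3
  gene models
- `src/poolseg/effects.py` — coding-effect annotation (K407E / Y87fs
  naming)
- `src/poolseg/inference.py` — fixation filter, cross-pool intersection,
  chance-fixation expectation, candidate ranking
- `src/poolseg/condensation.py` — mass segmentation, loop pruning,
  ROI-mask classification, field scoring
- `src/poolseg/stats.py` — chi-square (goodness of fit, independence) and
  two-sample t-test
- `docs/methods.md` — models, assumptions, parameter choices, limitations
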