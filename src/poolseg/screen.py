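"""Simulated spontaneous-suppressor screens.

A haploid revertant founder carries one suppressor mutation plus ``m``
unlinked passenger heterozygosities (relative to the wildtype parent).
The founder is backcrossed to wildtype a configurable number of times
(default 2); at each round a single revertant-phenotype spore is carried
forward, and the final cross is sporulated to yield phenotype-selected
segregants. Segregants are pooled (default 6 per pool, the usual pooled
sequencing design) and "sequenced" with Poisson depth and binomial
alt-read counting, so the causal allele sits at pool frequency 1.0 while
passengers segregate to multiples of 1/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .genome import GenomeSpec
from .variants import (
    PoolFrequencyRecord,
    PoolFrequencyTable,
    VariantRecord,
)

__all__ = [
    "FounderStrain",
    "CrossSpec",
    "PoolSpec",
    "SegregantGenotype",
    "spawn_revertant",
    "draw_segregants",
    "make_pool",
    "sequence_pool",
    "simulate_screen",
    "write_ground_truth",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class FounderStrain:
    """The revertant isolate: one suppressor + m passenger mutations."""

    suppressor: VariantRecord
    passengers: tuple[VariantRecord, ...]

    def __post_init__(self) -> None:
        loci = [(v.chromosome, v.position) for v in self.variants]
        if len(set(loci)) != len(loci):
            raise ValueError("founder variant loci must be pairwise distinct")

    @property
    def m(self) -> int:
        return len(self.passengers)

    @property
    def variants(self) -> tuple[VariantRecord, ...]:
        return (self.suppressor,) + tuple(self.passengers)


@dataclass(frozen=True)
class CrossSpec:
    """Backcross design and recombination model.

    ``unlinked`` treats every pair of loci as independent;
    ``haldane`` applies the Haldane map function
    ``r = (1 - exp(-2 d / 100)) / 2`` between neighbouring loci on a
    chromosome, with map distance ``d = |Δbp| / 1000 * map_cM_per_kb``.
    """

    n_backcrosses: int = 2
    recombination_model: str = "unlinked"
    map_cM_per_kb: float = 0.35
    select_revertant_phenotype: bool = True

    def __post_init__(self) -> None:
        if self.n_backcrosses < 1:
            raise ValueError("n_backcrosses must be >= 1")
        if self.recombination_model not in ("unlinked", "haldane"):
            raise ValueError("recombination_model must be 'unlinked' or 'haldane'")


@dataclass(frozen=True)
class PoolSpec:
    """Pool size and sequencing-noise model parameters."""

    k: int = 6
    depth: float = 100.0
    base_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")


@dataclass
class SegregantGenotype:
    """Haploid allele vector over the founder's mutated loci (0 wt, 1 mut)."""

    alleles: dict[VariantRecord, int]

    def carries(self, variant: VariantRecord) -> bool:
        return self.alleles.get(variant, 0) == 1


def spawn_revertant(genome: GenomeSpec, m: int, seed: int) -> FounderStrain:
    """Draw a revertant founder with 1 suppressor and ``m`` passengers.

    The suppressor is a 1-bp coding deletion in a random gene (a
    loss-of-function allele, as suppressors recovered in such screens
    typically are); passengers are SNVs at random distinct genomic
    positions, coding or not.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    rng = np.random.default_rng(seed)
    sizes = genome.chromosome_sizes
    total = sum(sizes.values())
    if total < m + 1 or not genome.genes:
        raise ValueError("genome has too few mutable loci for m passengers")

    gene = genome.genes[rng.integers(len(genome.genes))]
    sup_pos = int(rng.integers(gene.cds_start, gene.cds_end + 1))
    suppressor = VariantRecord(
        chromosome=gene.chromosome,
        position=sup_pos,
        ref_allele=gene.genomic_base(sup_pos),
        alt_allele="",
        gene_id=gene.gene_id,
    )

    chrom_names = list(sizes)
    weights = np.array([sizes[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    taken = {(suppressor.chromosome, suppressor.position)}
    passengers: list[VariantRecord] = []
    while len(passengers) < m:
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        pos = int(rng.integers(1, sizes[chrom] + 1))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        hit = genome.gene_at(chrom, pos)
        ref = hit.genomic_base(pos) if hit is not None else _BASES[rng.integers(4)]
        alt = _BASES[rng.integers(4)]
        while alt == ref:
            alt = _BASES[rng.integers(4)]
        passengers.append(
            VariantRecord(
                chromosome=chrom, position=pos, ref_allele=ref, alt_allele=alt,
                gene_id=hit.gene_id if hit is not None else None,
            )
        )
    return FounderStrain(suppressor=suppressor, passengers=tuple(passengers))


def _haldane_r(d_cM: float) -> float:
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def _meiosis_spore(
    carrier: dict[VariantRecord, int],
    founder: FounderStrain,
    cross: CrossSpec,
    rng: np.random.Generator,
) -> dict[VariantRecord, int]:
    """One spore of carrier x wildtype, conditioned on the suppressor when
    phenotype selection is on.

    The spore inherits, at each locus, either the carrier (mutant-derived)
    or the wildtype haplotype. Under ``haldane`` the haplotype choice is a
    Markov walk along each chromosome with Haldane recombination
    probabilities between adjacent loci; the walk on the suppressor's
    chromosome is anchored at the suppressor when selection is on.
    """
    select = cross.select_revertant_phenotype
    spore: dict[VariantRecord, int] = {}

    if cross.recombination_model == "unlinked":
        for v in founder.variants:
            from_carrier = bool(rng.random() < 0.5)
            if select and v is founder.suppressor:
                from_carrier = True
            spore[v] = carrier[v] if from_carrier else 0
        if select:
            spore[founder.suppressor] = 1
        return spore

    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in founder.variants:
        by_chrom.setdefault(v.chromosome, []).append(v)
    for chrom, loci in by_chrom.items():
        loci = sorted(loci, key=lambda v: v.position)
        anchored = select and founder.suppressor.chromosome == chrom
        if anchored:
            start = next(i for i, v in enumerate(loci) if v is founder.suppressor)
        else:
            start = 0
        state = True if anchored else bool(rng.random() < 0.5)
        # haplotype walk outward from the anchor in both directions
        states: dict[VariantRecord, bool] = {loci[start]: state}
        for direction in (1, -1):
            h = state
            idx = start
            while 0 <= idx + direction < len(loci):
                a, b = loci[idx], loci[idx + direction]
                d_cM = abs(b.position - a.position) / 1000.0 * cross.map_cM_per_kb
                if rng.random() < _haldane_r(d_cM):
                    h = not h
                states[b] = h
                idx += direction
        for v in loci:
            spore[v] = carrier[v] if states[v] else 0
    if select:
        spore[founder.suppressor] = 1
    return spore


def draw_segregants(
    founder: FounderStrain,
    cross: CrossSpec,
    n: int,
    seed: int,
) -> list[SegregantGenotype]:
    """Backcross the founder and draw ``n`` selected segregants.

    ``cross.n_backcrosses - 1`` intermediate rounds each carry forward a
    single revertant spore (so unlinked passengers survive each round
    with probability 1/2); the final cross is sporulated ``n`` times.
    With phenotype selection on, every returned segregant carries the
    suppressor.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    carrier = {v: 1 for v in founder.variants}
    for _ in range(cross.n_backcrosses - 1):
        carrier = _meiosis_spore(carrier, founder, cross, rng)
    return [
        SegregantGenotype(alleles=_meiosis_spore(carrier, founder, cross, rng))
        for _ in range(n)
    ]


def make_pool(
    segregants: list[SegregantGenotype], pool: PoolSpec
) -> dict[VariantRecord, float]:
    """True (noise-free) pooled allele frequencies: carriers / k."""
    if len(segregants) != pool.k:
        raise ValueError(
            f"pool expects exactly k={pool.k} segregants, got {len(segregants)}"
        )
    loci = list(segregants[0].alleles)
    return {
        v: sum(s.alleles.get(v, 0) for s in segregants) / pool.k for v in loci
    }


def sequence_pool(
    true_freqs: Mapping[VariantRecord, float],
    pool: PoolSpec,
    pool_id: str = "pool",
) -> PoolFrequencyTable:
    """Observe pooled frequencies under sequencing noise.

    Per locus: ``depth_i ~ Poisson(depth)`` and alt reads
    ``~ Binomial(depth_i, f (1 - e) + (1 - f) e)`` with per-read error
    ``e``; the observed frequency is the alt-read ratio (0 when a locus
    happens to draw zero reads, recorded with depth 0).
    """
    rng = np.random.default_rng(pool.seed)
    records = []
    for variant, f in true_freqs.items():
        d = int(rng.poisson(pool.depth))
        p = f * (1.0 - pool.base_error) + (1.0 - f) * pool.base_error
        alt = int(rng.binomial(d, p)) if d > 0 else 0
        records.append(
            PoolFrequencyRecord(
                variant=variant,
                frequency=alt / d if d > 0 else 0.0,
                depth=d,
                pool_id=pool_id,
            )
        )
    return PoolFrequencyTable(pool_id=pool_id, records=records)


def simulate_screen(
    genome: GenomeSpec,
    m: int,
    n_pools: int,
    cross: CrossSpec,
    pool: PoolSpec,
    seed: int,
) -> tuple[FounderStrain, list[PoolFrequencyTable], list[dict[VariantRecord, float]]]:
    """Full screen: founder -> backcrosses -> pools -> noisy frequency tables.

    Each pool draws its own segregants from an independently repeated
    backcross of the same founder (pools A, B, ... of one revertant).
    Returns (founder, observed tables, true per-pool frequencies).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * n_pools + 1, dtype=np.uint32)
    founder = spawn_revertant(genome, m, int(child[0]) % 2**31)
    tables, truths = [], []
    for i in range(n_pools):
        segs = draw_segregants(
            founder, cross, pool.k, int(child[1 + 2 * i]) % 2**31
        )
        truth = make_pool(segs, pool)
        pool_i = replace(pool, seed=int(child[2 + 2 * i]) % 2**31)
        pool_id = f"pool_{chr(ord('A') + i)}" if i < 26 else f"pool_{i}"
        tables.append(sequence_pool(truth, pool_i, pool_id=pool_id))
        truths.append(truth)
    return founder, tables, truths


def write_ground_truth(
    founder: FounderStrain,
    truths: list[dict[VariantRecord, float]],
    path: str | Path,
) -> None:
    """Tab-separated ground truth: locus, gene, is_suppressor, per-pool truth."""
    import pandas as pd

    rows = []
    for v in founder.variants:
        row = {
            "locus": f"{v.chromosome}_{v.position}",
            "change": v.change_label,
            "gene": v.gene_id or "",
            "is_suppressor": int(v is founder.suppressor),
        }
        for i, truth in enumerate(truths):
            label = chr(ord("A") + i) if i < 26 else str(i)
            row[f"true_frequency_pool_{label}"] = truth[v]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
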