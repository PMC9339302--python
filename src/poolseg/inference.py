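"""Suppressor inference from pooled segregant allele frequencies.

The causal (suppressor) allele is carried by every phenotype-selected
segregant, so it sits at pool frequency 1.0, while unlinked passenger
mutations segregate randomly and land at multiples of 1/k. Keeping the
(near-)fixed variants in each pool and intersecting across independent
pools isolates the suppressor; the expected number of passengers fixed
in all pools by chance is ``m * (2^-k)^n_pools``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .effects import EffectAnnotation
from .variants import PoolFrequencyRecord, PoolFrequencyTable, VariantRecord

__all__ = [
    "FilterSpec",
    "SharedCandidate",
    "CandidateReport",
    "filter_fixed",
    "intersect_pools",
    "expected_false_fixed",
    "rank_candidates",
]


@dataclass(frozen=True)
class FilterSpec:
    """Fixation filter: epsilon-tolerant frequency floor plus depth gate.

    ``min_frequency`` defaults to 0.95 because observed frequencies are
    finite-depth read ratios; pin it to 1.0 when filtering exact printed
    tables. ``exclude_genes`` drops known hits (the in-silico analogue of
    discarding candidates already explained by complementation).
    """

    min_frequency: float = 0.95
    min_depth: int = 10
    exclude_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.min_frequency <= 1.0:
            raise ValueError("min_frequency must be in (0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class SharedCandidate:
    """A variant fixed in every pool, with its per-pool frequencies."""

    variant: VariantRecord
    gene_id: str | None
    frequencies: dict[str, float]  # pool_id -> observed frequency
    annotation: EffectAnnotation | None = None

    @property
    def mean_frequency(self) -> float:
        return sum(self.frequencies.values()) / len(self.frequencies)


@dataclass
class CandidateReport:
    """Outcome of cross-pool intersection of fixed variants."""

    shared_candidates: list[SharedCandidate]
    per_pool_fixed: dict[str, list[PoolFrequencyRecord]]
    expected_false_fixed: float

    def __post_init__(self) -> None:
        fixed_keys = {
            pool: {r.variant.key() for r in recs}
            for pool, recs in self.per_pool_fixed.items()
        }
        for cand in self.shared_candidates:
            for pool, keys in fixed_keys.items():
                if cand.variant.key() not in keys and not any(
                    r.variant.gene_id == cand.gene_id and cand.gene_id
                    for r in self.per_pool_fixed[pool]
                ):
                    raise ValueError(
                        f"shared candidate {cand.variant.change_label} absent "
                        f"from fixed set of pool {pool!r}"
                    )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "expected_false_fixed": self.expected_false_fixed,
            "shared_candidates": [
                {
                    "gene": c.gene_id,
                    "chromosome": c.variant.chromosome,
                    "position": c.variant.position,
                    "change": c.variant.change_label,
                    "annotation": c.annotation.label if c.annotation else None,
                    "frequencies": c.frequencies,
                }
                for c in self.shared_candidates
            ],
            "per_pool_fixed": {
                pool: [
                    {
                        "chromosome": r.variant.chromosome,
                        "position": r.variant.position,
                        "change": r.variant.change_label,
                        "gene": r.variant.gene_id,
                        "frequency": r.frequency,
                    }
                    for r in recs
                ]
                for pool, recs in self.per_pool_fixed.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for c in self.shared_candidates:
            row = {
                "gene": c.gene_id or "",
                "chromosome": c.variant.chromosome,
                "position": c.variant.position,
                "change": c.variant.change_label,
                "annotation": c.annotation.label if c.annotation else "",
            }
            row.update({f"freq_{p}": f for p, f in c.frequencies.items()})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_fixed(
    table: PoolFrequencyTable, spec: FilterSpec = FilterSpec()
) -> list[PoolFrequencyRecord]:
    """Variants at (near-)fixation in one pool, in input order.

    Keeps records with ``frequency >= min_frequency`` whose depth, when
    recorded, is at least ``min_depth``, excluding listed genes.
    """
    out = []
    for rec in table.records:
        if rec.frequency < spec.min_frequency:
            continue
        if rec.depth is not None and rec.depth < spec.min_depth:
            continue
        if rec.variant.gene_id and rec.variant.gene_id in spec.exclude_genes:
            continue
        out.append(rec)
    return out


def intersect_pools(
    tables: Sequence[PoolFrequencyTable],
    spec: FilterSpec = FilterSpec(),
    gene_level: bool = False,
) -> CandidateReport:
    """Intersect fixed variants across pools.

    Matching is variant-level — (chromosome, position, alt) — by default;
    ``gene_level=True`` instead matches by gene so independent alleles of
    one gene arising in different revertants still implicate the gene.
    ``expected_false_fixed`` in the report assumes pools of equal size
    k = 6 unless recomputed by the caller; it is informational only.
    """
    if len(tables) == 0:
        raise ValueError("intersect_pools requires at least one pool")
    ids = [t.pool_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate pool_ids: {ids}")
    if len(tables) == 1:
        warnings.warn(
            "intersecting a single pool: every fixed variant is a candidate",
            stacklevel=2,
        )
    per_pool_fixed = {t.pool_id: filter_fixed(t, spec) for t in tables}

    def match_key(rec: PoolFrequencyRecord):
        if gene_level and rec.variant.gene_id:
            return ("gene", rec.variant.gene_id)
        return ("variant",) + rec.variant.key()

    keysets = [
        {match_key(r) for r in recs} for recs in per_pool_fixed.values()
    ]
    shared_keys = set.intersection(*keysets)

    first_pool = tables[0].pool_id
    shared: list[SharedCandidate] = []
    for rec in per_pool_fixed[first_pool]:
        k = match_key(rec)
        if k not in shared_keys:
            continue
        freqs = {}
        for pool, recs in per_pool_fixed.items():
            hit = next(r for r in recs if match_key(r) == k)
            freqs[pool] = hit.frequency
        ann = rec.annotation if isinstance(rec.annotation, EffectAnnotation) else None
        shared.append(
            SharedCandidate(
                variant=rec.variant,
                gene_id=rec.variant.gene_id,
                frequencies=freqs,
                annotation=ann,
            )
        )
    # the per-pool mean passenger count is unknown here; report the chance
    # expectation for the canonical design (k = 6) scaled by observed pools
    m_obs = max(len(t) for t in tables) - 1
    eff = expected_false_fixed(max(m_obs, 0), 6, len(tables))
    return CandidateReport(
        shared_candidates=shared,
        per_pool_fixed=per_pool_fixed,
        expected_false_fixed=eff,
    )


def expected_false_fixed(m: int, k: int, n_pools: int) -> float:
    """Expected unlinked passengers fixed in all pools by chance.

    Each of ``m`` passengers reaches frequency 1.0 in a pool of ``k``
    selected segregants with probability ``2^-k``, independently across
    pools: returns ``m * (2^-k)^n_pools``.
    """
    if m < 0 or k < 1 or n_pools < 1:
        raise ValueError("require m >= 0, k >= 1, n_pools >= 1")
    return m * (2.0 ** -k) ** n_pools


_CLASS_RANK = {"frameshift": 0, "nonsense": 0, "missense": 1}


def rank_candidates(
    report: CandidateReport,
    annotations: Mapping[tuple[str, int, str], EffectAnnotation] | None = None,
) -> list[SharedCandidate]:
    """Order shared candidates by likely functional impact.

    Protein-truncating effects (frameshift, nonsense) first, then
    missense, then everything else; ties broken by mean frequency
    (descending) then genomic coordinate.
    """
    def sort_key(c: SharedCandidate):
        ann = c.annotation
        if ann is None and annotations is not None:
            ann = annotations.get(c.variant.key())
        rank = _CLASS_RANK.get(ann.effect_class, 2) if ann else 2
        return (rank, -c.mean_frequency, c.variant.chromosome, c.variant.position)

    return sorted(report.shared_candidates, key=sort_key)
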