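"""Run configuration: one YAML document, one global seed.

The global seed fans out deterministically to per-stage streams via
named substreams, so re-running any stage with the same config
reproduces its output bit for bit while stages stay independent.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .condensation import MaskSpec
from .inference import FilterSpec
from .screen import CrossSpec, PoolSpec

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class SimulationConfig:
    m: int = 10
    k: int = 6
    n_pools: int = 2
    depth: float = 100.0
    base_error: float = 0.001
    backcrosses: int = 2
    n_chromosomes: int = 4
    genes_per_chromosome: int = 5
    cds_codons: int = 300

    def cross_spec(self) -> CrossSpec:
        return CrossSpec(n_backcrosses=self.backcrosses)

    def pool_spec(self, seed: int = 0) -> PoolSpec:
        return PoolSpec(k=self.k, depth=self.depth,
                        base_error=self.base_error, seed=seed)


@dataclass
class RunConfig:
    """Seed + parameter blocks for every pipeline stage."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    mask: MaskSpec = field(default_factory=MaskSpec)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.get("simulation", {}))
        filt_raw = dict(raw.get("filter", {}))
        if "exclude_genes" in filt_raw:
            filt_raw["exclude_genes"] = tuple(filt_raw["exclude_genes"])
        filt = FilterSpec(**filt_raw)
        mask = MaskSpec(**raw.get("mask", {}))
        return cls(
            seed=int(raw.get("seed", 0)),
            simulation=sim,
            filter=filt,
            mask=mask,
            paths=dict(raw.get("paths", {})),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulation": asdict(self.simulation),
            "filter": {
                "min_frequency": self.filter.min_frequency,
                "min_depth": self.filter.min_depth,
                "exclude_genes": list(self.filter.exclude_genes),
            },
            "mask": asdict(self.mask),
            "paths": self.paths,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
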