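"""Run configuration: every tunable threshold with its default."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    """Pipeline thresholds.

    Defaults follow the method's operating point: a 248-nt pseudo-reference
    (124 nt per side) with an 8-nt seed (4 nt per side of the junction),
    minimum A-tailing junction count 2, resistance cutoff at the 0.95
    linear-ratio quantile, split-junction support >= 3, switch test at
    p < 0.05 with inclusion difference > 0.2, and the top decile of
    context++ scores for miRNA top targets.
    """

    flank: int = 124
    seed_flank: int = 4
    max_mismatch: int = 3
    min_overlap: int = 48
    kmer: int = 12
    remap_kmer: int = 16
    min_count: int = 2
    quantile: float = 0.95
    pseudocount: float = 0.5
    min_split_reads: int = 3
    anchor: int = 8
    switch_alpha: float = 0.05
    min_inclusion_diff: float = 0.2
    context_percentile: float = 0.90
    editing_alpha: float = 0.05
    min_editing_coverage: int = 10
    min_linear_refs: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_flank > self.flank:
            raise ValueError("seed_flank exceeds flank")
        for q in (self.quantile, self.context_percentile):
            if not 0 < q < 1:
                raise ValueError("quantiles must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
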