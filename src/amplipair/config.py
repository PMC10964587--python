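"""Pipeline configuration: one YAML file, every threshold defaulted.

The defaults are the study's operating point: bootstrap confidence floor 80,
best-hit identity floor 97%, full query coverage, 2-point identity gap,
rarefaction depth 4500, top-20 taxa for concordance, 0.1% presence
threshold, 999 permutations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # taxonomy assignment
    kmer_k: int = 8
    n_boot: int = 100
    min_conf: float = 80.0
    min_identity: float = 97.0
    min_coverage: float = 100.0
    gap: float = 2.0
    restrict_to_genus: bool = False
    # diversity
    rarefaction_depth: int = 4500
    # platform comparison
    top_n: int = 20
    shared_threshold: float = 0.1  # percent mean relative abundance
    n_permutations: int = 999
    # randomness
    seed: int = 0
    # file paths (optional; analysis drivers and CLI fill these in)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)
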