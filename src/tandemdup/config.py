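"""Pipeline configuration: the three length scales and every threshold.

min_unit_length (ℓ, 500 bp) is the smallest reportable duplication unit;
max_copy_gap (T, 150 kb) bounds the distance between copies of one array;
max_chain_gap (L, 40 kb) bounds the gap between chained anchors and is also
the margin added around each array region.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .anchoring import ScoringScheme


@dataclass
class Config:
    min_unit_length: int = 500          # ℓ
    max_copy_gap: int = 150_000         # T
    max_chain_gap: int = 40_000         # L
    max_out_edges: int = 15             # k, G1 out-degree cap
    min_overlap: float = 0.5            # G2 edge threshold
    min_unit_fraction: float = 0.5      # TU must cover this much of the unit
    detection_threshold: float = 0.70   # evaluation coverage criterion
    max_enlarge: float = 0.25           # TU enlargement per side
    search_mode: str = "translated"     # reconstruction search backend
    mask: bool = True                   # DUST preprocessing
    dust_window: int = 64
    dust_threshold: float = 20.0
    seed: int = 0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self):
        if self.min_unit_length <= 0:
            raise ValueError("min_unit_length must be > 0")
        if self.max_chain_gap > self.max_copy_gap:
            raise ValueError("max_chain_gap (L) must not exceed max_copy_gap (T)")
        for t in (self.min_overlap, self.min_unit_fraction, self.detection_threshold):
            if not (0 < t <= 1):
                raise ValueError("thresholds must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scoring" in d and isinstance(d["scoring"], dict):
            d["scoring"] = ScoringScheme(**d["scoring"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
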