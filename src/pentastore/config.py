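"""Run configuration: every tunable of the storage system in one place.

Defaults reproduce the canonical design: quinary alphabet (A,T,C,G,M),
22-byte segments, 100-letter oligos with a 12-digit address field, XOR
parity on, identity screen at 0.85, methylation threshold 128, piece
length window 80-120 nt, sequencing depth 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    alphabet: str = "ATCGM"
    segment_length: int = 22
    oligo_length: int = 100
    address_digits: int = 12
    with_xor: bool = True
    error_rate: float = 0.0
    error_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    min_identity: float = 0.85
    meth_threshold: int = 128
    length_window: tuple[int, int] = (80, 120)
    depth: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("error_mix", "length_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Read a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def table(self):
        from .codec import ExpandedAlphabet, build_rotation_table

        return build_rotation_table(ExpandedAlphabet.from_string(self.alphabet))
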