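"""Synthetic nanopore-like reads over methylated fragments.

Stands in for real long-read sequencing of assembled 5mC fragments: the
basecaller reports only the four natural bases, and every basecalled C
carries a methylation probability (an integer 0-255, the scale used by
BAM ML tags).  True 5mC positions tend to score high, plain cytosines
low; the confusion rates of the caller are configurable, as are per-base
substitution/insertion/deletion rates and flanking barcodes.

These reads emulate the *shape* of nanopore output (error mix, per-C
methylation scores, barcoded flanks), not its sequence-context error
biases or quality drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReadSimConfig", "ReadRecord", "simulate_reads", "make_read_set"]

BASES = "ACGT"


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters.

    Default noise is a modest nanopore-like profile: 0.5% substitutions,
    0.25% insertions, 0.25% deletions per base, and a 5% chance of the
    methylation caller scoring a site on the wrong side of the threshold
    in either direction.  Sequencing depth defaults to 10 reads per
    fragment.
    """

    depth: int = 10
    sub_rate: float = 0.005
    ins_rate: float = 0.0025
    del_rate: float = 0.0025
    meth_miss_rate: float = 0.05  # true-M site scored below threshold
    meth_false_rate: float = 0.05  # true-C site scored above threshold
    barcode_left: str = ""
    barcode_right: str = ""

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for name in ("sub_rate", "ins_rate", "del_rate", "meth_miss_rate", "meth_false_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.sub_rate + self.ins_rate + self.del_rate > 1.0:
            raise ValueError("per-base error rates sum above 1")


@dataclass
class ReadRecord:
    """One basecalled read: natural bases plus per-C methylation scores."""

    bases: str
    meth_probs: dict[int, int] = field(default_factory=dict)  # C position -> 0..255
    flanks: tuple[str, str] = ("", "")
    source_address: int | None = None

    def __post_init__(self):
        for pos, p in self.meth_probs.items():
            if self.bases[pos] != "C":
                raise ValueError(f"meth prob at non-C position {pos}")
            if not 0 <= p <= 255:
                raise ValueError(f"meth prob {p} outside 0..255")


def _sample_prob(high: bool, rng: np.random.Generator) -> int:
    """A methylation score on the requested side of the 128 threshold."""
    return int(rng.integers(128, 256)) if high else int(rng.integers(0, 128))


def simulate_reads(
    fragment: str,
    cfg: ReadSimConfig,
    rng: np.random.Generator,
    source_address: int | None = None,
) -> list[ReadRecord]:
    """Generate ``cfg.depth`` noisy reads of a fragment (letters incl. M).

    Each read renders M as C, applies independent per-base errors
    (substitution to a different natural base, insertion of a uniform
    base after the position, deletion), samples a methylation score for
    every basecalled C (high at surviving true-M sites, low elsewhere,
    subject to the confusion rates) and attaches the barcodes.
    Deterministic for a fixed generator state.
    """
    if not fragment:
        raise ValueError("empty fragment")
    template = [("C", True) if c == "M" else (c, False) for c in fragment]
    reads = []
    p_sub, p_ins, p_del = cfg.sub_rate, cfg.ins_rate, cfg.del_rate
    for _ in range(cfg.depth):
        out: list[tuple[str, bool]] = [(c, False) for c in cfg.barcode_left]
        for base, is_m in template:
            u = rng.random()
            if u < p_del:
                continue
            if u < p_del + p_sub:
                others = [b for b in BASES if b != base]
                out.append((others[rng.integers(3)], False))
            else:
                out.append((base, is_m))
                if u < p_del + p_sub + p_ins:
                    out.append((BASES[rng.integers(4)], False))
        out.extend((c, False) for c in cfg.barcode_right)
        bases = "".join(b for b, _ in out)
        probs: dict[int, int] = {}
        for i, (b, is_m) in enumerate(out):
            if b != "C":
                continue
            if is_m:
                high = rng.random() >= cfg.meth_miss_rate
            else:
                high = rng.random() < cfg.meth_false_rate
            probs[i] = _sample_prob(high, rng)
        reads.append(
            ReadRecord(bases, probs, (cfg.barcode_left, cfg.barcode_right), source_address)
        )
    return reads


def make_read_set(
    fragments: list[str],
    cfg: ReadSimConfig,
    seed: int = 0,
) -> list[ReadRecord]:
    """Reads for a whole store: ``depth`` reads per fragment, seeded."""
    reads = []
    for i, frag in enumerate(fragments):
        rng = np.random.default_rng([seed, i])
        reads.extend(simulate_reads(frag, cfg, rng, source_address=i))
    return reads
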