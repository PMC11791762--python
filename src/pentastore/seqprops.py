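"""GC content and homopolymer statistics of encoded sequences.

M is chemically a methylated cytosine, so it counts toward GC content
and, when collapsed to C, can form homopolymer runs even though the raw
rotational code never emits two identical letters in a row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codec import RotationTable, default_table
from .packets import encode_store

__all__ = ["PropertyReport", "gc_content", "max_homopolymer", "profile_encoding"]

GC_LETTERS = frozenset("GCM")


def gc_content(seq: str, count_m: bool = True) -> float:
    """Fraction of letters that are G, C or (by default) M.

    M is included because 5-methylcytosine is chemically a cytosine; pass
    ``count_m=False`` for a natural-bases-only sensitivity analysis.
    """
    if not seq:
        raise ValueError("empty sequence")
    targets = GC_LETTERS if count_m else frozenset("GC")
    return sum(c in targets for c in seq) / len(seq)


def max_homopolymer(seq: str, collapse_m_to_c: bool = True) -> int:
    """Longest run of identical symbols, optionally rewriting M to C first.

    With the collapse (the chemical reading) a raw encoded sequence can
    contain C-runs through alternating C/M; without it, raw rotational
    output always returns 1.
    """
    if not seq:
        raise ValueError("empty sequence")
    if collapse_m_to_c:
        seq = seq.replace("M", "C")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


@dataclass
class PropertyReport:
    """Per-oligo GC and homopolymer statistics with aggregate summaries."""

    gc: np.ndarray
    homopolymer: np.ndarray
    whole_stream_max_homopolymer: int | None = None
    gc_histogram: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)

    @property
    def gc_mean(self) -> float:
        return float(self.gc.mean())

    @property
    def gc_min(self) -> float:
        return float(self.gc.min())

    @property
    def gc_max(self) -> float:
        return float(self.gc.max())

    @property
    def gc_range(self) -> float:
        return self.gc_max - self.gc_min

    @property
    def max_homopolymer(self) -> int:
        return int(self.homopolymer.max())

    def as_dict(self) -> dict:
        return {
            "n_oligos": int(self.gc.size),
            "gc_mean": self.gc_mean,
            "gc_min": self.gc_min,
            "gc_max": self.gc_max,
            "gc_range": self.gc_range,
            "homopolymer_mean": float(self.homopolymer.mean()),
            "homopolymer_max": self.max_homopolymer,
            "whole_stream_max_homopolymer": self.whole_stream_max_homopolymer,
        }


def _per_oligo_stats(letters: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-oligo GC fraction and collapsed max run."""
    n = len(letters)
    L = len(letters[0])
    arr = np.frombuffer("".join(letters).encode("ascii"), dtype=np.uint8).reshape(n, L)
    coll = arr.copy()
    coll[coll == ord("M")] = ord("C")
    gc = ((coll == ord("C")) | (coll == ord("G"))).mean(axis=1)
    # run lengths: positions where letter differs from predecessor reset the run
    runs = np.ones((n, L), dtype=np.int32)
    same = coll[:, 1:] == coll[:, :-1]
    for j in range(1, L):  # cumulative run length, row-parallel
        runs[:, j] = np.where(same[:, j - 1], runs[:, j - 1] + 1, 1)
    return gc, runs.max(axis=1)


def profile_encoding(
    data: bytes,
    table: RotationTable | None = None,
    whole_stream: bool = False,
    histogram_bins: int = 20,
    with_xor: bool = True,
) -> PropertyReport:
    """Encode a file and report the GC/homopolymer profile of its oligos.

    ``whole_stream=True`` additionally reports the maximum collapsed run
    over the concatenation of all oligos (file-level statistics).
    """
    table = table or default_table()
    oligos, _ = encode_store(data, table, with_xor=with_xor)
    letters = [o.letters for o in oligos]
    if not letters:
        raise ValueError("no oligos encoded (empty input)")
    gc, homo = _per_oligo_stats(letters)
    stream_max = max_homopolymer("".join(letters)) if whole_stream else None
    hist = np.histogram(gc, bins=histogram_bins, range=(0.0, 1.0))
    return PropertyReport(gc, homo, stream_max, hist)
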