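"""Design of short ligation adaptors by composition and distance filtering.

Adaptors are 8-mers over the natural bases used as sticky ends to direct
ordered ligation of oligos into long fragments.  Candidates are screened
for biocompatibility (GC content 40-60%, homopolymer runs of at most 2)
and then separated by Hamming distance so that ligation junctions remain
mutually distinguishable.

Two distance-selection modes exist.  The *literal* all-pairs rule (keep a
candidate only if it is far from every other candidate) can annihilate
the set, because survivors of the composition filter come in close
clusters; *greedy* code construction (lexicographic scan, keep a
candidate if it is far from everything already kept) always yields a
maximal distance-separated set and is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "AdaptorSet",
    "enumerate_candidates",
    "composition_filter",
    "hamming",
    "select_adaptors",
    "reverse_complement",
    "design_adaptors",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class AdaptorSet:
    """A distance-separated adaptor collection."""

    adaptors: tuple[str, ...]
    min_pairwise_hamming: int

    def __len__(self) -> int:
        return len(self.adaptors)

    def __iter__(self):
        return iter(self.adaptors)

    def __getitem__(self, i):
        return self.adaptors[i]


def enumerate_candidates(length: int = 8) -> list[str]:
    """All 4^length sequences over {A,C,G,T} in lexicographic order."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return ["".join(p) for p in product(BASES, repeat=length)]


def _max_run(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def composition_filter(
    candidates: list[str],
    gc_bounds: tuple[float, float] = (0.4, 0.6),
    max_homopolymer: int = 2,
) -> list[str]:
    """Keep candidates with GC in ``gc_bounds`` (inclusive) and short runs.

    For 8-mers the default bounds admit exactly four G/C letters, since
    only 4/8 = 50% falls within [40%, 60%].
    """
    lo, hi = gc_bounds
    out = []
    for s in candidates:
        gc = sum(c in "GC" for c in s) / len(s)
        if lo <= gc <= hi and _max_run(s) <= max_homopolymer:
            out.append(s)
    return out


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _as_matrix(seqs: list[str]) -> np.ndarray:
    L = len(seqs[0])
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), L
    )


def select_adaptors(
    survivors: list[str],
    min_distance: int = 5,
    mode: str = "greedy",
    forbid_revcomp_clash: bool = False,
) -> AdaptorSet:
    """Select a Hamming-separated adaptor set from the composition survivors.

    ``literal``: keep s iff hamming(s, t) >= min_distance for *every other*
    survivor t (the all-pairs reading; may be empty).
    ``greedy``: scan survivors in order, keeping s iff it is at distance
    >= min_distance from everything already kept (maximal by construction).

    ``forbid_revcomp_clash`` additionally rejects a candidate equal to the
    reverse complement of an already-kept adaptor (greedy) or of any other
    survivor (literal).
    """
    if mode not in ("greedy", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    if not survivors:
        return AdaptorSet((), min_distance)
    M = _as_matrix(survivors)
    n = len(survivors)
    if mode == "literal":
        keep = np.ones(n, dtype=bool)
        chunk = 512
        for i in range(0, n, chunk):
            blk = M[i : i + chunk]
            d = (blk[:, None, :] != M[None, :, :]).sum(axis=2)
            for j in range(len(blk)):
                row = d[j]
                row[i + j] = len(survivors[0]) + min_distance  # ignore self
                if row.min() < min_distance:
                    keep[i + j] = False
        kept = [survivors[i] for i in np.nonzero(keep)[0]]
        if forbid_revcomp_clash:
            rcs = {reverse_complement(s) for s in survivors}
            kept = [s for s in kept if s not in rcs or s == reverse_complement(s)]
    else:
        kept = []
        kept_mat = None
        rc_seen: set[str] = set()
        for i, s in enumerate(survivors):
            if forbid_revcomp_clash and s in rc_seen:
                continue
            if kept_mat is not None:
                if int((M[i] != kept_mat).sum(axis=1).min()) < min_distance:
                    continue
            kept.append(s)
            kept_mat = M[i : i + 1] if kept_mat is None else np.vstack([kept_mat, M[i]])
            if forbid_revcomp_clash:
                rc_seen.add(reverse_complement(s))
    return AdaptorSet(tuple(kept), min_distance)


def design_adaptors(
    length: int = 8,
    min_distance: int = 5,
    mode: str = "greedy",
    gc_bounds: tuple[float, float] = (0.4, 0.6),
    max_homopolymer: int = 2,
    forbid_revcomp_clash: bool = False,
) -> AdaptorSet:
    """Full pipeline: enumerate, composition-filter, distance-select."""
    survivors = composition_filter(
        enumerate_candidates(length), gc_bounds, max_homopolymer
    )
    return select_adaptors(survivors, min_distance, mode, forbid_revcomp_clash)
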