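"""Pairwise alignment utilities over the expanded alphabet.

Thin wrappers around edlib, which treats M as an ordinary symbol (no
IUPAC interpretation).  Identity uses a semi-global alignment (the
reference located within the read, end gaps on the read free); error
classification uses a global alignment of consensus against reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = ["ErrorStats", "identity", "error_statistics", "global_cigar"]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _ops(cigar: str):
    for m in _CIGAR_RE.finditer(cigar):
        yield int(m.group(1)), m.group(2)


def identity(read: str, reference: str) -> float:
    """Matches over alignment length of a semi-global alignment.

    The reference is aligned within the read (terminal read overhangs,
    e.g. barcodes, are free); the alignment length is the number of
    aligned columns, so every mismatch and internal gap dilutes identity.
    """
    if not read or not reference:
        raise ValueError("empty sequence")
    res = edlib.align(reference, read, mode="HW", task="path")
    matches = cols = 0
    for n, op in _ops(res["cigar"]):
        cols += n
        if op == "=":
            matches += n
    return matches / cols if cols else 0.0


def global_cigar(query: str, target: str) -> str:
    """Extended cigar ('='/'X'/'I'/'D') of a global query-vs-target alignment.

    'I' is a base present in the query but not the target; 'D' the
    converse.
    """
    return edlib.align(query, target, mode="NW", task="path")["cigar"] or ""


@dataclass
class ErrorStats:
    """Classified differences between a consensus and its reference.

    Insertions are attributed to the reference position they precede;
    counts are per aligned column (an n-base gap counts n events).
    """

    ref_length: int
    n_substitutions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    n_cm_substitutions: int = 0  # substitutions exchanging C and M
    per_position_sub: np.ndarray = field(default=None, repr=False)
    per_position_ins: np.ndarray = field(default=None, repr=False)
    per_position_del: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        for name in ("per_position_sub", "per_position_ins", "per_position_del"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.ref_length, dtype=np.int64))

    @property
    def n_errors(self) -> int:
        return self.n_substitutions + self.n_insertions + self.n_deletions

    @property
    def proportions(self) -> dict[str, float]:
        """Share of each error type; sums to 1 when any errors exist."""
        n = self.n_errors
        if n == 0:
            return {"substitution": 0.0, "insertion": 0.0, "deletion": 0.0}
        return {
            "substitution": self.n_substitutions / n,
            "insertion": self.n_insertions / n,
            "deletion": self.n_deletions / n,
        }

    @property
    def cm_fraction(self) -> float:
        """Fraction of substitutions that swap C and 5mC."""
        if self.n_substitutions == 0:
            return 0.0
        return self.n_cm_substitutions / self.n_substitutions

    def per_position_error_rate(self) -> np.ndarray:
        """Total errors attributed to each reference position."""
        return self.per_position_sub + self.per_position_ins + self.per_position_del

    @classmethod
    def merge(cls, stats: list["ErrorStats"]) -> "ErrorStats":
        """Aggregate statistics over same-length references (e.g. oligos)."""
        if not stats:
            raise ValueError("nothing to merge")
        L = max(s.ref_length for s in stats)

        def padded(arrs):
            out = np.zeros(L, dtype=np.int64)
            for a in arrs:
                out[: a.size] += a
            return out

        return cls(
            ref_length=L,
            n_substitutions=sum(s.n_substitutions for s in stats),
            n_insertions=sum(s.n_insertions for s in stats),
            n_deletions=sum(s.n_deletions for s in stats),
            n_cm_substitutions=sum(s.n_cm_substitutions for s in stats),
            per_position_sub=padded([s.per_position_sub for s in stats]),
            per_position_ins=padded([s.per_position_ins for s in stats]),
            per_position_del=padded([s.per_position_del for s in stats]),
        )


def error_statistics(consensus: str, reference: str) -> ErrorStats:
    """Globally align consensus to reference and classify every difference."""
    if not consensus or not reference:
        raise ValueError("empty sequence")
    stats = ErrorStats(ref_length=len(reference))
    qpos = rpos = 0
    for n, op in _ops(global_cigar(consensus, reference)):
        if op == "=":
            qpos += n
            rpos += n
        elif op == "X":
            for k in range(n):
                pair = {consensus[qpos + k], reference[rpos + k]}
                if pair == {"C", "M"}:
                    stats.n_cm_substitutions += 1
                stats.per_position_sub[rpos + k] += 1
            stats.n_substitutions += n
            qpos += n
            rpos += n
        elif op == "I":  # extra bases in the consensus
            stats.n_insertions += n
            stats.per_position_ins[min(rpos, len(reference) - 1)] += n
            qpos += n
        elif op == "D":  # bases missing from the consensus
            stats.n_deletions += n
            stats.per_position_del[rpos : rpos + n] += 1
            rpos += n
    return stats
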