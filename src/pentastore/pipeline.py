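"""Decoding noisy methylation-aware reads back into files.

The pipeline mirrors how assembled 5mC fragments are read back by long-
read sequencing: methylation calling at a score threshold turns
basecalled C into M; reads are screened by alignment identity against
reference fragments (with-reference mode); barcodes and ligation
adaptors are trimmed to cut reads into oligo-sized pieces; pieces (or
whole reads) covering the same unit are combined by multiple-sequence-
alignment consensus; and the consensus oligos are decoded and
reassembled with XOR erasure recovery.

Two decode modes exist.  *with_reference* groups reads by their best-
matching reference fragment and takes a consensus per fragment before
cutting it into oligos — robust, but requires knowing the designed
fragments.  *without_reference* cuts every read first, decodes each
piece's address field, and groups pieces by decoded address — fully
blind, but pieces whose length or transitions were corrupted cannot be
grouped and are lost.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .align import ErrorStats, error_statistics, global_cigar, identity, _ops
from .codec import RotationTable, default_table
from .packets import StoreManifest, decode_oligo, reassemble_file
from .readsim import ReadRecord

__all__ = [
    "ConsensusReport",
    "call_methylation",
    "filter_reads",
    "trim_and_size_filter",
    "msa_consensus",
    "decode_store",
    "error_statistics",
    "identity",
]

METH_THRESHOLD = 128
MIN_IDENTITY = 0.85
LENGTH_WINDOW = (80, 120)
CONSENSUS_PRECEDENCE = "ATCGM"  # tie-break order, A strongest


def call_methylation(read: ReadRecord, threshold: int = METH_THRESHOLD) -> str:
    """Rewrite basecalled C as M wherever its score reaches the threshold.

    The threshold is inclusive: a score of exactly 128 calls methylation.
    """
    out = list(read.bases)
    for pos, p in read.meth_probs.items():
        if p >= threshold:
            out[pos] = "M"
    return "".join(out)


def filter_reads(
    reads: list[str],
    references: list[str],
    min_identity: float = MIN_IDENTITY,
) -> list[tuple[int, str, int, float]]:
    """Screen called reads by alignment identity against the references.

    Returns ``(read index, read, best reference index, identity)`` for
    every read whose best identity is >= ``min_identity`` (inclusive).
    """
    kept = []
    for i, read in enumerate(reads):
        best_ref, best_id = -1, -1.0
        for j, ref in enumerate(references):
            ident = identity(read, ref)
            if ident > best_id:
                best_ref, best_id = j, ident
        if best_id >= min_identity:
            kept.append((i, read, best_ref, best_id))
    return kept


def _find_next_adaptor(
    seq: str, start: int, adaptors: tuple[str, ...], max_mismatch: int
) -> tuple[int, int] | None:
    """Earliest adaptor occurrence at or after ``start``: (position, length).

    Exact occurrences are preferred; the mismatch fallback only applies
    when no adaptor matches exactly in the remainder, which keeps
    spurious near-matches inside payloads from fragmenting clean reads.
    """
    exact_best = None
    for a in adaptors:
        p = seq.find(a, start)
        if p != -1 and (exact_best is None or p < exact_best[0]):
            exact_best = (p, len(a))
    if exact_best is not None:
        return exact_best
    if max_mismatch > 0:
        for p in range(start, len(seq)):
            for a in adaptors:
                if p + len(a) > len(seq):
                    continue
                mm = sum(x != y for x, y in zip(seq[p : p + len(a)], a))
                if mm <= max_mismatch:
                    return (p, len(a))
    return None


def _strip_barcode(seq: str, barcode: str, end: str, slack: int = 12) -> str:
    """Trim a flanking barcode found within ``slack`` letters of the end.

    Searches with up to one mismatch; if the barcode is not found the
    sequence is returned unchanged.
    """
    if not barcode:
        return seq
    L = len(barcode)
    window = range(0, slack + 1) if end == "left" else range(
        len(seq) - L, len(seq) - L - slack - 1, -1
    )
    for p in window:
        if p < 0 or p + L > len(seq):
            continue
        mm = sum(x != y for x, y in zip(seq[p : p + L], barcode))
        if mm <= 1:
            return seq[p + L :] if end == "left" else seq[:p]
    return seq


def trim_and_size_filter(
    read: str,
    barcodes: tuple[str, str] = ("", ""),
    adaptors: tuple[str, ...] = (),
    length_window: tuple[int, int] = LENGTH_WINDOW,
    adaptor_max_mismatch: int = 1,
) -> list[str]:
    """Cut a called read into oligo-sized pieces.

    Flanking barcodes are removed first (fuzzy search near the ends),
    then the read is split at adaptor occurrences and the adaptors
    discarded.  Only pieces whose length lies in ``length_window``
    (inclusive bounds) survive.
    """
    seq = _strip_barcode(read, barcodes[0], "left")
    seq = _strip_barcode(seq, barcodes[1], "right")
    pieces = []
    pos = 0
    while True:
        hit = _find_next_adaptor(seq, pos, tuple(adaptors), adaptor_max_mismatch)
        if hit is None:
            pieces.append(seq[pos:])
            break
        p, alen = hit
        pieces.append(seq[pos:p])
        pos = p + alen
    lo, hi = length_window
    return [p for p in pieces if lo <= len(p) <= hi]


def _star_columns(pieces: list[str], center_idx: int) -> dict:
    """Column letter-counts of a star MSA around ``pieces[center_idx]``.

    Columns are keyed ``(centre position, insertion rank)``; rank 0 is
    the centre base itself, higher ranks are insertions between centre
    positions.  Every piece contributes one letter or a gap per column.
    """
    centre = pieces[center_idx]
    n = len(pieces)
    counts: dict[tuple[int, int], defaultdict] = {
        (i, 0): defaultdict(int) for i in range(len(centre))
    }
    for i, ch in enumerate(centre):
        counts[(i, 0)][ch] += 1
    contributed: dict[tuple[int, int], int] = {k: 1 for k in counts}
    for pi, piece in enumerate(pieces):
        if pi == center_idx:
            continue
        qpos = cpos = 0
        for num, op in _ops(global_cigar(piece, centre)):
            if op in "=X":
                for k in range(num):
                    counts[(cpos + k, 0)][piece[qpos + k]] += 1
                    contributed[(cpos + k, 0)] = contributed.get((cpos + k, 0), 0) + 1
                qpos += num
                cpos += num
            elif op == "I":  # piece has extra letters before centre position cpos
                for r in range(num):
                    key = (cpos, r + 1)
                    counts.setdefault(key, defaultdict(int))[piece[qpos + r]] += 1
                    contributed[key] = contributed.get(key, 0) + 1
                qpos += num
            elif op == "D":  # piece lacks these centre positions (gap)
                cpos += num
    # anything a piece did not cover is a gap; gaps = n - contributed
    return {k: (dict(v), n - contributed.get(k, 0)) for k, v in counts.items()}


def msa_consensus(pieces: list[str]) -> str:
    """Per-column majority consensus of a star multiple alignment.

    The centre is the piece of median length (first such piece on ties);
    all others are globally aligned to it.  A column whose strict
    majority is gaps emits nothing; otherwise the most frequent letter
    wins, ties broken by the fixed precedence A < T < C < G < M.
    """
    pieces = [p for p in pieces if p]
    if not pieces:
        raise ValueError("no pieces for consensus")
    if len(pieces) == 1:
        return pieces[0]
    lengths = sorted(len(p) for p in pieces)
    median = lengths[len(lengths) // 2]
    center_idx = min(
        range(len(pieces)), key=lambda i: (abs(len(pieces[i]) - median), i)
    )
    cols = _star_columns(pieces, center_idx)
    n = len(pieces)
    out = []
    # keys sorted so insertions appear before the centre base they precede
    for key in sorted(cols, key=lambda k: (k[0], k[1] == 0, k[1])):
        letter_counts, gaps = cols[key]
        if gaps > n / 2:
            continue
        best = max(
            letter_counts.items(),
            key=lambda kv: (kv[1], -CONSENSUS_PRECEDENCE.index(kv[0])),
        )
        out.append(best[0])
    return "".join(out)


@dataclass
class ConsensusReport:
    """Outcome of a decode run: consensus sequences, errors, recovery."""

    mode: str
    n_reads: int = 0
    n_reads_kept: int | None = None
    n_pieces: int = 0
    consensus: dict = field(default_factory=dict)
    error_stats: ErrorStats | None = None
    recovery_rate: float | None = None
    segment_status: dict = field(default_factory=dict)


def decode_store(
    reads: list[ReadRecord],
    mode: str,
    manifest: StoreManifest,
    references: list[str] | None = None,
    original: bytes | None = None,
    barcodes: tuple[str, str] = ("", ""),
    adaptors: tuple[str, ...] = (),
    table: RotationTable | None = None,
    min_identity: float = MIN_IDENTITY,
    meth_threshold: int = METH_THRESHOLD,
    length_window: tuple[int, int] = LENGTH_WINDOW,
    adaptor_max_mismatch: int = 1,
) -> tuple[bytes, ConsensusReport]:
    """Decode a read set back into a file.

    ``with_reference`` needs ``references`` (the designed fragments,
    letters incl. M, without barcodes).  ``original`` (the true file) is
    only used to report the bit recovery rate.  Unrecoverable segments
    decode as zeros and are reported, never raised.
    """
    if mode not in ("with_reference", "without_reference"):
        raise ValueError(f"unknown mode {mode!r}")
    if manifest is None:
        raise ValueError("manifest required")
    table = table or default_table()
    report = ConsensusReport(mode=mode, n_reads=len(reads))
    called = [call_methylation(r, meth_threshold) for r in reads]
    called = [c for c in called if c]

    oligo_letters: list[str] = []
    if mode == "with_reference":
        if not references:
            raise ValueError("with_reference mode needs reference fragments")
        inserts = [
            _strip_barcode(_strip_barcode(c, barcodes[0], "left"), barcodes[1], "right")
            for c in called
        ]
        kept = filter_reads(inserts, list(references), min_identity)
        report.n_reads_kept = len(kept)
        by_ref: dict[int, list[str]] = defaultdict(list)
        for _, read, ref_idx, _ in kept:
            by_ref[ref_idx].append(read)
        stats = []
        for ref_idx, group in sorted(by_ref.items()):
            cons = msa_consensus(group)
            report.consensus[ref_idx] = cons
            stats.append(error_statistics(cons, references[ref_idx]))
            pieces = trim_and_size_filter(
                cons, ("", ""), tuple(adaptors), length_window, adaptor_max_mismatch
            )
            oligo_letters.extend(pieces)
        if stats:
            report.error_stats = ErrorStats.merge(stats)
        report.n_pieces = len(oligo_letters)
    else:
        by_address: dict[int, list[str]] = defaultdict(list)
        n_pieces = 0
        for c in called:
            pieces = trim_and_size_filter(
                c, barcodes, tuple(adaptors), length_window, adaptor_max_mismatch
            )
            n_pieces += len(pieces)
            for piece in pieces:
                dec = decode_oligo(
                    piece,
                    table,
                    manifest.oligo_length,
                    manifest.address_digits,
                    expected_segments=manifest.n_segments,
                )
                if dec.valid:
                    by_address[dec.address].append(piece)
        report.n_pieces = n_pieces
        for address, group in sorted(by_address.items()):
            cons = msa_consensus(group)
            report.consensus[address] = cons
            oligo_letters.append(cons)

    data, rec = reassemble_file(oligo_letters, manifest, table, original)
    report.recovery_rate = rec.recovery_rate
    report.segment_status = rec.status
    return data, report
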