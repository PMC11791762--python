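"""Rotational transcoding between bytes, base-N digits and DNA letters.

The codec works over an *expanded molecular alphabet*: an ordered set of
K distinct letters, of which the default is the quinary set
(A, T, C, G, M) where M denotes 5-methylcytosine.  A rotational code over
K letters has radix N = K - 1: each digit d in 0..N-1 selects the next
letter by rotating d+1 places past the previous letter in the alphabet
order, so the previous letter itself can never be emitted twice in a row.
The per-base information ceiling of such a code is log2(K) bits.

Encoding of the first position uses a *virtual* previous letter
(``A`` by default), which is reset at the start of every independently
decodable unit (oligo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpandedAlphabet",
    "RotationTable",
    "AlphabetError",
    "InvalidTransitionError",
    "FramingError",
    "DEFAULT_ALPHABET",
    "build_rotation_table",
    "digits_per_byte",
    "bytes_to_digits",
    "digits_to_bytes",
    "encode_digits",
    "decode_letters",
    "density_limit",
]


class AlphabetError(ValueError):
    """Raised for an invalid alphabet configuration (duplicates, too small)."""


class InvalidTransitionError(ValueError):
    """A letter equals its predecessor: impossible under a rotational code.

    Signals corruption of the sequence.  ``position`` is the 0-based index
    of the offending letter.
    """

    def __init__(self, position: int, message: str | None = None):
        self.position = position
        super().__init__(message or f"invalid letter transition at position {position}")


class FramingError(ValueError):
    """Digit-stream length is not a whole number of byte frames."""


@dataclass(frozen=True)
class ExpandedAlphabet:
    """An ordered molecular alphabet of K distinct single-character letters.

    The rotational radix is N = K - 1.  The default instance is the quinary
    alphabet (A, T, C, G, M) with N = 4.
    """

    letters: tuple[str, ...] = ("A", "T", "C", "G", "M")

    def __post_init__(self):
        if len(self.letters) < 2:
            raise AlphabetError("alphabet needs at least 2 letters")
        if len(set(self.letters)) != len(self.letters):
            raise AlphabetError(f"duplicate letters in alphabet {self.letters!r}")
        for l in self.letters:
            if len(l) != 1:
                raise AlphabetError(f"letters must be single characters, got {l!r}")

    @classmethod
    def from_string(cls, order: str) -> "ExpandedAlphabet":
        return cls(tuple(order))

    @property
    def size(self) -> int:
        return len(self.letters)

    @property
    def radix(self) -> int:
        return len(self.letters) - 1

    def index(self, letter: str) -> int:
        try:
            return self.letters.index(letter)
        except ValueError:
            raise AlphabetError(f"letter {letter!r} not in alphabet {self.letters!r}")

    def __str__(self) -> str:
        return "".join(self.letters)


DEFAULT_ALPHABET = ExpandedAlphabet()


@dataclass(frozen=True)
class RotationTable:
    """The (previous letter, digit) -> next letter mapping of a rotational code.

    ``forward[prev][d] = letters[(index(prev) + 1 + d) mod K]`` — a cyclic
    rotation that skips the previous letter, so for every ``prev`` the row
    of the table is a bijection from digits {0..N-1} onto the other N
    letters and no letter can immediately repeat.
    """

    alphabet: ExpandedAlphabet
    forward: dict[str, dict[int, str]] = field(repr=False)
    inverse: dict[str, dict[str, int]] = field(repr=False)

    # byte lookup tables for the vectorised paths
    _char_to_index: np.ndarray = field(repr=False, compare=False)
    _index_to_char: np.ndarray = field(repr=False, compare=False)

    @property
    def radix(self) -> int:
        return self.alphabet.radix

    def next_letter(self, prev: str, digit: int) -> str:
        return self.forward[prev][digit]

    def digit_for(self, prev: str, letter: str) -> int:
        return self.inverse[prev][letter]


def build_rotation_table(alphabet: ExpandedAlphabet = DEFAULT_ALPHABET) -> RotationTable:
    """Build the rotational transcoding table for ``alphabet``.

    Raises :class:`AlphabetError` for invalid alphabets (checked at
    alphabet construction).
    """
    K = alphabet.size
    letters = alphabet.letters
    forward: dict[str, dict[int, str]] = {}
    inverse: dict[str, dict[str, int]] = {}
    for i, prev in enumerate(letters):
        row = {d: letters[(i + 1 + d) % K] for d in range(K - 1)}
        forward[prev] = row
        inverse[prev] = {v: d for d, v in row.items()}

    c2i = np.full(256, -1, dtype=np.int16)
    for i, l in enumerate(letters):
        c2i[ord(l)] = i
    i2c = np.frombuffer("".join(letters).encode("ascii"), dtype=np.uint8).copy()
    return RotationTable(alphabet, forward, inverse, c2i, i2c)


def digits_per_byte(radix: int) -> int:
    """Number of base-``radix`` digits needed to represent any byte (0..255)."""
    if radix < 2:
        raise ValueError(f"radix must be >= 2, got {radix}")
    k = 1
    while radix**k < 256:
        k += 1
    return k


def bytes_to_digits(data: bytes, radix: int = 4) -> np.ndarray:
    """Expand each byte into its fixed-width base-``radix`` digits, MSB first.

    Every byte maps to ``digits_per_byte(radix)`` digits (4 for the quinary
    code's radix 4), preserving byte boundaries for random access.
    Returns a uint8 array of length ``len(data) * digits_per_byte(radix)``.
    """
    k = digits_per_byte(radix)
    arr = np.frombuffer(bytes(data), dtype=np.uint8).astype(np.int64)
    out = np.empty((len(arr), k), dtype=np.uint8)
    for j in range(k - 1, -1, -1):
        out[:, j] = arr % radix
        arr //= radix
    return out.reshape(-1)


def digits_to_bytes(digits: np.ndarray | list[int], radix: int = 4) -> bytes:
    """Inverse of :func:`bytes_to_digits`.

    Raises :class:`FramingError` if the digit count is not a multiple of
    the per-byte width, and ``ValueError`` for digits outside the radix.
    """
    k = digits_per_byte(radix)
    d = np.asarray(digits, dtype=np.int64)
    if d.size % k:
        raise FramingError(f"{d.size} digits is not a multiple of {k} per byte")
    if d.size and (d.min() < 0 or d.max() >= radix):
        raise ValueError(f"digit out of range for radix {radix}")
    frames = d.reshape(-1, k)
    vals = np.zeros(len(frames), dtype=np.int64)
    for j in range(k):
        vals = vals * radix + frames[:, j]
    if vals.size and vals.max() > 255:
        raise ValueError("digit frame exceeds byte range")
    return vals.astype(np.uint8).tobytes()


def _letters_to_indices(seq: str, table: RotationTable) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = table._char_to_index[raw]
    bad = np.nonzero(idx < 0)[0]
    if bad.size:
        raise AlphabetError(
            f"symbol {seq[bad[0]]!r} at position {int(bad[0])} is not in "
            f"alphabet {table.alphabet!s}"
        )
    return idx.astype(np.int64)


def encode_digits(
    digits: np.ndarray | list[int],
    table: RotationTable | None = None,
    initial_prev: str = "A",
) -> str:
    """Transcode a digit string into letters via the rotation table.

    The first position rotates from the virtual previous letter
    ``initial_prev``.  Output never contains two equal adjacent letters and
    its first letter differs from ``initial_prev``.
    """
    table = table or default_table()
    K = table.alphabet.size
    d = np.asarray(digits, dtype=np.int64)
    if d.size == 0:
        return ""
    if d.min() < 0 or d.max() >= table.radix:
        raise ValueError(f"digit out of range for radix {table.radix}")
    p0 = table.alphabet.index(initial_prev)
    # idx[i] = (p0 + (i+1) + sum_{j<=i} d[j]) mod K  — the cumulative form of
    # idx[i] = idx[i-1] + 1 + d[i] (mod K)
    idx = (p0 + np.cumsum(d + 1)) % K
    return table._index_to_char[idx].tobytes().decode("ascii")


def decode_letters(
    seq: str,
    table: RotationTable | None = None,
    initial_prev: str = "A",
) -> np.ndarray:
    """Invert :func:`encode_digits`; returns the digit array.

    Raises :class:`InvalidTransitionError` when a letter equals its
    predecessor (or the first letter equals the virtual letter) — the
    signature of sequence corruption — and :class:`AlphabetError` for
    symbols outside the alphabet.
    """
    table = table or default_table()
    K = table.alphabet.size
    if not seq:
        return np.empty(0, dtype=np.uint8)
    idx = _letters_to_indices(seq, table)
    prev = np.empty_like(idx)
    prev[0] = table.alphabet.index(initial_prev)
    prev[1:] = idx[:-1]
    d = (idx - prev - 1) % K
    bad = np.nonzero(d == K - 1)[0]  # letter == previous letter
    if bad.size:
        raise InvalidTransitionError(int(bad[0]))
    return d.astype(np.uint8)


def density_limit(alphabet_size: int) -> float:
    """Information-density ceiling, in bits per base, of a K-letter alphabet.

    For a molecular alphabet of size K the limit is log2(K): 2.0 for the
    four natural bases, ~2.32 bits/base for the quinary alphabet with
    5-methylcytosine, 3.0 for K = 8.
    """
    if alphabet_size < 2:
        raise ValueError(f"alphabet size must be >= 2, got {alphabet_size}")
    return math.log2(alphabet_size)


_DEFAULT_TABLE: RotationTable | None = None


def default_table() -> RotationTable:
    """The quinary (A, T, C, G, M) rotation table, cached."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = build_rotation_table(DEFAULT_ALPHABET)
    return _DEFAULT_TABLE
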