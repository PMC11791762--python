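"""File segmentation, XOR erasure redundancy and oligo (de)construction.

A file is split into fixed-size addressed segments (22 bytes by default).
Every pair of consecutive data segments (2k, 2k+1) contributes one XOR
parity segment, so any single lost member of a triple (x, y, x^y) is
recoverable from the other two — a rate-2/3 erasure code.  Each segment
becomes one fixed-length oligo (100 letters by default): a 12-digit
base-4 address field followed by the 88 payload digits, transcoded as a
single digit stream starting from the virtual letter A.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .codec import (
    RotationTable,
    InvalidTransitionError,
    AlphabetError,
    FramingError,
    bytes_to_digits,
    digits_to_bytes,
    digits_per_byte,
    decode_letters,
    encode_digits,
    default_table,
)

__all__ = [
    "DataSegment",
    "Oligo",
    "StoreManifest",
    "DecodedOligo",
    "RecoveryReport",
    "SEGMENT_LENGTH",
    "OLIGO_LENGTH",
    "ADDRESS_DIGITS",
    "segment_file",
    "xor_segment",
    "recover_segment",
    "add_redundancy",
    "build_oligo",
    "decode_oligo",
    "encode_store",
    "reassemble_file",
]

SEGMENT_LENGTH = 22  # bytes of payload per segment
OLIGO_LENGTH = 100  # letters per oligo
ADDRESS_DIGITS = 12  # base-4 digits of address field (24-bit address space)

VIRTUAL_LETTER = "A"


@dataclass(frozen=True)
class DataSegment:
    """A fixed-size addressed byte payload; role is ``data`` or ``xor``."""

    address: int
    payload: bytes
    role: str = "data"

    def __post_init__(self):
        if self.address < 0:
            raise ValueError("address must be non-negative")
        if self.role not in ("data", "xor"):
            raise ValueError(f"unknown segment role {self.role!r}")


@dataclass(frozen=True)
class Oligo:
    """A fixed-length encoded DNA string carrying one segment."""

    address: int
    letters: str
    role: str = "data"


@dataclass
class StoreManifest:
    """Decode-time metadata: sizes, counts, alphabet order and a checksum."""

    file_length: int
    segment_length: int = SEGMENT_LENGTH
    n_data_segments: int = 0
    n_xor_segments: int = 0
    alphabet: str = "ATCGM"
    sha256: str = ""
    oligo_length: int = OLIGO_LENGTH
    address_digits: int = ADDRESS_DIGITS

    @property
    def n_segments(self) -> int:
        return self.n_data_segments + self.n_xor_segments

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StoreManifest":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class DecodedOligo:
    """Decoding outcome of one oligo; invalid oligos are erasure candidates."""

    address: int | None
    payload: bytes | None
    valid: bool
    reason: str = ""


@dataclass
class RecoveryReport:
    """Per-segment decode status and the bit-level recovery rate."""

    status: dict[int, str] = field(default_factory=dict)  # address -> ok|recovered|missing
    n_ok: int = 0
    n_recovered: int = 0
    n_missing: int = 0
    recovery_rate: float | None = None  # vs a supplied original, if available


def segment_file(data: bytes, segment_length: int = SEGMENT_LENGTH) -> list[DataSegment]:
    """Split ``data`` into zero-padded segments addressed 0..n-1 in file order."""
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    data = bytes(data)
    n = -(-len(data) // segment_length)  # ceil
    out = []
    for a in range(n):
        chunk = data[a * segment_length : (a + 1) * segment_length]
        chunk = chunk.ljust(segment_length, b"\x00")
        out.append(DataSegment(a, chunk, "data"))
    return out


def xor_segment(x: DataSegment, y: DataSegment, address: int | None = None) -> DataSegment:
    """Bytewise XOR parity of two segments.

    The parity's address defaults to 0; :func:`add_redundancy` assigns the
    next free address after all data segments.
    """
    if len(x.payload) != len(y.payload):
        raise ValueError("payload length mismatch")
    z = bytes(a ^ b for a, b in zip(x.payload, y.payload))
    return DataSegment(address if address is not None else 0, z, "xor")


def recover_segment(a: DataSegment, b: DataSegment) -> bytes:
    """XOR of two members of a parity triple = the payload of the third."""
    if len(a.payload) != len(b.payload):
        raise ValueError("payload length mismatch")
    return bytes(p ^ q for p, q in zip(a.payload, b.payload))


def add_redundancy(segments: list[DataSegment]) -> list[DataSegment]:
    """Append one XOR parity segment per pair of consecutive data segments.

    Pairs are (0,1), (2,3), ...; an odd trailing segment pairs with an
    implicit all-zero phantom so the recovery algebra stays uniform.  For
    n data segments the result holds n + ceil(n/2) segments, data first.
    """
    n = len(segments)
    seg_len = segments[0].payload.__len__() if segments else SEGMENT_LENGTH
    zero = DataSegment(0, b"\x00" * seg_len, "data")
    parities = []
    for k in range(0, n, 2):
        x = segments[k]
        y = segments[k + 1] if k + 1 < n else zero
        parities.append(xor_segment(x, y, address=n + k // 2))
    return list(segments) + parities


def _address_to_digits(address: int, radix: int, width: int) -> np.ndarray:
    if address < 0 or address >= radix**width:
        raise ValueError(
            f"address {address} out of the {width}-digit base-{radix} field"
        )
    digs = np.empty(width, dtype=np.uint8)
    a = address
    for j in range(width - 1, -1, -1):
        digs[j] = a % radix
        a //= radix
    return digs


def build_oligo(
    segment: DataSegment,
    table: RotationTable | None = None,
    oligo_length: int = OLIGO_LENGTH,
    address_digits: int = ADDRESS_DIGITS,
) -> Oligo:
    """Encode one segment as a fixed-length oligo.

    The address field (12 base-4 digits, MSB first) and the payload digits
    are transcoded as one digit stream from the virtual letter A, so each
    oligo is independently decodable.
    """
    table = table or default_table()
    radix = table.radix
    addr = _address_to_digits(segment.address, radix, address_digits)
    payload = bytes_to_digits(segment.payload, radix)
    digits = np.concatenate([addr, payload])
    if digits.size != oligo_length:
        raise ValueError(
            f"segment encodes to {digits.size} digits, expected {oligo_length}"
        )
    letters = encode_digits(digits, table, VIRTUAL_LETTER)
    return Oligo(segment.address, letters, segment.role)


def decode_oligo(
    letters: str,
    table: RotationTable | None = None,
    oligo_length: int = OLIGO_LENGTH,
    address_digits: int = ADDRESS_DIGITS,
    expected_segments: int | None = None,
) -> DecodedOligo:
    """Decode one oligo into (address, payload).

    Never raises on corrupt input: wrong length, an invalid letter
    transition, a foreign symbol, or an out-of-range address all yield an
    invalid record, so the store can treat the oligo as an erasure and
    attempt XOR recovery.
    """
    table = table or default_table()
    if len(letters) != oligo_length:
        return DecodedOligo(None, None, False, f"length {len(letters)} != {oligo_length}")
    try:
        digits = decode_letters(letters, table, VIRTUAL_LETTER)
    except InvalidTransitionError as e:
        return DecodedOligo(None, None, False, f"invalid transition at {e.position}")
    except AlphabetError as e:
        return DecodedOligo(None, None, False, str(e))
    radix = table.radix
    address = 0
    for d in digits[:address_digits]:
        address = address * radix + int(d)
    if expected_segments is not None and address >= expected_segments:
        return DecodedOligo(None, None, False, f"address {address} out of range")
    try:
        payload = digits_to_bytes(digits[address_digits:], radix)
    except (FramingError, ValueError) as e:
        return DecodedOligo(None, None, False, str(e))
    return DecodedOligo(address, payload, True)


def encode_store(
    data: bytes,
    table: RotationTable | None = None,
    segment_length: int = SEGMENT_LENGTH,
    with_xor: bool = True,
    oligo_length: int = OLIGO_LENGTH,
    address_digits: int = ADDRESS_DIGITS,
) -> tuple[list[Oligo], StoreManifest]:
    """Encode a whole file into oligos plus its manifest."""
    table = table or default_table()
    segments = segment_file(data, segment_length)
    n_data = len(segments)
    if with_xor:
        segments = add_redundancy(segments)
    manifest = StoreManifest(
        file_length=len(data),
        segment_length=segment_length,
        n_data_segments=n_data,
        n_xor_segments=len(segments) - n_data,
        alphabet=str(table.alphabet),
        sha256=hashlib.sha256(bytes(data)).hexdigest(),
        oligo_length=oligo_length,
        address_digits=address_digits,
    )
    oligos = _build_oligos_bulk(segments, table, oligo_length, address_digits)
    return oligos, manifest


def _build_oligos_bulk(
    segments: list[DataSegment],
    table: RotationTable,
    oligo_length: int,
    address_digits: int,
) -> list[Oligo]:
    """Vectorised encoding of many equal-size segments at once."""
    if not segments:
        return []
    radix = table.radix
    K = table.alphabet.size
    n = len(segments)
    addr = np.array([s.address for s in segments], dtype=np.int64)
    if addr.max() >= radix**address_digits:
        raise ValueError("address out of field capacity")
    addr_digits = np.empty((n, address_digits), dtype=np.int64)
    a = addr.copy()
    for j in range(address_digits - 1, -1, -1):
        addr_digits[:, j] = a % radix
        a //= radix
    payload = np.frombuffer(b"".join(s.payload for s in segments), dtype=np.uint8)
    k = digits_per_byte(radix)
    seg_len = len(segments[0].payload)
    pay = payload.astype(np.int64).reshape(n, seg_len)
    pay_digits = np.empty((n, seg_len * k), dtype=np.int64)
    tmp = pay.copy()
    for j in range(k - 1, -1, -1):
        pay_digits[:, j::k] = tmp % radix
        tmp //= radix
    digits = np.concatenate([addr_digits, pay_digits], axis=1)
    if digits.shape[1] != oligo_length:
        raise ValueError(
            f"segments encode to {digits.shape[1]} digits, expected {oligo_length}"
        )
    p0 = table.alphabet.index(VIRTUAL_LETTER)
    idx = (p0 + np.cumsum(digits + 1, axis=1)) % K
    chars = table._index_to_char[idx]
    flat = chars.tobytes().decode("ascii")
    return [
        Oligo(s.address, flat[i * oligo_length : (i + 1) * oligo_length], s.role)
        for i, s in enumerate(segments)
    ]


def reassemble_file(
    oligos: list[str] | list[Oligo],
    manifest: StoreManifest,
    table: RotationTable | None = None,
    original: bytes | None = None,
) -> tuple[bytes, RecoveryReport]:
    """Decode an oligo store back into a file, with XOR erasure recovery.

    Valid oligos are decoded; for every parity triple (x, y, x^y) with
    exactly one member missing or invalid, the missing payload is
    recovered from the other two.  Unrecoverable data segments decode as
    zero bytes so the recovery-rate denominator is always the full file.
    When ``original`` is given, the report carries the bit-level recovery
    rate against it.
    """
    if manifest is None:
        raise ValueError("manifest required to size the output")
    table = table or default_table()
    n_data = manifest.n_data_segments
    n_total = manifest.n_segments
    seg_len = manifest.segment_length

    payloads: dict[int, bytes] = {}
    for o in oligos:
        letters = o.letters if isinstance(o, Oligo) else o
        dec = decode_oligo(
            letters,
            table,
            manifest.oligo_length,
            manifest.address_digits,
            expected_segments=n_total,
        )
        if dec.valid and dec.address not in payloads:
            payloads[dec.address] = dec.payload

    report = RecoveryReport()
    zero = b"\x00" * seg_len
    n_pairs = -(-n_data // 2)
    for k in range(n_pairs):
        ax, ay, az = 2 * k, 2 * k + 1, n_data + k
        phantom_y = ay >= n_data  # odd data count: y is the implicit zero segment
        triple = {ax: payloads.get(ax), az: payloads.get(az)}
        if not phantom_y:
            triple[ay] = payloads.get(ay)
        missing = [a for a, p in triple.items() if p is None]
        if len(missing) == 1:
            m = missing[0]
            known = [p for a, p in triple.items() if a != m]
            if phantom_y:
                known.append(zero)
            payloads[m] = bytes(p ^ q for p, q in zip(*known))
            report.status[m] = "recovered"
        for a in triple:
            if a not in report.status:
                report.status[a] = "ok" if payloads.get(a) is not None else "missing"

    out = bytearray()
    for a in range(n_data):
        out += payloads.get(a, zero)
    data = bytes(out[: manifest.file_length])

    report.n_ok = sum(1 for s in report.status.values() if s == "ok")
    report.n_recovered = sum(1 for s in report.status.values() if s == "recovered")
    report.n_missing = sum(1 for s in report.status.values() if s == "missing")
    if original is not None:
        from .channel import recovery_rate

        report.recovery_rate = recovery_rate(original, data)
    return data, report
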