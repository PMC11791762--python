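"""Segmentation, XOR parity algebra, oligo construction and reassembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pentastore.packets import (
    DataSegment,
    add_redundancy,
    build_oligo,
    decode_oligo,
    encode_store,
    reassemble_file,
    recover_segment,
    segment_file,
    xor_segment,
)


def _random_segment(rng, address=0, n=22, role="data"):
    return DataSegment(address, rng.bytes(n), role)


class TestSegmentation:
    @pytest.mark.parametrize(
        "size,expected",
        [(44, 2), (45, 3), (5929, 270), (0, 0), (1, 1), (22, 1)],
    )
    def test_segment_counts(self, size, expected):
        assert len(segment_file(b"\x01" * size)) == expected

    def test_padding_and_addresses(self):
        segs = segment_file(b"\xff" * 45)
        assert [s.address for s in segs] == [0, 1, 2]
        assert segs[-1].payload == b"\xff" + b"\x00" * 21
        assert all(len(s.payload) == 22 for s in segs)


class TestXorAlgebra:
    def test_self_xor_is_zero(self):
        rng = np.random.default_rng(0)
        x = _random_segment(rng)
        assert xor_segment(x, x).payload == b"\x00" * 22

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=50)
    def test_triple_recovery(self, seed):
        """Any member of (x, y, x^y) is the XOR of the other two."""
        rng = np.random.default_rng(seed)
        x, y = _random_segment(rng, 0), _random_segment(rng, 1)
        z = xor_segment(x, y, address=2)
        assert recover_segment(y, z) == x.payload
        assert recover_segment(x, z) == y.payload
        assert recover_segment(x, y) == z.payload
        triple_sum = bytes(
            a ^ b ^ c for a, b, c in zip(x.payload, y.payload, z.payload)
        )
        assert triple_sum == b"\x00" * 22

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            xor_segment(DataSegment(0, b"aa"), DataSegment(1, b"a"))

    @pytest.mark.parametrize("n_data,n_total", [(270, 405), (2, 3), (5, 8), (1, 2)])
    def test_redundancy_counts(self, n_data, n_total):
        segs = segment_file(b"\x01" * (22 * n_data))
        assert len(add_redundancy(segs)) == n_total

    def test_parity_addresses_follow_data(self):
        out = add_redundancy(segment_file(b"\x01" * (22 * 4)))
        assert [s.address for s in out] == [0, 1, 2, 3, 4, 5]
        assert [s.role for s in out] == ["data"] * 4 + ["xor"] * 2


class TestOligoConstruction:
    def test_oligo_is_100_letters(self, table):
        rng = np.random.default_rng(1)
        o = build_oligo(_random_segment(rng, address=17), table)
        assert len(o.letters) == 100

    def test_zero_segment_first_letter(self, table):
        """All-zero digits rotate A->T at every step's first digit."""
        o = build_oligo(DataSegment(0, b"\x00" * 22), table)
        assert o.letters[0] == "T"

    def test_address_capacity(self, table):
        with pytest.raises(ValueError):
            build_oligo(DataSegment(2**24, b"\x00" * 22), table)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=100)
    def test_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        seg = _random_segment(rng, address=int(rng.integers(2**24)))
        dec = decode_oligo(build_oligo(seg).letters)
        assert dec.valid and dec.address == seg.address and dec.payload == seg.payload

    def test_short_oligo_invalid(self, table):
        o = build_oligo(_random_segment(np.random.default_rng(2)), table)
        dec = decode_oligo(o.letters[:-1], table)
        assert not dec.valid and "length" in dec.reason

    def test_repeat_creating_substitution_invalid(self, table):
        """A substitution that duplicates its neighbour breaks a transition."""
        o = build_oligo(_random_segment(np.random.default_rng(3)), table)
        corrupt = o.letters[:50] + o.letters[49] + o.letters[51:]
        dec = decode_oligo(corrupt, table)
        assert not dec.valid and "transition" in dec.reason

    def test_out_of_range_address_invalid(self, table):
        o = build_oligo(_random_segment(np.random.default_rng(4), address=300), table)
        dec = decode_oligo(o.letters, table, expected_segments=10)
        assert not dec.valid and "address" in dec.reason


class TestReassembly:
    def test_intact_store(self, poem_sized_store):
        data, oligos, manifest = poem_sized_store
        out, report = reassemble_file(oligos, manifest, original=data)
        assert out == data
        assert report.recovery_rate == 1.0
        assert report.n_missing == 0

    @pytest.mark.parametrize("drop", [0, 1, 2])
    def test_single_erasure_any_member(self, drop, table):
        """Dropping any one member of an XOR triple is fully recoverable."""
        data = np.random.default_rng(5).bytes(44)
        oligos, manifest = encode_store(data, table)
        assert len(oligos) == 3
        kept = [o.letters for i, o in enumerate(oligos) if i != drop]
        out, report = reassemble_file(kept, manifest, table, original=data)
        assert out == data and report.recovery_rate == 1.0
        if drop < 2:  # parity loss needs no recovery of data segments
            assert report.n_recovered == 1

    def test_double_erasure_rate(self, table):
        """Losing both members of a pair zeroes those segments only."""
        rng = np.random.default_rng(6)
        data = rng.bytes(88)  # 4 data segments, 2 parity
        oligos, manifest = encode_store(data, table)
        kept = [o.letters for o in oligos if o.address not in (0, 4)]
        # segments 0 (data) and 4 (its parity) both gone -> segment 0 zeroed,
        # but its pair member (1) is intact
        out, report = reassemble_file(kept, manifest, table, original=data)
        assert out[22:] == data[22:]
        assert out[:22] == b"\x00" * 22
        wrong_bits = bin(
            int.from_bytes(data[:22], "big") ^ int.from_bytes(out[:22], "big")
        ).count("1")
        assert report.recovery_rate == pytest.approx(1 - wrong_bits / (8 * 88))

    def test_odd_segment_count_phantom_pairing(self, table):
        """With odd data counts the last parity pairs against zeros."""
        data = np.random.default_rng(7).bytes(22 * 5)
        oligos, manifest = encode_store(data, table)
        assert manifest.n_xor_segments == 3
        # drop the final data segment; recover it from its parity alone
        kept = [o.letters for o in oligos if o.address != 4]
        out, report = reassemble_file(kept, manifest, table, original=data)
        assert out == data and report.status[4] == "recovered"

    def test_single_data_segment(self, table):
        data = b"hello"
        oligos, manifest = encode_store(data, table)
        assert len(oligos) == 2
        out, _ = reassemble_file([oligos[1].letters], manifest, table)
        assert out == data

    @given(st.binary(max_size=2000))
    @settings(deadline=None, max_examples=30)
    def test_end_to_end_identity(self, data):
        oligos, manifest = encode_store(data)
        out, _ = reassemble_file(oligos, manifest)
        assert out == data

    def test_counting_law(self):
        """B bytes yield ceil(B/22) + ceil(ceil(B/22)/2) oligos."""
        for size in (0, 1, 21, 22, 23, 100, 5929):
            oligos, _ = encode_store(b"\x01" * size)
            n_data = -(-size // 22)
            assert len(oligos) == n_data + -(-n_data // 2)

    def test_manifest_required(self, table):
        with pytest.raises(ValueError):
            reassemble_file([], None, table)
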