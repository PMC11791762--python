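"""Rotational codec: table structure, byte/digit/letter conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pentastore.codec import (
    AlphabetError,
    DEFAULT_ALPHABET,
    ExpandedAlphabet,
    FramingError,
    InvalidTransitionError,
    build_rotation_table,
    bytes_to_digits,
    decode_letters,
    default_table,
    density_limit,
    digits_per_byte,
    digits_to_bytes,
    encode_digits,
)


class TestRotationTable:
    @pytest.mark.parametrize(
        "prev,digit,expected",
        [("A", 2, "G"), ("G", 1, "A"), ("A", 1, "C"), ("C", 2, "A"), ("M", 0, "A")],
    )
    def test_quinary_cells(self, table, prev, digit, expected):
        assert table.next_letter(prev, digit) == expected

    @pytest.mark.parametrize("size", range(3, 9))
    def test_bijective_rows(self, size):
        """Each row maps digits onto exactly the other letters, never prev."""
        rng = np.random.default_rng(size)
        letters = tuple(
            chr(ord("a") + i) for i in rng.permutation(size)
        )
        t = build_rotation_table(ExpandedAlphabet(letters))
        for prev in letters:
            row = [t.next_letter(prev, d) for d in range(size - 1)]
            assert prev not in row
            assert sorted(row) == sorted(set(letters) - {prev})
            for d, nxt in enumerate(row):
                assert t.digit_for(prev, nxt) == d

    def test_duplicate_letters_rejected(self):
        with pytest.raises(AlphabetError):
            ExpandedAlphabet(("A", "C", "A"))

    def test_default_alphabet_order(self):
        assert DEFAULT_ALPHABET.letters == ("A", "T", "C", "G", "M")
        assert DEFAULT_ALPHABET.radix == 4


class TestByteDigitConversion:
    @pytest.mark.parametrize(
        "byte,expected",
        [(150, [2, 1, 1, 2]), (0, [0, 0, 0, 0]), (255, [3, 3, 3, 3])],
    )
    def test_single_byte_base4(self, byte, expected):
        assert bytes_to_digits(bytes([byte])).tolist() == expected
        assert digits_to_bytes(expected) == bytes([byte])

    def test_exhaustive_single_byte_roundtrip(self):
        for b in range(256):
            assert digits_to_bytes(bytes_to_digits(bytes([b]))) == bytes([b])

    @given(st.binary(max_size=200))
    @settings(deadline=None)
    def test_roundtrip_arbitrary_bytes(self, data):
        assert digits_to_bytes(bytes_to_digits(data)) == data

    def test_fixed_width_expansion(self):
        assert bytes_to_digits(b"\x00" * 7).size == 28
        assert digits_per_byte(4) == 4
        assert digits_per_byte(7) == 3  # radix 7: 7^3 = 343 >= 256

    def test_framing_error(self):
        with pytest.raises(FramingError):
            digits_to_bytes([1, 2, 3])

    def test_digit_out_of_range(self):
        with pytest.raises(ValueError):
            digits_to_bytes([4, 0, 0, 0])


class TestTranscoding:
    def test_worked_example(self, table):
        """Byte 150 -> quaternary 2112 -> GACA from the virtual letter A."""
        assert encode_digits([2, 1, 1, 2], table) == "GACA"
        assert decode_letters("GACA", table).tolist() == [2, 1, 1, 2]

    def test_empty(self, table):
        assert encode_digits([], table) == ""
        assert decode_letters("", table).size == 0

    @given(st.binary(min_size=1, max_size=300))
    @settings(deadline=None)
    def test_roundtrip_and_no_adjacent_repeats(self, data):
        t = default_table()
        letters = encode_digits(bytes_to_digits(data), t)
        assert len(letters) == 4 * len(data)
        assert all(a != b for a, b in zip(letters, letters[1:]))
        assert letters[0] != "A"  # rotation always moves off the virtual letter
        assert digits_to_bytes(decode_letters(letters, t)) == data

    def test_first_letter_equal_to_virtual_is_invalid(self, table):
        with pytest.raises(InvalidTransitionError) as e:
            decode_letters("AACG", table)
        assert e.value.position == 0

    def test_adjacent_repeat_is_invalid(self, table):
        with pytest.raises(InvalidTransitionError) as e:
            decode_letters("GAAC", table)
        assert e.value.position == 2

    def test_unknown_symbol(self, table):
        with pytest.raises(AlphabetError):
            decode_letters("GAXC", table)

    def test_digit_out_of_range_encoding(self, table):
        with pytest.raises(ValueError):
            encode_digits([4], table)

    def test_octal_alphabet_roundtrip(self):
        """A radix-7 code packs each byte into 3 digits and round-trips."""
        t = build_rotation_table(ExpandedAlphabet(tuple("ABCDEFGH")))
        data = bytes(range(0, 256, 7))
        letters = encode_digits(bytes_to_digits(data, 7), t, initial_prev="A")
        assert len(letters) == 3 * len(data)
        assert digits_to_bytes(decode_letters(letters, t), 7) == data


class TestDensityLimit:
    @pytest.mark.parametrize(
        "size,expected", [(4, 2.0), (5, 2.32), (6, 2.58), (7, 2.81), (8, 3.0)]
    )
    def test_published_table(self, size, expected):
        assert round(density_limit(size), 2) == expected

    def test_too_small(self):
        with pytest.raises(ValueError):
            density_limit(1)
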