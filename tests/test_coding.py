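"""Unit and property tests for the core codec."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddqr.coding import (
    CodingScheme,
    Profile,
    base64_to_bits,
    bits_to_base64,
    compression_rate,
    count_frequencies,
    ddqr_decode,
    ddqr_encode,
    encode_payload,
    encode_record,
    huffman_expected_cost,
    normalize_sequence,
    pack_header,
    parse_header,
    payload_bit_length,
    rank_bases,
    rate_from_counts,
    select_scheme,
)
from ddqr.errors import (
    CorruptHeaderError,
    EmptySequenceError,
    InvalidBase64Error,
    InvalidBaseError,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=500)


class TestNormalize:
    def test_lowercase_accepted(self):
        assert normalize_sequence("acgt") == "ACGT"

    def test_whitespace_stripped(self):
        assert normalize_sequence(" AC\nGT\t") == "ACGT"

    @pytest.mark.parametrize("bad,pos", [("ACGN", 4), ("NACG", 1), ("AC-T", 3), ("ACGU", 4)])
    def test_invalid_characters_located(self, bad, pos):
        with pytest.raises(InvalidBaseError) as exc:
            normalize_sequence(bad)
        assert exc.value.position == pos

    def test_empty_rejected(self):
        with pytest.raises(EmptySequenceError):
            normalize_sequence("  \n ")


class TestFrequenciesAndRanking:
    def test_counts_and_freqs(self):
        f = count_frequencies("AAAT")
        assert f.counts == {"A": 3, "T": 1, "C": 0, "G": 0}
        assert f.freqs == {"A": 0.75, "T": 0.25, "C": 0.0, "G": 0.0}

    def test_uniform(self):
        f = count_frequencies("ACGT")
        assert all(v == 1 for v in f.counts.values())

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAT", ("A", "T", "C", "G")),  # C/G tie broken alphabetically
            ("ACGT", ("A", "C", "G", "T")),  # full tie -> alphabetical
            ("TTTTTGGGGCCCAA", ("T", "G", "C", "A")),  # strict ordering
        ],
    )
    def test_rank_bases(self, seq, expected):
        assert rank_bases(count_frequencies(seq)) == expected

    @given(dna)
    @settings(derandomize=True, max_examples=200)
    def test_ranking_is_descending_permutation(self, seq):
        f = count_frequencies(seq)
        order = rank_bases(f)
        assert sorted(order) == list("ACGT")
        counts = [f.counts[b] for b in order]
        assert counts == sorted(counts, reverse=True)


class TestHuffmanCost:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 40, "C": 30, "G": 20, "T": 10}, 1.9),
            ({"A": 25, "C": 25, "G": 25, "T": 25}, 2.25),
            ({"A": 100, "C": 0, "G": 0, "T": 0}, 1.0),
        ],
    )
    def test_expected_cost(self, counts, expected):
        seq = "".join(b * n for b, n in counts.items())
        f = count_frequencies(seq)
        order = rank_bases(f)
        assert huffman_expected_cost(f, order) == pytest.approx(expected)

    @given(dna)
    @settings(derandomize=True, max_examples=200)
    def test_cost_times_length_is_exact_bit_count(self, seq):
        f = count_frequencies(seq)
        order = rank_bases(f)
        bits = payload_bit_length(f, order, CodingScheme.HUFFMAN)
        assert huffman_expected_cost(f, order) * f.length == pytest.approx(bits)


# independent per-base table-lookup oracle for payload encoding
def _payload_oracle(seq, order, scheme):
    table = (
        {order[0]: "00", order[1]: "01", order[2]: "10", order[3]: "11"}
        if scheme is CodingScheme.BINARY
        else {order[0]: "1", order[1]: "01", order[2]: "001", order[3]: "000"}
    )
    out = ""
    for base in seq:
        out += table[base]
    return out


class TestPayload:
    @pytest.mark.parametrize(
        "seq,order,scheme,expected",
        [
            ("AAAT", ("A", "T", "C", "G"), CodingScheme.HUFFMAN, "11101"),
            ("ACGT", ("A", "C", "G", "T"), CodingScheme.BINARY, "00011011"),
            ("A", ("A", "C", "G", "T"), CodingScheme.HUFFMAN, "1"),
        ],
    )
    def test_hand_traces(self, seq, order, scheme, expected):
        assert encode_payload(seq, order, scheme) == expected
        assert _payload_oracle(seq, order, scheme) == expected

    @given(dna, st.sampled_from([CodingScheme.BINARY, CodingScheme.HUFFMAN]))
    @settings(derandomize=True, max_examples=200)
    def test_matches_lookup_oracle(self, seq, scheme):
        order = rank_bases(count_frequencies(seq))
        assert encode_payload(seq, order, scheme) == _payload_oracle(seq, order, scheme)


class TestSchemeSelection:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAAT", CodingScheme.HUFFMAN), ("ACGT", CodingScheme.BINARY)],
    )
    def test_examples(self, seq, expected):
        assert select_scheme(seq, rank_bases(count_frequencies(seq))) is expected

    def test_tie_goes_to_binary(self):
        # 2*c1 + c2 == L exactly: counts (2, 2, 1, 1), L = 6
        seq = "AACCGT"
        f = count_frequencies(seq)
        order = rank_bases(f)
        assert payload_bit_length(f, order, CodingScheme.HUFFMAN) == 2 * len(seq)
        assert select_scheme(seq, order) is CodingScheme.BINARY

    @given(dna)
    @settings(derandomize=True, max_examples=500)
    def test_algebraic_identity(self, seq):
        """HUFFMAN chosen iff 2*c1 + c2 > L (brute-force payload comparison)."""
        f = count_frequencies(seq)
        order = rank_bases(f)
        chosen = select_scheme(seq, order)
        c = sorted(f.counts.values(), reverse=True)
        should_huffman = 2 * c[0] + c[1] > f.length
        brute = len(encode_payload(seq, order, CodingScheme.HUFFMAN)) < len(
            encode_payload(seq, order, CodingScheme.BINARY)
        )
        assert should_huffman == brute
        assert (chosen is CodingScheme.HUFFMAN) == should_huffman


class TestHeader:
    @pytest.mark.parametrize(
        "scheme,order,pad,profile,expected",
        [
            (CodingScheme.HUFFMAN, ("A", "T", "C", "G"), 0, Profile.PAPER, "000001101"),
            (CodingScheme.BINARY, ("A", "C", "G", "T"), 0, Profile.PAPER, "111000110"),
            (CodingScheme.BINARY, ("A", "C", "G", "T"), 4, Profile.ROBUST, "111000110100"),
        ],
    )
    def test_pack(self, scheme, order, pad, profile, expected):
        assert pack_header(scheme, order, pad, profile) == expected

    def test_pack_parse_round_trip(self):
        for order in itertools.permutations("ACGT"):
            for scheme in CodingScheme:
                for pad in range(6):
                    bits = pack_header(scheme, order, pad, Profile.ROBUST)
                    s, o, p = parse_header(bits, Profile.ROBUST)
                    assert (s, o, p) == (scheme, order, pad)

    def test_pad_out_of_range(self):
        with pytest.raises(ValueError):
            pack_header(CodingScheme.BINARY, tuple("ACGT"), 6, Profile.ROBUST)

    def test_bad_tag_rejected(self):
        with pytest.raises(CorruptHeaderError):
            parse_header("010" + "000110", Profile.PAPER)

    def test_duplicate_order_ids_rejected(self):
        with pytest.raises(CorruptHeaderError):
            parse_header("111" + "000001", Profile.PAPER)


class TestBase64:
    @pytest.mark.parametrize(
        "bits,expected",
        [
            ("000001101111010000", "BvQ"),
            ("111000110000110110", "4w2"),
            ("000000", "A"),
            ("00000110111101", "BvQ"),  # 14 bits -> padded with four '0's
        ],
    )
    def test_bits_to_base64(self, bits, expected):
        assert bits_to_base64(bits) == expected

    def test_base64_to_bits_inverse(self):
        assert base64_to_bits("BvQ") == "000001101111010000"
        assert base64_to_bits("A") == "000000"

    def test_invalid_character_located(self):
        with pytest.raises(InvalidBase64Error) as exc:
            base64_to_bits("B*Q")
        assert exc.value.position == 2

    @given(st.binary(min_size=1, max_size=80))
    @settings(derandomize=True, max_examples=200)
    def test_round_trip_restores_bits_plus_zero_pad(self, raw):
        bits = "".join(format(b, "08b") for b in raw)
        back = base64_to_bits(bits_to_base64(bits))
        assert back.startswith(bits)
        assert set(back[len(bits):]) <= {"0"}
        assert len(back) % 6 == 0


class TestPipeline:
    def test_worked_examples(self):
        assert ddqr_encode("AAAT", Profile.PAPER) == "BvQ"
        assert ddqr_encode("ACGT", Profile.PAPER) == "4w2"

    def test_robust_example_header(self):
        text = ddqr_encode("AAAT", Profile.ROBUST)
        bits = base64_to_bits(text)
        # scheme tag, order (A,T,C), pad count recomputed for the 12-bit header
        assert bits[:3] == "000"
        assert bits[3:9] == "001101"
        pad = int(bits[9:12], 2)
        assert (12 + 5 + pad) % 6 == 0

    def test_deterministic(self):
        for profile in Profile:
            a = ddqr_encode("ACGTACGTTTT", profile)
            b = ddqr_encode("ACGTACGTTTT", profile)
            assert a == b

    def test_char_count_formula(self, random_sequences):
        for seq in random_sequences(200):
            for profile in Profile:
                rec = encode_record(seq, profile)
                f = count_frequencies(seq)
                p = payload_bit_length(f, rec.order, rec.scheme)
                assert rec.char_count == math.ceil((profile.header_bits + p) / 6)

    def test_paper_decode_worked_example(self):
        d = ddqr_decode("BvQ", Profile.PAPER)
        assert d.sequence == "AAAT"
        assert d.tail_ambiguous  # several pad interpretations were consistent

    def test_robust_round_trip_exhaustive_short(self):
        for length in range(1, 7):
            for tup in itertools.product("ACGT", repeat=length):
                s = "".join(tup)
                back = ddqr_decode(ddqr_encode(s, Profile.ROBUST), Profile.ROBUST)
                assert back.sequence == s
                assert not back.tail_ambiguous

    @given(dna)
    @settings(derandomize=True, max_examples=300)
    def test_robust_round_trip_property(self, seq):
        assert ddqr_decode(ddqr_encode(seq, Profile.ROBUST), Profile.ROBUST).sequence == seq

    @given(dna)
    @settings(derandomize=True, max_examples=300)
    def test_paper_decode_is_prefix_with_bounded_loss(self, seq):
        d = ddqr_decode(ddqr_encode(seq, Profile.PAPER), Profile.PAPER)
        assert seq.startswith(d.sequence)
        assert len(seq) - len(d.sequence) <= 2
        if len(d.sequence) < len(seq):
            assert d.tail_ambiguous

    def test_corrupt_text_rejected(self):
        with pytest.raises(CorruptHeaderError):
            # first three bits 010 -> invalid scheme tag ('Q' = 010000)
            ddqr_decode("QQQ", Profile.PAPER)


class TestCompressionRate:
    @pytest.mark.parametrize(
        "length,expected",
        [(200, 69 / 200), (300, 102 / 300), (400, 135 / 400)],
    )
    def test_binary_closed_form(self, length, expected):
        seq = "ACGT" * (length // 4)  # uniform -> binary branch
        assert compression_rate(seq, Profile.PAPER) == pytest.approx(expected)
        assert expected == pytest.approx(math.ceil((2 * length + 9) / 6) / length)

    def test_small_example(self):
        assert compression_rate("AAAT", Profile.PAPER) == pytest.approx(0.75)

    def test_rate_from_counts_matches_full_encode(self, random_sequences):
        for seq in random_sequences(300):
            counts = {b: seq.count(b) for b in "ACGT"}
            for profile in Profile:
                assert rate_from_counts(counts, profile) == pytest.approx(
                    compression_rate(seq, profile)
                )

    def test_skew_benefit_monotone_at_fixed_length(self):
        """Moving mass to the dominant base never worsens the rate (L=60)."""
        L = 60
        rates = {}
        for c1 in range(15, L + 1):
            # spread the rest as evenly as possible
            rest = L - c1
            c2 = (rest + 2) // 3
            c3 = (rest + 1) // 3
            c4 = rest // 3
            if not c1 >= c2 >= c3 >= c4:
                continue
            rates[c1] = rate_from_counts({"A": c1, "C": c2, "G": c3, "T": c4})
        keys = sorted(rates)
        for a, b in zip(keys, keys[1:]):
            assert rates[b] <= rates[a] + 1e-12
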