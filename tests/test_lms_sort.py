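import numpy as np
import pytest

from kfmindex import (
    SyntheticSpec,
    classify_ls_types,
    encode_reduced_reference,
    find_lms_positions,
    generate_sequence,
    prefix_double_ranks,
    segment_substring,
    sort_lms_bucket_split,
    sort_lms_direct,
)
from kfmindex.oracles import naive_korder_sa

from conftest import fuzz_sequences, seq_of


def lms_of(seq):
    return find_lms_positions(classify_ls_types(seq))


def oracle_lms_order(seq, lms, k):
    """Independent reference: stable sort of LMS suffixes by first-k chars."""
    tb = seq.text.tobytes()
    if k is None:
        return sorted(lms.tolist(), key=lambda p: tb[p:])
    return sorted(lms.tolist(), key=lambda p: tb[p : p + k])


def encode_chunk_oracle(chars):
    """Independent base-5 positional encoder used to check every symbol."""
    v = 0
    for c in chars:
        v = v * 5 + int(c)
    return v


class TestDirectSort:
    @pytest.mark.parametrize(
        "k,expected", [(8, [6, 4, 1]), (1, [6, 1, 4]), (2, [6, 4, 1])]
    )
    def test_cattag_examples(self, cattag, k, expected):
        assert sort_lms_direct(cattag, lms_of(cattag), k).tolist() == expected

    def test_unbounded_is_true_lexicographic(self):
        for seq, _ in fuzz_sequences(20, seed=21, max_len=300):
            lms = lms_of(seq)
            got = sort_lms_direct(seq, lms, None).tolist()
            assert got == oracle_lms_order(seq, lms, None)


class TestBucketSplit:
    @pytest.mark.parametrize("k", [1, 2, 8])
    def test_equals_direct_on_cattag(self, cattag, k):
        lms = lms_of(cattag)
        assert np.array_equal(
            sort_lms_bucket_split(cattag, lms, k, l_bucket=3),
            sort_lms_direct(cattag, lms, k),
        )

    def test_equals_direct_fuzzed(self):
        rng = np.random.default_rng(50)
        for i in range(50):
            seq = generate_sequence(
                SyntheticSpec(length=int(rng.integers(50, 2000)), seed=i)
            )
            lms = lms_of(seq)
            assert np.array_equal(
                sort_lms_bucket_split(seq, lms, 16, l_bucket=4),
                sort_lms_direct(seq, lms, 16),
            )

    def test_degenerate_single_char_buckets(self):
        for seq, k in fuzz_sequences(12, seed=9, max_len=200):
            lms = lms_of(seq)
            assert np.array_equal(
                sort_lms_bucket_split(seq, lms, k, l_bucket=1),
                sort_lms_direct(seq, lms, k),
            )


class TestReducedReference:
    def test_worked_segmentation_accta(self):
        """LMS substring ACCTA, l=3: chunks ACC and TAA, the second completed
        from the following text."""
        text = seq_of("ACCTAA").text
        chunks = segment_substring(text, 0, 4, 3)
        decoded = ["".join("$ACGT"[c] for c in ch) for ch in chunks]
        assert decoded == ["ACC", "TAA"]

    def test_cattag_encoding(self, cattag):
        red = encode_reduced_reference(cattag, lms_of(cattag), l=3)
        # substrings ATTA / AG$ / $; chunks ATT, AG$, AG$, $$$
        expected = [
            encode_chunk_oracle(ch)
            for ch in ([1, 4, 4], [1, 3, 0], [1, 3, 0], [0, 0, 0])
        ]
        assert red.symbols.tolist() == expected == [49, 40, 40, 0]
        assert red.lms_offsets.tolist() == [0, 2, 3]

    def test_sentinel_only_substring(self):
        seq = seq_of("AAAA")
        red = encode_reduced_reference(seq, lms_of(seq), l=2)
        assert red.symbols.tolist() == [0]
        assert red.lms_offsets.tolist() == [0]

    def test_every_symbol_matches_independent_encoder(self):
        for seq, _ in fuzz_sequences(25, seed=33, max_len=300):
            lms = lms_of(seq)
            for l in (2, 3, 8):
                red = encode_reduced_reference(seq, lms, l=l)
                assert np.all(red.symbols < 5**l)
                assert np.all(np.diff(red.lms_offsets) > 0)
                padded = np.concatenate([seq.text, np.zeros(l, dtype=np.uint8)])
                stops = np.concatenate([lms[1:], [seq.n - 1]])
                si = 0
                for j, p in enumerate(lms.tolist()):
                    length = int(stops[j]) - p + 1
                    for t in range(-(-length // l)):
                        chunk = padded[p + t * l : p + (t + 1) * l]
                        assert red.symbols[si] == encode_chunk_oracle(chunk)
                        si += 1
                assert si == len(red.symbols)

    def test_oversized_l_rejected(self, cattag):
        with pytest.raises(ValueError):
            encode_reduced_reference(cattag, lms_of(cattag), l=40)


class TestPrefixDoubling:
    def test_cattag_equals_direct(self, cattag):
        lms = lms_of(cattag)
        red = encode_reduced_reference(cattag, lms, l=3)
        assert prefix_double_ranks(red, 8).tolist() == [6, 4, 1]

    def test_tandem_partitions_match_naive_k4(self):
        seq = generate_sequence(
            SyntheticSpec(length=400, mode="tandem_repeat", repeat_unit="AT", seed=0)
        )
        lms = lms_of(seq)
        red = encode_reduced_reference(seq, lms, l=3)
        got = prefix_double_ranks(red, 4)
        assert np.array_equal(got, sort_lms_direct(seq, lms, 4))

    def test_single_lms(self):
        seq = seq_of("AAAA")
        red = encode_reduced_reference(seq, lms_of(seq), l=2)
        assert prefix_double_ranks(red, 4).tolist() == [4]

    @pytest.mark.parametrize("l", [2, 3, 8])
    def test_strategy_equivalence_grid(self, l):
        """Direct sort, bucket split, and encode+doubling agree exactly under
        the stable position tie rule, across text modes and k values."""
        for seq, k in fuzz_sequences(35, seed=100 + l, max_len=600):
            lms = lms_of(seq)
            direct = sort_lms_direct(seq, lms, k)
            red = encode_reduced_reference(seq, lms, l=l)
            assert np.array_equal(prefix_double_ranks(red, k), direct), (
                seq.name,
                k,
                l,
            )

    def test_round_bound_on_self_concatenated_genome(self):
        """Doubling on a genome concatenated with itself stays within
        ceil(log2(max(1, ceil(k/l)))) + 1 rounds."""
        import math

        for seed in range(5):
            seq = generate_sequence(
                SyntheticSpec(length=4000, mode="self_concatenated", seed=seed)
            )
            lms = lms_of(seq)
            for k in (4, 16, 64, 256):
                for l in (2, 3):
                    red = encode_reduced_reference(seq, lms, l=l)
                    stats = {}
                    got = prefix_double_ranks(red, k, stats=stats)
                    bound = math.ceil(math.log2(max(1, -(-k // l)))) + 1
                    assert stats["rounds"] <= bound, (seed, k, l, stats)
                    assert np.array_equal(got, sort_lms_direct(seq, lms, k))

    def test_rank_refinement_is_monotone(self):
        """Re-running with larger k never coarsens the k-order partition of
        the output (equal-prefix groups can only split)."""
        seq = generate_sequence(SyntheticSpec(length=300, seed=8))
        lms = lms_of(seq)
        red = encode_reduced_reference(seq, lms, l=3)
        prev_groups = None
        for k in (1, 2, 4, 8, 16):
            order = prefix_double_ranks(red, k)
            tb = seq.text.tobytes()
            key_of = {int(p): tb[p : p + k] for p in order.tolist()}
            groups = {}
            for p in order.tolist():
                groups.setdefault(key_of[p], set()).add(p)
            if prev_groups is not None:
                for members in groups.values():
                    assert any(
                        members <= prev for prev in prev_groups.values()
                    ), f"partition coarsened at k={k}"
            prev_groups = groups
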