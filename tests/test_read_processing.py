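import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crispramp._seq import revcomp
from crispramp.model import PipelineConfig
from crispramp.reads import (
    filter_reason,
    filter_reads,
    merge_pair,
    process_pairs,
    sliding_window_trim,
)

from conftest import make_read, random_dna


def brute_force_trim_length(quals, window, threshold):
    """Independent oracle for the sliding-window rule: find the first window
    whose mean is below threshold, then keep leading in-window bases whose own
    quality still meets it."""
    n = len(quals)
    if n < window:
        return n
    for start in range(n - window + 1):
        if sum(quals[start : start + window]) / window < threshold:
            cut = start
            while cut < n and quals[cut] >= threshold:
                cut += 1
            return cut
    return n


class TestSlidingWindowTrim:
    def test_high_quality_read_unchanged(self):
        read = make_read("A" * 250, 30)
        out = sliding_window_trim(read, 4, 20)
        assert out.sequence == read.sequence

    def test_documented_low_quality_example(self):
        quals = [30, 30, 30, 30, 2, 2, 2, 2] + [30] * 12
        read = make_read("ACGTACGTACGTACGTACGT", quals)
        out = sliding_window_trim(read, 4, 10)
        expected = brute_force_trim_length(quals, 4, 10)
        assert expected == 4  # frozen from the oracle
        assert len(out) == 4
        assert out.sequence == read.sequence[:4]

    def test_threshold_zero_never_trims(self, rng):
        quals = rng.integers(0, 41, size=120)
        read = make_read(random_dna(rng, 120), quals)
        assert sliding_window_trim(read, 4, 0).sequence == read.sequence

    def test_read_shorter_than_window_unchanged(self):
        read = make_read("ACG", [2, 2, 2])
        assert sliding_window_trim(read, 4, 30).sequence == "ACG"

    def test_empty_read(self):
        read = make_read("", np.array([], dtype=np.int16))
        assert sliding_window_trim(read, 4, 20).sequence == ""

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_trim(make_read("ACGT"), 0, 10)

    @settings(max_examples=60, deadline=None)
    @given(
        quals=st.lists(st.integers(0, 40), min_size=0, max_size=80),
        window=st.integers(1, 8),
        threshold=st.integers(0, 40),
    )
    def test_matches_brute_force_and_never_lengthens(self, quals, window, threshold):
        seq = "A" * len(quals)
        out = sliding_window_trim(make_read(seq, quals), window, threshold)
        assert len(out) == brute_force_trim_length(quals, window, threshold)
        assert out.sequence == seq[: len(out)]  # always a prefix


class TestFilterReads:
    def test_short_r1_dropped(self, cfg):
        read = make_read("A" * 199, 40, mate="R1")
        assert filter_reason(read, cfg) == "too_short"

    def test_exact_minimum_length_kept(self, cfg):
        read = make_read("A" * 200, 40, mate="R1")
        assert filter_reason(read, cfg) is None

    def test_r2_has_its_own_minimum(self, cfg):
        read = make_read("A" * 70, 40, mate="R2")
        assert filter_reason(read, cfg) is None
        assert filter_reason(make_read("A" * 69, 40, mate="R2"), cfg) == "too_short"

    def test_exactly_80_percent_good_bases_kept(self, cfg):
        quals = [30] * 160 + [10] * 40  # exactly 80% >= Q20
        assert filter_reason(make_read("A" * 200, quals), cfg) is None

    def test_79_percent_good_bases_dropped(self, cfg):
        quals = [30] * 79 + [10] * 21
        read = make_read("A" * 100, quals, mate="R2")
        assert filter_reason(read, cfg) == "low_quality"

    def test_filtering_never_modifies_sequences(self, cfg, rng):
        reads = [
            make_read(random_dna(rng, n), rng.integers(0, 41, n), mate="R2", read_id=str(i))
            for i, n in enumerate(rng.integers(50, 300, size=30))
        ]
        kept = list(filter_reads(reads, cfg))
        originals = {r.read_id: r.sequence for r in reads}
        for read in kept:
            assert read.sequence == originals[read.read_id]

    def test_drop_reasons_logged(self, cfg):
        from collections import Counter

        dropped = Counter()
        reads = [make_read("A" * 10, 40, mate="R1"), make_read("A" * 250, 5, mate="R1")]
        assert list(filter_reads(reads, cfg, dropped)) == []
        assert dropped == {"R1_too_short": 1, "R1_low_quality": 1}


def make_pair(template, r1_len, r2_len, rng=None, pair_id="p"):
    r1 = make_read(template[:r1_len], 35, mate="R1", read_id=pair_id)
    r2 = make_read(revcomp(template)[:r2_len], 30, mate="R2", read_id=pair_id)
    return r1, r2


class TestMergePair:
    def test_exact_overlap_reconstructs_template(self, cfg, rng):
        template = random_dna(rng, 400)
        r1, r2 = make_pair(template, 250, 250)
        amp = merge_pair(r1, r2, cfg)
        assert amp is not None
        assert amp.sequence == template
        assert amp.overlap_length == 100
        assert len(amp) == 250 + 250 - 100

    def test_59_base_overlap_fails(self, cfg, rng):
        template = random_dna(rng, 2 * 250 - 59)
        r1, r2 = make_pair(template, 250, 250)
        assert merge_pair(r1, r2, cfg) is None

    def test_identity_exactly_090_succeeds(self, cfg, rng):
        template = random_dna(rng, 300)
        r1 = make_read(template[:200], 35, mate="R1")
        r2_fwd = list(template[100:])
        # corrupt 10 of the 100 overlap positions on the R2 side
        positions = rng.choice(100, size=10, replace=False)
        for p in positions:
            r2_fwd[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r2_fwd[p]]
        r2 = make_read(revcomp("".join(r2_fwd)), 20, mate="R2")
        amp = merge_pair(r1, r2, cfg)
        assert amp is not None
        assert amp.overlap_length == 100
        # R1 bases win the disagreements (higher quality)
        assert amp.sequence == template

    def test_disagreement_tie_takes_r1_base(self, cfg, rng):
        template = random_dna(rng, 260)
        r1 = make_read(template[:160], 30, mate="R1")
        r2_fwd = list(template[100:])
        r2_fwd[0] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r2_fwd[0]]
        r2 = make_read(revcomp("".join(r2_fwd)), 30, mate="R2")  # equal quality
        amp = merge_pair(r1, r2, cfg)
        assert amp is not None
        assert amp.sequence == template
        assert amp.qualities[100] == 30

    def test_higher_quality_r2_base_wins(self, cfg, rng):
        template = random_dna(rng, 260)
        r1_seq = list(template[:160])
        r1_seq[100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r1_seq[100]]
        r1 = make_read("".join(r1_seq), 20, mate="R1")
        r2 = make_read(revcomp(template[100:]), 35, mate="R2")
        amp = merge_pair(r1, r2, cfg)
        assert amp is not None
        assert amp.sequence == template

    def test_error_free_pairs_always_reconstruct(self, cfg, rng):
        for i in range(50):
            tlen = int(rng.integers(200, 550))
            template = random_dna(rng, tlen)
            r1_len = min(300, tlen)
            r2_len = min(300, tlen)
            if r1_len + r2_len - tlen < cfg.min_overlap:
                continue
            r1, r2 = make_pair(template, r1_len, r2_len)
            amp = merge_pair(r1, r2, cfg)
            assert amp is not None, f"pair {i} failed to merge"
            assert amp.sequence == template
            assert len(amp) == r1_len + r2_len - amp.overlap_length


def test_process_pairs_conservation(cfg, rng):
    pairs = []
    for i in range(40):
        template = random_dna(rng, 440)
        r1 = make_read(template[:300], 35, mate="R1", read_id=f"p{i}")
        r2 = make_read(revcomp(template)[:300], 30, mate="R2", read_id=f"p{i}")
        pairs.append((r1, r2))
    # one doomed pair: R1 too short after construction
    pairs.append(
        (
            make_read("A" * 100, 35, mate="R1", read_id="short"),
            make_read("A" * 100, 30, mate="R2", read_id="short"),
        )
    )
    result = process_pairs(pairs, cfg)
    by_stage = {row["stage"]: row for row in result.attrition}
    assert by_stage["input"]["pairs_in"] == 41
    assert by_stage["filter"]["pairs_out"] == 40
    assert by_stage["merge"]["pairs_out"] == len(result.merged) == 40
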