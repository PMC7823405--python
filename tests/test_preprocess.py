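import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirap.adapter_detect import AdapterCall
from mirap.fastq_io import ReadRecord
from mirap.preprocess import (
    PreprocessConfig,
    TrimmedRead,
    adapter_kmers,
    find_adapter_match,
    kmer_cleanse,
    length_histograms,
    preprocess_library,
    quality_trim_3prime,
)
from tests.conftest import TRUSEQ

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def q(chars):
    """Quality string from a list of Phred scores."""
    return "".join(chr(c + 33) for c in chars)


def brute_force_quality_cut(quality, threshold):
    """Running-sum oracle: evaluate every cut point, keep the best."""
    scores = {}
    qs = [ord(c) - 33 for c in quality]
    for cut in range(len(qs) + 1):
        scores[cut] = sum(threshold - v for v in qs[cut:])
    best = max(scores.values())
    if best <= 0:
        return len(qs)
    return max(c for c, s in scores.items() if s == best)


def brute_force_adapter_match(sequence, adapter, error_rate=0.1, min_overlap=3):
    """Enumerate every 3'-side candidate; fewest errors, then leftmost cut."""
    ls, la = len(sequence), len(adapter)
    candidates = []
    for start in range(ls - la + 1):
        err = sum(a != b for a, b in zip(sequence[start : start + la], adapter))
        if err <= int(error_rate * la):
            candidates.append((err, start))
    for overlap in range(min_overlap, min(la, ls) + 1):
        err = sum(a != b for a, b in zip(sequence[ls - overlap :], adapter[:overlap]))
        if err <= int(error_rate * overlap):
            candidates.append((err, ls - overlap))
    if not candidates:
        return None
    err, cut = min(candidates)
    return cut, err


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        seq, qual = "ACGTACGTAC", q([35] * 10)
        assert quality_trim_3prime(seq, qual, 20) == (seq, qual)

    def test_low_quality_tail_removed(self):
        # frozen from the all-cut-points oracle: Q40 x 20 then Q2 x 5 -> cut 20
        seq = "A" * 25
        qual = q([40] * 20 + [2] * 5)
        assert brute_force_quality_cut(qual, 20) == 20
        trimmed_seq, trimmed_qual = quality_trim_3prime(seq, qual, 20)
        assert trimmed_seq == "A" * 20
        assert trimmed_qual == q([40] * 20)

    def test_uniformly_bad_read_becomes_empty(self):
        assert quality_trim_3prime("ACGT", q([2] * 4), 20) == ("", "")

    @settings(deadline=None, max_examples=100)
    @given(
        quals=st.lists(st.integers(0, 41), min_size=1, max_size=40),
        threshold=st.integers(5, 30),
    )
    def test_matches_all_cut_points_oracle(self, quals, threshold):
        seq = "A" * len(quals)
        cut = brute_force_quality_cut(q(quals), threshold)
        got_seq, got_qual = quality_trim_3prime(seq, q(quals), threshold)
        assert len(got_seq) == cut
        assert got_qual == q(quals)[:cut]


class TestFindAdapterMatch:
    def test_full_adapter_with_trailing_bases(self):
        read = "ACGTACGTACGTACGTACGTAC" + TRUSEQ + "TT"
        assert find_adapter_match(read, TRUSEQ) == (22, 0)

    def test_terminal_adapter_prefix(self):
        read = "ACGTACGTACGTACGTAC" + "TGGAA"
        cut, err = find_adapter_match(read, TRUSEQ)
        assert (cut, err) == (18, 0)

    def test_absent_adapter_returns_none(self):
        assert find_adapter_match("ACACACACACACACACAC", TRUSEQ) is None

    def test_overlap_below_minimum_ignored(self):
        read = "ACACACACACACACACAC" + "TG"  # 2 < min_overlap
        assert find_adapter_match(read, TRUSEQ, min_overlap=3) is None

    def test_full_match_tolerates_error_budget(self):
        mutated = TRUSEQ[:5] + "A" + TRUSEQ[6:]
        assert mutated != TRUSEQ
        read = "ACGTACGTACGTACGTACGTAC" + mutated + "TT"
        cut, err = find_adapter_match(read, TRUSEQ)
        assert cut == 22
        assert err == 1

    def test_5prime_side_mirror(self):
        read = TRUSEQ + "ACGTACGTACGTACGTACGT"
        cut, err = find_adapter_match(read, TRUSEQ, side="5prime")
        assert (cut, err) == (len(TRUSEQ), 0)
        # adapter suffix anchored at the read's 5' end
        read2 = TRUSEQ[-6:] + "ACGTACGTACGTACGTACGT"
        cut2, err2 = find_adapter_match(read2, TRUSEQ, side="5prime")
        assert (cut2, err2) == (6, 0)

    @settings(deadline=None, max_examples=150)
    @given(read=dna, planted=st.booleans(), data=st.data())
    def test_matches_semi_global_oracle(self, read, planted, data):
        adapter = TRUSEQ[:12]
        if planted and len(read) >= 4:
            pos = data.draw(st.integers(0, len(read) - 1))
            read = read[:pos] + adapter + read[pos:]
        expected = brute_force_adapter_match(read, adapter)
        got = find_adapter_match(read, adapter)
        assert got == expected


class TestKmerCleanse:
    CFG = PreprocessConfig()

    def test_fragmented_adapter_rescued(self):
        # the read tail is the adapter fragment at offset 3; the full pass
        # misses it, the k-mer loop rescues the read
        read = TrimmedRead("r1", "ACGTACGTACGT" + "GAATTCTCGG", "I" * 22)
        assert find_adapter_match(read.sequence, TRUSEQ) is None
        (out,) = kmer_cleanse([read], TRUSEQ, self.CFG)
        # with the default 10% error rate the offset-1 k-mer GGAATTCTCG
        # already matches with 1 mismatch one base earlier (loop order wins)
        assert out.sequence == "ACGTACGTACG"
        assert out.trimmed_by == "kmer:1"
        assert out.read_class == "mappable_cleansed"

    def test_fragmented_adapter_exact_loop(self):
        # with mismatches disabled, the exact tail k-mer (offset 3) is the
        # first to hit and the insert is recovered verbatim
        read = TrimmedRead("r1", "ACGTACGTACGT" + "GAATTCTCGG", "I" * 22)
        cfg = PreprocessConfig(error_rate=0.0)
        (out,) = kmer_cleanse([read], TRUSEQ, cfg)
        assert out.sequence == "ACGTACGTACGT"
        assert out.trimmed_by == "kmer:2"  # GAATTCTCGG starts at adapter offset 2
        assert out.read_class == "mappable_cleansed"

    def test_clean_read_untouched(self):
        read = TrimmedRead("r1", "ACACACACACACACACACAC", "I" * 20)
        (out,) = kmer_cleanse([read], TRUSEQ, self.CFG)
        assert out.sequence == "ACACACACACACACACACAC"
        assert out.trimmed_by == "none"

    def test_already_trimmed_read_not_revisited(self):
        read = TrimmedRead(
            "r1", "ACGTACGTACGT" + "GAATTCTCGG", "I" * 22,
            read_class="mappable", trimmed_by="full_adapter",
        )
        (out,) = kmer_cleanse([read], TRUSEQ, self.CFG)
        assert out.sequence == "ACGTACGTACGT" + "GAATTCTCGG"
        assert out.read_class == "mappable"

    def test_kmers_enumerated_in_5prime_order(self):
        kmers = adapter_kmers(TRUSEQ, 10)
        assert len(kmers) == len(TRUSEQ) - 9
        assert kmers[0] == TRUSEQ[:10]
        assert kmers[-1] == TRUSEQ[-10:]

    def test_adapter_shorter_than_kmer_rejected(self):
        with pytest.raises(ValueError):
            kmer_cleanse([], "ACGTA", self.CFG)


def _record(seq, read_id="r"):
    return ReadRecord(read_id, seq, "I" * len(seq))


class TestPreprocessLibrary:
    CALL = AdapterCall(TRUSEQ, provenance="user")

    def test_four_way_partition(self):
        insert = "ACGTACGTACGTACGTACGT"
        reads = [
            _record(insert + TRUSEQ, "full"),  # mappable
            _record(insert + "GAATTCTCGG", "frag"),  # mappable_cleansed
            _record("ACACACACACACACACACACAC", "noad"),  # without_adapter
            _record("ACG" + TRUSEQ, "short"),  # too_short
        ]
        emitted, stats = preprocess_library(reads, self.CALL)
        total = sum(stats.class_counts.values()) + stats.too_long
        assert total == 4
        assert stats.class_counts == {
            "mappable": 1, "mappable_cleansed": 1,
            "without_adapter": 1, "too_short": 1,
        }
        assert sorted(r.read_id for r in emitted) == ["frag", "full"]

    def test_cleansed_read_emitted_when_long_enough(self):
        insert = "ACGTACGTACGTACGTACGT"
        reads = [_record(insert + "GAATTCTCGG", "frag")]
        emitted, stats = preprocess_library(reads, self.CALL)
        assert stats.class_counts["mappable_cleansed"] == 1
        # tolerant loop: the offset-1 k-mer matches one base early (see
        # TestKmerCleanse), so the cleansed read is the insert minus 1 nt
        assert emitted[0].sequence == insert[:-1]

    def test_adapter_free_mode_emits_in_range_reads(self, adapter_free_library):
        reads, _, _ = adapter_free_library
        call = AdapterCall("", provenance="none")
        emitted, stats = preprocess_library(reads, call)
        in_range = sum(1 for r in reads if 18 <= len(r) <= 50)
        assert len(emitted) == in_range
        assert stats.class_counts["without_adapter"] == 0

    def test_ligated_library_fully_mappable(self, ligated_library):
        reads, truth, annotation = ligated_library
        emitted, stats = preprocess_library(reads, self.CALL)
        assert stats.class_counts["without_adapter"] == 0
        assert stats.class_counts["mappable"] + stats.class_counts[
            "mappable_cleansed"
        ] == len(reads)
        # error-free: every emitted read equals its true insert exactly
        raw = {r.read_id: r.sequence for r in reads}
        for trimmed in emitted:
            insert = raw[trimmed.read_id][: raw[trimmed.read_id].find(TRUSEQ)]
            assert trimmed.sequence == insert

    def test_partition_and_monotonicity_invariants(self, adapter_free_library):
        reads, _, _ = adapter_free_library
        sub = reads[:3000]
        emitted, stats = preprocess_library(sub, self.CALL)
        assert sum(stats.class_counts.values()) + stats.too_long == len(sub)
        raw_len = {r.read_id: len(r) for r in sub}
        assert all(len(t.sequence) <= raw_len[t.read_id] for t in emitted)
        assert sum(len(t.sequence) for t in emitted) <= sum(raw_len.values())

    def test_quality_trim_feeds_adapter_removal(self):
        insert = "ACGTACGTACGTACGTACGT"
        seq = insert + TRUSEQ + "AAAAA"
        qual = "I" * (len(seq) - 5) + q([2] * 5)
        emitted, stats = preprocess_library([ReadRecord("r", seq, qual)], self.CALL)
        assert emitted[0].sequence == insert
        assert emitted[0].bases_removed_quality == 5
        assert emitted[0].bases_removed_adapter == len(TRUSEQ)


class TestLengthHistograms:
    def test_empty_library_reports_zeros(self):
        _, stats = preprocess_library([], AdapterCall("", provenance="none"))
        before, after, fractions = length_histograms(stats)
        assert before == {} and after == {}
        assert fractions == {
            "mappable": 0.0, "mappable_cleansed": 0.0,
            "without_adapter": 0.0, "too_short": 0.0,
        }

    def test_single_mode_at_insert_length(self, small_pool):
        from mirap.simulate import SimulationConfig, simulate_library

        annotation, pools = small_pool
        # fixed-length inserts: take one mature, repeat it
        mid = sorted(annotation.matures)[0]
        hid, start, end = annotation.matures[mid]
        insert = annotation.hairpins[hid][start - 1 : end]
        reads = [_record(insert + TRUSEQ, f"r{i}") for i in range(100)]
        _, stats = preprocess_library(reads, AdapterCall(TRUSEQ, provenance="user"))
        _, after, _ = length_histograms(stats)
        assert after == {len(insert): 100}

    def test_fractions_sum_to_one(self, adapter_free_library):
        reads, _, _ = adapter_free_library
        _, stats = preprocess_library(
            reads[:2000], AdapterCall(TRUSEQ, provenance="user")
        )
        _, _, fractions = length_histograms(stats)
        assert sum(fractions.values()) == pytest.approx(1.0)
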