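"""Adapter trimming and pair merging must reconstruct the simulated insert
exactly on error-free data and behave like a conservative merger otherwise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotail._seqmatch import shift_matches
from mitotail._util import revcomp
from mitotail.preprocess import (
    MergedRead,
    TrimSpec,
    merge_pair,
    preprocess_batch,
    qc_summary,
    trim_adapters,
)
from mitotail.simulate import (
    CAPTURE_ADAPTOR,
    ReadPair,
    SimConfig,
    TailModel,
    build_amplicon,
    sequence_pair,
    simulate_library,
)

ADAPTER = CAPTURE_ADAPTOR

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _pair(r1, r2, q1=None, q2=None):
    return ReadPair("p", r1, r2, q1 or "I" * len(r1), q2 or "I" * len(r2))


@given(dna, dna)
@settings(max_examples=200, deadline=None)
def test_shift_matches_equals_brute_force(a, b):
    """The correlation-based match counter agrees with a direct double loop."""
    got = shift_matches(a, b)
    for s in range(-(len(b) - 1), len(a)):
        expected = sum(
            1
            for i in range(len(b))
            if 0 <= i + s < len(a) and b[i] == a[i + s]
        )
        assert got[s + len(b) - 1] == expected


class TestTrimming:
    def test_full_adapter_occurrence_removed(self):
        pair = _pair("CCGGTT" + ADAPTER + "GGG", "ACGTACGTACGT")
        assert trim_adapters(pair).r1_seq == "CCGGTT"

    def test_read_without_adapter_unchanged(self):
        pair = _pair("CCGGTTACGTACGT", "ACGTACGTACGT")
        trimmed = trim_adapters(pair)
        assert trimmed.r1_seq == pair.r1_seq

    def test_partial_adapter_at_read_end_removed(self):
        # brute-force scan over suffix/adapter-prefix alignments says the
        # 5-base suffix "ATGTG" is the best (and only) admissible match
        read = "CCGGTTAAGG" + ADAPTER[:5]
        pair = _pair(read, "ACGTACGTACGT")
        assert trim_adapters(pair).r1_seq == "CCGGTTAAGG"

    def test_partial_below_min_overlap_kept(self):
        read = "CCGGTTAAGG" + ADAPTER[:2]
        pair = _pair(read, "ACGTACGTACGT")
        assert trim_adapters(pair).r1_seq == read

    def test_r2_five_prime_and_three_prime_both_removed(self):
        spec = TrimSpec()
        insert = "GATTACAGATTACAGATTACA"
        r2 = spec.r2_five_prime_adapter + insert + spec.r2_three_prime_adapter[:10]
        pair = _pair("ACGTACGTACGT", r2)
        assert trim_adapters(pair, spec).r2_seq == insert

    def test_quality_sliced_with_sequence(self):
        read = "CCGGTT" + ADAPTER
        qual = "ABCDEF" + "#" * len(ADAPTER)
        pair = _pair(read, "ACGTACGTACGT", q1=qual)
        trimmed = trim_adapters(pair)
        assert trimmed.r1_qual == "ABCDEF"

    def test_trimming_never_lengthens_and_is_idempotent(self, toy_ref):
        # min_overlap 5: at the default of 3, a trimmed read can end in a
        # coincidental 3-base adapter prefix that a second application would
        # also remove (see test below) - inherent to finite-round trimming
        spec = TrimSpec(min_overlap=5)
        cfg = SimConfig(
            n_pairs=40,
            end_usage={"canonical": 0.6, "alternate": 0.4, "other": 0.0},
            tail_model=TailModel("normal", mean=45, sd=12, min_length=3),
            substitution_error_rate=0.01,
            seed=9,
        )
        pairs, _ = simulate_library(toy_ref, cfg)
        for pair in pairs:
            once = trim_adapters(pair, spec)
            assert len(once.r1_seq) <= len(pair.r1_seq)
            assert len(once.r2_seq) <= len(pair.r2_seq)
            twice = trim_adapters(once, spec)
            assert twice.r1_seq == once.r1_seq
            assert twice.r2_seq == once.r2_seq

    def test_coincidental_suffix_breaks_strict_idempotence(self):
        """A templated suffix equal to a short adapter prefix is re-trimmed
        on a second application: known behaviour at min_overlap 3, asserted
        rather than hidden."""
        spec = TrimSpec(rounds=1)
        read = "CCGGTT" + ADAPTER[:3] + ADAPTER + "GG"
        pair = _pair(read, "ACGTACGTACGT")
        once = trim_adapters(pair, spec)
        assert once.r1_seq == "CCGGTT" + ADAPTER[:3]
        twice = trim_adapters(once, spec)
        assert twice.r1_seq == "CCGGTT"


class TestMerging:
    def _simulated_insert_pair(self, toy_ref, tail, read_length=150, seed=3):
        gene = toy_ref.gene("ND3")
        cfg = SimConfig(
            n_pairs=1,
            end_usage={"canonical": 1.0, "alternate": 0.0, "other": 0.0},
            tail_model=TailModel("fixed", length=tail),
            read_length=read_length,
            seed=seed,
        )
        amp = build_amplicon(toy_ref, gene, gene.canonical_end, tail, cfg)
        insert = amp[: -len(cfg.adaptor_seq)]  # templated + tail
        return sequence_pair(amp, cfg), insert

    @pytest.mark.parametrize("tail", [0, 3, 25, 48, 49, 51])
    def test_error_free_pair_recovers_insert_exactly(self, toy_ref, tail):
        """Exact insert recovery across tail lengths that exercise full
        adapter read-through, partial read-through, and no read-through."""
        pair, insert = self._simulated_insert_pair(toy_ref, tail)
        merged = merge_pair(trim_adapters(pair))
        assert merged is not None
        assert merged.seq == insert
        assert merged.mismatches_in_overlap == 0

    def test_disjoint_reads_do_not_merge(self, toy_ref):
        r1 = toy_ref.sequence[100:160]
        r2 = revcomp(toy_ref.sequence[400:460])
        assert merge_pair(_pair(r1, r2)) is None

    def test_higher_quality_base_wins_in_overlap(self):
        insert = "ACGTACGTAGCTTAGCCGATCGAT"
        r1 = insert
        r2_true = revcomp(insert)
        # substitution in R1 at overlap position 5 (A->G), R2 higher quality
        r1_err = r1[:5] + "G" + r1[6:]
        q1 = "#" * len(r1)  # low quality
        q2 = "I" * len(r2_true)
        merged = merge_pair(_pair(r1_err, r2_true, q1=q1, q2=q2), min_overlap=12)
        assert merged is not None
        assert merged.seq == insert  # R2's base restored the truth
        assert merged.mismatches_in_overlap == 1

    def test_tie_on_quality_goes_to_r1(self):
        insert = "ACGTACGTAGCTTAGCCGATCGAT"
        r1_err = insert[:5] + "G" + insert[6:]
        merged = merge_pair(_pair(r1_err, revcomp(insert)), min_overlap=12)
        assert merged is not None
        assert merged.seq == r1_err

    def test_merge_rate_monotone_in_mismatch_tolerance(self, toy_ref):
        cfg = SimConfig(
            n_pairs=150,
            end_usage={"canonical": 1.0, "alternate": 0.0, "other": 0.0},
            tail_model=TailModel("normal", mean=40, sd=10, min_length=3),
            substitution_error_rate=0.03,
            seed=21,
        )
        pairs, _ = simulate_library(toy_ref, cfg)
        rates = []
        for frac in (0.2, 0.1, 0.02, 0.0):
            _, qc = preprocess_batch(pairs, max_mismatch_frac=frac)
            rates.append(qc["merge_rate"])
        assert rates == sorted(rates, reverse=True)

    def test_merged_length_identity_without_overhang(self):
        insert = "ACGTTGCATGCATCCGGATAGCTAGCTAACG"
        r1, r2 = insert[:24], revcomp(insert[10:])
        merged = merge_pair(_pair(r1, r2), min_overlap=12)
        assert merged is not None
        assert merged.clipped_overhang == 0
        assert len(merged.seq) == len(r1) + len(r2) - merged.overlap_len
        assert merged.seq == insert


class TestQC:
    def test_zero_pairs(self):
        assert qc_summary(0, 0, 0) == {
            "pairs_in": 0,
            "pairs_trimmed": 0,
            "pairs_merged": 0,
            "merge_rate": 0.0,
        }

    def test_error_free_batch_merges_completely_and_reruns_identically(
        self, toy_ref, error_free_library
    ):
        _, pairs, _ = error_free_library
        merged_a, qc_a = preprocess_batch(pairs)
        merged_b, qc_b = preprocess_batch(pairs)
        assert qc_a["merge_rate"] == 1.0
        assert qc_a == qc_b
        assert [m.seq for m in merged_a] == [m.seq for m in merged_b]
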