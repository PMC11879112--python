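"""Adapter trimming and paired-end overlap merging.

Reimplements the preprocessing of a poly(A)-capture library: each read is
stripped of the capture adaptor / anti-adaptor primer / sequencing-adapter
read-through (3' adapters removed together with everything downstream, the 5'
adapter with everything upstream, best match first, repeated ``rounds``
times), then the trimmed mates are merged into a single insert sequence by
overlapping R1 with the reverse complement of R2.

Adapter matching is semi-global with unit mismatch cost and no indels: the
simulator's error model is substitution-only, and at the error rates of an
amplicon MiSeq run an indel-free scan is an excellent approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seqmatch import shift_matches
from ._util import decode, encode, revcomp
from .simulate import ANTI_ADAPTOR_PRIMER, CAPTURE_ADAPTOR, SEQUENCING_ADAPTER, ReadPair


@dataclass(frozen=True)
class TrimSpec:
    """Which adapters to remove from each mate, and how strictly.

    Defaults mirror the capture design: the capture adaptor is a 3' adapter on
    R1, the sequencing adapter a 3' adapter on R2, and the anti-adaptor primer
    a 5' adapter on R2.  ``max_error_rate`` and ``min_overlap`` are the
    standard trimming-tool defaults (10% errors, 3 nt minimum overlap); two
    rounds per read so both R2 adapters are removed.
    """

    r1_three_prime_adapters: tuple[str, ...] = (CAPTURE_ADAPTOR,)
    r2_three_prime_adapter: str = SEQUENCING_ADAPTER
    r2_five_prime_adapter: str = ANTI_ADAPTOR_PRIMER
    max_error_rate: float = 0.1
    min_overlap: int = 3
    rounds: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_len: int
    mismatches_in_overlap: int
    clipped_overhang: int = 0


def _best_3p_candidate(
    read: str, adapter: str, max_error_rate: float, min_overlap: int
) -> Optional[tuple[int, int, int]]:
    """Best 3'-adapter occurrence as (mismatches, -overlap, start) or None.

    Candidates are every placement of the adapter starting at ``s`` within the
    read, including partial matches running off the read's 3' end; a
    placement is admissible when its overlap is at least ``min_overlap`` and
    its mismatch count is at most ``floor(max_error_rate * overlap)``.
    """
    L, A = len(read), len(adapter)
    if L < min_overlap:
        return None
    starts = np.arange(0, L - min_overlap + 1)
    overlaps = np.minimum(A, L - starts)
    matches = shift_matches(read, adapter)[starts + A - 1]
    mism = overlaps - matches
    ok = mism <= np.floor(max_error_rate * overlaps).astype(np.int64)
    if not ok.any():
        return None
    cand = np.flatnonzero(ok)
    order = np.lexsort((starts[cand], -overlaps[cand], mism[cand]))
    i = cand[order[0]]
    return int(mism[i]), int(-overlaps[i]), int(starts[i])


def _best_5p_candidate(
    read: str, adapter: str, max_error_rate: float, min_overlap: int
) -> Optional[tuple[int, int, int]]:
    """Best 5'-adapter occurrence as (mismatches, -overlap, end) or None.

    The adapter may start before the read (partial match at the read's 5'
    end) but must end inside it; the read is cut at the adapter's end.
    """
    L, A = len(read), len(adapter)
    if L < min_overlap:
        return None
    starts = np.arange(-(A - min_overlap), max(L - A, 0) + 1)
    starts = starts[starts + A <= L]
    if starts.size == 0:
        return None
    overlaps = A + np.minimum(starts, 0)
    matches = shift_matches(read, adapter)[starts + A - 1]
    mism = overlaps - matches
    ok = mism <= np.floor(max_error_rate * overlaps).astype(np.int64)
    if not ok.any():
        return None
    cand = np.flatnonzero(ok)
    order = np.lexsort((starts[cand], -overlaps[cand], mism[cand]))
    i = cand[order[0]]
    return int(mism[i]), int(-overlaps[i]), int(starts[i] + A)


def _trim_read(
    seq: str,
    qual: str,
    three_prime: Sequence[str],
    five_prime: Optional[str],
    spec: TrimSpec,
) -> tuple[str, str]:
    for _ in range(spec.rounds):
        best = None  # (mism, -overlap, kind, cut)
        for adapter in three_prime:
            c = _best_3p_candidate(seq, adapter, spec.max_error_rate, spec.min_overlap)
            if c is not None:
                key = (c[0], c[1], 0, c[2])
                if best is None or key < best:
                    best = key
        if five_prime is not None:
            c = _best_5p_candidate(seq, five_prime, spec.max_error_rate, spec.min_overlap)
            if c is not None:
                key = (c[0], c[1], 1, c[2])
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, _, kind, cut = best
        if kind == 0:  # 3' adapter: drop the match and everything downstream
            seq, qual = seq[:cut], qual[:cut]
        else:  # 5' adapter: drop the match and everything upstream
            seq, qual = seq[cut:], qual[cut:]
    return seq, qual


def trim_adapters(pair: ReadPair, spec: Optional[TrimSpec] = None) -> ReadPair:
    """Remove adapters from both mates; empty reads are retained."""
    spec = spec or TrimSpec()
    r1_seq, r1_qual = _trim_read(
        pair.r1_seq, pair.r1_qual, spec.r1_three_prime_adapters, None, spec
    )
    r2_seq, r2_qual = _trim_read(
        pair.r2_seq,
        pair.r2_qual,
        (spec.r2_three_prime_adapter,),
        spec.r2_five_prime_adapter,
        spec,
    )
    return ReadPair(pair.id, r1_seq, r2_seq, r1_qual, r2_qual, truth=pair.truth)


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 12,
    max_mismatch_frac: float = 0.1,
    ambiguity_margin: int = 2,
) -> Optional[MergedRead]:
    """Merge a trimmed pair into one insert sequence, or None.

    Every signed offset of reverse-complement(R2) against R1 with overlap at
    least ``min_overlap`` is scored by mismatch count.  The merge is accepted
    only if the best overlap's mismatch fraction is at most
    ``max_mismatch_frac`` and it beats the runner-up by at least
    ``ambiguity_margin`` fewer mismatches.  Disagreements are resolved by the
    higher-quality base (ties to R1).  Overhangs incompatible with the
    forward/reverse amplicon architecture (R2 sequence 5' of R1's start, R1
    sequence 3' of R2's anchored insert end) are 1-2 nt adapter read-through
    relics below the trimmer's minimum overlap and are clipped; the clipped
    count is recorded.
    """
    r1, q1 = pair.r1_seq, pair.r1_qual
    s2 = revcomp(pair.r2_seq)
    q2 = pair.r2_qual[::-1]
    l1, l2 = len(r1), len(s2)
    if min(l1, l2) < min_overlap:
        return None

    offsets = np.arange(-(l2 - 1), l1)  # offset of s2[0] relative to r1[0]
    overlaps = np.minimum(l1, offsets + l2) - np.maximum(0, offsets)
    matches = shift_matches(r1, s2)
    mism = overlaps - matches
    ok = overlaps >= min_overlap
    if not ok.any():
        return None
    cand = np.flatnonzero(ok)
    order = np.argsort(mism[cand], kind="stable")
    best = cand[order[0]]
    best_mism = int(mism[best])
    best_ov = int(overlaps[best])
    if best_mism > max_mismatch_frac * best_ov:
        return None
    if order.size > 1:
        second_mism = int(mism[cand[order[1]]])
        if second_mism - best_mism < ambiguity_margin:
            return None

    d = int(offsets[best])
    a0, a1 = max(0, d), max(0, d) + best_ov  # overlap interval on r1
    b0 = max(0, -d)  # overlap start on s2
    c1, c2 = encode(r1[a0:a1]), encode(s2[b0 : b0 + best_ov])
    p1, p2 = encode(q1[a0:a1]), encode(q2[b0 : b0 + best_ov])
    cons = decode(np.where((c1 == c2) | (p1 >= p2), c1, c2))
    consq = decode(np.maximum(p1, p2))
    seq = r1[:a0] + cons + s2[b0 + best_ov :]
    qual = q1[:a0] + consq + q2[b0 + best_ov :]
    clipped = b0 + (l1 - a1)  # read-through relics outside the insert
    return MergedRead(
        id=pair.id,
        seq=seq,
        qual=qual,
        overlap_len=best_ov,
        mismatches_in_overlap=best_mism,
        clipped_overhang=clipped,
    )


def preprocess_batch(
    pairs: Iterable[ReadPair],
    spec: Optional[TrimSpec] = None,
    min_overlap: int = 12,
    max_mismatch_frac: float = 0.1,
    ambiguity_margin: int = 2,
) -> tuple[list[MergedRead], dict]:
    """Trim and merge a batch; returns merged reads plus QC counters."""
    spec = spec or TrimSpec()
    merged: list[MergedRead] = []
    n_in = n_trimmed = 0
    for pair in pairs:
        n_in += 1
        trimmed = trim_adapters(pair, spec)
        if len(trimmed.r1_seq) < len(pair.r1_seq) or len(trimmed.r2_seq) < len(pair.r2_seq):
            n_trimmed += 1
        m = merge_pair(trimmed, min_overlap, max_mismatch_frac, ambiguity_margin)
        if m is not None:
            merged.append(m)
    qc = qc_summary(n_in, n_trimmed, len(merged))
    return merged, qc


def qc_summary(pairs_in: int, pairs_trimmed: int, pairs_merged: int) -> dict:
    """Stage counters: pairs in, trimmed, merged, and the merge rate."""
    return {
        "pairs_in": pairs_in,
        "pairs_trimmed": pairs_trimmed,
        "pairs_merged": pairs_merged,
        "merge_rate": (pairs_merged / pairs_in) if pairs_in else 0.0,
    }
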