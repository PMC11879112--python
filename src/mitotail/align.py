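"""Glocal alignment of tail-trimmed reads to a small mitochondrial reference.

The reference is a ~16.5 kb (or toy ~2 kb) sequence, so a heavyweight
FM-index aligner is unnecessary: reads are anchored by exact k-mer seeds and
extended with a banded affine-gap dynamic program.  Alignments are glocal
(the whole read against a local reference window, no soft clipping), mirroring
the end-to-end mode of the short-read aligner whose behaviour this pipeline
reproduces.  Scoring: +2 match, -3 mismatch, -5 first gap base, -2 each
additional gap base; a read is reported mapped when its best score reaches
``min_score_fraction`` of the perfect-match score.

The reference is treated as linear; the assayed 3' ends are internal, so
origin-spanning reads do not arise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._util import revcomp
from .simulate import MitoReference

_NEG = -(10**9)


@dataclass(frozen=True)
class AlnParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5  # score of the first base of a gap
    gap_extend: int = -2  # each additional gap base
    seed_length: int = 16
    min_score_fraction: float = 0.6
    band: int = 12  # half-width of the DP band (max net indel per read)
    seed_step: int = 4
    rescue_seed_length: int = 8  # fallback k when no primary seed survives

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass(frozen=True)
class Alignment:
    read_id: str
    ref_start: int
    strand: str
    cigar: str
    score: int
    unique: bool = True

    @property
    def mapped(self) -> bool:
        return True


@dataclass(frozen=True)
class Unmapped:
    read_id: str
    reason: str

    @property
    def mapped(self) -> bool:
        return False


class ReferenceIndex:
    """Exact k-mer index of the forward reference strand.

    Secondary k-mer sizes (the rescue seed) are built lazily on first use and
    cached, so a batch pays the indexing cost once.
    """

    def __init__(self, ref: MitoReference, k: int):
        self.k = k
        self._ref = ref
        self._tables: dict[int, dict[str, list[int]]] = {k: self._build(k)}

    def _build(self, k: int) -> dict[str, list[int]]:
        table: dict[str, list[int]] = {}
        seq = self._ref.sequence
        for i in range(len(seq) - k + 1):
            table.setdefault(seq[i : i + k], []).append(i)
        return table

    def lookup(self, kmer: str, k: Optional[int] = None) -> list[int]:
        k = self.k if k is None else k
        if k not in self._tables:
            self._tables[k] = self._build(k)
        return self._tables[k].get(kmer, [])


def _candidate_diagonals(
    seq: str, index: ReferenceIndex, step: int, band: int, k: Optional[int] = None
) -> list[int]:
    """Cluster seed hits into candidate read-start diagonals."""
    k = index.k if k is None else k
    starts = list(range(0, len(seq) - k + 1, step))
    if starts and starts[-1] != len(seq) - k:
        starts.append(len(seq) - k)
    diags = set()
    for s in starts:
        for p in index.lookup(seq[s : s + k], k):
            diags.add(p - s)
    clustered: list[int] = []
    for d in sorted(diags):
        if not clustered or d - clustered[-1] > band:
            clustered.append(d)
    return clustered


def _banded_glocal(
    seq: str, window: str, params: AlnParams
) -> Optional[tuple[int, int, str]]:
    """Align ``seq`` end-to-end against ``window`` with free reference ends.

    Returns (score, start column in window, CIGAR) for the best path through
    a band of half-width ``params.band`` around the leading diagonal, or None
    if no complete path fits in the band.  NUL characters in ``window`` mark
    positions outside the reference (edge padding that keeps the band
    centred); they can never be matched or deleted.
    """
    m, n = len(seq), len(window)
    b = params.band
    w = 2 * b + 1
    mt, mm, go, ge = params.match, params.mismatch, params.gap_open, params.gap_extend

    H = np.full((m + 1, w), _NEG, dtype=np.int64)
    E = np.full((m + 1, w), _NEG, dtype=np.int64)
    F = np.full((m + 1, w), _NEG, dtype=np.int64)
    PH = np.zeros((m + 1, w), dtype=np.uint8)  # 0 diag, 1 from E, 2 from F
    PE = np.zeros((m + 1, w), dtype=np.uint8)  # 0 open, 1 extend
    PF = np.zeros((m + 1, w), dtype=np.uint8)

    for c in range(w):
        if c <= n:
            H[0, c] = 0  # free reference prefix: start at column j = c
    for i in range(1, m + 1):
        base = seq[i - 1]
        Hp, Ep, Fp = H[i - 1], E[i - 1], F[i - 1]
        Hi, Ei, Fi = H[i], E[i], F[i]
        for c in range(w):
            j = i + c
            if j > n:
                break
            # F: gap in the reference (insertion), consumes a read base
            if c + 1 < w:
                fo, fe = Hp[c + 1] + go, Fp[c + 1] + ge
                if fo >= fe:
                    Fi[c] = fo
                else:
                    Fi[c], PF[i, c] = fe, 1
            ch = window[j - 1]
            # E: gap in the read (deletion), consumes a reference base
            if c >= 1 and ch != "\0":
                eo, ee = Hi[c - 1] + go, Ei[c - 1] + ge
                if eo >= ee:
                    Ei[c] = eo
                else:
                    Ei[c], PE[i, c] = ee, 1
            d = _NEG if ch == "\0" else Hp[c] + (mt if base == ch else mm)
            best, ptr = d, 0
            if Ei[c] > best:
                best, ptr = Ei[c], 1
            if Fi[c] > best:
                best, ptr = Fi[c], 2
            Hi[c] = best
            PH[i, c] = ptr

    valid = [c for c in range(w) if m + c <= n]
    if not valid or max(H[m, c] for c in valid) <= _NEG // 2:
        return None
    c = min(valid, key=lambda cc: (-H[m, cc], cc))
    score = int(H[m, c])

    ops: list[str] = []
    i, state = m, "H"
    while i > 0 or state != "H":
        if state == "H":
            p = PH[i, c]
            if p == 0:
                ops.append("M")
                i -= 1
            elif p == 1:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            nxt = "H" if PE[i, c] == 0 else "E"
            c -= 1
            state = nxt
        else:
            ops.append("I")
            nxt = "H" if PF[i, c] == 0 else "F"
            i -= 1
            c += 1
            state = nxt
    start = c  # j = i + c with i == 0
    ops.reverse()
    cigar = []
    run, prev = 0, ""
    for op in ops:
        if op == prev:
            run += 1
        else:
            if prev:
                cigar.append(f"{run}{prev}")
            run, prev = 1, op
    cigar.append(f"{run}{prev}")
    return score, start, "".join(cigar)


def _evaluate_candidate(
    seq: str, ref_seq: str, diag: int, params: AlnParams
) -> Optional[tuple[int, int, str]]:
    """Score one candidate diagonal; returns (score, ref_start, cigar)."""
    m = len(seq)
    # exact-match fast path: a full-length identity is always optimal
    if 0 <= diag and diag + m <= len(ref_seq) and ref_seq[diag : diag + m] == seq:
        return params.match * m, diag, f"{m}M"
    ws = diag - params.band
    we = diag + m + params.band
    lpad, rpad = max(0, -ws), max(0, we - len(ref_seq))
    core = ref_seq[max(0, ws) : min(len(ref_seq), we)]
    if not core:
        return None
    res = _banded_glocal(seq, "\0" * lpad + core + "\0" * rpad, params)
    if res is None:
        return None
    score, start, cigar = res
    return score, ws + start, cigar


def align_read(
    body_seq: str,
    ref: MitoReference,
    params: Optional[AlnParams] = None,
    index: Optional[ReferenceIndex] = None,
    read_id: str = "read",
) -> Alignment | Unmapped:
    """Map one tail-trimmed read to the reference, or report why not.

    Both strands are seeded; every candidate diagonal is scored and the
    best-scoring alignment returned if it reaches ``min_score_fraction`` of
    the perfect score.  Ties on score are broken by leftmost reference start,
    then plus strand, and flagged non-unique.
    """
    params = params or AlnParams()
    if len(body_seq) < params.seed_length:
        return Unmapped(read_id, "shorter than seed length")
    index = index or ReferenceIndex(ref, params.seed_length)
    if index.k != params.seed_length:
        raise ValueError("index k-mer size does not match params.seed_length")

    threshold = params.min_score_fraction * params.match * len(body_seq)
    strands = (("+", body_seq), ("-", revcomp(body_seq)))

    def _collect(k: Optional[int]) -> dict[tuple[int, str], tuple[int, str]]:
        found: dict[tuple[int, str], tuple[int, str]] = {}
        for strand, seq in strands:
            for diag in _candidate_diagonals(seq, index, params.seed_step, params.band, k):
                res = _evaluate_candidate(seq, ref.sequence, diag, params)
                if res is None:
                    continue
                score, ref_start, cigar = res
                key = (ref_start, strand)
                if key not in found or score > found[key][0]:
                    found[key] = (score, cigar)
        return found

    results = _collect(None)
    best_score = max((score for score, _ in results.values()), default=_NEG)
    if best_score < threshold and params.rescue_seed_length < params.seed_length:
        # a heavily mutated read can lose every long seed; retry with short ones
        for key, val in _collect(params.rescue_seed_length).items():
            if key not in results or val[0] > results[key][0]:
                results[key] = val
        best_score = max((score for score, _ in results.values()), default=_NEG)

    if not results:
        return Unmapped(read_id, "no seed match")
    if best_score < threshold:
        return Unmapped(read_id, "best score below threshold")
    optima = sorted(
        (start, strand)
        for (start, strand), (score, _) in results.items()
        if score == best_score
    )
    start, strand = optima[0]
    return Alignment(
        read_id=read_id,
        ref_start=start,
        strand=strand,
        cigar=results[(start, strand)][1],
        score=best_score,
        unique=len(optima) == 1,
    )


def align_batch(
    reads: Iterable[tuple[str, str]],
    ref: MitoReference,
    params: Optional[AlnParams] = None,
) -> tuple[list[Alignment | Unmapped], dict]:
    """Align (read_id, body_seq) records; returns alignments plus counters."""
    params = params or AlnParams()
    index = ReferenceIndex(ref, params.seed_length)
    out: list[Alignment | Unmapped] = []
    for read_id, seq in reads:
        out.append(align_read(seq, ref, params, index=index, read_id=read_id))
    return out, alignment_stats(out)


def alignment_stats(alignments: Sequence[Alignment | Unmapped]) -> dict:
    mapped = [a for a in alignments if a.mapped]
    multi = [a for a in mapped if not a.unique]
    return {
        "total": len(alignments),
        "mapped": len(mapped),
        "unmapped": len(alignments) - len(mapped),
        "multi": len(multi),
    }


def write_sam(
    alignments: Sequence[Alignment | Unmapped],
    ref: MitoReference,
    path,
    seqs: Optional[dict[str, str]] = None,
) -> None:
    """Write alignments as a standard SAM file (1-based POS, AS score tag).

    ``seqs`` maps read id to the tail-trimmed read sequence; minus-strand
    records store the reverse complement, per the SAM convention.  Non-unique
    alignments get MAPQ 0, unique ones MAPQ 60; unmapped reads are emitted as
    flag-4 records.
    """
    import pysam

    seqs = seqs or {}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": ref.name, "LN": len(ref.sequence)}],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as handle:
        for aln in alignments:
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.read_id
            seq = seqs.get(aln.read_id)
            if not aln.mapped:
                rec.flag = 4
                rec.reference_id = -1
                rec.reference_start = -1
                if seq:
                    rec.query_sequence = seq
                handle.write(rec)
                continue
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = 0
            rec.reference_start = aln.ref_start
            rec.mapping_quality = 60 if aln.unique else 0
            rec.cigarstring = aln.cigar
            if seq:
                rec.query_sequence = seq if aln.strand == "+" else revcomp(seq)
            rec.set_tag("AS", aln.score)
            handle.write(rec)


def read_sam(path) -> list[Alignment | Unmapped]:
    """Read back a SAM file written by :func:`write_sam`."""
    import pysam

    out: list[Alignment | Unmapped] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped:
                out.append(Unmapped(rec.query_name, "unmapped in SAM"))
                continue
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    ref_start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    cigar=rec.cigarstring,
                    score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                    unique=rec.mapping_quality > 0,
                )
            )
    return out
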