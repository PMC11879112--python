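"""Terminal poly(A) detection, trimming, and per-read tail-length calls.

Merged reads carrying at least ``min_terminal_a`` A's at their 3' end (an
exact, zero-error check) are retained; their maximal terminal A-run is then
trimmed off and recorded as the read's poly(A) tail length.  The exact run is
the default because the simulator writes substitution-free tails; a tolerant
mode that allows up to 10% non-A bases inside the run is available for
error-rate robustness (a single substitution inside a long homopolymer
otherwise truncates the called tail and leaves untemplated A's on the body).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .preprocess import MergedRead


@dataclass(frozen=True)
class TailSpec:
    min_terminal_a: int = 3
    exact_match: bool = True
    max_non_a_frac: float = 0.1  # tolerant mode only

    def __post_init__(self) -> None:
        if self.min_terminal_a < 1:
            raise ValueError("min_terminal_a must be >= 1")


@dataclass(frozen=True)
class TailCall:
    read_id: str
    tail_length: int
    body_seq: str


def has_terminal_a_run(seq: str, spec: Optional[TailSpec] = None) -> bool:
    """True iff the final ``min_terminal_a`` bases are all A (exact)."""
    spec = spec or TailSpec()
    if len(seq) < spec.min_terminal_a:
        return False
    return seq[-spec.min_terminal_a :] == "A" * spec.min_terminal_a


def trim_poly_a(seq: str, spec: Optional[TailSpec] = None) -> tuple[str, int]:
    """Split a read into (tail-trimmed body, tail length).

    Exact mode removes the maximal terminal A-run, so
    ``body + "A" * tail == seq`` always holds.  Tolerant mode takes the
    longest suffix that starts with an A and contains at most
    ``floor(max_non_a_frac * suffix_length)`` non-A bases; the tail length is
    that suffix length.  A read with no terminal A is returned unchanged with
    tail 0; an all-A read yields an empty (unmappable) body.
    """
    spec = spec or TailSpec()
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    if spec.exact_match:
        return seq[:i], n - i
    if i == n:  # no terminal A at all
        return seq, 0
    best = n - i
    non_a = 0
    for k in range(n - i + 1, n + 1):
        if seq[n - k] != "A":
            non_a += 1
        elif non_a <= int(spec.max_non_a_frac * k):
            best = k
    return seq[: n - best], best


def tail_table(
    reads: Iterable[MergedRead], spec: Optional[TailSpec] = None
) -> tuple[list[TailCall], dict]:
    """One TailCall per read passing the terminal-A filter, plus counters."""
    spec = spec or TailSpec()
    calls: list[TailCall] = []
    n_in = n_no_tail = 0
    for read in reads:
        n_in += 1
        if not has_terminal_a_run(read.seq, spec):
            n_no_tail += 1
            continue
        body, tail = trim_poly_a(read.seq, spec)
        calls.append(TailCall(read_id=read.id, tail_length=tail, body_seq=body))
    counts = {"reads_in": n_in, "reads_without_tail": n_no_tail, "reads_with_tail": len(calls)}
    return calls, counts
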