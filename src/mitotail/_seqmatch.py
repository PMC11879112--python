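"""Vectorised ungapped sequence matching.

Both adapter trimming and pair merging reduce to the same primitive: slide one
sequence along another and, at every offset, count matching bases over the
region where the two overlap.  Computed as a four-channel cross-correlation so
a single call replaces an O(len(a) * len(b)) Python loop.
"""

from __future__ import annotations

import numpy as np

from ._util import encode

_CHANNELS = (ord("A"), ord("C"), ord("G"), ord("T"))


def shift_matches(a: str, b: str) -> np.ndarray:
    """Matches between ``a`` and ``b`` placed at every signed offset.

    Returns an integer array ``m`` of length ``len(a) + len(b) - 1`` where
    ``m[s + len(b) - 1]`` is the number of positions ``i`` with
    ``b[i] == a[i + s]`` for the offset ``s`` of ``b[0]`` relative to ``a[0]``,
    ``s`` ranging over ``[-(len(b) - 1), len(a) - 1]``.  Only the overlapping
    region contributes; bases outside either sequence are ignored.
    """
    ua, ub = encode(a), encode(b)
    out = np.zeros(len(ua) + len(ub) - 1)
    for c in _CHANNELS:
        out += np.correlate((ua == c).astype(np.float64), (ub == c).astype(np.float64), "full")
    return np.rint(out).astype(np.int64)


def overlap_lengths_3p(read_len: int, adapter_len: int, starts: np.ndarray) -> np.ndarray:
    """Overlap size when an adapter is placed at ``starts`` within a read,
    running off the read's 3' end where necessary."""
    return np.minimum(adapter_len, read_len - starts)
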