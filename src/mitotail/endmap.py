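"""3'-end mapping: per-read terminal positions, scaled depth tracks, and
canonical / alternate / other end classification.

Each mapped, tail-trimmed read contributes one count at the reference
position of its 3'-terminal templated nucleotide (computed from the CIGAR
reference span); counts are scaled to reads per 1000 mapped so tracks are
comparable across libraries.  A read's end is "canonical" when it coincides
with the annotated transcript end, "alternate" when it lies the annotated
offset upstream in transcript sense (for MT-ND3-like genes, 3 nt upstream,
missing the final U of the stop codon), and "other" elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .align import Alignment, Unmapped
from .simulate import GeneEndAnnotation, MitoReference

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


@dataclass(frozen=True)
class EndProfile:
    """Scaled 3'-terminal-nucleotide depth over the reference.

    ``depth`` holds, per position, the count of read 3' ends multiplied by
    ``scale = 1000 / total_mapped``, so the track sums to 1000 whenever at
    least one read is mapped.
    """

    ref_name: str
    depth: np.ndarray
    scale: float
    total_mapped: int


@dataclass(frozen=True)
class EndClassification:
    read_id: str
    end_position: int
    label: str
    gene: Optional[str]


def reference_span(cigar: str) -> int:
    """Total reference length consumed by a CIGAR string.

    Sums M/D/N/=/X operation lengths; insertions and clips consume no
    reference.  Malformed CIGARs raise with the offending token named.
    """
    if not cigar:
        raise ValueError("empty CIGAR")
    pos = 0
    span = 0
    for tok in _CIGAR_TOKEN.finditer(cigar):
        if tok.start() != pos:
            raise ValueError(f"malformed CIGAR at {cigar[pos:]!r}")
        if tok.group(2) in _REF_CONSUMING:
            span += int(tok.group(1))
        pos = tok.end()
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR at {cigar[pos:]!r}")
    return span


def three_prime_position(aln: Alignment) -> int:
    """Reference coordinate of the transcript's 3'-terminal templated base.

    Plus-strand reads end at ``ref_start + reference_span - 1``; minus-strand
    reads at ``ref_start`` (the alignment's left edge is the transcript's 3'
    terminus in reference coordinates).
    """
    if not isinstance(aln, Alignment):
        raise ValueError("three_prime_position requires a mapped alignment")
    if aln.strand == "+":
        return aln.ref_start + reference_span(aln.cigar) - 1
    return aln.ref_start


def _usable(alignments: Iterable[Alignment | Unmapped]) -> list[Alignment]:
    """Mapped, unique alignments (multi-mappers are excluded downstream)."""
    return [a for a in alignments if isinstance(a, Alignment) and a.unique]


def end_depth_profile(
    alignments: Sequence[Alignment | Unmapped], ref: MitoReference
) -> EndProfile:
    """Scaled 3'-terminal depth track over the reference.

    Each mapped (unique) read contributes exactly one count at its 3'
    position; counts are multiplied by 1000 / total mapped reads.  With zero
    mapped reads an all-zero profile is returned (no division).
    """
    counts = np.zeros(len(ref.sequence), dtype=np.float64)
    usable = _usable(alignments)
    for aln in usable:
        counts[three_prime_position(aln)] += 1
    total = len(usable)
    scale = 1000.0 / total if total else 0.0
    return EndProfile(ref_name=ref.name, depth=counts * scale, scale=scale, total_mapped=total)


def write_bedgraph(profile: EndProfile, path) -> None:
    """Write the depth track as bedGraph (0-based half-open, zeros omitted)."""
    with open(path, "w") as handle:
        for pos in np.flatnonzero(profile.depth):
            handle.write(
                f"{profile.ref_name}\t{pos}\t{pos + 1}\t{profile.depth[pos]:.6g}\n"
            )


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    rows = []
    with open(path) as handle:
        for line in handle:
            chrom, start, end, value = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return rows


def classify_end(
    end_position: int,
    annotation: GeneEndAnnotation,
    tolerance: int = 0,
    read_id: str = "",
) -> EndClassification:
    """Label a 3'-end position against one gene's annotation.

    Canonical wins on (only possible with tolerance > 0) overlap with the
    alternate window.
    """
    if abs(end_position - annotation.canonical_end) <= tolerance:
        label = "canonical"
    elif abs(end_position - annotation.alternate_end) <= tolerance:
        label = "alternate"
    else:
        label = "other"
    return EndClassification(
        read_id=read_id, end_position=end_position, label=label, gene=annotation.gene
    )


def classify_alignments(
    alignments: Sequence[Alignment | Unmapped],
    genes: Sequence[GeneEndAnnotation],
    tolerance: int = 0,
) -> list[EndClassification]:
    """Classify every mapped, unique read against its gene.

    The gene is the strand-matched annotation whose canonical end is nearest
    the read's 3' position; reads on a strand with no annotated gene are
    labelled "other" with no gene.
    """
    by_strand: dict[str, list[GeneEndAnnotation]] = {"+": [], "-": []}
    for g in genes:
        by_strand[g.strand].append(g)
    out = []
    for aln in _usable(alignments):
        pos = three_prime_position(aln)
        candidates = by_strand[aln.strand]
        if not candidates:
            out.append(EndClassification(aln.read_id, pos, "other", None))
            continue
        gene = min(candidates, key=lambda g: abs(pos - g.canonical_end))
        out.append(classify_end(pos, gene, tolerance, read_id=aln.read_id))
    return out


def end_usage_fractions(
    classifications: Sequence[EndClassification], gene: Optional[str] = None
) -> dict[str, float]:
    """Fractions of canonical / alternate / other ends (summing to 1)."""
    subset = [c for c in classifications if gene is None or c.gene == gene]
    if not subset:
        raise ValueError(f"no classified reads{f' for gene {gene}' if gene else ''}")
    n = len(subset)
    return {
        label: sum(c.label == label for c in subset) / n
        for label in ("canonical", "alternate", "other")
    }


def end_usage_from_positions(
    positions: np.ndarray, annotation: GeneEndAnnotation, tolerance: int = 0
) -> dict[str, float]:
    """Vectorised end-usage fractions straight from 3'-end coordinates.

    Same classification rule as :func:`classify_end`; used where per-read
    records are not needed (e.g. repeated statistical simulations).
    """
    positions = np.asarray(positions)
    if positions.size == 0:
        raise ValueError("no positions to classify")
    canonical = np.abs(positions - annotation.canonical_end) <= tolerance
    alternate = (~canonical) & (np.abs(positions - annotation.alternate_end) <= tolerance)
    n = positions.size
    nc, na = int(canonical.sum()), int(alternate.sum())
    return {
        "canonical": nc / n,
        "alternate": na / n,
        "other": (n - nc - na) / n,
    }
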