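"""Synthetic poly(A)-capture amplicon simulator.

Emulates the wet-lab design of a poly(A) tail capture experiment on
mitochondrial mRNA: transcripts end either at the gene's canonical 3' end, at
an alternate end a few nucleotides upstream, or elsewhere; a poly(A) tail of
configurable length is appended; a DNA adaptor oligonucleotide is ligated to
the tail; and the amplicon bounded by a gene-specific primer and an
anti-adaptor primer is read as an Illumina-style paired-end fragment with a
configurable per-base substitution error rate.  Every simulated read pair
carries its ground truth (gene, 3'-end coordinate, tail length), so the whole
downstream pipeline is testable without any external data.

The toy reference stands in for the human mitochondrial genome; the pipeline
accepts any FASTA, so a real chrM sequence can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, revcomp

# The capture adaptor ligated to mRNA 3' ends, as it appears at the 3' end of
# read 1 (and reverse-complemented at the 5' end of read 2).
CAPTURE_ADAPTOR = "ATGTGAGATCATGCACAGTCATA"
# The anti-adaptor primer sequence seen at the 5' end of read 2.
ANTI_ADAPTOR_PRIMER = revcomp(CAPTURE_ADAPTOR)
# Library (sequencing) adapter read through when the insert is shorter than
# the read length; Nextera-style.
SEQUENCING_ADAPTER = "CTGTCTCTTATACACATCTGACGCTGCCGACGA"

END_CATEGORIES = ("canonical", "alternate", "other")


@dataclass(frozen=True)
class GeneEndAnnotation:
    """Per-gene 3'-end annotation.

    ``canonical_end`` is the 0-based reference coordinate of the transcript's
    final templated nucleotide.  The alternate end lies ``alternate_offset``
    nucleotides upstream in transcript sense (for MT-ND3-like genes the
    default of 3 removes the final three nucleotides including the last U).
    ``body_length`` is the sense-strand extent of the gene body used for
    primer placement and bounds checking.
    """

    gene: str
    strand: str
    canonical_end: int
    alternate_offset: int = 3
    terminal_base: str = "T"
    body_length: int = 120

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.alternate_offset < 1:
            raise ValueError("alternate_offset must be >= 1")
        if self.alternate_offset >= self.body_length:
            raise ValueError("alternate end falls outside the gene body")

    def sense_upstream(self, k: int) -> int:
        """Reference coordinate ``k`` nt upstream of the canonical end in
        transcript sense."""
        return self.canonical_end - k if self.strand == "+" else self.canonical_end + k

    @property
    def alternate_end(self) -> int:
        return self.sense_upstream(self.alternate_offset)

    def body_interval(self) -> tuple[int, int]:
        """0-based half-open reference interval covered by the gene body."""
        if self.strand == "+":
            return self.canonical_end - self.body_length + 1, self.canonical_end + 1
        return self.canonical_end, self.canonical_end + self.body_length


@dataclass(frozen=True)
class MitoReference:
    """A (toy or real) mitochondrial reference with annotated gene ends."""

    name: str
    sequence: str
    circular: bool = True
    genes: tuple[GeneEndAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        if set(self.sequence) - set(BASES):
            raise ValueError("reference alphabet restricted to ACGT")
        for g in self.genes:
            if not 0 <= g.canonical_end < len(self.sequence):
                raise ValueError(
                    f"gene {g.gene}: canonical end {g.canonical_end} outside "
                    f"reference of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, name: str) -> GeneEndAnnotation:
        for g in self.genes:
            if g.gene == name:
                return g
        raise KeyError(name)


@dataclass(frozen=True)
class GeneSpec:
    """Input description of a gene to place on the toy reference."""

    name: str
    canonical_end: int
    strand: str = "+"
    alternate_offset: int = 3
    body_length: int = 120


@dataclass(frozen=True)
class TailModel:
    """Poly(A)-tail length distribution: fixed, normal (rounded) or geometric.

    Sampled lengths are non-negative integers clipped at ``min_length``.  For
    the geometric model ``mean`` is the distribution mean (``mean >=
    min_length`` required).
    """

    kind: str
    length: Optional[int] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    min_length: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        if self.kind == "fixed":
            if self.length is None or self.length < self.min_length:
                raise ValueError("fixed tail model needs length >= min_length")
        elif self.kind == "normal":
            if self.mean is None or self.sd is None or self.sd < 0:
                raise ValueError("normal tail model needs mean and sd >= 0")
        elif self.kind == "geometric":
            if self.mean is None or self.mean < self.min_length:
                raise ValueError("geometric tail model needs mean >= min_length")
        else:
            raise ValueError(f"unknown tail model kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.length, dtype=np.int64)
        if self.kind == "normal":
            draws = np.rint(rng.normal(self.mean, self.sd, size=n)).astype(np.int64)
            return np.maximum(draws, self.min_length)
        # geometric, support {min_length, min_length + 1, ...}
        p = 1.0 / (self.mean - self.min_length + 1.0)
        return self.min_length + rng.geometric(p, size=n) - 1


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated library (one gene's amplicon pool)."""

    n_pairs: int
    end_usage: Mapping[str, float]
    tail_model: TailModel
    adaptor_seq: str = CAPTURE_ADAPTOR
    sequencing_adapter: str = SEQUENCING_ADAPTER
    gsp_seq: Optional[str] = None
    gsp_length: int = 20
    gsp_distance: int = 100
    other_offset: int = 7
    read_length: int = 150
    substitution_error_rate: float = 0.0
    indel_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        total = sum(self.end_usage.get(c, 0.0) for c in END_CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"end_usage fractions must sum to 1, got {total}")
        if set(self.end_usage) - set(END_CATEGORIES):
            raise ValueError(f"end_usage keys must be from {END_CATEGORIES}")
        for rate in (self.substitution_error_rate, self.indel_error_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("error rates must be in [0, 1)")

    def usage_vector(self) -> np.ndarray:
        return np.array([self.end_usage.get(c, 0.0) for c in END_CATEGORIES])


@dataclass(frozen=True)
class ReadPair:
    """One paired-end record with optional simulation truth attached."""

    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str
    truth: Optional[tuple[str, int, int]] = None  # (gene, end_coordinate, tail_length)

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError("sequence and quality lengths must match")


def build_toy_reference(
    seed: int,
    length: int = 2000,
    gene_specs: Sequence[GeneSpec] = (),
    guard: bool = True,
    name: str = "chrM_toy",
) -> MitoReference:
    """Generate a random ACGT reference with annotated gene 3' ends.

    With ``guard`` (default), the reference is locally edited so that tail
    trimming cannot erode templated sequence: the canonical terminal base is
    forced to T on the sense strand (a terminal U on the transcript) and the
    ``alternate_offset + 7`` sense-strand bases immediately upstream of each
    canonical end carry no A, deep enough that the mismatch-tolerant poly(A)
    trimmer cannot walk past either the canonical or the alternate end.
    Disable the guard to study the resulting known bias.
    """
    if length < 500:
        raise ValueError("reference length must be >= 500")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(BASES), size=length))

    intervals = []
    annotations = []
    for spec in gene_specs:
        ann = GeneEndAnnotation(
            gene=spec.name,
            strand=spec.strand,
            canonical_end=spec.canonical_end,
            alternate_offset=spec.alternate_offset,
            body_length=spec.body_length,
        )
        lo, hi = ann.body_interval()
        if lo < 0 or hi > length:
            raise ValueError(
                f"gene {spec.name} does not fit: body [{lo}, {hi}) vs reference length {length}"
            )
        intervals.append((lo, hi, spec.name))
        annotations.append(ann)

    intervals.sort()
    for (lo1, hi1, n1), (lo2, hi2, n2) in zip(intervals, intervals[1:]):
        if lo2 < hi1:
            raise ValueError(f"gene specs overlap: {n1} and {n2}")

    guarded = []
    for ann in annotations:
        if guard:
            depth = ann.alternate_offset + 7  # protects alternate-end reads too
            if ann.strand == "+":
                seq[ann.canonical_end] = "T"
                for p in range(ann.canonical_end - depth, ann.canonical_end):
                    if seq[p] == "A":
                        seq[p] = rng.choice(["C", "G", "T"])
            else:
                seq[ann.canonical_end] = "A"  # sense base is U/T
                for p in range(ann.canonical_end + 1, ann.canonical_end + depth + 1):
                    if seq[p] == "T":
                        seq[p] = rng.choice(["A", "C", "G"])
        terminal = seq[ann.canonical_end]
        if ann.strand == "-":
            terminal = revcomp(terminal)
        guarded.append(replace(ann, terminal_base=terminal))

    return MitoReference(name=name, sequence="".join(seq), circular=True, genes=tuple(guarded))


def _sample_truths(
    rng: np.random.Generator, cfg: SimConfig, gene: GeneEndAnnotation, n: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (category index, end coordinate, tail length) per simulated read."""
    n = cfg.n_pairs if n is None else n
    cats = rng.choice(3, size=n, p=cfg.usage_vector())
    offsets = np.array([0, gene.alternate_offset, cfg.other_offset])
    sign = -1 if gene.strand == "+" else 1
    ends = gene.canonical_end + sign * offsets[cats]
    tails = cfg.tail_model.sample(rng, n)
    return cats, ends, tails


def sample_transcript_truths(
    cfg: SimConfig, gene: GeneEndAnnotation
) -> list[tuple[int, int]]:
    """Per-read ground truth (3'-end coordinate, tail length) for a library.

    Categories are drawn i.i.d. from ``cfg.end_usage`` ("canonical" at the
    annotated end, "alternate" ``alternate_offset`` nt upstream in sense,
    "other" ``cfg.other_offset`` nt upstream); tail lengths come from the tail
    model.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    _, ends, tails = _sample_truths(rng, cfg, gene)
    return list(zip(ends.tolist(), tails.tolist()))


def _sense_body(ref: MitoReference, gene: GeneEndAnnotation) -> str:
    lo, hi = gene.body_interval()
    body = ref.sequence[lo:hi]
    return body if gene.strand == "+" else revcomp(body)


def _sense_index(gene: GeneEndAnnotation, coord: int) -> int:
    """Position of reference coordinate ``coord`` within the sense-strand body."""
    lo, hi = gene.body_interval()
    return coord - lo if gene.strand == "+" else (hi - 1) - coord


def build_amplicon(
    ref: MitoReference,
    gene: GeneEndAnnotation,
    end_coordinate: int,
    tail_length: int,
    cfg: SimConfig,
) -> str:
    """Amplicon in transcript-sense orientation.

    Layout: gene-specific primer region, templated sequence through the
    transcript's final nucleotide at ``end_coordinate``, ``tail_length``
    non-templated A's, then the capture adaptor.  Sequencing-adapter
    read-through is added at sequencing time (see :func:`sequence_pair`).
    """
    if tail_length < 0:
        raise ValueError("tail_length must be >= 0")
    body = _sense_body(ref, gene)
    end_idx = _sense_index(gene, end_coordinate)
    if not 0 <= end_idx < len(body):
        raise ValueError(f"end coordinate {end_coordinate} outside gene body of {gene.gene}")
    if cfg.gsp_seq is not None:
        gsp_start = body.find(cfg.gsp_seq)
        if gsp_start < 0:
            raise ValueError(f"gene-specific primer not found in {gene.gene} body")
        gsp_end = gsp_start + len(cfg.gsp_seq) - 1
    else:
        gsp_start = _sense_index(gene, gene.canonical_end) - (cfg.gsp_distance - 1)
        gsp_end = gsp_start + cfg.gsp_length - 1
    if gsp_start < 0 or gsp_end > end_idx:
        raise ValueError(
            f"gene-specific primer region not upstream of end coordinate "
            f"{end_coordinate} in {gene.gene}"
        )
    templated = body[gsp_start : end_idx + 1]
    return templated + "A" * tail_length + cfg.adaptor_seq


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hits.size == 0:
        return seq
    idx = np.array([BASES.index(b) for b in arr[hits]])
    arr[hits] = np.array(list(BASES))[(idx + rng.integers(1, 4, size=hits.size)) % 4]
    return "".join(arr)


def _indel(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    out = []
    for b in seq:
        r = rng.random()
        if r < rate:  # deletion
            continue
        if r < 2 * rate:  # insertion before this base
            out.append(rng.choice(list(BASES)))
        out.append(b)
    return "".join(out)


def sequence_pair(
    amplicon: str,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    read_id: str = "read",
    truth: Optional[tuple[str, int, int]] = None,
) -> ReadPair:
    """Read an amplicon as an Illumina-style pair.

    R1 reads the amplicon 5'->3' from the gene-specific primer; R2 reads the
    reverse complement from the anti-adaptor end.  When the insert is shorter
    than the read length the sequencing adapter is read through.  Substitution
    (and, if enabled, indel) errors are applied i.i.d. per base; base
    qualities are constant Q40.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    r1_template = amplicon + cfg.sequencing_adapter
    r2_template = revcomp(amplicon) + cfg.sequencing_adapter
    if cfg.read_length > min(len(r1_template), len(r2_template)):
        raise ValueError("read_length exceeds amplicon plus adapter length")
    r1 = r1_template[: cfg.read_length]
    r2 = r2_template[: cfg.read_length]
    r1 = _indel(_mutate(r1, cfg.substitution_error_rate, rng), cfg.indel_error_rate, rng)
    r2 = _indel(_mutate(r2, cfg.substitution_error_rate, rng), cfg.indel_error_rate, rng)
    return ReadPair(
        id=read_id,
        r1_seq=r1,
        r2_seq=r2,
        r1_qual="I" * len(r1),
        r2_qual="I" * len(r2),
        truth=truth,
    )


def simulate_library(
    ref: MitoReference,
    cfg: SimConfig,
    genes: Optional[Iterable[GeneEndAnnotation]] = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate a full library and its truth table.

    ``cfg.n_pairs`` pairs are split as evenly as possible across ``genes``
    (default: all genes on the reference).  Returns the read pairs and a truth
    DataFrame with one row per pair (read_id, gene, category, end_coordinate,
    tail_length).  Deterministic for a fixed ``cfg.seed``.
    """
    genes = list(ref.genes if genes is None else genes)
    if not genes:
        raise ValueError("no genes to simulate from")
    rng = np.random.default_rng(cfg.seed)
    counts = [cfg.n_pairs // len(genes)] * len(genes)
    for i in range(cfg.n_pairs % len(genes)):
        counts[i] += 1

    pairs: list[ReadPair] = []
    rows = []
    serial = 0
    for gene, n in zip(genes, counts):
        cats, ends, tails = _sample_truths(rng, cfg, gene, n)
        for cat, end, tail in zip(cats.tolist(), ends.tolist(), tails.tolist()):
            read_id = f"sim_{serial:06d}"
            serial += 1
            amplicon = build_amplicon(ref, gene, end, tail, cfg)
            pairs.append(
                sequence_pair(amplicon, cfg, rng=rng, read_id=read_id, truth=(gene.gene, end, tail))
            )
            rows.append(
                {
                    "read_id": read_id,
                    "gene": gene.gene,
                    "category": END_CATEGORIES[cat],
                    "end_coordinate": end,
                    "tail_length": tail,
                }
            )
    truth = pd.DataFrame(
        rows, columns=["read_id", "gene", "category", "end_coordinate", "tail_length"]
    )
    return pairs, truth


# Study-condition presets: wild-type libraries carry mostly canonical ends and
# long tails (matching the longer in vitro construct); knockout-like libraries
# shift end usage toward the truncated alternate end and shorten tails
# (matching the shorter construct).
def wt_preset(seed: int, n_pairs: int = 10_000) -> SimConfig:
    return SimConfig(
        n_pairs=n_pairs,
        end_usage={"canonical": 0.7, "alternate": 0.3, "other": 0.0},
        tail_model=TailModel("normal", mean=51, sd=8, min_length=5),
        seed=seed,
    )


def ko_preset(seed: int, n_pairs: int = 10_000) -> SimConfig:
    return SimConfig(
        n_pairs=n_pairs,
        end_usage={"canonical": 0.35, "alternate": 0.65, "other": 0.0},
        tail_model=TailModel("normal", mean=25, sd=8, min_length=5),
        seed=seed,
    )
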