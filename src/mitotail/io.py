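"""File-format plumbing: FASTQ/FASTA via Biopython, tables as TSV."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import MergedRead
from .simulate import GeneEndAnnotation, MitoReference, ReadPair
from .tailcall import TailCall


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _to_record(read_id: str, seq: str, qual: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
    return rec


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    with _open_text(r1_path, "w") as h1, _open_text(r2_path, "w") as h2:
        for pair in pairs:
            SeqIO.write(_to_record(pair.id, pair.r1_seq, pair.r1_qual), h1, "fastq")
            SeqIO.write(_to_record(pair.id, pair.r2_seq, pair.r2_qual), h2, "fastq")


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    pairs = []
    with _open_text(r1_path, "r") as h1, _open_text(r2_path, "r") as h2:
        for rec1, rec2 in zip(SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq")):
            if rec1.id != rec2.id:
                raise ValueError(f"unpaired FASTQ records: {rec1.id} vs {rec2.id}")
            q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
            q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
            pairs.append(ReadPair(rec1.id, str(rec1.seq), str(rec2.seq), q1, q2))
    return pairs


def write_merged_fastq(reads: Iterable[MergedRead], path) -> None:
    with _open_text(path, "w") as handle:
        for read in reads:
            SeqIO.write(_to_record(read.id, read.seq, read.qual), handle, "fastq")


def read_merged_fastq(path) -> list[MergedRead]:
    out = []
    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(MergedRead(rec.id, str(rec.seq), qual, overlap_len=0, mismatches_in_overlap=0))
    return out


def write_reference_fasta(ref: MitoReference, path) -> None:
    with _open_text(path, "w") as handle:
        SeqIO.write(SeqRecord(Seq(ref.sequence), id=ref.name, description=""), handle, "fasta")


def read_reference_fasta(path, annotation_path=None, circular: bool = True) -> MitoReference:
    with _open_text(path, "r") as handle:
        rec = next(SeqIO.parse(handle, "fasta"))
    genes = tuple(read_annotation_tsv(annotation_path)) if annotation_path else ()
    return MitoReference(
        name=rec.id, sequence=str(rec.seq).upper(), circular=circular, genes=genes
    )


ANNOTATION_COLUMNS = [
    "gene",
    "strand",
    "canonical_end",
    "alternate_offset",
    "terminal_base",
    "body_length",
]


def write_annotation_tsv(genes: Sequence[GeneEndAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "gene": g.gene,
                "strand": g.strand,
                "canonical_end": g.canonical_end,
                "alternate_offset": g.alternate_offset,
                "terminal_base": g.terminal_base,
                "body_length": g.body_length,
            }
            for g in genes
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> list[GeneEndAnnotation]:
    frame = pd.read_csv(path, sep="\t")
    return [
        GeneEndAnnotation(
            gene=row["gene"],
            strand=row["strand"],
            canonical_end=int(row["canonical_end"]),
            alternate_offset=int(row["alternate_offset"]),
            terminal_base=str(row.get("terminal_base", "T")),
            body_length=int(row.get("body_length", 120)),
        )
        for _, row in frame.iterrows()
    ]


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_tail_table(calls: Sequence[TailCall], path) -> None:
    pd.DataFrame(
        [{"read_id": c.read_id, "tail_length": c.tail_length} for c in calls],
        columns=["read_id", "tail_length"],
    ).to_csv(path, sep="\t", index=False)


def write_body_fasta(calls: Sequence[TailCall], path) -> None:
    with _open_text(path, "w") as handle:
        for call in calls:
            SeqIO.write(
                SeqRecord(Seq(call.body_seq), id=call.read_id, description=""),
                handle,
                "fasta",
            )


def read_body_fasta(path) -> list[tuple[str, str]]:
    with _open_text(path, "r") as handle:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
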