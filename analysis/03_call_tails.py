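"""Extract poly(A)-tailed reads and call per-read tail lengths.

Uses the error-tolerant trimmer (the libraries carry sequencing errors, and
a single substitution inside a homopolymer would otherwise truncate the
call).  Writes tails.tsv and bodies.fasta per replicate.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from mitotail.io import read_merged_fastq, write_body_fasta, write_tail_table
from mitotail.tailcall import TailSpec, tail_table

SPEC = TailSpec(exact_match=False)


def main() -> None:
    for sample in common.SAMPLES:
        for rep in common.REPLICATES:
            out = common.rep_dir(sample, rep)
            reads = read_merged_fastq(out / "merged.fastq")
            calls, counts = tail_table(reads, SPEC)
            write_tail_table(calls, out / "tails.tsv")
            write_body_fasta(calls, out / "bodies.fasta")
            (out / "tail_counts.json").write_text(json.dumps(counts, indent=2) + "\n")
            mean_tail = sum(c.tail_length for c in calls) / max(len(calls), 1)
            print(
                f"{sample}/{rep}: {counts['reads_with_tail']}/{counts['reads_in']} "
                f"reads with >=3 terminal A, mean called tail {mean_tail:.1f} nt"
            )


if __name__ == "__main__":
    main()
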