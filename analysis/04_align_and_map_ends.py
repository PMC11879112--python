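"""Align tail-trimmed reads and map 3'-end usage per replicate.

Writes per replicate: SAM alignments, the scaled 3'-terminal depth track
(bedGraph, sums to 1000 by construction), per-read end classifications, and
the per-gene metrics row consumed by the reporting step.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from mitotail.align import align_batch, write_sam
from mitotail.endmap import (
    classify_alignments,
    end_depth_profile,
    end_usage_fractions,
    write_bedgraph,
)
from mitotail.io import read_body_fasta
from mitotail.pipeline import PipelineResult, replicate_metrics
from mitotail.stats import tail_length_summary
from mitotail.tailcall import TailCall


def main() -> None:
    ref = common.reference()
    for sample in common.SAMPLES:
        for rep in common.REPLICATES:
            out = common.rep_dir(sample, rep)
            reads = read_body_fasta(out / "bodies.fasta")
            bodies = dict(reads)
            tails = pd.read_csv(out / "tails.tsv", sep="\t")
            calls = [
                TailCall(r.read_id, int(r.tail_length), bodies[r.read_id])
                for r in tails.itertuples()
            ]
            alignments, stats = align_batch(reads, ref)
            write_sam(alignments, ref, out / "alignments.sam", seqs=dict(reads))
            profile = end_depth_profile(alignments, ref)
            write_bedgraph(profile, out / "end_depth.bedgraph")
            classifications = classify_alignments(alignments, ref.genes)
            fractions = {g.gene: end_usage_fractions(classifications, g.gene) for g in ref.genes}
            result = PipelineResult(
                qc={"pairs_in": len(reads), "pairs_merged": len(reads)},
                merged=[],
                tail_calls=calls,
                tail_counts={"reads_with_tail": len(calls)},
                alignments=alignments,
                aln_stats=stats,
                profile=profile,
                classifications=classifications,
                fractions=fractions,
                tail_summaries=tail_length_summary(calls, classifications),
            )
            metrics = replicate_metrics(result, ref, sample=sample, replicate=rep)
            metrics.drop(columns=["sample", "replicate"]).to_csv(
                out / "metrics.tsv", sep="\t", index=False
            )
            fr = fractions["ND3"]
            print(
                f"{sample}/{rep}: mapped {stats['mapped']}/{stats['total']}, "
                f"canonical {fr['canonical']:.3f}, alternate {fr['alternate']:.3f}, "
                f"depth sum {profile.depth.sum():.1f}"
            )


if __name__ == "__main__":
    main()
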