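"""Simulate the study's libraries: WT and knockout-like triplicates.

Writes, per replicate, paired FASTQ and the truth table, plus the shared toy
mitochondrial reference and gene 3'-end annotation, under results/run/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from mitotail.io import (
    write_annotation_tsv,
    write_fastq_pairs,
    write_reference_fasta,
    write_truth_tsv,
)
from mitotail.simulate import simulate_library


def main() -> None:
    ref = common.reference()
    common.RUN.mkdir(parents=True, exist_ok=True)
    write_reference_fasta(ref, common.RUN / "reference.fasta")
    write_annotation_tsv(ref.genes, common.RUN / "annotation.tsv")

    for sample in common.SAMPLES:
        for i, rep in enumerate(common.REPLICATES):
            cfg = common.library_config(sample, i)
            pairs, truth = simulate_library(ref, cfg)
            out = common.rep_dir(sample, rep)
            out.mkdir(parents=True, exist_ok=True)
            write_fastq_pairs(pairs, out / "reads_R1.fastq", out / "reads_R2.fastq")
            write_truth_tsv(truth, out / "truth.tsv")
            frac = (truth["category"] == "canonical").mean()
            print(
                f"{sample}/{rep}: {len(pairs)} pairs, truth canonical fraction "
                f"{frac:.3f}, mean tail {truth['tail_length'].mean():.1f} nt"
            )
    print(f"libraries written under {common.RUN}")


if __name__ == "__main__":
    main()
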