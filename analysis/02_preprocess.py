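"""Trim adapters and merge each replicate's read pairs.

Writes merged.fastq and qc.json per replicate; prints the merge rates (at
this error rate essentially every pair should merge).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from mitotail.io import read_fastq_pairs, write_merged_fastq
from mitotail.preprocess import preprocess_batch


def main() -> None:
    for sample in common.SAMPLES:
        for rep in common.REPLICATES:
            out = common.rep_dir(sample, rep)
            pairs = read_fastq_pairs(out / "reads_R1.fastq", out / "reads_R2.fastq")
            merged, qc = preprocess_batch(pairs)
            write_merged_fastq(merged, out / "merged.fastq")
            (out / "qc.json").write_text(json.dumps(qc, indent=2) + "\n")
            print(
                f"{sample}/{rep}: merged {qc['pairs_merged']}/{qc['pairs_in']} "
                f"(rate {qc['merge_rate']:.3f})"
            )


if __name__ == "__main__":
    main()
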