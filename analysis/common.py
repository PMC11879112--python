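"""Shared layout and study conditions for the analysis drivers.

The simulated study mirrors the wet-lab design: two conditions (wild-type
and a FASTKD4-knockout-like state) in biological triplicate, one plus-strand
MT-ND3-like gene, 2,000 read pairs per replicate library at a MiSeq-like
substitution error rate of 0.002.  Wild type: 70% canonical ends, tails
~N(51, 8); knockout-like: 35% canonical, tails ~N(25, 8).
"""

from dataclasses import replace
from pathlib import Path

from mitotail.simulate import GeneSpec, build_toy_reference, ko_preset, wt_preset

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "run"

BASE_SEED = 20260927
REF_SEED = 101
N_PAIRS = 2000
ERROR_RATE = 0.002
SAMPLES = ("wt", "ko")
REPLICATES = ("rep1", "rep2", "rep3")


def reference():
    return build_toy_reference(
        seed=REF_SEED, length=2000, gene_specs=[GeneSpec("ND3", 1200)]
    )


def library_config(sample: str, rep_index: int):
    preset = wt_preset if sample == "wt" else ko_preset
    seed = BASE_SEED + 100 * (0 if sample == "wt" else 1) + rep_index
    cfg = preset(seed=seed, n_pairs=N_PAIRS)
    return replace(cfg, substitution_error_rate=ERROR_RATE)


def rep_dir(sample: str, rep: str) -> Path:
    return RUN / sample / rep
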