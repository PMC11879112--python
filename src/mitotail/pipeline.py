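"""End-to-end orchestration: read pairs in, end usage and tail calls out.

One call runs the whole analysis a library goes through — adapter trimming,
pair merging, terminal-A extraction, poly(A) trimming, alignment, 3'-end
depth and classification — and returns every intermediate product, so tests,
the analysis drivers and the acceptance script all share a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .align import Alignment, AlnParams, Unmapped, align_batch
from .endmap import (
    EndClassification,
    EndProfile,
    classify_alignments,
    end_depth_profile,
    end_usage_fractions,
)
from .preprocess import MergedRead, TrimSpec, preprocess_batch
from .simulate import MitoReference, ReadPair, SimConfig, simulate_library
from .stats import TailDistribution, tail_length_summary
from .tailcall import TailCall, TailSpec, tail_table


@dataclass
class PipelineResult:
    qc: dict
    merged: list[MergedRead]
    tail_calls: list[TailCall]
    tail_counts: dict
    alignments: list[Alignment | Unmapped]
    aln_stats: dict
    profile: EndProfile
    classifications: list[EndClassification]
    fractions: dict[str, dict[str, float]]
    tail_summaries: dict[str, TailDistribution] = field(default_factory=dict)


def run_pipeline(
    pairs: Sequence[ReadPair],
    ref: MitoReference,
    trim_spec: Optional[TrimSpec] = None,
    tail_spec: Optional[TailSpec] = None,
    aln_params: Optional[AlnParams] = None,
    tolerance: int = 0,
    min_overlap: int = 12,
    max_mismatch_frac: float = 0.1,
) -> PipelineResult:
    merged, qc = preprocess_batch(
        pairs, trim_spec, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac
    )
    calls, tail_counts = tail_table(merged, tail_spec)
    alignments, aln_stats = align_batch(
        [(c.read_id, c.body_seq) for c in calls], ref, aln_params
    )
    profile = end_depth_profile(alignments, ref)
    classifications = classify_alignments(alignments, ref.genes, tolerance=tolerance)
    fractions = {}
    for gene in ref.genes:
        try:
            fractions[gene.gene] = end_usage_fractions(classifications, gene.gene)
        except ValueError:
            fractions[gene.gene] = None  # no classified reads for this gene
    summaries = tail_length_summary(calls, classifications)
    return PipelineResult(
        qc=qc,
        merged=merged,
        tail_calls=calls,
        tail_counts=tail_counts,
        alignments=alignments,
        aln_stats=aln_stats,
        profile=profile,
        classifications=classifications,
        fractions=fractions,
        tail_summaries=summaries,
    )


def simulate_and_run(
    ref: MitoReference, cfg: SimConfig, **kwargs
) -> tuple[PipelineResult, pd.DataFrame]:
    """Simulate a library from ``cfg`` and push it through the pipeline."""
    pairs, truth = simulate_library(ref, cfg)
    return run_pipeline(pairs, ref, **kwargs), truth


def replicate_metrics(
    result: PipelineResult, ref: MitoReference, sample: str = "", replicate: str = ""
) -> pd.DataFrame:
    """One metrics row per gene for a processed replicate library."""
    rows = []
    for gene in ref.genes:
        fr = result.fractions.get(gene.gene)
        dist = result.tail_summaries.get(gene.gene)
        rows.append(
            {
                "sample": sample,
                "replicate": replicate,
                "gene": gene.gene,
                "pairs_in": result.qc["pairs_in"],
                "pairs_merged": result.qc["pairs_merged"],
                "reads_with_tail": result.tail_counts["reads_with_tail"],
                "mapped": result.aln_stats["mapped"],
                "canonical_fraction": fr["canonical"] if fr else float("nan"),
                "alternate_fraction": fr["alternate"] if fr else float("nan"),
                "other_fraction": fr["other"] if fr else float("nan"),
                "mean_tail_length": dist.mean if dist else float("nan"),
                "median_tail_length": dist.median if dist else float("nan"),
                "sd_tail_length": dist.sd if dist else float("nan"),
            }
        )
    return pd.DataFrame(rows)
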